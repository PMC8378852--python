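#!/usr/bin/env python
"""Corpus-level trends: new reactions per year, median yield over time
with bootstrap CIs, yield histograms with the multiples-of-ten spike
index, cumulative reagent coverage, the ligand Zipf fit and class shares
over time."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, ensure_dirs, load_processed

import pandas as pd

import bhmeta as bm


def main() -> None:
    ensure_dirs()
    processed = load_processed()

    per_year = bm.reactions_per_year(processed, split_by_doc_type=True)
    per_year.to_csv(RESULTS / "reactions_per_year.csv", index=False)
    post = per_year[per_year.year >= 2014]
    print(f"post-2014: {post.patent.sum()} patent vs "
          f"{post.nonpatent.sum()} non-patent reactions")

    yield_ci = bm.median_yield_timeseries(
        processed, window=2, n_boot=2000, seed=7
    )
    yield_ci.to_csv(RESULTS / "median_yield_timeseries.csv", index=False)

    histograms = []
    for doc_type in ("patent", "nonpatent"):
        frame, spike = bm.yield_histogram(processed, doc_type=doc_type)
        frame["doc_type"] = doc_type
        histograms.append(frame)
        print(f"{doc_type}: multiples-of-ten spike index {spike:.2f}")
    pd.concat(histograms, ignore_index=True).to_csv(
        RESULTS / "yield_histogram.csv", index=False
    )

    coverages = []
    for kind in ("solvent", "base", "ligand"):
        frame = bm.cumulative_coverage(processed, kind)
        frame["reagent_kind"] = kind
        coverages.append(frame)
        k = min(2 if kind != "ligand" else 8, len(frame))
        print(f"top-{k} {kind}s cover "
              f"{100 * frame.coverage.iloc[k - 1]:.0f}% of reactions")
    pd.concat(coverages, ignore_index=True).to_csv(
        RESULTS / "cumulative_coverage.csv", index=False
    )

    table, _ = bm.reagent_counts(processed, "ligand")
    exponent, r_squared = bm.zipf_fit(table, min_count=5)
    pd.DataFrame(
        [{"exponent": exponent, "r_squared": r_squared,
          "n_ligands": len(table.items)}]
    ).to_csv(RESULTS / "ligand_zipf_fit.csv", index=False)
    print(f"ligand frequency-rank Zipf exponent {exponent:.2f} "
          f"(r^2 = {r_squared:.3f})")

    shares = bm.class_share_timeseries(processed, "n_class")
    shares.to_csv(RESULTS / "nucleophile_share_timeseries.csv", index=False)
    arom = shares[shares.group == "aromN"]
    pre = arom[arom.year < 2014]["count"].sum() / shares[shares.year < 2014]["count"].sum()
    post_share = (
        arom[arom.year >= 2014]["count"].sum()
        / shares[shares.year >= 2014]["count"].sum()
    )
    print(f"aromatic-N nucleophile share: {100 * pre:.1f}% before 2014, "
          f"{100 * post_share:.1f}% after")


if __name__ == "__main__":
    main()
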