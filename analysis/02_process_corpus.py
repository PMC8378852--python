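#!/usr/bin/env python
"""Run the curation pipeline over the simulated corpus: template and Pd
filters, reagent role resolution, reactant classification and
keep-earliest deduplication.

Writes per-stage counts and the discard log to results/ and the flattened
processed reactions to scratch/ for the downstream analyses.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import CORPUS_CSV, PROCESSED_CSV, RESULTS, SCRATCH, ensure_dirs

import pandas as pd

import bhmeta as bm
from bhmeta.pipeline import processed_to_frame


def main() -> None:
    ensure_dirs()
    if not CORPUS_CSV.exists():
        raise SystemExit(f"{CORPUS_CSV} not found - run 01_simulate_corpus.py first")
    records, errors = bm.parse_reactions(CORPUS_CSV)
    print(f"parsed {len(records)} records ({len(errors)} malformed rows)")

    result = bm.process_corpus(records)
    assert result.conservation_ok(), "pipeline lost records"

    stages = pd.DataFrame([s.__dict__ for s in result.stages])
    stages.to_csv(RESULTS / "pipeline_stage_counts.csv", index=False)
    print(stages.to_string(index=False))

    discards = pd.DataFrame(
        [
            {"record_id": rid, "code": reason.code.value, "detail": reason.detail}
            for rid, reason in result.discards
        ]
    )
    discards.to_csv(SCRATCH / "discard_log.csv", index=False)
    if len(discards):
        summary = discards.code.value_counts().rename_axis("code").reset_index(name="n")
    else:
        summary = pd.DataFrame(columns=["code", "n"])
    summary.to_csv(RESULTS / "discard_summary.csv", index=False)

    dupes = pd.DataFrame(
        [
            {
                "key": g.key,
                "kept": g.kept_id,
                "removed": ";".join(g.removed_ids),
                "yield_spread": g.yield_spread,
            }
            for g in result.duplicate_groups
        ]
    )
    dupes.to_csv(SCRATCH / "duplicate_groups.csv", index=False)

    processed_to_frame(result.processed).to_csv(PROCESSED_CSV, index=False)
    tautomer = sum(1 for p in result.processed if p.tautomer_used)
    print(f"{len(result.processed)} unique curated reactions "
          f"({tautomer} needed the tautomer branch)")
    print(f"processed table -> {PROCESSED_CSV}")


if __name__ == "__main__":
    main()
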