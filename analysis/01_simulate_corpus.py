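#!/usr/bin/env python
"""Generate the default 5,000-reaction synthetic corpus with ground truth.

Writes the raw corpus CSV and ground-truth JSON to scratch/ (inputs for the
later steps) and a small class-composition summary to results/.
"""

import sys
from collections import Counter
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import CORPUS_CSV, N_REACTIONS, RESULTS, SEED, TRUTH_JSON, ensure_dirs

import pandas as pd

from bhmeta.synth import GeneratorConfig, generate, write_corpus


def main() -> None:
    ensure_dirs()
    config = GeneratorConfig(n_reactions=N_REACTIONS, seed=SEED)
    rows, truth = generate(config)
    write_corpus(rows, CORPUS_CSV)
    truth.to_json(TRUTH_JSON)

    classes = Counter(
        (t.e_class, t.n_class) for t in truth.records.values()
    )
    summary = pd.DataFrame(
        [
            {"e_class": e, "n_class": n, "n_records": c}
            for (e, n), c in sorted(classes.items())
        ]
    )
    summary.to_csv(RESULTS / "corpus_class_composition.csv", index=False)

    n_dupes = sum(len(v) - 1 for v in truth.duplicate_groups.values())
    with_yield = sum(1 for r in rows if r["yield_percent"])
    print(f"emitted {len(rows)} rows ({N_REACTIONS} unique reactions, "
          f"{n_dupes} planted cross-source duplicates)")
    print(f"{with_yield} rows ({100 * with_yield / len(rows):.1f}%) report a yield")
    print(f"corpus -> {CORPUS_CSV}")
    print(f"ground truth -> {TRUTH_JSON}")
    print(f"class composition -> {RESULTS / 'corpus_class_composition.csv'}")


if __name__ == "__main__":
    main()
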