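#!/usr/bin/env python
"""Median-yield matrices by reagent and substrate class, plus the product
diversity proxies (molecular weight, heteroatom count, Tanimoto distance)
used to judge how hard each reagent's substrates were."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, ensure_dirs, load_processed

import bhmeta as bm


def main() -> None:
    ensure_dirs()
    processed = load_processed()

    for rows, cols, name in [
        ("ligand", "n_class", "matrix_ligand_by_nucleophile.csv"),
        ("ligand", "e_class", "matrix_ligand_by_electrophile.csv"),
        ("base", "n_class", "matrix_base_by_nucleophile.csv"),
        ("base", "e_class", "matrix_base_by_electrophile.csv"),
    ]:
        frame = bm.median_yield_matrix(processed, rows, cols)
        frame.to_csv(RESULTS / name, index=False)
        print(f"{name}: {len(frame)} cells")

    for grouping, name in [
        ("ligand", "diversity_by_ligand.csv"),
        ("base", "diversity_by_base.csv"),
        ("n_class", "diversity_by_nucleophile_class.csv"),
    ]:
        table = bm.diversity_table(processed, grouping, seed=0)
        table.to_csv(RESULTS / name, index=False)

    overall = bm.median_yield_matrix(processed, "e_class", "n_class")
    overall.to_csv(RESULTS / "matrix_class_by_class.csv", index=False)
    top = overall.sort_values("n", ascending=False).head(3)
    print("largest substrate-class cells:")
    print(top.to_string(index=False))


if __name__ == "__main__":
    main()
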