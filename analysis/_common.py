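"""Shared paths and loaders for the numbered analysis drivers."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

CORPUS_CSV = SCRATCH / "synthetic_corpus.csv"
TRUTH_JSON = SCRATCH / "ground_truth.json"
PROCESSED_CSV = SCRATCH / "processed_reactions.csv"

SEED = 7
N_REACTIONS = 5000


def ensure_dirs() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)


def ligand_names() -> dict[str, str]:
    """Canonical ligand SMILES (as the pipeline reports them) -> display
    name from the generator vocabulary."""
    import bhmeta as bm
    from bhmeta.synth import LIGAND_SMILES

    return {
        bm.normalize_molecule(s, "reagent").canonical_smiles: name
        for name, s in LIGAND_SMILES.items()
    }


def load_processed():
    """Rebuild the processed reactions written by 02_process_corpus.py."""
    from bhmeta.pipeline import processed_from_frame

    if not PROCESSED_CSV.exists():
        raise SystemExit(
            f"{PROCESSED_CSV} not found - run analysis/02_process_corpus.py first"
        )
    frame = pd.read_csv(PROCESSED_CSV, keep_default_na=False, na_values=[""])
    return processed_from_frame(frame)
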