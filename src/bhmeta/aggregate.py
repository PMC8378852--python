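"""Count/median-yield matrices, the condition cheatsheet and diversity
proxies.

Medians are computed on the yield-bearing subset of each group while counts
cover all records in the group (matching the size/color separation of the
performance matrices). The cheatsheet ranks ligand/base combinations by
median yield within each electrophile-class x nucleophile-class cell and
only reports combinations backed by at least ``min_count`` reactions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import Descriptors, rdFingerprintGenerator

from .chem import heteroatom_count
from .pipeline_types import ProcessedReaction

GroupKey = str | Callable[[ProcessedReaction], Optional[str]]

_FIELD_GETTERS: dict[str, Callable[[ProcessedReaction], Optional[str]]] = {
    "ligand": lambda p: p.ligand_smiles,
    "base": lambda p: (p.base_name or (p.base.canonical_smiles if p.base else None)),
    "solvent": lambda p: (
        p.solvent_name or (p.solvent.canonical_smiles if p.solvent else None)
    ),
    "e_class": lambda p: p.e_class,
    "n_class": lambda p: p.n_class,
    "lg_code": lambda p: p.lg_code,
    "pub_year": lambda p: str(p.record.pub_year),
    "doc_type": lambda p: p.record.doc_type.value,
}


def _getter(key: GroupKey) -> Callable[[ProcessedReaction], Optional[str]]:
    if callable(key):
        return key
    if key not in _FIELD_GETTERS:
        raise ValueError(
            f"unknown grouping {key!r}; expected one of {sorted(_FIELD_GETTERS)}"
        )
    return _FIELD_GETTERS[key]


@dataclass(frozen=True)
class YieldCell:
    row: str
    col: str
    n: int
    median_yield: Optional[float]
    q1: Optional[float]
    q3: Optional[float]


def _yield_stats(yields: Sequence[float]) -> tuple[Optional[float], Optional[float], Optional[float]]:
    if not yields:
        return np.nan, np.nan, np.nan
    arr = np.asarray(yields, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q1), float(q3)


def median_yield_matrix(
    records: Sequence[ProcessedReaction], row_key: GroupKey, col_key: GroupKey
) -> pd.DataFrame:
    """Long-format matrix of (row, col, n, median, q1, q3).

    Records for which either grouping value is undefined (e.g. missing
    base) are excluded from the matrix; within a cell, the median uses only
    records with a reported yield while ``n`` counts all of them.
    """
    row_get, col_get = _getter(row_key), _getter(col_key)
    cells: dict[tuple[str, str], list[ProcessedReaction]] = {}
    for p in records:
        row, col = row_get(p), col_get(p)
        if row is None or col is None:
            continue
        cells.setdefault((row, col), []).append(p)
    out = []
    for (row, col), members in sorted(cells.items()):
        yields = [m.yield_percent for m in members if m.yield_percent is not None]
        med, q1, q3 = _yield_stats(yields)
        out.append(YieldCell(row, col, len(members), med, q1, q3))
    return pd.DataFrame([c.__dict__ for c in out])


@dataclass(frozen=True)
class CheatsheetEntry:
    ligand: str
    base: str
    median_yield: float
    n: int


@dataclass(frozen=True)
class CheatsheetCell:
    e_class: str
    n_class: str
    entries: tuple[CheatsheetEntry, ...]


def build_cheatsheet(
    records: Sequence[ProcessedReaction],
    min_count: int = 20,
    top_k: int = 3,
) -> list[CheatsheetCell]:
    """Top ``top_k`` ligand/base combinations per substrate-class pair.

    Only records with both ligand and base resolved participate. A
    combination qualifies only with at least ``min_count`` reactions; its
    median is computed over the reported yields of those reactions. Exact
    median ties rank the larger ``n`` first, then ligand name
    lexicographically.
    """
    cells: dict[tuple[str, str], dict[tuple[str, str], list[float]]] = {}
    counts: dict[tuple[str, str], dict[tuple[str, str], int]] = {}
    for p in records:
        if p.ligand is None or p.base is None:
            continue
        cell = (p.e_class, p.n_class)
        combo = (p.ligand_smiles, p.base_name or p.base.canonical_smiles)
        counts.setdefault(cell, {}).setdefault(combo, 0)
        counts[cell][combo] += 1
        if p.yield_percent is not None:
            cells.setdefault(cell, {}).setdefault(combo, []).append(p.yield_percent)

    out: list[CheatsheetCell] = []
    for cell in sorted(counts):
        entries = []
        for combo, n in counts[cell].items():
            if n < min_count:
                continue
            yields = cells.get(cell, {}).get(combo, [])
            if not yields:
                continue
            entries.append(
                CheatsheetEntry(
                    ligand=combo[0],
                    base=combo[1],
                    median_yield=float(np.median(yields)),
                    n=n,
                )
            )
        entries.sort(key=lambda e: (-e.median_yield, -e.n, e.ligand))
        out.append(CheatsheetCell(cell[0], cell[1], tuple(entries[:top_k])))
    return out


def cheatsheet_frame(cheatsheet: list[CheatsheetCell]) -> pd.DataFrame:
    rows = []
    for cell in cheatsheet:
        for rank, e in enumerate(cell.entries, start=1):
            rows.append(
                dict(
                    e_class=cell.e_class,
                    n_class=cell.n_class,
                    rank=rank,
                    ligand=e.ligand,
                    base=e.base,
                    median_yield=e.median_yield,
                    n=e.n,
                )
            )
    return pd.DataFrame(rows)


# -- diversity proxies --------------------------------------------------------

FP_RADIUS = 4
FP_BITS = 2048


def _fp_generator(radius: int = FP_RADIUS, n_bits: int = FP_BITS):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


def morgan_fingerprint(mol: Chem.Mol, radius: int = FP_RADIUS, n_bits: int = FP_BITS):
    return _fp_generator(radius, n_bits).GetFingerprint(mol)


def mean_pairwise_tanimoto_distance(
    mols: Sequence[Chem.Mol],
    radius: int = FP_RADIUS,
    n_bits: int = FP_BITS,
    cap: int = 300,
    seed: int = 0,
) -> Optional[float]:
    """Mean 1 - Tanimoto over all pairs; a seeded subsample of ``cap``
    molecules is used for larger groups. None for fewer than two."""
    if len(mols) < 2:
        return None
    if len(mols) > cap:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(mols), size=cap, replace=False)
        mols = [mols[i] for i in idx]
    gen = _fp_generator(radius, n_bits)
    fps = [gen.GetFingerprint(m) for m in mols]
    total, pairs = 0.0, 0
    for i in range(len(fps)):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1 :])
        total += sum(1.0 - s for s in sims)
        pairs += len(sims)
    return total / pairs


@dataclass(frozen=True)
class DiversityRow:
    group: str
    n: int
    mean_product_mw: float
    mean_product_heteroatoms: float
    mean_pairwise_tanimoto_distance: Optional[float]


def diversity_table(
    records: Sequence[ProcessedReaction],
    grouping: GroupKey,
    fp_radius: int = FP_RADIUS,
    cap: int = 300,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-group product diversity/difficulty proxies: mean molecular
    weight, mean heteroatom count and mean pairwise Tanimoto distance."""
    get = _getter(grouping)
    groups: dict[str, list[ProcessedReaction]] = {}
    for p in records:
        g = get(p)
        if g is not None:
            groups.setdefault(g, []).append(p)
    rows = []
    for g, members in sorted(groups.items()):
        mols = [m.product.mol for m in members]
        rows.append(
            DiversityRow(
                group=g,
                n=len(members),
                mean_product_mw=float(
                    np.mean([Descriptors.MolWt(m) for m in mols])
                ),
                mean_product_heteroatoms=float(
                    np.mean([heteroatom_count(m) for m in mols])
                ),
                mean_pairwise_tanimoto_distance=mean_pairwise_tanimoto_distance(
                    mols, radius=fp_radius, cap=cap, seed=seed
                ),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
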