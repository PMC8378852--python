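"""Ligand profiling and Pareto-front ranking.

Every ligand gets a profile of medians and population standard deviations
of substrate/product properties (molecular weight, heteroatom count, ring
count, heteroatom-H group count, ortho-substituent count, Tanimoto
distance) plus yield, computed over the reactions it was used in. Ligands
are then ranked by iterated Pareto-front peeling on user-selected columns
(front 1 = non-dominated under maximization), and a median-yield threshold
can be applied after ranking without recomputing fronts — mirroring a
two-step select-then-filter workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import Descriptors, rdMolDescriptors

from .aggregate import FP_BITS, FP_RADIUS, _fp_generator
from .chem import heteroatom_count, heteroatom_h_count
from .pipeline_types import ProcessedReaction

SCOPES = ("electrophile", "nucleophile", "product")
PROPERTIES = ("mw", "heteroatoms", "rings", "heteroatom_h", "ortho", "tanimoto")
STATISTICS = ("median", "sd")


def count_ortho_substituents(
    mol: Chem.Mol, reactive_idx: int, nucleophile_mode: bool = False
) -> tuple[int, bool]:
    """Number of non-hydrogen substituents on ring atoms adjacent to the
    reactive atom, excluding ring bonds (and thereby the leaving group,
    which sits on the reactive atom itself).

    For nucleophiles (``nucleophile_mode``) the count covers ortho positions
    of the aromatic carbons bonded to the reacting nitrogen. Returns
    ``(count, flagged)`` where ``flagged`` marks a non-ring reactive atom
    (count 0 by convention).
    """
    atom = mol.GetAtomWithIdx(reactive_idx)

    def ortho_subs(center: Chem.Atom, exclude: set[int]) -> int:
        count = 0
        for ring_neighbor in center.GetNeighbors():
            if not ring_neighbor.IsInRing():
                continue
            bond = mol.GetBondBetweenAtoms(center.GetIdx(), ring_neighbor.GetIdx())
            if not bond.IsInRing():
                continue
            for sub in ring_neighbor.GetNeighbors():
                if sub.GetIdx() in exclude or sub.GetIdx() == center.GetIdx():
                    continue
                sub_bond = mol.GetBondBetweenAtoms(
                    ring_neighbor.GetIdx(), sub.GetIdx()
                )
                if sub_bond.IsInRing():
                    continue
                if sub.GetAtomicNum() > 1:
                    count += 1
        return count

    if nucleophile_mode:
        total = 0
        for neighbor in atom.GetNeighbors():
            if neighbor.GetIsAromatic() and neighbor.GetAtomicNum() == 6:
                total += ortho_subs(neighbor, {reactive_idx})
        return total, False
    if not atom.IsInRing():
        return 0, True
    return ortho_subs(atom, set()), False


@lru_cache(maxsize=100_000)
def _scalar_properties(smiles: str) -> tuple[float, int, int, int]:
    mol = Chem.MolFromSmiles(smiles)
    return (
        Descriptors.MolWt(mol),
        heteroatom_count(mol),
        rdMolDescriptors.CalcNumRings(mol),
        heteroatom_h_count(mol),
    )


@lru_cache(maxsize=100_000)
def _cached_fp(smiles: str):
    return _fp_generator(FP_RADIUS, FP_BITS).GetFingerprint(
        Chem.MolFromSmiles(smiles)
    )


@dataclass
class LigandProfile:
    ligand: str  # canonical SMILES
    n_reactions: int
    values: dict[str, float]  # "stat:prop:scope" and "median:yield"/"sd:yield"
    low_support: bool = False  # single observation: sd 0, distance 0 by fiat


def _population_sd(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def build_profiles(
    records: Sequence[ProcessedReaction],
    fp_radius: int = FP_RADIUS,
    tanimoto_cap: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-ligand property profile over all reactions using that ligand.

    The per-reaction Tanimoto distance is the mean distance of the
    reaction's molecule (per scope) to the other reactions' molecules of
    the same ligand; groups larger than ``tanimoto_cap`` compare against a
    seeded subsample. Returns a DataFrame indexed by ligand canonical
    SMILES with columns ``median:<prop>:<scope>``, ``sd:<prop>:<scope>``,
    ``median:yield``, ``sd:yield``, ``n_reactions``, ``low_support``.
    """
    groups: dict[str, list[ProcessedReaction]] = {}
    for p in records:
        if p.ligand is None:
            continue
        groups.setdefault(p.ligand.canonical_smiles, []).append(p)

    rng = np.random.default_rng(seed)
    rows = {}
    for ligand, members in sorted(groups.items()):
        values: dict[str, list[float]] = {}
        scope_smiles = {
            "electrophile": [m.electrophile.canonical_smiles for m in members],
            "nucleophile": [m.nucleophile.canonical_smiles for m in members],
            "product": [m.product.canonical_smiles for m in members],
        }
        for scope in SCOPES:
            smis = scope_smiles[scope]
            scal = [_scalar_properties(s) for s in smis]
            values[f"mw:{scope}"] = [v[0] for v in scal]
            values[f"heteroatoms:{scope}"] = [v[1] for v in scal]
            values[f"rings:{scope}"] = [v[2] for v in scal]
            values[f"heteroatom_h:{scope}"] = [v[3] for v in scal]
            # ortho substituents: reactive-site based for the reactants;
            # undefined for the product (recorded as 0, see docs)
            if scope == "electrophile":
                values[f"ortho:{scope}"] = [
                    float(
                        count_ortho_substituents(
                            m.electrophile.mol, m.reactive_carbon
                        )[0]
                    )
                    for m in members
                ]
            elif scope == "nucleophile":
                values[f"ortho:{scope}"] = [
                    float(
                        count_ortho_substituents(
                            m.nucleophile.mol, m.reactive_nitrogen, True
                        )[0]
                    )
                    for m in members
                ]
            else:
                values[f"ortho:{scope}"] = [0.0] * len(members)
            values[f"tanimoto:{scope}"] = _per_reaction_distances(
                smis, tanimoto_cap, rng
            )
        yields = [m.yield_percent for m in members if m.yield_percent is not None]

        row: dict[str, float] = {"n_reactions": len(members)}
        row["low_support"] = len(members) < 2
        for key, series in values.items():
            arr = np.asarray(series, dtype=float)
            row[f"median:{key}"] = float(np.median(arr))
            row[f"sd:{key}"] = _population_sd(arr)
        yarr = np.asarray(yields, dtype=float) if yields else np.asarray([np.nan])
        row["median:yield"] = float(np.nanmedian(yarr))
        row["sd:yield"] = _population_sd(yarr) if yields else 0.0
        rows[ligand] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "ligand"
    return frame


def _per_reaction_distances(
    smiles: list[str], cap: int, rng: np.random.Generator
) -> list[float]:
    n = len(smiles)
    if n < 2:
        return [0.0] * n  # undefined for a single observation; flagged upstream
    fps = [_cached_fp(s) for s in smiles]
    out = []
    for i in range(n):
        others = list(range(n))
        others.pop(i)
        if len(others) > cap:
            others = list(rng.choice(others, size=cap, replace=False))
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], [fps[j] for j in others])
        out.append(float(np.mean([1.0 - s for s in sims])))
    return out


# -- Pareto ranking -----------------------------------------------------------


@dataclass(frozen=True)
class ParetoResult:
    ligand: str
    front: int
    selected_properties: tuple[str, ...]


def selection_column(prop: str, scope: Optional[str], statistic: str = "median") -> str:
    """Column name for a (property, scope, statistic) selection."""
    if prop == "yield":
        return f"{statistic}:yield"
    return f"{statistic}:{prop}:{scope}"


def pareto_rank(
    profiles: pd.DataFrame,
    selected: Sequence[str],
    invert: Sequence[str] = (),
) -> list[ParetoResult]:
    """Iterated Pareto-front peeling under maximization.

    ``a`` dominates ``b`` iff ``a >= b`` on all selected columns and
    ``a > b`` on at least one. Front 1 is the non-dominated set; it is
    peeled off and the process repeats. Columns listed in ``invert`` are
    negated first (minimize instead of maximize).
    """
    if not selected:
        raise ValueError("at least one property must be selected")
    missing = [c for c in selected if c not in profiles.columns]
    if missing:
        raise ValueError(f"selected columns not in profiles: {missing}")
    matrix = profiles.loc[:, list(selected)].to_numpy(dtype=float).copy()
    if np.isnan(matrix).any():
        raise ValueError("selected values contain NaN")
    for j, col in enumerate(selected):
        if col in invert:
            matrix[:, j] = -matrix[:, j]
    n = matrix.shape[0]
    # domination counts + adjacency (fast non-dominated sort)
    ge = np.ones((n, n), dtype=bool)
    gt = np.zeros((n, n), dtype=bool)
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        ge &= col[:, None] >= col[None, :]
        gt |= col[:, None] > col[None, :]
    dominates = ge & gt  # dominates[i, j]: i dominates j
    dominated_by_count = dominates.sum(axis=0)
    fronts = np.zeros(n, dtype=int)
    current = np.where(dominated_by_count == 0)[0]
    front_no = 1
    remaining = dominated_by_count.copy()
    while current.size:
        fronts[current] = front_no
        for i in current:
            remaining[dominates[i]] -= 1
        remaining[current] = -1
        current = np.where(remaining == 0)[0]
        front_no += 1
    ligands = list(profiles.index)
    return [
        ParetoResult(ligands[i], int(fronts[i]), tuple(selected)) for i in range(n)
    ]


def filter_by_yield(
    results: Sequence[ParetoResult],
    profiles: pd.DataFrame,
    threshold: float,
) -> list[ParetoResult]:
    """Drop ligands whose median yield is below ``threshold`` AFTER the
    ranking; front numbers are deliberately not recomputed."""
    keep = profiles["median:yield"] >= threshold
    return [r for r in results if bool(keep.get(r.ligand, False))]


def ranking_frame(
    results: Sequence[ParetoResult], profiles: pd.DataFrame
) -> pd.DataFrame:
    """Tabular view: ligand, front, n_reactions, selected values, yield."""
    base_columns = ["ligand", "front", "n_reactions", "median_yield"]
    if not results:
        return pd.DataFrame(columns=base_columns)
    rows = []
    for r in sorted(results, key=lambda r: (r.front, r.ligand)):
        row = {
            "ligand": r.ligand,
            "front": r.front,
            "n_reactions": int(profiles.loc[r.ligand, "n_reactions"]),
            "median_yield": float(profiles.loc[r.ligand, "median:yield"]),
        }
        for col in r.selected_properties:
            row[col] = float(profiles.loc[r.ligand, col])
        rows.append(row)
    return pd.DataFrame(rows)
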