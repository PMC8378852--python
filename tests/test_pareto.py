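"""Ligand profiles, ortho-substituent counting and Pareto-front peeling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import bhmeta as bm
from bhmeta.chem import normalize_molecule as ent
from bhmeta.classify import find_reactive_carbon
from bhmeta.pareto import (
    ParetoResult,
    build_profiles,
    count_ortho_substituents,
    filter_by_yield,
    pareto_rank,
    ranking_frame,
    selection_column,
)

from conftest import make_processed


def brute_force_fronts(matrix: np.ndarray) -> list[int]:
    """Independent O(n^2) oracle: repeatedly peel the non-dominated set."""
    n = matrix.shape[0]
    fronts = [0] * n
    remaining = set(range(n))
    front = 1
    while remaining:
        nondominated = set()
        for i in remaining:
            dominated = False
            for j in remaining:
                if j == i:
                    continue
                if all(matrix[j] >= matrix[i]) and any(matrix[j] > matrix[i]):
                    dominated = True
                    break
            if not dominated:
                nondominated.add(i)
        for i in nondominated:
            fronts[i] = front
        remaining -= nondominated
        front += 1
    return fronts


def rank_table(matrix, columns=None):
    matrix = np.asarray(matrix, dtype=float)
    columns = columns or [f"p{j}" for j in range(matrix.shape[1])]
    frame = pd.DataFrame(matrix, columns=columns)
    frame.index = [f"L{i}" for i in range(len(frame))]
    return frame, columns


class TestParetoRank:
    def test_single_property_reduces_to_sorting(self):
        frame, cols = rank_table([[3.0], [1.0], [2.0], [2.0]])
        results = {r.ligand: r.front for r in pareto_rank(frame, cols)}
        assert results == {"L0": 1, "L1": 3, "L2": 2, "L3": 2}

    def test_incomparable_points_share_front_one(self):
        frame, cols = rank_table([[3, 1], [1, 3], [2, 2]])
        results = pareto_rank(frame, cols)
        assert all(r.front == 1 for r in results)
        frame, cols = rank_table([[3, 1], [1, 3], [2, 2], [1, 1]])
        results = {r.ligand: r.front for r in pareto_rank(frame, cols)}
        assert results == {"L0": 1, "L1": 1, "L2": 1, "L3": 2}

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=1, max_value=60),
        k=st.integers(min_value=1, max_value=4),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_fronts_match_brute_force_oracle(self, n, k, seed):
        rng = np.random.default_rng(seed)
        # small integer grid to force plenty of ties and dominance
        matrix = rng.integers(0, 5, size=(n, k)).astype(float)
        frame, cols = rank_table(matrix)
        got = [r.front for r in pareto_rank(frame, cols)]
        assert got == brute_force_fronts(matrix)

    def test_front_one_is_never_dominated(self):
        rng = np.random.default_rng(3)
        matrix = rng.normal(size=(80, 3))
        frame, cols = rank_table(matrix)
        front1 = [
            int(r.ligand[1:]) for r in pareto_rank(frame, cols) if r.front == 1
        ]
        for i in front1:
            for j in range(len(matrix)):
                if j != i:
                    assert not (
                        all(matrix[j] >= matrix[i]) and any(matrix[j] > matrix[i])
                    )

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(5)
        matrix = rng.integers(0, 4, size=(40, 2)).astype(float)
        frame, cols = rank_table(matrix)
        base = {r.ligand: r.front for r in pareto_rank(frame, cols)}
        shuffled = frame.sample(frac=1.0, random_state=0)
        again = {r.ligand: r.front for r in pareto_rank(shuffled, cols)}
        assert base == again

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(7)
        matrix = rng.uniform(0.1, 5.0, size=(50, 2))
        frame, cols = rank_table(matrix)
        base = [r.front for r in pareto_rank(frame, cols)]
        transformed = frame.copy()
        transformed[cols[0]] = np.exp(transformed[cols[0]])
        transformed[cols[1]] = transformed[cols[1]] ** 3
        assert [r.front for r in pareto_rank(transformed, cols)] == base

    def test_peeling_front_one_shifts_remaining_fronts(self):
        rng = np.random.default_rng(9)
        matrix = rng.integers(0, 5, size=(30, 2)).astype(float)
        frame, cols = rank_table(matrix)
        full = {r.ligand: r.front for r in pareto_rank(frame, cols)}
        rest = frame.loc[[l for l, f in full.items() if f > 1]]
        if len(rest):
            shifted = {r.ligand: r.front for r in pareto_rank(rest, cols)}
            for ligand, front in shifted.items():
                assert front == full[ligand] - 1

    def test_invert_flag_minimizes(self):
        frame, cols = rank_table([[1.0], [2.0], [3.0]])
        results = {
            r.ligand: r.front
            for r in pareto_rank(frame, cols, invert=cols)
        }
        assert results == {"L0": 1, "L1": 2, "L2": 3}

    def test_empty_selection_rejected(self):
        frame, _ = rank_table([[1.0]])
        with pytest.raises(ValueError):
            pareto_rank(frame, [])


class TestYieldFilter:
    def _profiles(self):
        frame = pd.DataFrame(
            {"median:yield": [90.0, 84.0, 60.0]}, index=["A", "B", "C"]
        )
        results = [
            ParetoResult("A", 1, ("x",)),
            ParetoResult("B", 1, ("x",)),
            ParetoResult("C", 2, ("x",)),
        ]
        return frame, results

    def test_threshold_drops_below_even_on_front_one(self):
        frame, results = self._profiles()
        kept = filter_by_yield(results, frame, 85.0)
        assert [r.ligand for r in kept] == ["A"]
        assert kept[0].front == 1  # ranks untouched

    def test_zero_threshold_is_identity(self):
        frame, results = self._profiles()
        assert filter_by_yield(results, frame, 0.0) == results

    def test_all_below_threshold_gives_empty_list(self):
        frame, results = self._profiles()
        assert filter_by_yield(results, frame, 99.0) == []


class TestOrthoSubstituents:
    def _reactive_carbon(self, smiles, product):
        e = ent(smiles)
        return e.mol, find_reactive_carbon(e, ent(product))

    def test_bromobenzene_has_none(self):
        mol, idx = self._reactive_carbon(
            "Brc1ccccc1", "c1ccc(Nc2ccccc2)cc1"
        )
        assert count_ortho_substituents(mol, idx) == (0, False)

    def test_single_ortho_methyl(self):
        mol, idx = self._reactive_carbon(
            "Cc1ccccc1Br", "Cc1ccccc1Nc1ccccc1"
        )
        assert count_ortho_substituents(mol, idx) == (1, False)

    def test_two_ortho_methyls(self):
        mol, idx = self._reactive_carbon(
            "Cc1cccc(C)c1Br", "Cc1cccc(C)c1Nc1ccccc1"
        )
        assert count_ortho_substituents(mol, idx) == (2, False)

    def test_non_ring_atom_flagged(self):
        mol = ent("CCN").mol
        assert count_ortho_substituents(mol, 0) == (0, True)

    def test_nucleophile_mode_counts_n_neighbor_ring_ortho(self):
        # 2,6-dimethylaniline: both positions ortho to the N-bearing carbon
        mol = ent("Cc1cccc(C)c1N").mol
        n_idx = next(
            a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 7
        )
        count, flagged = count_ortho_substituents(mol, n_idx, nucleophile_mode=True)
        assert (count, flagged) == (2, False)


class TestProfiles:
    def test_two_yield_profile_median_and_population_sd(self):
        records = [
            make_processed(record_id="A", ligand="BINAP", yield_percent=60.0),
            make_processed(record_id="B", ligand="BINAP", yield_percent=80.0),
        ]
        profiles = build_profiles(records)
        assert len(profiles) == 1
        assert profiles["median:yield"].iloc[0] == pytest.approx(70.0)
        assert profiles["sd:yield"].iloc[0] == pytest.approx(10.0)  # population

    def test_single_use_ligand_flagged_with_zero_spread(self):
        profiles = build_profiles([make_processed(ligand="XPhos")])
        assert bool(profiles["low_support"].iloc[0]) is True
        assert profiles["sd:mw:product"].iloc[0] == 0.0
        assert profiles["median:tanimoto:product"].iloc[0] == 0.0

    def test_medians_match_brute_force_recomputation(self, processed_small):
        from rdkit.Chem import Descriptors

        profiles = build_profiles(processed_small)
        by_ligand = {}
        for p in processed_small:
            by_ligand.setdefault(p.ligand_smiles, []).append(p)
        for ligand, members in list(by_ligand.items())[:5]:
            mws = [Descriptors.MolWt(m.product.mol) for m in members]
            assert profiles.loc[ligand, "median:mw:product"] == pytest.approx(
                float(np.median(mws))
            )
            yields = [
                m.yield_percent for m in members if m.yield_percent is not None
            ]
            assert profiles.loc[ligand, "median:yield"] == pytest.approx(
                float(np.median(yields))
            )
            assert profiles.loc[ligand, "n_reactions"] == len(members)

    def test_specialist_ligand_surfaces_at_front_one(self, processed_small):
        """The rarely used phosphatrane planted on heteroatom-rich,
        high-yield couplings must win the matching property selection."""
        profiles = build_profiles(processed_small)
        selection = [
            selection_column("heteroatoms", "electrophile"),
            selection_column("heteroatoms", "nucleophile"),
        ]
        results = pareto_rank(profiles, selection)
        specialist = ent(
            bm.synth.LIGAND_SMILES["triisobutylphosphatrane"], "reagent"
        ).canonical_smiles
        fronts = {r.ligand: r.front for r in results}
        assert fronts[specialist] == 1
        survivors = filter_by_yield(results, profiles, 85.0)
        assert specialist in {r.ligand for r in survivors}

    def test_ranking_frame_is_front_sorted(self, processed_small):
        profiles = build_profiles(processed_small)
        cols = [selection_column("mw", "product")]
        frame = ranking_frame(pareto_rank(profiles, cols), profiles)
        assert list(frame.front) == sorted(frame.front)
        assert {"ligand", "front", "n_reactions", "median_yield"} <= set(
            frame.columns
        )
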