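"""Leaving-group bookkeeping, reactive-site detection and substrate
classes."""

import pytest

from bhmeta.chem import normalize_molecule as ent
from bhmeta.classify import (
    ClassificationError,
    NucleophileClass,
    ReactiveAtomFail,
    RolesUnresolved,
    classify_electrophile,
    classify_nucleophile,
    classify_reaction,
    count_leaving_groups,
    find_reactive_carbon,
    find_reactive_nitrogen,
    identify_roles,
    leaving_groups,
)
from bhmeta.synth import build_product

from conftest import read_data_csv

LG = {spec.code: spec for spec in leaving_groups()}


class TestCountLeavingGroups:
    @pytest.mark.parametrize(
        "smiles, code, expected",
        [
            ("Brc1ccccc1", "Br", 1),
            ("Brc1ccc(Cl)cc1", "Br", 1),
            ("Brc1ccc(Cl)cc1", "Cl", 1),
            ("Brc1ccc(Br)cc1", "Br", 2),
            ("O=S(=O)(Oc1ccccc1)C(F)(F)F", "OTf", 1),
            # triflate fluorines are not aryl-F leaving groups
            ("O=S(=O)(Oc1ccccc1)C(F)(F)F", "F", 0),
            ("Cc1ccc(S(=O)(=O)Oc2ccccc2)cc1", "OTs", 1),
            ("Fc1ccccc1", "F", 1),
            ("BrCc1ccccc1", "Br", 0),  # benzylic halide: not aryl-attached
            ("Nc1ccccc1", "Br", 0),
        ],
    )
    def test_counts(self, smiles, code, expected):
        assert count_leaving_groups(ent(smiles).mol, LG[code]) == expected


class TestIdentifyRoles:
    def test_primary_rule(self):
        pair = identify_roles(
            ent("Brc1ccccc1"), ent("Nc1ccccc1"), ent("c1ccc(Nc2ccccc2)cc1")
        )
        assert pair.electrophile.canonical_smiles == ent("Brc1ccccc1").canonical_smiles
        assert pair.lg_code == "Br" and not pair.via_fallback

    def test_symmetric_in_reactant_order(self):
        product = ent("c1ccc(Nc2ccccc2)cc1")
        forward = identify_roles(ent("Brc1ccccc1"), ent("Nc1ccccc1"), product)
        swapped = identify_roles(ent("Nc1ccccc1"), ent("Brc1ccccc1"), product)
        assert (
            forward.electrophile.canonical_key
            == swapped.electrophile.canonical_key
        )
        assert (
            forward.nucleophile.canonical_key
            == swapped.nucleophile.canonical_key
        )

    def test_both_reactants_carry_lg_falls_back_to_nh(self):
        # 4-bromoaniline keeps its bromide: the Br bookkeeping is ambiguous,
        # the N-H count is not
        pair = identify_roles(
            ent("Brc1ccccc1"),
            ent("Nc1ccc(Br)cc1"),
            ent("Brc1ccc(Nc2ccccc2)cc1"),
        )
        assert pair.via_fallback
        assert pair.nucleophile.canonical_key == ent("Nc1ccc(Br)cc1").canonical_key

    def test_two_lg_types_changing_is_unresolved(self):
        # both Br and Cl consumed (double coupling): no clean assignment
        assert (
            identify_roles(
                ent("Brc1ccc(Cl)cc1"),
                ent("Nc1ccccc1"),
                ent("c1ccc(Nc2ccc(Nc3ccccc3)cc2)cc1"),
            )
            is None
        )

    def test_retained_lg_on_other_ring_is_fine(self):
        pair = identify_roles(
            ent("Brc1ccccc1"),
            ent("Nc1ccccc1"),
            ent("c1ccc(Nc2ccccc2)cc1"),
        )
        assert pair is not None


class TestFindReactiveCarbon:
    def test_sole_candidate(self):
        idx = find_reactive_carbon(
            ent("Brc1ccccc1"), ent("c1ccc(Nc2ccccc2)cc1")
        )
        atom = ent("Brc1ccccc1").mol.GetAtomWithIdx(idx)
        assert atom.GetSymbol() == "C" and atom.GetIsAromatic()

    def test_retained_halide_rejected_by_substructure(self):
        # product keeps the chloride, so only the Br severing matches
        e = ent("Brc1ccc(Cl)cc1")
        idx = find_reactive_carbon(e, ent("Clc1ccc(Nc2ccccc2)cc1"))
        assert any(
            n.GetSymbol() == "Br" for n in e.mol.GetAtomWithIdx(idx).GetNeighbors()
        )

    def test_symmetry_equivalent_candidates_collapse(self):
        # 1,4-dibromobenzene, mono-coupled: both severings succeed but the
        # two carbons are automorphic
        idx = find_reactive_carbon(
            ent("Brc1ccc(Br)cc1"), ent("Brc1ccc(Nc2ccccc2)cc1")
        )
        assert idx is not None

    def test_inequivalent_double_hit_fails(self):
        # 1,3-dibromo-nitrobenzene-like asymmetric double candidate: craft a
        # case where both severings match the product
        e = ent("Brc1ccccc1")
        assert find_reactive_carbon(e, ent("c1ccccc1")) is not None
        # wrong product: nothing matches
        assert find_reactive_carbon(e, ent("OCCO")) is None


class TestFindReactiveNitrogen:
    def test_single_candidate(self):
        idx, taut = find_reactive_nitrogen(
            ent("Nc1ccccc1"), ent("c1ccc(Nc2ccccc2)cc1")
        )
        assert ent("Nc1ccccc1").mol.GetAtomWithIdx(idx).GetSymbol() == "N"
        assert taut is False

    def test_symmetric_diamine_collapses(self):
        result = find_reactive_nitrogen(
            ent("C1CNCCN1"), ent("c1ccc(N2CCNCC2)cc1")
        )
        assert result is not None and result[1] is False

    def test_tautomer_fallback_hydroxypyridine(self):
        idx, taut = find_reactive_nitrogen(
            ent("Oc1ccccn1"), ent("O=c1ccccn1-c1ccccc1")
        )
        assert taut is True
        assert ent("Oc1ccccn1").mol.GetAtomWithIdx(idx).GetSymbol() == "N"

    def test_pyridone_form_needs_no_tautomer(self):
        idx, taut = find_reactive_nitrogen(
            ent("O=c1cccc[nH]1"), ent("O=c1ccccn1-c1ccccc1")
        )
        assert taut is False

    def test_no_match_fails(self):
        assert find_reactive_nitrogen(ent("Nc1ccccc1"), ent("CCCC")) is None


class TestClassifyElectrophile:
    @pytest.mark.parametrize(
        "smiles, product, label",
        [
            ("Brc1ccccc1", "c1ccc(Nc2ccccc2)cc1", "Br_ARY"),
            ("Clc1ccccn1", "c1ccc(Nc2ccccn2)cc1", "Cl_HAR"),
        ],
    )
    def test_basic(self, smiles, product, label):
        e = ent(smiles)
        idx = find_reactive_carbon(e, ent(product))
        got = classify_electrophile(e, idx, smiles[:2].rstrip("c"))
        assert got.label == label

    def test_fused_heteroaromatic_is_har_at_system_level(self):
        # bromide on the carbocyclic ring of quinoline: the fused aromatic
        # system contains nitrogen
        e = ent("Brc1ccc2ncccc2c1")
        idx = find_reactive_carbon(e, ent("c1ccc(Nc2ccc3ncccc3c2)cc1"))
        assert classify_electrophile(e, idx, "Br").label == "Br_HAR"
        # smallest-ring reading sees only the carbocycle
        assert (
            classify_electrophile(e, idx, "Br", system_level_har=False).label
            == "Br_ARY"
        )

    def test_non_aromatic_reactive_carbon_is_an_error(self):
        vinyl = ent("BrC=Cc1ccccc1")
        br_carbon = next(
            a.GetIdx()
            for a in vinyl.mol.GetAtoms()
            if a.GetSymbol() == "C"
            and any(n.GetSymbol() == "Br" for n in a.GetNeighbors())
        )
        with pytest.raises(ClassificationError):
            classify_electrophile(vinyl, br_carbon, "Br")


class TestClassifyNucleophile:
    @pytest.mark.parametrize(
        "smiles, expected",
        [
            ("Nc1ccccc1", NucleophileClass.ARYL),
            ("c1ccc(Nc2ccccc2)cc1", NucleophileClass.DIARYL),
            ("NCc1ccccc1", NucleophileClass.ALKYL),
            ("C1COCCN1", NucleophileClass.DIALKYL),
            ("CNc1ccccc1", NucleophileClass.ALKYLARYL),
            ("c1ccc2c(c1)[nH]c1ccccc12", NucleophileClass.AROMN),
            ("N=C(c1ccccc1)c1ccccc1", NucleophileClass.KETIMINE),
            ("NC(=O)c1ccccc1", NucleophileClass.AMIDE),
            ("CC(N)=O", NucleophileClass.AMIDE),
            ("N", NucleophileClass.OTHER),  # ammonia
            ("NN", NucleophileClass.OTHER),  # hydrazine: N-N only
        ],
    )
    def test_classes(self, smiles, expected):
        n = ent(smiles)
        idx = next(
            a.GetIdx()
            for a in n.mol.GetAtoms()
            if a.GetAtomicNum() == 7 and a.GetTotalNumHs() >= 1
        )
        assert classify_nucleophile(n, idx) is expected

    def test_amide_precedence_over_neighbor_count(self):
        # benzamide nitrogen also has one carbon neighbor; amide wins
        benzamide = ent("NC(=O)c1ccccc1")
        assert classify_nucleophile(benzamide, 0) is NucleophileClass.AMIDE

    def test_lactam_is_amide_not_dialkyl(self):
        lactam = ent("O=C1CCCN1")
        idx = next(
            a.GetIdx() for a in lactam.mol.GetAtoms() if a.GetAtomicNum() == 7
        )
        assert classify_nucleophile(lactam, idx) is NucleophileClass.AMIDE


class TestSubstrateFixture:
    """Closed loop over the shipped 25-substrate fixture: couple each
    substrate with a standard partner and verify the assigned class."""

    def test_full_agreement(self):
        rows = read_data_csv("substrate_fixture.csv")
        assert len(rows) == 25
        tautomer_exercised = False
        for row in rows:
            if row["kind"] == "electrophile":
                e_smi, n_smi, join = row["smiles"], "Nc1ccccc1", "Nc1ccccc1"
            else:
                e_smi, n_smi = "Brc1ccccc1", row["smiles"]
                join = "O=c1cccc[nH]1" if row["name"] == "2-hydroxypyridine" else n_smi
            product, _, _ = build_product(e_smi, join)
            result = classify_reaction(ent(e_smi), ent(n_smi), ent(product))
            got = (
                result.e_class.label
                if row["kind"] == "electrophile"
                else result.n_class.value
            )
            assert got == row["label"], row["name"]
            tautomer_exercised |= result.site.tautomer_used
        assert tautomer_exercised  # the hydroxypyridine/pyridone case


class TestClassifyReaction:
    def test_unresolved_roles_raise(self):
        with pytest.raises(RolesUnresolved):
            classify_reaction(
                ent("Brc1ccc(Cl)cc1"),
                ent("Nc1ccccc1"),
                ent("c1ccc(Nc2ccc(Nc3ccccc3)cc2)cc1"),
            )

    def test_reactive_atom_failure_raises(self):
        # product unrelated to the nucleophile
        with pytest.raises(ReactiveAtomFail):
            classify_reaction(
                ent("Brc1ccccc1"), ent("Nc1ccccc1"), ent("c1ccccc1")
            )

    def test_reactive_carbon_carries_selected_leaving_group(self):
        result = classify_reaction(
            ent("Brc1ccc(Cl)cc1"),
            ent("Nc1ccccc1"),
            ent("Clc1ccc(Nc2ccccc2)cc1"),
        )
        carbon = result.electrophile.mol.GetAtomWithIdx(
            result.site.carbon_index
        )
        assert any(n.GetSymbol() == "Br" for n in carbon.GetNeighbors())
        assert result.lg_code == "Br"
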