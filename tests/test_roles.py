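"""Reagent role assignment: lookup precedence, ligand rules, complex
extraction and per-reaction resolution."""

import pytest

import bhmeta as bm
from bhmeta.chem import normalize_molecule
from bhmeta.records import DiscardCode
from bhmeta.roles import (
    LigandKind,
    Role,
    assign_role,
    extract_ligands_from_complex,
    is_nhc_ligand,
    is_phosphine_ligand,
    resolve_reaction_reagents,
)
from bhmeta.synth import build_pd_complex

from conftest import read_data_csv


def reagent(smiles):
    return normalize_molecule(smiles, "reagent")


def test_role_fixture_full_agreement(tables):
    """Every entry of the shipped 40-reagent fixture is assigned its
    curated role and ligand kind."""
    rows = read_data_csv("reagent_fixture.csv")
    assert len(rows) == 40
    for row in rows:
        assignment = assign_role(reagent(row["smiles"]), tables)
        assert assignment.role.value == row["role"], row["name"]
        kind = assignment.ligand_kind.value if assignment.ligand_kind else ""
        assert kind == row["ligand_kind"], row["name"]


class TestPrecedence:
    def test_phosphorus_base_is_base_not_ligand(self, tables):
        phosphazene = reagent("CC(C)(C)N=P(N(C)C)(N(C)C)N(C)C")
        assert is_phosphine_ligand(phosphazene)  # the rule alone would fire
        assert assign_role(phosphazene, tables).role is Role.BASE

    def test_phosphate_base_is_base_not_ligand(self, tables):
        k3po4 = reagent("[K+].[K+].[K+].[O-]P(=O)([O-])[O-]")
        assert assign_role(k3po4, tables).role is Role.BASE

    def test_solvent_lookup_first(self, tables):
        assert assign_role(reagent("Cc1ccccc1"), tables).role is Role.SOLVENT

    def test_unknown_species_is_generic(self, tables):
        assert assign_role(reagent("CCOC(C)=O"), tables).role is Role.GENERIC

    def test_total_and_deterministic(self, tables):
        first = assign_role(reagent("CCCCN"), tables)
        second = assign_role(reagent("CCCCN"), tables)
        assert first == second


class TestPhosphineRule:
    @pytest.mark.parametrize(
        "smiles, expected",
        [
            ("CC(C)(C)P(C(C)(C)C)C(C)(C)C", True),  # tri-tBu-phosphine
            ("ClP(Cl)Cl", False),  # P-Cl: reactive species
            ("FP(F)F", False),
            ("CC(C)CN1CCN2CCN(CC(C)C)P1N(CC(C)C)CC2", True),  # P-N allowed
            ("c1ccc(OP(Oc2ccccc2)Oc2ccccc2)cc1", True),  # P-O allowed
            ("Nc1ccccc1", False),  # no phosphorus at all
        ],
    )
    def test_rule(self, smiles, expected):
        assert is_phosphine_ligand(reagent(smiles)) is expected

    def test_positive_implies_phosphorus_present(self):
        for smiles in ["CC(C)(C)P(C(C)(C)C)C(C)(C)C", "CCO", "ClP(Cl)Cl"]:
            mol = reagent(smiles)
            if is_phosphine_ligand(mol):
                assert any(a.GetAtomicNum() == 15 for a in mol.mol.GetAtoms())


class TestNhcRule:
    IPR_CARBENE = "CC(C)c1cccc(C(C)C)c1N1C=CN(c2c(C(C)C)cccc2C(C)C)[C]1"
    IPR_SALT = "[Cl-].CC(C)c1cccc(C(C)C)c1[n+]1ccn(-c2c(C(C)C)cccc2C(C)C)c1"

    @pytest.mark.parametrize(
        "smiles, expected",
        [
            (IPR_CARBENE, True),
            (IPR_SALT, True),  # azolium precursor counts
            ("c1cnc[nH]1", False),  # plain imidazole must not match
            ("Cn1ccnc1", False),
            ("c1ccc(P(c2ccccc2)c2ccccc2)cc1", False),  # no N-heterocycle
        ],
    )
    def test_rule(self, smiles, expected, tables):
        assert is_nhc_ligand(reagent(smiles), tables.nhc_patterns) is expected


class TestComplexExtraction:
    PPH3 = "c1ccc(P(c2ccccc2)c2ccccc2)cc1"
    PCY3 = "C1CCC(P(C2CCCCC2)C2CCCCC2)CC1"

    def test_homoleptic_complex_yields_one_distinct_ligand(self):
        complex_entity = reagent(build_pd_complex(self.PPH3))
        ligands = extract_ligands_from_complex(complex_entity)
        assert len(ligands) == 1
        assert ligands[0].canonical_key == reagent(self.PPH3).canonical_key

    def test_mixed_phosphine_complex_is_ambiguous(self):
        from rdkit import Chem
        from rdkit.Chem import RWMol

        combo = Chem.MolFromSmiles("[Pd]")
        donors = []
        for smi in (self.PPH3, self.PCY3):
            lig = Chem.MolFromSmiles(smi)
            offset = combo.GetNumAtoms()
            combo = Chem.CombineMols(combo, lig)
            donors.append(
                offset
                + next(
                    a.GetIdx() for a in lig.GetAtoms() if a.GetAtomicNum() == 15
                )
            )
        rw = RWMol(combo)
        for d in donors:
            rw.AddBond(d, 0, Chem.BondType.DATIVE)
        mixed = rw.GetMol()
        Chem.SanitizeMol(mixed)
        ligands = extract_ligands_from_complex(
            reagent(Chem.MolToSmiles(mixed))
        )
        assert len(ligands) == 2  # ambiguity signal

    def test_ligand_free_pd_salt_yields_nothing(self):
        assert extract_ligands_from_complex(reagent("CC(=O)O[Pd]OC(C)=O")) == []

    def test_no_fragment_contains_the_metal(self):
        for lig in (self.PPH3, "CC(C)(C)P(C(C)(C)C)C(C)(C)C"):
            for extracted in extract_ligands_from_complex(
                reagent(build_pd_complex(lig))
            ):
                assert not any(
                    a.GetAtomicNum() == 46 for a in extracted.mol.GetAtoms()
                )

    def test_chelating_ligand_extracted_whole(self):
        binap = (
            "c1ccc(P(c2ccccc2)c2ccc3ccccc3c2-c2c(P(c3ccccc3)c3ccccc3)"
            "ccc3ccccc23)cc1"
        )
        ligands = extract_ligands_from_complex(reagent(build_pd_complex(binap)))
        assert len(ligands) == 1
        assert ligands[0].canonical_key == reagent(binap).canonical_key


def _rec(reagents, i=0):
    rows = [
        {
            "record_id": f"RR{i}",
            "source": "CAS",
            "doc_type": "nonpatent",
            "pub_year": "2012",
            "reactant_smiles": "Brc1ccccc1;Nc1ccccc1",
            "product_smiles": "c1ccc(Nc2ccccc2)cc1",
            "reagents": reagents,
            "yield_percent": "",
            "temperature_C": "",
            "time_h": "",
        }
    ]
    return bm.records_from_rows(rows)[0]


PD2DBA3 = (
    "O=C(/C=C/c1ccccc1)/C=C/c1ccccc1.O=C(/C=C/c1ccccc1)/C=C/c1ccccc1."
    "O=C(/C=C/c1ccccc1)/C=C/c1ccccc1.[Pd].[Pd]"
)
BINAP = (
    "c1ccc(P(c2ccccc2)c2ccc3ccccc3c2-c2c(P(c3ccccc3)c3ccccc3)ccc3ccccc23)cc1"
)


class TestResolveReagents:
    def test_standard_quartet(self, tables):
        record = _rec(
            f"{PD2DBA3}|catalyst;{BINAP}|reagent;"
            "CC(C)(C)[O-].[Na+]|reagent;Cc1ccccc1|solvent"
        )
        resolved = resolve_reaction_reagents(record, tables)
        assert resolved.discard is None
        assert resolved.ligand.canonical_key == reagent(BINAP).canonical_key
        assert resolved.base_name == "NaOtBu"
        assert resolved.solvent_name == "toluene"
        assert resolved.pd_source is not None

    def test_no_ligand_anywhere_is_undetected(self, tables):
        record = _rec(
            "CC(=O)O[Pd]OC(C)=O|catalyst;CC(C)(C)[O-].[Na+]|reagent;"
            "Cc1ccccc1|solvent"
        )
        resolved = resolve_reaction_reagents(record, tables)
        assert resolved.discard.code is DiscardCode.LIGAND_UNDETECTED

    def test_two_free_ligands_is_ambiguous(self, tables):
        xphos = "CC(C)c1cc(C(C)C)c(-c2ccccc2P(C2CCCCC2)C2CCCCC2)c(C(C)C)c1"
        sphos = "COc1cccc(OC)c1-c1ccccc1P(C1CCCCC1)C1CCCCC1"
        record = _rec(
            f"CC(=O)O[Pd]OC(C)=O|catalyst;{xphos}|reagent;{sphos}|reagent;"
            "[Cs+].[Cs+].[O-]C([O-])=O|reagent;C1COCCO1|solvent"
        )
        resolved = resolve_reaction_reagents(record, tables)
        assert resolved.discard.code is DiscardCode.LIGAND_AMBIGUOUS

    def test_free_and_extracted_same_ligand_pool_to_one(self, tables):
        pph3 = TestComplexExtraction.PPH3
        record = _rec(
            f"{build_pd_complex(pph3)}|catalyst;{pph3}|reagent;"
            "CC(C)(C)[O-].[Na+]|reagent"
        )
        resolved = resolve_reaction_reagents(record, tables)
        assert resolved.discard is None
        assert resolved.ligand.canonical_key == reagent(pph3).canonical_key

    def test_multiple_bases_keep_first_and_warn(self, tables):
        record = _rec(
            f"{BINAP}|reagent;CC(C)(C)[O-].[Na+]|reagent;"
            "[Cs+].[Cs+].[O-]C([O-])=O|reagent"
        )
        resolved = resolve_reaction_reagents(record, tables)
        assert resolved.discard is None
        assert resolved.base_name == "NaOtBu"
        assert any("base" in w for w in resolved.warnings)

    def test_multiple_bases_discard_under_strict_roles(self, tables):
        record = _rec(
            f"{BINAP}|reagent;CC(C)(C)[O-].[Na+]|reagent;"
            "[Cs+].[Cs+].[O-]C([O-])=O|reagent"
        )
        resolved = resolve_reaction_reagents(record, tables, strict_roles=True)
        assert resolved.discard.code is DiscardCode.ROLES_UNRESOLVED

    def test_name_alias_lookup(self, tables):
        record = _rec(f"{BINAP}|reagent;NaOtBu|reagent;toluene|solvent")
        resolved = resolve_reaction_reagents(record, tables)
        assert resolved.base_name == "NaOtBu"
        assert resolved.solvent_name == "toluene"

    def test_unresolvable_name_warns_but_does_not_fail(self, tables):
        record = _rec(f"{BINAP}|reagent;mystery powder|reagent")
        resolved = resolve_reaction_reagents(record, tables)
        assert resolved.discard is None
        assert any("mystery powder" in w for w in resolved.warnings)


def test_solvent_and_base_tables_disjoint(tables):
    assert not set(tables.solvents) & set(tables.bases)


def test_base_strength_ordering_available(tables):
    naotbu = reagent("CC(C)(C)[O-].[Na+]").canonical_key
    k2co3 = reagent("[K+].[K+].[O-]C([O-])=O").canonical_key
    assert tables.base_strength_rank(naotbu) < tables.base_strength_rank(k2co3)
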