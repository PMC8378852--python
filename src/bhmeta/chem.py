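"""Molecular structure handling: parsing, normalization and canonical keys.

All structures in the pipeline are carried as :class:`MoleculeEntity` objects,
which pair the original input string with a canonical SMILES, a canonical key
(standard InChI) used for identity comparisons and deduplication, and the
underlying RDKit molecule.

Two normalization modes exist:

``substrate``
    For reactants and products: the largest organic fragment is kept (salts
    and co-crystallized species stripped) and trivially ionized centres are
    neutralized.

``reagent``
    For declared reagents: multi-fragment salts are kept intact, so that e.g.
    sodium tert-butoxide remains distinguishable from potassium
    tert-butoxide in the lookup tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from rdkit import Chem, RDLogger
from rdkit.Chem import inchi
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")


class StructureError(ValueError):
    """Base class for structure-level failures."""


class MoleculeParseError(StructureError):
    """Input text could not be parsed into a valid molecular graph."""


class MissingStructureError(StructureError):
    """Input text was empty / absent where a structure was required."""


@dataclass(frozen=True)
class MoleculeEntity:
    """A parsed, normalized molecule with canonical identifiers."""

    input_string: str
    canonical_smiles: str
    canonical_key: str
    graph: Chem.Mol = field(compare=False, repr=False, hash=False)

    def __hash__(self) -> int:  # identity is the canonical key
        return hash(self.canonical_key)

    @property
    def mol(self) -> Chem.Mol:
        return self.graph


_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_UNCHARGER = rdMolStandardize.Uncharger()


def _canonical_key(mol: Chem.Mol) -> str:
    """Standard InChI of ``mol``; canonical-SMILES fallback for species
    outside the InChI domain (e.g. dative-bond organometallics)."""
    key = inchi.MolToInchi(mol, treatWarningAsError=False)
    if not key:
        key = "SMI:" + Chem.MolToSmiles(mol)
    return key


@lru_cache(maxsize=200_000)
def _normalize_cached(s: str, mode: str) -> MoleculeEntity:
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise MoleculeParseError(f"unparsable structure: {s!r}")
    if mode == "substrate":
        mol = _LARGEST_FRAGMENT.choose(mol)
        mol = _UNCHARGER.uncharge(mol)
        Chem.SanitizeMol(mol)
    return MoleculeEntity(
        input_string=s,
        canonical_smiles=Chem.MolToSmiles(mol),
        canonical_key=_canonical_key(mol),
        graph=mol,
    )


def normalize_molecule(s: str, mode: str = "substrate") -> MoleculeEntity:
    """Parse and normalize a SMILES string.

    Parameters
    ----------
    s:
        SMILES text. Empty / whitespace-only input raises
        :class:`MissingStructureError`; unparsable input raises
        :class:`MoleculeParseError`.
    mode:
        ``"substrate"`` (largest organic fragment, neutralized) or
        ``"reagent"`` (salts kept intact).
    """
    if mode not in ("substrate", "reagent"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if s is None or not str(s).strip():
        raise MissingStructureError("empty structure field")
    return _normalize_cached(str(s).strip(), mode)


def mol_from_smiles(s: str) -> Chem.Mol:
    """Strict SMILES parse; raises :class:`MoleculeParseError` on failure."""
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise MoleculeParseError(f"unparsable structure: {s!r}")
    return mol


# -- small structural predicates shared across modules ----------------------

#: Atomic numbers treated as transition metals (3d, 4d, 5d blocks).
TRANSITION_METALS = frozenset(
    list(range(21, 31)) + list(range(39, 49)) + [57] + list(range(72, 81))
)

PD_ATOMIC_NUM = 46


def contains_element(mol: Chem.Mol, atomic_num: int) -> bool:
    return any(a.GetAtomicNum() == atomic_num for a in mol.GetAtoms())


def contains_transition_metal(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() in TRANSITION_METALS for a in mol.GetAtoms())


def heteroatom_count(mol: Chem.Mol) -> int:
    """Number of heavy atoms that are neither carbon nor hydrogen."""
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6))


def heteroatom_h_count(mol: Chem.Mol) -> int:
    """Number of heteroatoms bearing at least one hydrogen (N-H, O-H, ...)."""
    return sum(
        1
        for a in mol.GetAtoms()
        if a.GetAtomicNum() not in (1, 6) and a.GetTotalNumHs() >= 1
    )
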