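"""Reagent role assignment: solvent/base lookup, ligand rules, complex
extraction and per-reaction reagent resolution.

Role precedence is fixed: solvent lookup -> base lookup -> phosphine rule ->
NHC rule -> metal source -> generic. The base lookup runs before the
phosphine rule so phosphorus-containing bases (phosphazenes, phosphate
salts) are never misclassified as ligands. Any unrecognized species falls
through to ``generic``.

Ligands bound in defined metal complexes are recovered by severing
phosphorus-metal (and, for NHC complexes, carbene-carbon-metal) bonds and
collecting the phosphine/NHC fragments. Zero distinct extracted+free ligands
signals ``ligand_undetected``; more than one signals ``ligand_ambiguous``.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from rdkit import Chem
from rdkit.Chem import RWMol

from .chem import (
    MoleculeEntity,
    StructureError,
    TRANSITION_METALS,
    contains_transition_metal,
    normalize_molecule,
)
from .records import (
    DeclaredReagent,
    DiscardCode,
    DiscardReason,
    ReactionRecord,
)


class Role(str, enum.Enum):
    SOLVENT = "solvent"
    BASE = "base"
    LIGAND = "ligand"
    METAL_SOURCE = "metal_source"
    GENERIC = "generic"


class LigandKind(str, enum.Enum):
    PHOSPHINE = "phosphine"
    NHC = "NHC"
    OTHER = "other"


class Provenance(str, enum.Enum):
    LOOKUP = "lookup"
    RULE = "rule"
    COMPLEX_EXTRACTION = "complex_extraction"


@dataclass(frozen=True)
class RoleAssignment:
    role: Role
    ligand_kind: Optional[LigandKind] = None
    provenance: Provenance = Provenance.RULE

    def __post_init__(self):
        if (self.role is Role.LIGAND) != (self.ligand_kind is not None):
            raise ValueError("ligand_kind must be present iff role is ligand")


@dataclass(frozen=True)
class TableEntry:
    name: str
    smiles: str
    canonical_key: str
    strength_rank: Optional[int] = None


_DATA_PACKAGE = "bhmeta.data"


def _data_path(filename: str) -> Path:
    return Path(resources.files(_DATA_PACKAGE) / filename)


@dataclass
class RoleTables:
    """Lookup tables for solvents and bases plus free-text name aliases.

    ``solvents`` and ``bases`` map canonical keys to table entries and are
    disjoint by construction; ``name_aliases`` maps lowercased display names
    to canonical SMILES for species declared by name instead of structure.
    """

    solvents: dict[str, TableEntry] = field(default_factory=dict)
    bases: dict[str, TableEntry] = field(default_factory=dict)
    name_aliases: dict[str, str] = field(default_factory=dict)
    nhc_patterns: list[Chem.Mol] = field(default_factory=list)

    @classmethod
    def load(
        cls,
        solvents_csv: str | Path | None = None,
        bases_csv: str | Path | None = None,
        nhc_smarts: str | Path | None = None,
    ) -> "RoleTables":
        solvents_csv = solvents_csv or _data_path("solvents.csv")
        bases_csv = bases_csv or _data_path("bases.csv")
        nhc_smarts = nhc_smarts or _data_path("nhc_patterns.smarts")
        tables = cls()
        for row in _read_csv(solvents_csv):
            entry = _make_entry(row)
            tables.solvents[entry.canonical_key] = entry
            tables.name_aliases[entry.name.lower()] = entry.smiles
        for row in _read_csv(bases_csv):
            entry = _make_entry(row, with_rank=True)
            if entry.canonical_key in tables.solvents:
                raise ValueError(
                    f"{entry.name}: canonical key present in both solvent and base tables"
                )
            tables.bases[entry.canonical_key] = entry
            tables.name_aliases[entry.name.lower()] = entry.smiles
        tables.nhc_patterns = load_smarts_file(nhc_smarts)
        return tables

    _default: "RoleTables | None" = None

    @classmethod
    def default(cls) -> "RoleTables":
        if cls._default is None:
            cls._default = cls.load()
        return cls._default

    def base_strength_rank(self, canonical_key: str) -> Optional[int]:
        entry = self.bases.get(canonical_key)
        return entry.strength_rank if entry else None


def _read_csv(path: str | Path) -> list[dict]:
    with Path(path).open(newline="", encoding="utf-8") as handle:
        return list(csv.DictReader(handle))


def _make_entry(row: dict, with_rank: bool = False) -> TableEntry:
    entity = normalize_molecule(row["smiles"], "reagent")
    return TableEntry(
        name=row["name"],
        smiles=row["smiles"],
        canonical_key=entity.canonical_key,
        strength_rank=int(row["strength_rank"]) if with_rank else None,
    )


def load_smarts_file(path: str | Path) -> list[Chem.Mol]:
    """One SMARTS per line; a line starting with '#' or anything after
    ' #' (whitespace then hash) is a comment. A bare '#' inside a pattern
    (SMARTS atomic number or triple bond) is preserved."""
    patterns = []
    for line in Path(path).read_text().splitlines():
        line = line.split(" #", 1)[0].strip()
        if not line or line.startswith("#"):
            continue
        patt = Chem.MolFromSmarts(line)
        if patt is None:
            raise ValueError(f"invalid SMARTS pattern: {line!r}")
        patterns.append(patt)
    return patterns


# -- ligand rules ------------------------------------------------------------

_HALOGENS = frozenset((9, 17, 35, 53))


def is_phosphine_ligand(m: MoleculeEntity | Chem.Mol) -> bool:
    """True iff the species contains phosphorus but no phosphorus-halogen
    bond. P-O and P-N bonds are allowed (phosphites and phosphatranes are
    ligands); P-halogen species are reactive reagents, not ligands."""
    mol = m.mol if isinstance(m, MoleculeEntity) else m
    has_p = False
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 15:
            continue
        has_p = True
        for neighbor in atom.GetNeighbors():
            if neighbor.GetAtomicNum() in _HALOGENS:
                return False
    return has_p


def is_nhc_ligand(
    m: MoleculeEntity | Chem.Mol, patterns: Iterable[Chem.Mol] | None = None
) -> bool:
    """True iff the species matches an N-heterocyclic-carbene pattern
    (imidazol-2-ylidene, imidazolin-2-ylidene, or their azolium salt
    precursors)."""
    mol = m.mol if isinstance(m, MoleculeEntity) else m
    if patterns is None:
        patterns = RoleTables.default().nhc_patterns
    return any(mol.HasSubstructMatch(p) for p in patterns)


def _carbene_metal_bonds(mol: Chem.Mol) -> list[tuple[int, int]]:
    """Bonds between a metal and a carbon flanked by two ring nitrogens
    (the NHC carbene carbon)."""
    out = []
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        metal, carbon = None, None
        if a.GetAtomicNum() in TRANSITION_METALS and b.GetAtomicNum() == 6:
            metal, carbon = a, b
        elif b.GetAtomicNum() in TRANSITION_METALS and a.GetAtomicNum() == 6:
            metal, carbon = b, a
        if carbon is None or not carbon.IsInRing():
            continue
        ring_n = sum(
            1
            for nb in carbon.GetNeighbors()
            if nb.GetAtomicNum() == 7 and nb.IsInRing()
        )
        if ring_n == 2:
            out.append((a.GetIdx(), b.GetIdx()))
    return out


def extract_ligands_from_complex(
    m: MoleculeEntity, patterns: Iterable[Chem.Mol] | None = None
) -> list[MoleculeEntity]:
    """Sever P-metal and carbene-C-metal bonds of a defined complex and
    return the distinct phosphine/NHC ligand fragments.

    An empty list means no ligand could be extracted (``ligand_undetected``
    at resolution time); more than one distinct fragment is the
    ``ligand_ambiguous`` signal. Fragments containing a metal atom are never
    returned.
    """
    mol = m.mol if isinstance(m, MoleculeEntity) else m
    to_sever = []
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        nums = {a.GetAtomicNum(), b.GetAtomicNum()}
        if nums & TRANSITION_METALS and 15 in nums:
            to_sever.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
    to_sever.extend(_carbene_metal_bonds(mol))
    if not to_sever:
        return []
    rw = RWMol(mol)
    for i, j in set(to_sever):
        rw.RemoveBond(i, j)
    severed = rw.GetMol()
    try:
        Chem.SanitizeMol(severed)
    except Exception:
        return []
    distinct: dict[str, MoleculeEntity] = {}
    for frag in Chem.GetMolFrags(severed, asMols=True, sanitizeFrags=False):
        try:
            Chem.SanitizeMol(frag)
        except Exception:
            continue
        if contains_transition_metal(frag):
            continue
        if is_phosphine_ligand(frag) or is_nhc_ligand(frag, patterns):
            entity = normalize_molecule(Chem.MolToSmiles(frag), "reagent")
            distinct[entity.canonical_key] = entity
    return list(distinct.values())


# -- role assignment ---------------------------------------------------------


def _is_defined_complex(mol: Chem.Mol) -> bool:
    """True when a donor atom (P or an NHC carbene carbon) is bonded
    directly to a transition metal: the species is a defined complex, not a
    free ligand. Metals elsewhere in the skeleton (the Fe of dppf's
    ferrocene backbone) do not count."""
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        nums = {a.GetAtomicNum(), b.GetAtomicNum()}
        if nums & TRANSITION_METALS and 15 in nums:
            return True
    return bool(_carbene_metal_bonds(mol))


def assign_role(m: MoleculeEntity, tables: RoleTables) -> RoleAssignment:
    """Assign exactly one role with the fixed precedence
    solvent -> base -> phosphine -> NHC -> metal source -> generic.

    Defined complexes (donor atom bonded to a transition metal) short-cut
    to ``metal_source`` so their ligands are recovered by extraction rather
    than the whole complex passing the phosphine rule."""
    if m.canonical_key in tables.solvents:
        return RoleAssignment(Role.SOLVENT, provenance=Provenance.LOOKUP)
    if m.canonical_key in tables.bases:
        return RoleAssignment(Role.BASE, provenance=Provenance.LOOKUP)
    if _is_defined_complex(m.mol):
        return RoleAssignment(Role.METAL_SOURCE, provenance=Provenance.RULE)
    if is_phosphine_ligand(m):
        return RoleAssignment(Role.LIGAND, LigandKind.PHOSPHINE, Provenance.RULE)
    if is_nhc_ligand(m, tables.nhc_patterns):
        return RoleAssignment(Role.LIGAND, LigandKind.NHC, Provenance.RULE)
    if contains_transition_metal(m.mol):
        return RoleAssignment(Role.METAL_SOURCE, provenance=Provenance.RULE)
    return RoleAssignment(Role.GENERIC, provenance=Provenance.RULE)


@dataclass
class ResolvedReagents:
    """Outcome of per-reaction reagent resolution."""

    ligand: Optional[MoleculeEntity] = None
    ligand_kind: Optional[LigandKind] = None
    base: Optional[MoleculeEntity] = None
    base_name: Optional[str] = None
    solvent: Optional[MoleculeEntity] = None
    solvent_name: Optional[str] = None
    pd_source: Optional[MoleculeEntity] = None
    discard: Optional[DiscardReason] = None
    warnings: list[str] = field(default_factory=list)


def _resolve_entity(
    reagent: DeclaredReagent, tables: RoleTables
) -> Optional[MoleculeEntity]:
    """Parse a declared reagent as SMILES, falling back to the name-alias
    table; None when neither applies (free-text name with no alias)."""
    try:
        return normalize_molecule(reagent.text, "reagent")
    except StructureError:
        alias = tables.name_aliases.get(reagent.text.strip().lower())
        if alias is None:
            return None
        return normalize_molecule(alias, "reagent")


def resolve_reaction_reagents(
    record: ReactionRecord,
    tables: RoleTables | None = None,
    strict_roles: bool = False,
) -> ResolvedReagents:
    """Resolve ligand, base and solvent for one reaction.

    Free ligands and ligands extracted from defined metal complexes are
    pooled; exactly one distinct ligand resolves, zero yields a
    ``ligand_undetected`` discard, several a ``ligand_ambiguous`` discard.
    Multiple distinct bases or solvents keep the first-declared species and
    log a warning (or discard under ``strict_roles``). The Pd source is
    recorded but never participates in downstream grouping keys.
    """
    tables = tables or RoleTables.default()
    out = ResolvedReagents()
    ligands: dict[str, tuple[MoleculeEntity, LigandKind]] = {}
    bases: list[MoleculeEntity] = []
    solvents: list[MoleculeEntity] = []

    for reagent in record.declared_reagents:
        entity = _resolve_entity(reagent, tables)
        if entity is None:
            out.warnings.append(f"unresolvable reagent text {reagent.text!r}")
            continue
        assignment = assign_role(entity, tables)
        if assignment.role is Role.SOLVENT:
            solvents.append(entity)
        elif assignment.role is Role.BASE:
            bases.append(entity)
        elif assignment.role is Role.LIGAND:
            ligands.setdefault(
                entity.canonical_key, (entity, assignment.ligand_kind)
            )
        elif assignment.role is Role.METAL_SOURCE:
            if out.pd_source is None:
                out.pd_source = entity
            for extracted in extract_ligands_from_complex(
                entity, tables.nhc_patterns
            ):
                kind = (
                    LigandKind.PHOSPHINE
                    if is_phosphine_ligand(extracted)
                    else LigandKind.NHC
                )
                ligands.setdefault(extracted.canonical_key, (extracted, kind))

    if len(ligands) == 0:
        out.discard = DiscardReason(
            DiscardCode.LIGAND_UNDETECTED, "no free or complexed ligand found"
        )
        return out
    if len(ligands) > 1:
        names = sorted(e.canonical_smiles for e, _ in ligands.values())
        out.discard = DiscardReason(
            DiscardCode.LIGAND_AMBIGUOUS, f"{len(ligands)} candidate ligands: {names}"
        )
        return out
    ((out.ligand, out.ligand_kind),) = ligands.values()

    out.base, out.base_name = _pick_unique(
        bases, tables.bases, "base", out, strict_roles
    )
    if out.discard:
        return out
    out.solvent, out.solvent_name = _pick_unique(
        solvents, tables.solvents, "solvent", out, strict_roles
    )
    return out


def _pick_unique(
    found: list[MoleculeEntity],
    table: dict[str, TableEntry],
    label: str,
    out: ResolvedReagents,
    strict: bool,
) -> tuple[Optional[MoleculeEntity], Optional[str]]:
    distinct: dict[str, MoleculeEntity] = {}
    for entity in found:
        distinct.setdefault(entity.canonical_key, entity)
    if not distinct:
        return None, None
    if len(distinct) > 1:
        if strict:
            out.discard = DiscardReason(
                DiscardCode.ROLES_UNRESOLVED,
                f"{len(distinct)} distinct {label}s declared",
            )
            return None, None
        out.warnings.append(
            f"{len(distinct)} distinct {label}s declared; keeping first"
        )
    first = found[0]
    entry = table.get(first.canonical_key)
    return first, entry.name if entry else None
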