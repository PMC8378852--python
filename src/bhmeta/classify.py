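"""Reactant role identification, reactive-site detection and substrate
classes for C-N couplings.

The electrophile is found by leaving-group bookkeeping: for each leaving
group type (Br, Cl, I, F, OTf, OTs) the reactant-side count must exceed the
product-side count by exactly one, only one type may change, and only one
reactant may carry that group. When that fails, the reactant carrying the
consumed N-H nitrogen is taken as the nucleophile; when that is ambiguous
too, both orientations are verified against the reactive-site tests and the
record is unresolved unless exactly one orientation checks out.

Reactive atoms are located without atom mapping: the reactive carbon by
severing each candidate carbon-leaving-group bond and testing the remainder
as a substructure of the product; the reactive nitrogen by grafting a carbon
onto each N-H nitrogen and testing the result as a substructure of the
product. Symmetry-equivalent candidates are collapsed through canonical atom
ranks before the uniqueness test, and a capped tautomer enumeration of both
product and nucleophile rescues pairs whose drawn tautomers differ
(hydroxypyridine reactant / N-aryl-pyridone product).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional

from rdkit import Chem
from rdkit.Chem import RWMol
from rdkit.Chem.MolStandardize import rdMolStandardize

from .chem import MoleculeEntity

DEFAULT_TAUTOMER_CAP = 64

LEAVING_GROUP_CODES = ("OTf", "OTs", "Br", "Cl", "I", "F")


@dataclass(frozen=True)
class LeavingGroupSpec:
    code: str
    smarts: str

    @property
    def pattern(self) -> Chem.Mol:
        return _compiled(self.smarts)


@lru_cache(maxsize=None)
def _compiled(smarts: str) -> Chem.Mol:
    patt = Chem.MolFromSmarts(smarts)
    if patt is None:
        raise ValueError(f"invalid SMARTS: {smarts!r}")
    return patt


def _leaving_group_path() -> Path:
    return Path(resources.files("bhmeta.data") / "leaving_groups.smarts")


@lru_cache(maxsize=1)
def leaving_groups() -> tuple[LeavingGroupSpec, ...]:
    """The six leaving-group patterns, in match-priority order (sulfonates
    before halogens so triflate fluorines are never counted as aryl-F)."""
    specs = {}
    for line in _leaving_group_path().read_text().splitlines():
        line = line.split(" #", 1)[0].strip()
        if not line or line.startswith("#"):
            continue
        code, smarts = line.split(None, 1)
        specs[code] = LeavingGroupSpec(code, smarts.strip())
    missing = [c for c in LEAVING_GROUP_CODES if c not in specs]
    if missing:
        raise ValueError(f"leaving_groups.smarts missing codes: {missing}")
    return tuple(specs[c] for c in LEAVING_GROUP_CODES)


def count_leaving_groups(m: MoleculeEntity | Chem.Mol, lg: LeavingGroupSpec) -> int:
    """Number of distinct aryl-attached instances of the leaving group."""
    mol = m.mol if isinstance(m, MoleculeEntity) else m
    return len(mol.GetSubstructMatches(lg.pattern))


def _lg_profile(mol: Chem.Mol) -> dict[str, int]:
    return {lg.code: count_leaving_groups(mol, lg) for lg in leaving_groups()}


# -- electrophile / nucleophile identification -------------------------------


@dataclass(frozen=True)
class RolePair:
    electrophile: MoleculeEntity
    nucleophile: MoleculeEntity
    lg_code: Optional[str]  # None when resolved by the N-H fallback only
    via_fallback: bool = False


def _nh_nitrogen_count(mol: Chem.Mol) -> int:
    return sum(
        1
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 7 and a.GetTotalNumHs() >= 1
    )


def _nh_hydrogen_count(mol: Chem.Mol) -> int:
    """Total hydrogens attached to nitrogen atoms."""
    return sum(
        a.GetTotalNumHs() for a in mol.GetAtoms() if a.GetAtomicNum() == 7
    )


def identify_roles(
    r1: MoleculeEntity, r2: MoleculeEntity, product: MoleculeEntity
) -> Optional[RolePair]:
    """Decide which reactant is the electrophile; None when unresolved."""
    p1, p2, pp = _lg_profile(r1.mol), _lg_profile(r2.mol), _lg_profile(product.mol)
    changing = [c for c in LEAVING_GROUP_CODES if p1[c] + p2[c] != pp[c]]
    if len(changing) == 1:
        code = changing[0]
        delta = p1[code] + p2[code] - pp[code]
        carriers = [m for m, prof in ((r1, p1), (r2, p2)) if prof[code] > 0]
        if delta == 1 and len(carriers) == 1:
            electro = carriers[0]
            nucleo = r2 if electro is r1 else r1
            return RolePair(electro, nucleo, code)
    # fallback: the reactant carrying the consumed N-H nitrogen. Exactly one
    # N-H hydrogen must disappear on the product side, otherwise the record
    # is not a clean single C-N coupling and stays unresolved.
    nh1, nh2 = _nh_hydrogen_count(r1.mol), _nh_hydrogen_count(r2.mol)
    if nh1 + nh2 - _nh_hydrogen_count(product.mol) != 1:
        return None
    candidates = [m for m, nh in ((r1, nh1), (r2, nh2)) if nh >= 1]
    if len(candidates) == 1:
        nucleo = candidates[0]
        electro = r2 if nucleo is r1 else r1
        return RolePair(electro, nucleo, None, via_fallback=True)
    if len(candidates) == 2:
        # both could be the nucleophile: accept an orientation only if it is
        # the single one whose reactive carbon AND nitrogen both verify
        viable = []
        for electro, nucleo in ((r1, r2), (r2, r1)):
            if (
                find_reactive_carbon(electro, product) is not None
                and find_reactive_nitrogen(nucleo, product) is not None
            ):
                viable.append((electro, nucleo))
        if len(viable) == 1:
            electro, nucleo = viable[0]
            return RolePair(electro, nucleo, None, via_fallback=True)
    return None


# -- reactive-site detection --------------------------------------------------


def _symmetry_classes(mol: Chem.Mol, indices) -> set[int]:
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    return {ranks[i] for i in indices}


def find_reactive_carbon(
    e: MoleculeEntity, product: MoleculeEntity, lg_code: Optional[str] = None
) -> Optional[int]:
    """Atom index of the carbon bearing the displaced leaving group.

    Each leaving-group instance is severed in turn and the remainder tested
    as a substructure of the product; the severing must succeed for exactly
    one symmetry-equivalence class of candidate carbons. ``lg_code``
    optionally restricts the scan to one leaving-group type.
    """
    emol, pmol = e.mol, product.mol
    hits: list[int] = []
    for lg in leaving_groups():
        if lg_code is not None and lg.code != lg_code:
            continue
        for match in emol.GetSubstructMatches(lg.pattern):
            carbon, lg_atoms = match[0], sorted(set(match[1:]), reverse=True)
            rw = RWMol(emol)
            for idx in lg_atoms:
                rw.RemoveAtom(idx)
            frag = rw.GetMol()
            try:
                Chem.SanitizeMol(frag)
            except Exception:
                continue
            if pmol.HasSubstructMatch(frag):
                hits.append(carbon)
    if not hits:
        return None
    if len(_symmetry_classes(emol, hits)) != 1:
        return None
    return hits[0]


def _graft_carbon(mol: Chem.Mol, n_idx: int) -> Optional[Chem.Mol]:
    """Replace one hydrogen on nitrogen ``n_idx`` by a carbon."""
    rw = RWMol(mol)
    new_c = rw.AddAtom(Chem.Atom(6))
    rw.AddBond(n_idx, new_c, Chem.BondType.SINGLE)
    atom = rw.GetAtomWithIdx(n_idx)
    atom.SetNumExplicitHs(max(0, atom.GetTotalNumHs() - 1))
    atom.SetNoImplicit(True)
    probe = rw.GetMol()
    try:
        Chem.SanitizeMol(probe)
    except Exception:
        return None
    return probe


@lru_cache(maxsize=4096)
def _tautomers(smiles: str, cap: int) -> tuple[Chem.Mol, ...]:
    enumerator = rdMolStandardize.TautomerEnumerator()
    enumerator.SetMaxTautomers(cap)
    mol = Chem.MolFromSmiles(smiles)
    result = enumerator.Enumerate(mol)
    if getattr(result, "status", None) is not None:
        # enumeration aborted on the cap: signal failure to the caller
        if result.status == rdMolStandardize.TautomerEnumeratorStatus.MaxTautomersReached:
            raise TautomerCapExceeded(smiles)
    return tuple(result)


class TautomerCapExceeded(RuntimeError):
    pass


def find_reactive_nitrogen(
    n: MoleculeEntity,
    product: MoleculeEntity,
    max_tautomers: int = DEFAULT_TAUTOMER_CAP,
) -> Optional[tuple[int, bool]]:
    """Atom index of the reacting N-H nitrogen, plus a flag for whether the
    tautomer fallback was needed. None when no unique candidate survives."""

    def candidates(mol: Chem.Mol) -> list[int]:
        return [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetAtomicNum() == 7 and a.GetTotalNumHs() >= 1
        ]

    def test(nmol: Chem.Mol, pmols) -> Optional[int]:
        hits = []
        for idx in candidates(nmol):
            probe = _graft_carbon(nmol, idx)
            if probe is not None and any(pm.HasSubstructMatch(probe) for pm in pmols):
                hits.append(idx)
        if hits and len(_symmetry_classes(nmol, hits)) == 1:
            return hits[0]
        return None

    hit = test(n.mol, (product.mol,))
    if hit is not None:
        return hit, False
    try:
        # tautomer enumeration preserves atom numbering, so indices found on
        # a nucleophile tautomer are valid on the input molecule
        product_tautomers = _tautomers(product.canonical_smiles, max_tautomers)
        nucleophile_tautomers = _tautomers(n.canonical_smiles, max_tautomers)
    except TautomerCapExceeded:
        return None
    for nt in nucleophile_tautomers:
        hit = test(nt, product_tautomers)
        if hit is not None:
            return hit, True
    return None


# -- substrate classes --------------------------------------------------------


class RingKind(str, enum.Enum):
    ARY = "ARY"
    HAR = "HAR"


@dataclass(frozen=True)
class ElectrophileClass:
    leaving_group: str
    ring_kind: RingKind

    @property
    def label(self) -> str:
        return f"{self.leaving_group}_{self.ring_kind.value}"


class NucleophileClass(str, enum.Enum):
    ARYL = "Aryl"
    DIARYL = "DiAryl"
    ALKYL = "Alkyl"
    DIALKYL = "DiAlkyl"
    ALKYLARYL = "AlkylAryl"
    AROMN = "aromN"
    KETIMINE = "Ketimine"
    AMIDE = "Amide"
    OTHER = "Other"


class ClassificationError(ValueError):
    pass


def _aromatic_ring_system(mol: Chem.Mol, atom_idx: int) -> set[int]:
    """Atoms of the fused aromatic ring system containing ``atom_idx``."""
    info = mol.GetRingInfo()
    rings = [set(r) for r in info.AtomRings()
             if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in r)]
    system = {atom_idx}
    grew = True
    while grew:
        grew = False
        for ring in rings:
            if ring & system and not ring <= system:
                system |= ring
                grew = True
    return system


def classify_electrophile(
    e: MoleculeEntity,
    reactive_carbon: int,
    lg_code: str,
    system_level_har: bool = True,
) -> ElectrophileClass:
    """Class label from leaving group and aryl/heteroaryl ring kind.

    With ``system_level_har`` (default) the fused aromatic ring system
    containing the reactive carbon decides ARY vs HAR, so a bromide on the
    carbocyclic ring of quinoline is still HAR; set it to False to judge
    only the smallest rings through the reactive carbon.
    """
    atom = e.mol.GetAtomWithIdx(reactive_carbon)
    if not atom.GetIsAromatic() or atom.GetAtomicNum() != 6:
        raise ClassificationError(
            "reactive carbon is not an aromatic carbon; vinyl/alkyl "
            "electrophiles are out of scope"
        )
    if system_level_har:
        system = _aromatic_ring_system(e.mol, reactive_carbon)
    else:
        info = e.mol.GetRingInfo()
        system = set()
        for ring in info.AtomRings():
            if reactive_carbon in ring:
                system |= set(ring)
    hetero = any(e.mol.GetAtomWithIdx(i).GetAtomicNum() != 6 for i in system)
    return ElectrophileClass(lg_code, RingKind.HAR if hetero else RingKind.ARY)


def classify_nucleophile(
    n: MoleculeEntity, reactive_nitrogen: int
) -> NucleophileClass:
    """Class of the reacting nitrogen's bonding environment.

    Precedence: amide (N bonded to a carbonyl carbon) before everything,
    then aromatic-ring nitrogen, then ketimine (a double bond to carbon and
    no single-bonded carbon), then the aromatic/aliphatic carbon-neighbor
    count classes; anything else (ammonia, hydrazines) is Other.
    """
    mol = n.mol
    atom = mol.GetAtomWithIdx(reactive_nitrogen)
    if atom.GetAtomicNum() != 7:
        raise ClassificationError("reactive atom is not nitrogen")

    for neighbor in atom.GetNeighbors():
        if neighbor.GetAtomicNum() == 6 and any(
            b.GetBondType() == Chem.BondType.DOUBLE
            and b.GetOtherAtom(neighbor).GetAtomicNum() == 8
            for b in neighbor.GetBonds()
        ):
            return NucleophileClass.AMIDE
    if atom.GetIsAromatic():
        return NucleophileClass.AROMN

    aromatic_c = aliphatic_c = 0
    double_to_c = False
    for bond in atom.GetBonds():
        other = bond.GetOtherAtom(atom)
        if other.GetAtomicNum() != 6:
            continue
        if bond.GetBondType() == Chem.BondType.DOUBLE:
            double_to_c = True
        elif other.GetIsAromatic():
            aromatic_c += 1
        else:
            aliphatic_c += 1
    if double_to_c and aromatic_c == 0 and aliphatic_c == 0:
        return NucleophileClass.KETIMINE
    if aromatic_c == 1 and aliphatic_c == 0:
        return NucleophileClass.ARYL
    if aromatic_c == 2 and aliphatic_c == 0:
        return NucleophileClass.DIARYL
    if aromatic_c == 0 and aliphatic_c == 1:
        return NucleophileClass.ALKYL
    if aromatic_c == 0 and aliphatic_c == 2:
        return NucleophileClass.DIALKYL
    if aromatic_c == 1 and aliphatic_c == 1:
        return NucleophileClass.ALKYLARYL
    return NucleophileClass.OTHER


@dataclass(frozen=True)
class ReactiveSite:
    carbon_index: int
    nitrogen_index: int
    tautomer_used: bool


@dataclass(frozen=True)
class ClassifiedReaction:
    """Full classification outcome for one (electrophile, nucleophile,
    product) triple."""

    electrophile: MoleculeEntity
    nucleophile: MoleculeEntity
    lg_code: str
    site: ReactiveSite
    e_class: ElectrophileClass
    n_class: NucleophileClass


_CLASSIFY_CACHE: dict[tuple[str, str, str], "ClassifiedReaction | str"] = {}


def classify_reaction(
    r1: MoleculeEntity, r2: MoleculeEntity, product: MoleculeEntity
) -> ClassifiedReaction:
    """Identify roles, locate the reactive atoms and classify both
    substrates. Raises :class:`RolesUnresolved` / :class:`ReactiveAtomFail`
    with the appropriate discard semantics.

    Results are cached on the canonical SMILES triple: literature corpora
    re-use substrates heavily, so the cache makes corpus-scale
    classification cheap.
    """
    cache_key = tuple(
        sorted((r1.canonical_smiles, r2.canonical_smiles))
    ) + (product.canonical_smiles,)
    cached = _CLASSIFY_CACHE.get(cache_key)
    if cached is not None:
        if isinstance(cached, ClassifiedReaction):
            return cached
        raise (RolesUnresolved if cached == "roles" else ReactiveAtomFail)(cache_key)
    try:
        result = _classify_uncached(r1, r2, product)
    except RolesUnresolved:
        _CLASSIFY_CACHE[cache_key] = "roles"
        raise
    except ReactiveAtomFail:
        _CLASSIFY_CACHE[cache_key] = "atoms"
        raise
    _CLASSIFY_CACHE[cache_key] = result
    return result


class RolesUnresolved(ValueError):
    pass


class ReactiveAtomFail(ValueError):
    pass


def _classify_uncached(
    r1: MoleculeEntity, r2: MoleculeEntity, product: MoleculeEntity
) -> ClassifiedReaction:
    pair = identify_roles(r1, r2, product)
    if pair is None:
        raise RolesUnresolved("electrophile/nucleophile could not be identified")
    carbon = find_reactive_carbon(pair.electrophile, product, pair.lg_code)
    if carbon is None:
        raise ReactiveAtomFail("no unique reactive carbon")
    nitrogen = find_reactive_nitrogen(pair.nucleophile, product)
    if nitrogen is None:
        raise ReactiveAtomFail("no unique reactive nitrogen")
    n_idx, tautomer_used = nitrogen
    # the leaving group actually severed at the reactive carbon
    lg_code = pair.lg_code
    if lg_code is None:
        for lg in leaving_groups():
            if any(
                match[0] == carbon
                for match in pair.electrophile.mol.GetSubstructMatches(lg.pattern)
            ):
                lg_code = lg.code
                break
    if lg_code is None:
        raise ReactiveAtomFail("reactive carbon carries no known leaving group")
    e_class = classify_electrophile(pair.electrophile, carbon, lg_code)
    n_class = classify_nucleophile(pair.nucleophile, n_idx)
    return ClassifiedReaction(
        electrophile=pair.electrophile,
        nucleophile=pair.nucleophile,
        lg_code=lg_code,
        site=ReactiveSite(carbon, n_idx, tautomer_used),
        e_class=e_class,
        n_class=n_class,
    )
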