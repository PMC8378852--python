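"""Reaction records: parsing of tabular inputs and the upstream filters.

The input schema is a CSV/TSV with the columns

``record_id, source, doc_type, pub_year, reactant_smiles, product_smiles,
reagents, yield_percent, temperature_C, time_h``

where ``reactant_smiles``/``product_smiles`` are semicolon-separated SMILES
and ``reagents`` is a semicolon-separated list of ``SMILES-or-name|field``
items with ``field`` one of ``reagent``, ``solvent``, ``catalyst``.

The upstream filters mirror the entry of the curation pipeline: the
two-reactants-one-product template, the missing-structure check, the
Pd-catalysis requirement and raw-field duplicate removal. Every filter is a
total function returning ``(kept, discarded)`` with
``len(kept) + len(discarded) == len(input)``.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .chem import (
    MissingStructureError,
    MoleculeEntity,
    MoleculeParseError,
    StructureError,
    contains_element,
    PD_ATOMIC_NUM,
    normalize_molecule,
)

YEAR_MIN = 1850
YEAR_MAX = 2100


class Source(str, enum.Enum):
    CAS = "CAS"
    REAXYS = "Reaxys"
    USPTO = "USPTO"
    SYNTHETIC = "synthetic"


class DocType(str, enum.Enum):
    PATENT = "patent"
    NONPATENT = "nonpatent"


class DeclaredField(str, enum.Enum):
    REAGENT = "reagent"
    SOLVENT = "solvent"
    CATALYST = "catalyst"


class DiscardCode(str, enum.Enum):
    NOT_SINGLE_STEP = "not_single_step"
    MISSING_STRUCTURE = "missing_structure"
    NOT_PD = "not_pd"
    LIGAND_UNDETECTED = "ligand_undetected"
    LIGAND_AMBIGUOUS = "ligand_ambiguous"
    ROLES_UNRESOLVED = "roles_unresolved"
    REACTIVE_ATOM_FAIL = "reactive_atom_fail"
    DUPLICATE = "duplicate"


@dataclass(frozen=True)
class DiscardReason:
    code: DiscardCode
    detail: str = ""


@dataclass(frozen=True)
class DeclaredReagent:
    """One declared reagent: raw text (SMILES or a free-text name) plus the
    database field it was declared in."""

    text: str
    declared_field: DeclaredField


@dataclass
class ReactionRecord:
    """One literature reaction as ingested, before role resolution."""

    record_id: str
    source: Source
    doc_type: DocType
    pub_year: int
    reactant_smiles: tuple[str, ...]
    product_smiles: tuple[str, ...]
    declared_reagents: tuple[DeclaredReagent, ...]
    yield_percent: Optional[float] = None
    temperature_C: Optional[float] = None
    time_h: Optional[float] = None
    # populated by filter_template
    reactants: list[MoleculeEntity] = field(default_factory=list)
    products: list[MoleculeEntity] = field(default_factory=list)

    def raw_key(self) -> tuple:
        """All raw fields, used by basic (pre-normalization) deduplication."""
        return (
            self.source,
            self.doc_type,
            self.pub_year,
            self.reactant_smiles,
            self.product_smiles,
            self.declared_reagents,
            self.yield_percent,
            self.temperature_C,
            self.time_h,
        )


@dataclass(frozen=True)
class RowError:
    row_number: int
    message: str


MANDATORY_COLUMNS = (
    "record_id",
    "source",
    "doc_type",
    "pub_year",
    "reactant_smiles",
    "product_smiles",
    "reagents",
)
OPTIONAL_COLUMNS = ("yield_percent", "temperature_C", "time_h")

_DIALECTS = {"csv": ",", "tsv": "\t"}


def _split_list(text: str) -> tuple[str, ...]:
    return tuple(part.strip() for part in text.split(";") if part.strip())


def _parse_optional_float(text: str, lo=None, hi=None) -> Optional[float]:
    if text is None or not str(text).strip():
        return None
    value = float(text)
    if lo is not None and value < lo:
        raise ValueError(f"value {value} below {lo}")
    if hi is not None and value > hi:
        raise ValueError(f"value {value} above {hi}")
    return value


def _parse_row(row: dict) -> ReactionRecord:
    record_id = (row.get("record_id") or "").strip()
    if not record_id:
        raise ValueError("missing record_id")
    source = Source(row["source"].strip())
    doc_type = DocType(row["doc_type"].strip())
    year_text = (row.get("pub_year") or "").strip()
    if not year_text.isdigit() or len(year_text) != 4:
        raise ValueError(f"pub_year {year_text!r} is not a 4-digit year")
    pub_year = int(year_text)
    if not (YEAR_MIN <= pub_year <= YEAR_MAX):
        raise ValueError(f"pub_year {pub_year} outside [{YEAR_MIN}, {YEAR_MAX}]")
    reactants = _split_list(row.get("reactant_smiles") or "")
    if not reactants:
        raise ValueError("empty reactant field")
    products = _split_list(row.get("product_smiles") or "")
    reagents = []
    for item in _split_list(row.get("reagents") or ""):
        if "|" in item:
            text, field_name = item.rsplit("|", 1)
        else:
            text, field_name = item, "reagent"
        reagents.append(
            DeclaredReagent(text.strip(), DeclaredField(field_name.strip()))
        )
    return ReactionRecord(
        record_id=record_id,
        source=source,
        doc_type=doc_type,
        pub_year=pub_year,
        reactant_smiles=reactants,
        product_smiles=products,
        declared_reagents=tuple(reagents),
        yield_percent=_parse_optional_float(row.get("yield_percent"), 0.0, 100.0),
        temperature_C=_parse_optional_float(row.get("temperature_C")),
        time_h=_parse_optional_float(row.get("time_h")),
    )


def parse_reactions(
    path: str | Path, dialect: str = "csv"
) -> tuple[list[ReactionRecord], list[RowError]]:
    """Parse a reaction table into records.

    Malformed rows are reported in the error list, never silently dropped;
    row order of well-formed rows is preserved. Column order in the file is
    irrelevant (header-driven parsing).
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter=_DIALECTS[dialect])
        header = reader.fieldnames or []
        missing = [c for c in MANDATORY_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"missing mandatory columns: {missing}")
        records: list[ReactionRecord] = []
        errors: list[RowError] = []
        for i, row in enumerate(reader, start=2):  # 1-based, after header
            try:
                records.append(_parse_row(row))
            except (ValueError, KeyError) as exc:
                errors.append(RowError(i, str(exc)))
    return records, errors


# -- upstream filters --------------------------------------------------------

Discarded = list[tuple[ReactionRecord, DiscardReason]]


def filter_template(
    records: Iterable[ReactionRecord],
) -> tuple[list[ReactionRecord], Discarded]:
    """Keep records with exactly two parseable reactants and one parseable
    product; populate their ``reactants``/``products`` entities.

    Records with the wrong reactant/product multiplicity are discarded as
    ``not_single_step``; records with the right multiplicity but empty or
    unparsable structures as ``missing_structure``.
    """
    kept: list[ReactionRecord] = []
    discarded: Discarded = []
    for record in records:
        if len(record.reactant_smiles) == 2 and len(record.product_smiles) == 0:
            # reactants present but no product structure at all
            discarded.append(
                (record, DiscardReason(DiscardCode.MISSING_STRUCTURE, "no product structure"))
            )
            continue
        if len(record.reactant_smiles) != 2 or len(record.product_smiles) != 1:
            discarded.append(
                (
                    record,
                    DiscardReason(
                        DiscardCode.NOT_SINGLE_STEP,
                        f"{len(record.reactant_smiles)} reactants, "
                        f"{len(record.product_smiles)} products",
                    ),
                )
            )
            continue
        try:
            reactants = [
                normalize_molecule(s, "substrate") for s in record.reactant_smiles
            ]
            products = [
                normalize_molecule(s, "substrate") for s in record.product_smiles
            ]
        except StructureError as exc:
            discarded.append(
                (record, DiscardReason(DiscardCode.MISSING_STRUCTURE, str(exc)))
            )
            continue
        record.reactants = reactants
        record.products = products
        kept.append(record)
    return kept, discarded


def filter_pd_catalyzed(
    records: Iterable[ReactionRecord],
) -> tuple[list[ReactionRecord], Discarded]:
    """Keep records where at least one declared species contains palladium.

    The declared field is deliberately ignored: catalysts are frequently
    declared as generic reagents, so Pd detection is element presence on any
    declared species.
    """
    kept: list[ReactionRecord] = []
    discarded: Discarded = []
    for record in records:
        has_pd = False
        for reagent in record.declared_reagents:
            try:
                entity = normalize_molecule(reagent.text, "reagent")
            except StructureError:
                continue  # names / unparsable species cannot carry the Pd flag
            if contains_element(entity.mol, PD_ATOMIC_NUM):
                has_pd = True
                break
        if has_pd:
            kept.append(record)
        else:
            discarded.append(
                (record, DiscardReason(DiscardCode.NOT_PD, "no Pd species declared"))
            )
    return kept, discarded


def basic_dedup(
    records: Sequence[ReactionRecord],
) -> tuple[list[ReactionRecord], Discarded]:
    """Collapse records that are identical on all raw fields.

    This is the pre-normalization duplicate removal at the pipeline entry:
    only byte-level identical rows (ignoring record_id) collapse; the
    structure-aware deduplication happens after role resolution.
    """
    seen: dict[tuple, str] = {}
    kept: list[ReactionRecord] = []
    discarded: Discarded = []
    for record in records:
        key = record.raw_key()
        if key in seen:
            discarded.append(
                (
                    record,
                    DiscardReason(
                        DiscardCode.DUPLICATE, f"raw duplicate of {seen[key]}"
                    ),
                )
            )
        else:
            seen[key] = record.record_id
            kept.append(record)
    return kept, discarded
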