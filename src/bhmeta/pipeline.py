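"""End-to-end curation pipeline: filters, role resolution, classification
and final deduplication, with per-stage conservation accounting.

Stage order mirrors the curation flow: single-step template and structure
checks, Pd filter, raw-field duplicate removal, reagent role resolution,
reactant classification, and structure-aware deduplication keeping the
earliest publication. Every stage is conservative:
``len(kept) + len(discarded) == len(input)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import dedup as dedup_mod
from .classify import (
    ClassificationError,
    ReactiveAtomFail,
    RolesUnresolved,
    classify_reaction,
)
from .pipeline_types import ProcessedReaction
from .records import (
    DiscardCode,
    DiscardReason,
    ReactionRecord,
    basic_dedup,
    filter_pd_catalyzed,
    filter_template,
)
from .roles import RoleTables, resolve_reaction_reagents


@dataclass
class StageCount:
    stage: str
    n_in: int
    n_kept: int
    n_discarded: int


@dataclass
class PipelineResult:
    processed: list[ProcessedReaction]
    discards: list[tuple[str, DiscardReason]]  # (record_id, reason)
    stages: list[StageCount] = field(default_factory=list)
    duplicate_groups: list = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return self.stages[0].n_in if self.stages else 0

    def conservation_ok(self) -> bool:
        """Every stage and the whole pipeline conserve records."""
        per_stage = all(s.n_in == s.n_kept + s.n_discarded for s in self.stages)
        total = self.n_input == len(self.processed) + len(self.discards)
        return per_stage and total


def process_corpus(
    records: Sequence[ReactionRecord],
    tables: RoleTables | None = None,
    strict_roles: bool = False,
    final_dedup: bool = True,
) -> PipelineResult:
    """Run the full curation pipeline over parsed records."""
    tables = tables or RoleTables.default()
    result = PipelineResult(processed=[], discards=[])

    def log_stage(name, n_in, kept, discarded_pairs):
        result.stages.append(StageCount(name, n_in, len(kept), len(discarded_pairs)))
        for rec, reason in discarded_pairs:
            rid = rec.record_id if isinstance(rec, ReactionRecord) else rec.record.record_id
            result.discards.append((rid, reason))

    n0 = len(records)
    kept, discarded = filter_template(records)
    log_stage("template", n0, kept, discarded)

    n1 = len(kept)
    kept, discarded = filter_pd_catalyzed(kept)
    log_stage("pd_catalyzed", n1, kept, discarded)

    n2 = len(kept)
    kept, discarded = basic_dedup(kept)
    log_stage("basic_dedup", n2, kept, discarded)

    n3 = len(kept)
    processed: list[ProcessedReaction] = []
    stage_discards: list[tuple[ReactionRecord, DiscardReason]] = []
    for record in kept:
        resolved = resolve_reaction_reagents(record, tables, strict_roles)
        if resolved.discard is not None:
            stage_discards.append((record, resolved.discard))
            continue
        try:
            classified = classify_reaction(
                record.reactants[0], record.reactants[1], record.products[0]
            )
        except RolesUnresolved as exc:
            stage_discards.append(
                (record, DiscardReason(DiscardCode.ROLES_UNRESOLVED, str(exc)))
            )
            continue
        except (ReactiveAtomFail, ClassificationError) as exc:
            stage_discards.append(
                (record, DiscardReason(DiscardCode.REACTIVE_ATOM_FAIL, str(exc)))
            )
            continue
        processed.append(
            ProcessedReaction(
                record=record,
                electrophile=classified.electrophile,
                nucleophile=classified.nucleophile,
                product=record.products[0],
                ligand=resolved.ligand,
                ligand_kind=resolved.ligand_kind,
                base=resolved.base,
                base_name=resolved.base_name,
                solvent=resolved.solvent,
                solvent_name=resolved.solvent_name,
                pd_source=resolved.pd_source,
                e_class=classified.e_class.label,
                n_class=classified.n_class.value,
                lg_code=classified.lg_code,
                reactive_carbon=classified.site.carbon_index,
                reactive_nitrogen=classified.site.nitrogen_index,
                tautomer_used=classified.site.tautomer_used,
            )
        )
    log_stage("roles_and_classes", n3, processed, stage_discards)

    if final_dedup:
        n4 = len(processed)
        processed, discarded_dupes, groups = dedup_mod.dedup_keep_earliest(processed)
        log_stage("final_dedup", n4, processed, discarded_dupes)
        result.duplicate_groups = groups
    else:
        for p in processed:
            p.key = dedup_mod.reaction_key(p).key

    result.processed = processed
    return result


# -- flat serialization of processed records ---------------------------------

import pandas as pd  # noqa: E402

from .chem import normalize_molecule  # noqa: E402
from .records import DocType, Source  # noqa: E402


def processed_to_frame(processed: Sequence[ProcessedReaction]) -> pd.DataFrame:
    """Flatten processed reactions to a plain table (one row per record)
    that round-trips through CSV via :func:`processed_from_frame`."""
    rows = []
    for p in processed:
        rows.append(
            dict(
                record_id=p.record.record_id,
                source=p.record.source.value,
                doc_type=p.record.doc_type.value,
                pub_year=p.record.pub_year,
                electrophile=p.electrophile.canonical_smiles,
                nucleophile=p.nucleophile.canonical_smiles,
                product=p.product.canonical_smiles,
                ligand=p.ligand.canonical_smiles if p.ligand else "",
                ligand_kind=p.ligand_kind.value if p.ligand_kind else "",
                base=p.base.canonical_smiles if p.base else "",
                base_name=p.base_name or "",
                solvent=p.solvent.canonical_smiles if p.solvent else "",
                solvent_name=p.solvent_name or "",
                e_class=p.e_class,
                n_class=p.n_class,
                lg_code=p.lg_code,
                reactive_carbon=p.reactive_carbon,
                reactive_nitrogen=p.reactive_nitrogen,
                tautomer_used=p.tautomer_used,
                yield_percent=p.record.yield_percent,
                key=p.key or "",
            )
        )
    return pd.DataFrame(rows)


def processed_from_frame(frame: pd.DataFrame) -> list[ProcessedReaction]:
    """Rebuild processed reactions from :func:`processed_to_frame` output."""
    from .records import ReactionRecord
    from .roles import LigandKind

    out = []
    for row in frame.itertuples(index=False):
        record = ReactionRecord(
            record_id=row.record_id,
            source=Source(row.source),
            doc_type=DocType(row.doc_type),
            pub_year=int(row.pub_year),
            reactant_smiles=(row.electrophile, row.nucleophile),
            product_smiles=(row.product,),
            declared_reagents=(),
            yield_percent=None
            if pd.isna(row.yield_percent)
            else float(row.yield_percent),
        )
        out.append(
            ProcessedReaction(
                record=record,
                electrophile=normalize_molecule(row.electrophile, "substrate"),
                nucleophile=normalize_molecule(row.nucleophile, "substrate"),
                product=normalize_molecule(row.product, "substrate"),
                ligand=normalize_molecule(row.ligand, "reagent")
                if row.ligand
                else None,
                ligand_kind=LigandKind(row.ligand_kind)
                if row.ligand_kind
                else None,
                base=normalize_molecule(row.base, "reagent") if row.base else None,
                base_name=row.base_name or None,
                solvent=normalize_molecule(row.solvent, "reagent")
                if row.solvent
                else None,
                solvent_name=row.solvent_name or None,
                e_class=row.e_class,
                n_class=row.n_class,
                lg_code=row.lg_code,
                reactive_carbon=int(row.reactive_carbon),
                reactive_nitrogen=int(row.reactive_nitrogen),
                tautomer_used=bool(row.tautomer_used),
                key=row.key or None,
            )
        )
    return out
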