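"""Cross-source duplicate identification via a fixed-order canonical hash.

Two reactions are the same reaction when electrophile, nucleophile, product,
solvent, base and ligand agree on canonical keys (InChI); temperature, time
and scale deliberately do not participate. Per duplicate group the earliest
publication is kept, so per-year counts downstream measure novel entries.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .records import DiscardCode, DiscardReason, DocType
from .pipeline_types import ProcessedReaction

#: Placeholder for an absent key component (missing solvent/base).
ABSENT = "∅"

KEY_VERSION = "inchi-sha256-v1"


@dataclass(frozen=True)
class ReactionKey:
    key: str
    components: tuple[str, ...]


class KeyError_(ValueError):
    pass


def reaction_key(p: ProcessedReaction) -> ReactionKey:
    """Digest of the six key components in fixed order.

    Solvent mixtures (if a caller resolves more than one solvent) are
    serialized as the '+'-joined sorted set of keys.
    """
    if p.electrophile is None or p.nucleophile is None or p.product is None:
        raise KeyError_(
            "unresolved electrophile/nucleophile/product; record should have "
            "been discarded upstream"
        )
    components = (
        p.electrophile.canonical_key,
        p.nucleophile.canonical_key,
        p.product.canonical_key,
        "+".join(sorted(p.solvent_keys)) if p.solvent_keys else ABSENT,
        p.base.canonical_key if p.base else ABSENT,
        p.ligand.canonical_key if p.ligand else ABSENT,
    )
    digest = hashlib.sha256("|".join(components).encode("utf-8")).hexdigest()
    return ReactionKey(digest, components)


@dataclass
class DuplicateGroup:
    key: str
    kept_id: str
    removed_ids: list[str]
    yield_spread: Optional[float]  # max - min over reported yields, if >= 2


def _precedence(p: ProcessedReaction) -> tuple:
    # earliest year first; ties: nonpatent before patent, then source name,
    # then record_id
    return (
        p.record.pub_year,
        0 if p.record.doc_type is DocType.NONPATENT else 1,
        p.record.source.value,
        p.record.record_id,
    )


def dedup_keep_earliest(
    records: Sequence[ProcessedReaction],
) -> tuple[list[ProcessedReaction], list[tuple[ProcessedReaction, DiscardReason]], list[DuplicateGroup]]:
    """One record per reaction key, keeping the earliest publication.

    Returns (kept, discarded, duplicate groups). Input order is preserved
    among kept records. Yield disagreement within a group is reported as the
    spread but never blocks deduplication.
    """
    for p in records:
        if p.key is None:
            p.key = reaction_key(p).key
    groups: dict[str, list[ProcessedReaction]] = {}
    order: list[str] = []
    for p in records:
        if p.key not in groups:
            order.append(p.key)
        groups.setdefault(p.key, []).append(p)

    kept: list[ProcessedReaction] = []
    discarded: list[tuple[ProcessedReaction, DiscardReason]] = []
    dupe_groups: list[DuplicateGroup] = []
    for key in order:
        members = sorted(groups[key], key=_precedence)
        winner = members[0]
        kept.append(winner)
        if len(members) > 1:
            yields = [
                m.record.yield_percent
                for m in members
                if m.record.yield_percent is not None
            ]
            spread = max(yields) - min(yields) if len(yields) >= 2 else None
            dupe_groups.append(
                DuplicateGroup(
                    key=key,
                    kept_id=winner.record.record_id,
                    removed_ids=[m.record.record_id for m in members[1:]],
                    yield_spread=spread,
                )
            )
            for m in members[1:]:
                discarded.append(
                    (
                        m,
                        DiscardReason(
                            DiscardCode.DUPLICATE,
                            f"duplicate of {winner.record.record_id} (key {key[:12]})",
                        ),
                    )
                )
    # restore input order among kept
    kept_ids = {id(p) for p in kept}
    kept = [p for p in records if id(p) in kept_ids]
    return kept, discarded, dupe_groups
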