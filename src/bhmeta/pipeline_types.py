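"""Shared container for a fully resolved reaction record."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .chem import MoleculeEntity
from .records import ReactionRecord
from .roles import LigandKind


@dataclass
class ProcessedReaction:
    """A record after role resolution and substrate classification."""

    record: ReactionRecord
    electrophile: MoleculeEntity
    nucleophile: MoleculeEntity
    product: MoleculeEntity
    ligand: Optional[MoleculeEntity] = None
    ligand_kind: Optional[LigandKind] = None
    base: Optional[MoleculeEntity] = None
    base_name: Optional[str] = None
    solvent: Optional[MoleculeEntity] = None
    solvent_name: Optional[str] = None
    pd_source: Optional[MoleculeEntity] = None
    e_class: str = ""
    n_class: str = ""
    lg_code: str = ""
    reactive_carbon: int = -1
    reactive_nitrogen: int = -1
    tautomer_used: bool = False
    key: Optional[str] = None

    @property
    def solvent_keys(self) -> tuple[str, ...]:
        return (self.solvent.canonical_key,) if self.solvent else ()

    @property
    def ligand_smiles(self) -> Optional[str]:
        return self.ligand.canonical_smiles if self.ligand else None

    @property
    def yield_percent(self) -> Optional[float]:
        return self.record.yield_percent
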