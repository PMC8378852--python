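"""Shared fixtures: role tables, a small synthetic corpus with ground
truth, its pipeline output, and a factory for hand-built processed
records."""

from __future__ import annotations

import csv
from importlib import resources

import pytest

import bhmeta as bm
from bhmeta.pipeline_types import ProcessedReaction
from bhmeta.records import DocType, ReactionRecord, Source
from bhmeta.synth import LIGAND_SMILES


@pytest.fixture(scope="session")
def tables():
    return bm.RoleTables.default()


@pytest.fixture(scope="session")
def small_corpus():
    """250 base reactions + 30% duplicates under a fixed seed."""
    config = bm.GeneratorConfig(n_reactions=250, seed=11)
    rows, truth = bm.generate(config)
    return config, rows, truth


@pytest.fixture(scope="session")
def small_pipeline(small_corpus):
    _, rows, _ = small_corpus
    return bm.process_corpus(bm.records_from_rows(rows))


@pytest.fixture(scope="session")
def processed_small(small_pipeline):
    return small_pipeline.processed


@pytest.fixture(scope="session")
def ligand_canonical():
    """Vocabulary ligand name -> canonical SMILES / key as the pipeline
    reports them."""
    out = {}
    for name, smiles in LIGAND_SMILES.items():
        entity = bm.normalize_molecule(smiles, "reagent")
        out[name] = (entity.canonical_smiles, entity.canonical_key)
    return out


def read_data_csv(filename: str) -> list[dict]:
    path = resources.files("bhmeta.data") / filename
    with open(path, newline="", encoding="utf-8") as handle:
        return list(csv.DictReader(handle))


def processed_from_truth(rows, truth) -> list[ProcessedReaction]:
    """ProcessedReaction objects built straight from generator ground
    truth: lets downstream statistics be tested on large corpora without
    re-running classification."""
    from bhmeta.synth import BASE_SMILES, SOLVENT_SMILES

    out = []
    for row in rows:
        t = truth.records[row["record_id"]]
        record = ReactionRecord(
            record_id=row["record_id"],
            source=Source(row["source"]),
            doc_type=DocType(row["doc_type"]),
            pub_year=int(row["pub_year"]),
            reactant_smiles=(t.electrophile_smiles, t.nucleophile_smiles),
            product_smiles=(t.product_smiles,),
            declared_reagents=(),
            yield_percent=float(row["yield_percent"])
            if row["yield_percent"]
            else None,
        )
        out.append(
            ProcessedReaction(
                record=record,
                electrophile=entity(t.electrophile_smiles),
                nucleophile=entity(t.nucleophile_smiles),
                product=entity(t.product_smiles),
                ligand=entity(LIGAND_SMILES[t.ligand], "reagent"),
                base=entity(BASE_SMILES[t.base], "reagent"),
                base_name=t.base,
                solvent=entity(SOLVENT_SMILES[t.solvent], "reagent"),
                solvent_name=t.solvent,
                e_class=t.e_class,
                n_class=t.n_class,
            )
        )
    return out


@pytest.fixture(scope="session")
def trend_corpus():
    """A 3,000-reaction truth-backed corpus for corpus-level statistics."""
    rows, truth = bm.generate(bm.GeneratorConfig(n_reactions=3000, seed=21))
    return processed_from_truth(rows, truth)


_ENTITIES: dict[tuple[str, str], bm.MoleculeEntity] = {}


def entity(smiles: str, mode: str = "substrate") -> bm.MoleculeEntity:
    key = (smiles, mode)
    if key not in _ENTITIES:
        _ENTITIES[key] = bm.normalize_molecule(smiles, mode)
    return _ENTITIES[key]


def make_processed(
    record_id: str = "R1",
    e_smiles: str = "Brc1ccccc1",
    n_smiles: str = "Nc1ccccc1",
    p_smiles: str = "c1ccc(Nc2ccccc2)cc1",
    ligand: str = "Xantphos",
    base: str | None = "NaOtBu",
    solvent: str | None = "toluene",
    e_class: str = "Br_ARY",
    n_class: str = "Aryl",
    yield_percent: float | None = 80.0,
    pub_year: int = 2010,
    doc_type: DocType = DocType.NONPATENT,
    source: Source = Source.SYNTHETIC,
    temperature_C: float | None = None,
) -> ProcessedReaction:
    """Hand-built processed record for aggregation/dedup tests; structures
    default to the bromobenzene + aniline coupling."""
    from bhmeta.synth import BASE_SMILES, SOLVENT_SMILES

    record = ReactionRecord(
        record_id=record_id,
        source=source,
        doc_type=doc_type,
        pub_year=pub_year,
        reactant_smiles=(e_smiles, n_smiles),
        product_smiles=(p_smiles,),
        declared_reagents=(),
        yield_percent=yield_percent,
        temperature_C=temperature_C,
    )
    return ProcessedReaction(
        record=record,
        electrophile=entity(e_smiles),
        nucleophile=entity(n_smiles),
        product=entity(p_smiles),
        ligand=entity(LIGAND_SMILES[ligand], "reagent") if ligand else None,
        base=entity(BASE_SMILES[base], "reagent") if base else None,
        base_name=base,
        solvent=entity(SOLVENT_SMILES[solvent], "reagent") if solvent else None,
        solvent_name=solvent,
        e_class=e_class,
        n_class=n_class,
        lg_code=e_class.split("_")[0],
        reactive_carbon=0,
        reactive_nitrogen=0,
    )
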