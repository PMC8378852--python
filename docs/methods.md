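# Methods

This note documents the models, rules and numerical choices behind
`bhmeta`, what the synthetic corpus generator does and does not emulate,
and the known limitations. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Structure handling

Every structure is carried as a `MoleculeEntity`: input string, canonical
SMILES, canonical key and RDKit graph. The canonical key is the standard
InChI; species outside the InChI domain (dative-bond organometallics) fall
back to a `SMI:`-prefixed canonical SMILES. Two normalization modes exist
by design:

* **substrate** — largest organic fragment kept, trivially ionized centres
  neutralized. Used for reactants and products, so salt forms of a
  substrate collapse to one identity.
* **reagent** — multi-fragment salts kept intact. Used for declared
  reagents, so sodium and potassium tert-butoxide remain distinct species
  in the base table.

Unparsable text is an error, never a silently skipped structure; empty
text is a distinct missing-structure error. Normalization is idempotent
and cached (literature corpora re-use a small species vocabulary heavily).

## Upstream filters

Stage order: two-reactants→one-product template (records with more than
one product are treated as multi-step and discarded; records with two
reactants but no product structure are discarded as missing-structure),
Pd requirement, raw-field duplicate removal. Pd detection is element
presence on *any* declared species regardless of its declared field,
because reagent fields in reaction databases are unreliable. The raw-field
deduplication compares all fields except the record identifier, before any
normalization. Every filter returns `(kept, discarded)` with
`|kept| + |discarded| = |input|`, and every discarded record carries exactly
one reason code.

## Reagent roles

Fixed precedence: solvent lookup → base lookup → phosphine rule → NHC rule
→ metal source → generic. Rationale for the order: the base lookup must
precede the phosphine rule so phosphorus-containing bases (phosphazenes,
K3PO4) are never classified as ligands; the catch-all `generic` makes the
assignment total.

* The phosphine rule reads "no P–X bond" as **no phosphorus–halogen bond**
  (F, Cl, Br, I). P–O and P–N bonds are allowed: phosphites and
  proazaphosphatranes are ligands, PCl3 is not.
* A species whose phosphorus (or NHC carbene carbon) is bonded directly to
  a transition metal is a **defined complex** and is routed to
  `metal_source` before the phosphine rule, so its ligands are recovered by
  extraction instead of the whole complex passing as a "ligand". A metal
  elsewhere in the skeleton does not trigger this: dppf, whose iron sits in
  the ferrocene backbone with no P–Fe bond, is a free phosphine ligand.
* Extraction severs all P–metal bonds and, as a deliberate extension,
  carbene-carbon–metal bonds, so NHC complexes are handled symmetrically.
  Distinct extracted fragments are pooled with free ligands; zero distinct
  ligands is the `ligand_undetected` signal, more than one is
  `ligand_ambiguous` (the active species cannot be determined). Counterions
  and dba-type debris are dropped with the metal fragment.
* NHC patterns (`data/nhc_patterns.smarts`): imidazol(in)-2-ylidene free
  carbenes and their aromatic/saturated azolium salt precursors. Plain
  imidazoles do not match (the patterns require a divalent carbene carbon
  or a positively charged ring).
* Multiple distinct bases or solvents: keep the first declared and log a
  warning; a strict mode (`strict_roles=True`) discards instead. The
  shipped tables cover common BH solvents and bases with a strength-rank
  column (a table attribute, not computed); both tables are user-editable
  CSVs and alias free-text names to structures.

## Reactant classification

The electrophile/nucleophile decision uses leaving-group bookkeeping over
Br, Cl, I, F, OTf, OTs (`data/leaving_groups.smarts`, patterns anchored to
an aromatic carbon; sulfonates are listed before halides so triflate
fluorines never count as aryl fluoride). The primary rule requires exactly
one changing LG type, a count change of exactly one, and exactly one
reactant carrying that LG. The fallback requires the total count of
N-bound hydrogens to drop by exactly one and a unique N–H-bearing
reactant; if both reactants carry N–H, the orientation is accepted only
when exactly one of the two passes both reactive-site tests. Anything else
is `roles_unresolved`.

Reactive-site detection avoids atom mapping:

* **Carbon**: sever each LG instance and test the remainder as a
  substructure of the product; success must be unique up to graph
  automorphism (symmetry-equivalent candidates, e.g. the two bromines of
  1,4-dibromobenzene, are collapsed via RDKit canonical ranks before the
  uniqueness test).
* **Nitrogen**: replace one hydrogen on each N–H nitrogen by a carbon and
  substructure-test against the product, with the same symmetry collapse
  (piperazine). If no unique hit exists, tautomers of the product *and* of
  the nucleophile are enumerated (RDKit canonical tautomer enumerator,
  capped at 64; exceeding the cap fails the record) and re-tested; a hit
  found this way sets `tautomer_used`. Enumerating the nucleophile side as
  well is required for reactants drawn in a tautomer without the reacting
  N–H at all (2-hydroxypyridine reacting as 2-pyridone).
* Substructure tests are performed on the severed/grafted molecule as an
  ordinary query, so hydrogen counts at the attachment point are not
  constrained.

Class definitions: electrophiles are labeled `<LG>_<ARY|HAR>`, where HAR
means the **fused aromatic ring system** containing the reactive carbon
holds at least one non-carbon ring atom. The system-level reading matches
chemical usage for benzo-fused heteroaromatics (a bromide on the
carbocyclic ring of quinoline is HAR); a flag switches to smallest-ring
semantics. Nucleophile classes follow the precedence amide (N bonded to a
carbonyl carbon) → aromatic-ring N → ketimine (only a double bond to
carbon) → counts of aromatic/aliphatic carbon neighbours (Aryl, DiAryl,
Alkyl, DiAlkyl, AlkylAryl) → Other (ammonia, hydrazine-type N–N).
Classification results are cached on the canonical SMILES triple; corpora
re-use substrates heavily, so corpus-scale classification is dominated by
the distinct triples.

## Deduplication

The reaction key is SHA-256 over the "|"-joined InChI strings of
electrophile, nucleophile, product, solvent, base and ligand in that fixed
order, with "∅" for an absent solvent or base. Temperature, time and yield
deliberately do not participate. Would-be solvent mixtures serialize as
the sorted, "+"-joined set. Within a key group the kept record minimizes
(publication year, nonpatent-before-patent, source name, record id); the
year granularity is the publication year because that is what reaction
databases report. Yield disagreement within a group is reported as a
spread but never blocks deduplication. Collision risk of the 256-bit
digest is negligible; the key scheme is versioned (`inchi-sha256-v1`).
Differing salt forms of a base are different species by design —
near-duplicate (fuzzy) matching is out of scope.

## Aggregation and the cheatsheet

Cell medians are computed over reported yields only, while `n` counts all
records in the cell (reported and unreported), separating support from
performance. Missing yields are treated as missing, not as zero. The
median of an even count is the midpoint of the two central values; this
matters because cheatsheet ranks are sensitive to it. The cheatsheet ranks
(ligand, base) combinations within each class cell by median yield and
reports the top 3 with at least 20 reactions (both config-exposed); exact
median ties rank the larger `n` first, then the ligand name. Diversity
proxies per group: mean product molecular weight, mean product heteroatom
count, and mean pairwise Tanimoto distance on Morgan fingerprints of
radius 4 folded to 2048 bits (the fold length is this package's choice);
groups larger than 300 molecules use a seeded subsample for the pairwise
distance.

## Ligand profiles and Pareto ranking

Per ligand and per scope (electrophile, nucleophile, product) the profile
holds median and standard deviation of molecular weight, heteroatom count,
ring count, heteroatom-H group count, ortho-substituent count and Tanimoto
distance, plus scope-free yield. Choices:

* Standard deviation is the **population** SD; a single-use ligand gets
  SD 0 and distance 0 with a `low_support` flag rather than exclusion, so
  the recommender does not discriminate against rarely used ligands.
* The per-reaction Tanimoto distance is the mean distance of that
  reaction's molecule to the ligand's other reactions' molecules (same
  scope), subsampled at 100 with a seed for large groups.
* Ortho substituents are counted on ring atoms adjacent to the reactive
  carbon (ring bonds and the leaving group excluded). For nucleophiles the
  count covers the ortho positions of aromatic carbons bonded to the
  reacting nitrogen — an extension, since the property is only meaningful
  for the electrophile side in the strict sense. For products the reactive
  atoms are not tracked and the value is recorded as 0; product-side ortho
  counts should not be used for ranking.
* Pareto ranking uses standard non-domination under maximization (a
  dominates b iff ≥ on all selected columns and > on one), peeled
  iteratively; this is the standard reading of Pareto optimality, adopted
  deliberately where looser verbal definitions ("all others worse in at
  least one property") would be ambiguous. A per-column invert flag allows
  minimization. The yield threshold is applied **after** ranking without
  recomputing fronts, matching a select-then-filter workflow; yield (or
  reaction count) can equally be included as a ranking column.

## Trend statistics

* Bootstrap CIs on the median: percentile method, default 2000 resamples,
  explicit seed. The percentile method can return degenerate intervals on
  constant windows, which is correct behavior.
* The yield **spike index** quantifies rounding to multiples of ten: mean
  histogram count on the bins 40, 50, …, 90 divided by the mean count on
  their immediate neighbour bins (1-point bins by default). It is an
  artifact-specific quantification of a qualitative phenomenon; ≈ 1 means
  no rounding excess.
* Cumulative coverage: reagents sorted by count; the curve value at k is
  the fraction of records using any top-k reagent, with records missing
  that reagent excluded from the denominator (so the curve always ends at
  1 over the resolvable subset).
* Zipf fit: least squares of log count vs log rank over items with count
  ≥ 5 (the cutoff avoids low-count tail bias); the exponent is the negated
  slope. Maximum-likelihood fitting would be an alternative but is not the
  default.
* Shares and counts per year use the publication year of the kept
  (earliest) record, so they measure novel entries over time.

## The synthetic corpus generator

The generator emulates the statistical structure of literature BH corpora,
not their chemistry. Products are built by direct C–N bond formation on
the labeled reactive sites — chemically simplistic by design; the fidelity
target is the pipeline's logic. Defaults and what they emulate:

* **Substrate library**: ≥ 1 curated, label-verified substrate per class
  (≥ 3 for the major classes), including 2-hydroxypyridine emitted in its
  hydroxy form but joined through the pyridone tautomer, so the tautomer
  branch is exercised end-to-end.
* **Reagent usage**: ligand draws follow Zipf weights with exponent 1 over
  a 12-ligand vocabulary; bases and solvents use fixed weights with two
  dominant members each (0.50/0.29 and 0.48/0.30), mirroring the
  concentration reported for real corpora.
* **Yields**: planted per-combination medians (85/72/64 for the top three
  combinations per cell under a stable hash ordering, a 52–67 tail so the
  distribution is right-skewed), Gaussian noise with SD 10, clipped to
  [1, 100]; 25% of records omit the yield; rounding to the nearest ten
  with probability 0.2 (reduced by a factor 4 in patents, where the spike
  phenomenon is weaker). Pre-2014 patent records get a 20-point median
  penalty, and the patent share rises from 0.35 to 0.65 in 2014, together
  with a doubling of the aromatic-N nucleophile share — the planted trend
  shifts that the trend statistics must recover.
* **Messiness**: solvents are declared in the generic reagent field half
  of the time, some bases/solvents are emitted by name instead of SMILES
  (exercising the alias table), and 20% of records declare Pd as a defined
  dative-bond complex of the drawn phosphine (bidentate ligands chelate,
  monodentate ligands bind twice), exercising ligand extraction. NHC
  ligands are always declared free as the azolium salt, because a carbene
  extracted from a complex would canonicalize to a different species than
  its salt precursor and break identity-based ground truth.
* **Duplicates**: a configurable fraction (default 0.3, matching the
  cross-source overlap scale of real corpora) of base records is re-emitted
  under a different source with a strictly later year and identical
  six key fields. Base records are resampled on key collision so the
  planted duplicate groups are exactly the duplicate groups — this is what
  makes dedup precision/recall testable at 1.0. A corpus with colliding
  base keys (the realistic case) would make "precision" ill-defined
  without semantic ground truth.
* **Specialist ligand**: triisobutylphosphatrane is drawn rarely (Zipf
  rank 11) but planted on a heteroatom-rich cell (heteroaryl chloride ×
  dialkylamine) with median 92, so the Pareto recommender's core use case —
  surfacing rare but excellent ligands — is testable.
* The `recovery_config` preset (3 ligands × 2 bases × 4 cells, explicit
  effect table with ≥ 15-point gaps, 2,400 reactions) sizes every
  combination above the 20-reaction support threshold for the cheatsheet
  recovery study.

What the generator does **not** emulate: realistic product structures
beyond the coupling bond, atom-mapping noise, multi-step entries, name-only
substrates, solvent mixtures, catalyst loading or stoichiometry, and
corpus-level absolute counts of any licensed database. Passing recovery
tests therefore demonstrates the pipeline's logic under the stated
statistical structure, not performance on raw commercial exports.

## Problem sizes and numerical tolerances

The default study corpus is 5,000 unique reactions (+30% duplicates); the
dedup study uses ~10,000 rows; cheatsheet recovery runs 20 corpora of
2,400; bootstrap coverage uses 500 replications of n = 80 with 1,000
resamples; Zipf recovery uses 10,000 draws over 50 ligands with a ±0.15
acceptance band; the Pareto implementation is checked against an O(n²)
peeling oracle on 100 random tables up to n = 200. These sizes keep the
full suite and the acceptance script in the minutes range on a single CPU
while leaving the statistical checks well-powered.

## Interfaces

The library functions plus the numbered drivers under `analysis/` are the
package's interface; no console-script CLI is installed. Inputs are plain
CSV/TSV per the schema in `bhmeta.records`; outputs are tidy CSV/JSON
tables under `results/`.

## Known limitations

* Name-to-structure resolution is a small alias table, not a name parser.
* The tosylate pattern is tosyl-specific; other aryl sulfonates (mesylate,
  besylate) are not counted as OTs.
* HAR/ARY for fused systems is a convention (system-level by default);
  both readings are implemented but only one can match any given external
  labeling.
* Dedup treats different salt forms of a base as different conditions;
  near-duplicate detection is explicitly out of scope.
* The Pareto front of heavily tied integer-valued properties (heteroatom
  medians) is large; the yield filter, not the front number, does most of
  the discrimination in that regime.
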