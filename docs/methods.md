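# Methods

This note documents the models, conventions and design choices behind each
stage of the package, and what the synthetic-data tests do and do not show
about real survey data.

## Geochemistry

Fold enrichment of an analyte is `observed / reference` with the reference
taken from average continental-crust abundances (chloride 145, sulphate
350, nitrate 19, fluoride 585 p.p.m.). Results are rounded **half-up to one
decimal**, the precision at which such multipliers are conventionally
printed; Python's default banker's rounding would disagree on exact `.x5`
quotients, so the division is done in decimal arithmetic. Censored cells
(`"<N"`, below the instrument detection limit) are never folded — the
function returns a "not computable" marker, not a number — but they do
participate in extreme-value flagging: a censored cell is a joint *lowest*
value whenever its limit does not exceed the minimum uncensored value of
its analyte, which reproduces the conventional annotation of such tables
(several `"<50"` sites tie as lowest while a measured 185 does not). An
analyte with no uncensored cells has no defined *highest* value and is
reported as such.

## Taxon–KO matrix and CPM

A *dataset* is an environment × taxon-group combination; the canonical
four are `{PMT, Topaz} × {Actinomycetota, Bacteria}`. Annotation rows
labelled `Other` (neither Actinomycetota nor other bacteria) are excluded
before counting. The raw count of a (dataset, KO) cell is the number of
queries in that dataset annotated with that KO; a query carrying *m* KO
identifiers contributes one full count to each of the *m* KOs (integer
counting keeps the conservation invariant — total counts equal total
(query, KO) assignments — simple; fractional splitting would not).
Duplicate query ids within a dataset are an error rather than silently
double-counted.

CPM is `raw × 10⁶ / mapped_total` per dataset, so each dataset's CPM
column sums to one million whenever any counts exist. When no explicit
mapped-read total is supplied, the number of annotation rows per dataset
stands in for it; an explicit totals table overrides. Raw counts are never
mutated by normalization. Presence of a KO in a dataset — the input to all
pan-classification — is `raw ≥ 1`, with no CPM floor.

The twofold screen flags features whose abundance ratio between two
conditions is **at least** 2 (boundary inclusive). Features with non-zero
abundance on one side only are reported separately as *exclusive* rather
than infinitely enriched, because presence/absence and fold change are
scientifically different statements; the screen is symmetric up to
direction labels.

## Pan-metagenome classes and Venn partition

The class of a KO is a pure function of the popcount of its 4-bit presence
mask: 4 → core, exactly 3 → softcore, exactly 2 → shell, 1 → cloud. The
verbal definition of softcore ("at least three") overlaps core when read
literally; the classes here are made disjoint (exactly 3) so that the four
fractions partition the KO universe and sum to 100 %. Class fractions are
computed over the union of the four KO sets — the only universe available
without per-read provenance — and a KO absent everywhere is a contract
violation, not a fifth class. The 15-region Venn partition is the per-KO
tabulation of membership masks; its regions are disjoint, sum to the union
size, and the four single-set regions equal the per-dataset unique-KO
(cloud) sets. All of these identities are exercised against brute-force
per-element tabulation on random instances.

## KEGG-module aggregation

Module abundance per dataset is the share of the dataset's total weight
carried by the module's member KOs. The default weight is CPM
(abundance-weighted); presence counting is available since "relative
abundance of orthologues" is ambiguous between the two readings. A KO
mapped to several modules keeps its full weight in each (the KEGG-mapper
convention) and the affected rows are flagged so users can switch to
fractional splitting themselves; KOs missing from the map pool into an
`unmapped` category so shares always total 100 %. *Exclusive* pathway
proportions of an environment use that dataset's unique (cloud) KOs only —
the narrowest defensible reading of "found exclusively"; broader
environment-restricted patterns (e.g. shell within one environment's two
taxon groups) can be composed from the partition but are not the default.

## BiNI

`BiNI = Σd / n` where `n` is the strain's total predicted cluster count
and `d` the per-cluster distance to the nearest known gene cluster family.
The `>900` novelty threshold is a **per-cluster flag**, not a filter on
which distances enter the sum: published strain scores below 900 are only
arithmetically possible if sub-threshold distances are summed. The flag is
strict (`901 → novel`, `900 → not`). One distance per cluster is summed.
A cluster with a missing distance contributes zero to the sum but still
counts in `n` — this biases the score down, so per-strain *coverage* (the
fraction of clusters with a distance) is always reported alongside.
Ranking is by descending score with alphabetical tie-breaks.

## Molecular networking

The modified cosine allows a fragment pair to match either directly
(`|Δm/z| ≤ tol`) or shifted by the precursor mass difference; intensities
are square-root transformed (linear mode available) and unit-normalized
per spectrum, and the score is the maximum of the summed weight products
over all one-to-one peak matchings. That maximum is computed **exactly**
at every spectrum size as a maximum-weight bipartite assignment
(`scipy.optimize.linear_sum_assignment` on the masked weight matrix):
desk-scale spectra are small enough that the cubic assignment cost is
negligible, so no greedy approximation is used anywhere and the oracle
contract (equality with exhaustive matching) holds identically. Scores are
clipped to [0, 1] against floating-point overshoot; a peak participates in
at most one match regardless of shift class.

Consensus clustering is greedy centroid clustering: seed with the most
intense unassigned spectrum, absorb spectra within the precursor tolerance
whose cosine against the seed reaches the clustering threshold (default
0.7), repeat. The consensus spectrum is an intensity-weighted merge of
member peaks grouped at the fragment tolerance. The minimum cluster size
(default 3) is applied at this consensus step — the MS-clustering
semantics — not as a network-component filter; it is configurable.
Network edges require both cosine ≥ 0.65 and ≥ 4 matched ions at 0.03 Da;
no top-K edge pruning is applied by default since none is part of the
stated parameter set. Library search uses the same scorer at the looser
0.5 / 4 thresholds, and per-strain superclass composition counts each node
once per member strain with unlabelled nodes as their own "no match"
category.

## Synthetic data: what it emulates and what it does not

The generators produce the study *conditions*, not the study: four
taxon–KO datasets with a configurable pan-class mix (default balanced
25/25/25/25 over 400 KOs — a size at which class recovery is exact by
construction and the suite runs in seconds), replicate MS/MS spectra in
planted compound families, BGC tables with uniform GCF distances over
600–1400 (bracketing the 900 novelty threshold), and geochemistry tables
whose cells are exactly `reference × fold`.

Deliberate idealizations, and hence the limits of what green tests show:

- **Counts** are over-dispersed (`1 + NB(r, p)`, mean 10, dispersion 2 per
  present cell) but presence downstream is binary, so any strictly
  positive integer model is equivalent for classification; the tests say
  nothing about abundance-estimation error in real profiles.
- **Fragment m/z** values sit on a 0.1 Da grid with disjoint blocks per
  family, so the 0.03 Da tolerance cannot cross-match distinct planted
  fragments and ground-truth edges are unambiguous. Real spectra share
  fragments across compound families, contain noise peaks and isotope
  envelopes, and their networks are correspondingly less clean; planted
  recovery shows the machinery is correct, not that real networks are.
- **Geochemical folds** are planted at one-decimal precision so that
  rounding recovery is exact.
- Every generator is a pure function of its seed; per-stage seeds derive
  from the run seed through a fixed hash so stages reproduce standalone.

The headline dataset-level numbers of a real survey of this kind (total
orthologue counts, the pan split, unique-orthologue counts, phylum
abundances, library match rates, per-strain BGC counts) depend on raw
sequencing archives and on the versions of external databases (taxonomic
classifier, orthology DB, GCF catalogue, spectral libraries). They are
therefore out of reach of a desk-scale re-analysis; the pipeline computes
quantities of exactly those kinds on synthetic studies, and the acceptance
checks assert the reproducible subset: printed worked examples
(geochemical multipliers, the Σd/n toy, the six-strain ranking) and exact
planted-truth recovery.

## Numerical conventions

- Fold enrichment: decimal division, `ROUND_HALF_UP` to one decimal.
- CPM conservation is asserted to 10⁻³ absolute on the per-dataset sum.
- Modified-cosine oracle equality is asserted to 10⁻⁹.
- Ties: strain ranking breaks by name; library hits break by library id;
  extreme-value flags report tie *sets* rather than picking a winner.
- Degenerate inputs: empty annotation tables and all-`Other` datasets give
  empty matrices with warnings; a strain with no clusters is skipped, one
  with no distances scores 0 at coverage 0; an all-censored analyte has
  undefined highest value; absent-everywhere KOs are rejected.
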