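# Methods

This note documents the models and procedures implemented in `netpharm`,
the conventions and numerical choices behind them, what the synthetic-data
generators do and do not emulate, and the package's known limitations.

## Evidence fusion and consensus

Disease-gene evidence arrives as per-source gene lists. Symbols are
normalised by uppercasing and trimming only; no ortholog mapping or alias
resolution is attempted unless the caller supplies an explicit
alias→canonical table (an alias mapping to two canonicals is rejected).
This keeps the fusion step deterministic and offline — curated synonym
handling belongs to the data-preparation step, not the pipeline.

A gene is retained when its *support* — the number of sources containing
it — reaches `min_sources` (default 2, with 3 sources the typical design).
Retention is monotone in `min_sources`, and the per-region Venn accounting
is reported exactly for up to 5 sources (2⁵ regions); beyond that only the
support histogram is meaningful to read.

Drug-target consensus applies the same k-of-n rule per drug across target
predictors. The drug–disease overlap supports two policies: `all_drugs`
(disease genes targeted by *every* drug; the default, matching the
intersection reading of a multi-drug Venn centre) and `any_drug` (the
union). Per-drug overlaps are always reported so the choice is auditable.

## Topology panel

Conventions follow Cytoscape's NetworkAnalyzer, the de-facto reporting
standard for PPI topology:

- **Betweenness** is exact (Brandes), endpoints excluded, normalised by
  (n−1)(n−2)/2 so values lie in [0, 1].
- **Closeness** is the reciprocal of the mean shortest-path distance to
  *reachable* nodes; an isolated node scores 0. (This is the classic
  Freeman closeness, not the Wasserman–Faust variant.)
- **Distance statistics** (characteristic path length, diameter, radius)
  are computed over connected ordered pairs only, and eccentricities over
  each node's reachable set. This keeps every statistic defined when a
  removal disconnects the network; the panel carries `n_components` so
  fragmentation is visible rather than silent.
- **Clustering coefficient** is the unweighted mean of local clustering
  coefficients with degree-<2 nodes contributing 0 — the Cytoscape
  convention. Alternatives (excluding low-degree nodes, or transitivity)
  give systematically different numbers; do not compare across
  conventions.
- **Heterogeneity** is the coefficient of variation of the degree
  distribution using the population (divide-by-n) variance, and
  **centralization** is Freeman degree centralization,
  (n/(n−2))·(max_deg/(n−1) − density). Both are pure functions of the
  degree sequence, which the test suite exploits as a closed-form oracle.

Hub ranking sorts by degree, then betweenness, then closeness (all
descending), with the gene symbol as a final tie-break so the ranking is
total and reproducible.

## Fragility analysis

Each designated hub is removed *independently* from the original network
— not cumulatively — and the full panel recomputed. Independent removal
matches the usual presentation of single-knockout columns (every column
has n−1 nodes) and makes the procedure order-invariant, which is asserted
by test. Edge loss per removal is exactly the removed node's degree.

## MCODE

The three-stage published algorithm. Vertex weight = k × density of the
highest k-core of the closed neighborhood (the core-clustering
coefficient weighting). Complex growth is a traversal from the
highest-weighted unassigned seed admitting nodes whose weight reaches
(1 − node_score_cutoff) × seed weight. The admission is inclusive — a
node exactly at the boundary joins, which matters on symmetric graphs
where whole weight-classes sit exactly at the cutoff — and each node
joins at most one complex. Post-processing drops complexes without a 2-core and, with
haircut on, trims each complex to its 2-core. Defaults are the published
defaults (node score cutoff 0.2, k-core 2, haircut on, fluff off), since
that is how the reference tool is typically run. Fluff (overlapping
complexes) is deliberately not implemented. All ties — seed selection,
output order — break on the symbol, making the output a pure function of
the input. Complex score is density × size = 2e/(n−1), so a clique K_n
scores n; a printed cluster of 11 nodes and 24 edges scores 4.8.

## Enrichment and term clustering

The over-representation test is the exact upper-tail hypergeometric
(one-sided Fisher), not the EASE-penalised variant some web tools apply:
the exact test is transparent, reproducible and validated against
closed-form enumeration in the suite. Published fold-enrichment values
from such tools are therefore context, not targets. FDR is
Benjamini–Hochberg within each annotation category, mirroring the
per-ontology correction those tools perform. Terms with fewer than
`min_hits` (default 2) hits are not tested.

Term redundancy is resolved with Cohen's kappa between binary membership
vectors. The agreement domain defaults to the hit list (the practice of
meta-analysis platforms that cluster terms over the query genes) and is
configurable to the full universe. Clusters are the connected components
of the kappa ≥ threshold graph (threshold 0.3 — the conventional cut for
"similar biological meaning"), i.e. single-linkage; the representative is
the member with the smallest p (ties: larger term, then term id). Raising
the threshold can only refine clusters, never merge them — a property the
suite asserts. Multi-stage merge heuristics of specific platforms are out
of scope.

Degenerate kappa: when both marginals force agreement (p_o = p_e = 1,
e.g. both terms equal the domain) kappa is defined as 1.

## TF-regulon overlay

TRRUST-dialect rows (TF, target, mode, reference) aggregate into
regulons; duplicate TF–target pairs collapse with first-seen mode.
Coverage of a key-gene set ranks TFs by |targets ∩ key genes|, then by a
hypergeometric overlap p of the TF's targets against the network genes
within an explicit, caller-supplied universe. Published regulon-overlap
p-values computed against a database's internal background are not
reproducible without that background and are carried as context only.

## Synthetic generators

Every generator is a pure function of its parameters including the seed
(numpy `default_rng`), and returns a truth record of all planted
structure; downstream recovery tests read only the truth record.

- **Source lists**: exact support design (how many genes in exactly s of
  n sources); which sources hold a gene is uniform. Emulates multi-source
  evidence overlap; does not emulate per-source biases or scoring.
- **Degree-sequence graphs**: Erdős–Gallai check, Havel–Hakimi
  construction, then seeded degree-preserving double edge swaps. Degrees
  are exact by construction (no rejection/repair loop); rigid sequences
  (triangle, stars) simply admit no swap and return the unique
  realization. The swap walk randomises wiring but is not a uniform
  sampler over realizations — irrelevant for the degree-determined
  statistics it exists to test.
- **Planted-cluster graphs**: Erdős–Rényi background (p = 0.05, n = 40 in
  the standard scenario) plus an embedded clique (size 6). p = 1 is
  flagged degenerate (clique indistinguishable).
- **Annotations**: uniform background terms plus one planted term whose
  members are drawn with hit genes weighted `effect`-fold (default 5);
  infinite effect saturates the term with hits.
- **TF tables**: background regulons drawn from the universe minus one
  reserved key gene, plus one planted regulon containing every key gene —
  the reservation makes full-coverage recovery unambiguous by design.

None of the generators model interaction confidence scores,
literature-mining noise, or annotation bias; passing recovery tests shows
the inference chain is correct on its stated input model, not that real
databases satisfy that model.

## The packaged worked example

The 14-gene network fixture carries the published degree sequence
(7,6,6,6,5,5,5,4,4,4,3,3,2,2 → 31 edges). The exact edge list behind the
published tables was not deposited, so the package freezes one realization
reconstructed by constraint search over degree-preserving edge swaps: the
printed closeness values were converted to exact per-node distance sums,
the printed path lengths to exact distance totals, the post-removal
heterogeneity/centralization values to exact neighbor-degree constraints,
and a steepest-descent search with random restarts then found a wiring
satisfying all of them simultaneously. Statistics determined by the degree
sequence alone (density 0.341, mean degree 4.429, heterogeneity 0.338,
centralization 0.231, and all node/edge counts before and after hub
removal) are reproduced exactly by *any* realization and asserted as such.
The wiring-dependent statistics of the frozen realization equal every
published whole-network cell to the printed precision — baseline
diameter 3 / radius 2 / path length 1.934 / clustering 0.679, and the
three removal columns (diameter 6/5/4, path length 2.397/2.244/2.115,
clustering 0.636/0.597/0.672, heterogeneity 0.374/0.406/0.393,
centralization 0.227/0.212/0.311) — and the per-node betweenness and
closeness to within one unit in the last printed digit (the printed table
itself rounds inconsistently in two closeness cells, e.g. a degree-6 node
whose distance sum must be an integer cannot produce the printed 0.649).
These pins are still regression pins on the packaged realization: other
wirings with the same degree sequence exist, and the published tables do
not determine the edge list uniquely.

The per-drug predictor tables and the disease list shipped with the
fixtures are synthetic stand-ins (the originals depend on live database
snapshots): they are constructed so that the documented 2-of-3 consensus
and all-drugs overlap rules yield exactly the published 14-gene shared
set, which is what the worked example demonstrates.

## Problem sizes and determinism

The standard test scenarios use universes of 300–1000 genes, 14–50-node
networks, 20-term annotation sets and 50–100-seed recovery ensembles —
small enough to re-run interactively while large enough that planted
structure is statistically unambiguous. All randomness flows through
explicit seeds; identical configuration yields byte-identical outputs,
which the pipeline tests assert file-by-file.

## Limitations

- No weighted or directed graph support; interaction confidence scores
  must be thresholded upstream.
- DAVID/Metascape internals (EASE score, multi-stage term merge,
  proprietary annotation snapshots) are approximated by exact
  hypergeometric + single-linkage kappa clustering, so enrichment numbers
  are comparable in kind but not in digit to those platforms.
- The consensus module treats predictor outputs as plain gene sets;
  prediction scores/ranks are ignored.
- Venn reporting is capped at 5 sources.
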