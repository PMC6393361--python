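# Methods

## Network construction

A pathway collection is read as a list of interaction records, each
with a type (`directed`, `catalysis`, `inhibition`, `conversion`,
`complex_participation`, `undirected`) and role-tagged participants.
Directed types carry at least one `source` and one `target`; undirected
types use `participant` only.  Construction proceeds in a fixed order:

1. **Currency exclusion.** Participants on the exclusion list are
   removed from every record *before* any other rule, because an
   interaction reduced to one participant carries no path information.
   The shipped synthetic currency list is editable; real analyses
   supply their own (ATP, ADP, H2O, H+, NAD(H), ...).
2. **Size rule.** Records retaining fewer than two distinct participant
   entities are dropped and counted in the build report.
3. **Merging.** Records merge when they share the interaction type and
   the multiset of (entity, role) pairs.  Pathway of origin and local
   ids are ignored, so re-statements of the same interaction within one
   pathway or across pathways collapse into one interaction node with
   `occurrence_count` = number of raw records and `provenance` = set of
   pathways.  Including the type in the merge key is a deliberate
   choice: a catalysis and an inhibition over the same molecules are
   different biology; the alternative (type-free keys) would fold them.
4. **Edges.** One edge per distinct (participant, role) pair; a
   molecule appearing as both source and target of one interaction
   yields two parallel edges (the graph is a `networkx.MultiGraph`
   keyed by role).

Complexes are atomic participants; no member expansion is performed.
The resulting graph is strictly bipartite and every interaction node
has at least two distinct neighbors — both are validated invariants.
Components are reported largest-first with ties broken by smallest
member id, making summaries reproducible.

## Expression mapping

The pipeline consumes a probe-level table of log2 fold changes and
p-values (the output of an upstream differential-expression fit, which
is out of scope).  Probes undetected in every sample are removed; if no
detection flags are present the filter is a logged no-op.  Probes map
to genes through a two-column table; multi-mapping probes fan out to
all their genes (the count is logged).  Multi-probe genes collapse
under one of two rules — `min_p` (default; keeps the most significant
probe, ties broken by larger |log2FC| then probe id) or `max_abs_fc`
(strongest change, ties by smaller p then probe id).  `min_p` is the
default because the downstream module score is p-value driven, and it
preserves the strongest evidence per gene.  Merging happens after
statistical testing, not before.

Significance criteria are boolean expressions over `log2FC` and
`pvalue` with strict/non-strict comparisons exactly as written, so a
gene at exactly log2FC = 0.58 fails `log2FC > 0.58`.  Genes with
missing statistics satisfy no criterion, including negated ones.

## Active-module analysis

Scoring follows the z-aggregation scheme: `z_i = Φ⁻¹(1 − p_i)` with p
clamped into `[ε, 1−ε]`, ε = 1e-12 (so p = 0 maps to z ≈ 7.03);
`zA = Σz/√k`; corrected score `sA = (zA − μ_k)/max(σ_k, 1e-9)`.  The
calibration table (μ_k, σ_k) is estimated from `n_draws` = 2,000
uniformly random size-k subsets of the *scored* nodes per k — no
connectivity requirement, since the question it answers is "how big is
zA for an arbitrary set of k measured genes".  The σ floor only matters
for degenerate inputs where all z are equal.  Missing p-values are
never imputed: a neutral p = 0.5 placeholder would add k without
evidence and dilute every module containing it.

**Search.** One greedy expansion per scored seed node.  Candidates are
scored nodes within graph distance `2 × search_depth` of the current
module — depth is counted in biological steps, one
gene→interaction→gene hop per step, so the default depth 2 means four
bipartite edges.  Adopting a candidate brings along its shortest
connecting path.  Two details are resolved beyond the basic scheme:

* Connecting paths may pass through *scored* intermediate genes.  Those
  are adopted too and counted in k and zA, and the candidate's gain is
  evaluated jointly over the whole added set.  This lets a weakly
  changed "bridge" gene enter when the strong gene behind it justifies
  the pair — without it, weak bridges would wall off parts of the
  network.
* "Shortest connecting path" is made canonical by minimizing the label
  (distance, number of scored nodes on the path, −z-sum) 
  lexicographically.  Tie-breaking this way makes search results
  independent of the order in which the module grew, and lets a plain
  from-scratch reimplementation in the test suite reproduce trajectories
  exactly.  Exactly tied alternatives can still differ in which
  *unscored* connectors they pick; scores and scored membership are
  unaffected.

Expansion stops when no candidate strictly increases sA or when the
module reaches `max_module_scored` scored genes (default 20 — the
module scale targeted at the synthetic study size; raise it, and
`k_max` of the calibration with it, for larger analyses).  Candidates
are ranked by sA (ties: fewer members, then smallest seed id) and
thinned by the overlap filter `|A∩B|/min(|A|,|B|) > overlap_threshold`
(default 0.8; Jaccard available via `overlap_measure="jaccard"`) down
to `n_modules` = 5.  An exhaustive optimizer over connected scored
subsets is provided for tiny instances (≤ 12 scored nodes) and serves
as the search oracle in the tests; simulated annealing is deliberately
not implemented.

## Enrichment

For N measured genes, R changed, a set with n measured members and r
changed: `z = (r − nR/N)/√(n·(R/N)(1−R/N)(1−(n−1)/(N−1)))` — the exact
standardization of r against its hypergeometric moments.  Sets are
intersected with the measured background first; n = 0, R = 0 or R = N
make the variance undefined and yield a "not evaluable" marker rather
than a number.  Permutation p-values redistribute the R changed labels
uniformly over the background (`n_perm` = 2,000) and use the add-one
estimator `(1 + #{z* ≥ z})/(n_perm + 1)`, so p is never zero.  Since
N, R, n are fixed under permutation, z* is monotone in the permuted
count r* and the comparison is done on counts.  Each gene set draws an
independent permutation stream spawned from the master seed: marginally
identical to one shared label permutation, but p-values of different
sets become independent under the null.  The result filter keeps
z > 1.96 AND perm p < 0.05 AND r ≥ 5 (lenient variant: r ≥ 3).  GO
analyses are supported by supplying terms as flat gene sets; no
GO-hierarchy pruning or multiple-testing correction is applied.

## Synthetic data

The generator emulates the statistical structure of a curated
multi-pathway collection, scaled to desk size:

| parameter | default | rationale |
|---|---|---|
| interactions per pathway | log-normal, median 22, σ = 1 | skewed like real collections (mean ≈ 36 ≫ median) |
| cross-pathway share rate | 0.08 | ≈ fraction of interactions stated by >1 pathway in curated human collections |
| within-pathway duplicate rate | 0.04 | ≈ excess of multiply-occurring over multi-pathway interactions |
| participant mix (gene/met/complex) | 0.70/0.15/0.15 | gene-product dominated |
| currency metabolites | 10, attach rate 0.15 | a few promiscuous small molecules |
| planted module | 15 genes, p ~ Beta(0.05, 1) | strong but not uniform signal; ~14% of planted genes land above p = 0.05 |
| background | p ~ U(0,1), log2FC ~ N(0, 0.2) | null genes |
| probes per gene | uniform 1–3 | multi-probe arrays |

Interactions are constructed with *unique* core (post-exclusion)
participant multisets, so the only merges the builder performs are the
deliberate copies the generator recorded — which is what lets the
`GroundTruth` bookkeeping predict the built network's full summary
(node/edge/kind counts, census, multi-occurrence counts, components via
union-find) exactly and independently of the builder's code.  The
planted gene set is snowball-sampled through shared interactions, so it
is connected in the gene–interaction–gene sense and discoverable at
search depth 2.  All generators take explicit seeds; the bundle writer
and CLI derive sub-seeds from one master seed via `SeedSequence`.

What the generator does **not** emulate: realistic intensity-level
microarray data (only statistics-level tables), probe-level noise
within a gene (probes of one gene share its statistics), correlated
expression between neighboring genes outside the planted module,
identifier ambiguity across namespaces, and the hub-degree distribution
of real pathway collections.  Passing tests therefore demonstrate the
pipeline's correctness and its power under idealized planted signal,
not performance on any real disease dataset.

## Numerical and design notes

* All stochastic operations are reproducible from integer seeds; the
  CLI pipeline rerun with the same master seed is byte-identical.
* The interchange TSV dialect carries pathway titles on `#pathway:`
  comment lines so TSV and JSON emissions re-read to equal collections.
* Desk-scale study conditions used by the tests and the acceptance
  script: ~60 pathways, ~1,500 unique interactions over ~1,000 gene
  products, planted 15-gene module, 2,000 calibration draws and
  permutations, 20 seeded replicates for recovery statistics.
* Known limitations: interaction directionality is stored but not used
  by the search (topology only); gene–gene projection of the bipartite
  network is intentionally not provided; enrichment reproduces the
  filter logic and a permutation Z-score, not any specific external
  tool's internals; the greedy search is a local optimizer — on
  adversarial instances the exhaustive optimum can exceed it.
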