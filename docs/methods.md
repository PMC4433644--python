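# Methods

## Model and procedure

`modmir` identifies disease-associated protein-interaction modules and
their candidate miRNA regulators from two independent two-group expression
designs (one gene-level, one miRNA-level; the samples need not be matched
across the two).

**Differential expression.** Each feature is tested with a two-sample
t-test between the case and control groups. The default is the classical
pooled-variance Student test — consistent with the homoscedastic noise
model assumed throughout — with Welch's test behind `variant="welch"`.
Significance uses the strict inequality `p < alpha` (default α = 0.01) so
reported counts are exactly reproducible. No multiple-testing correction
is applied by default; Benjamini–Hochberg is available via
`correction="bh"`. The sign convention is fixed once: t > 0 ⇔ higher mean
in the case group ⇔ direction "up". Features that are constant within both
groups cannot be tested; they are flagged `degenerate` and assigned
t = ±∞ with P = 0 when the group means differ (t = 0, P = 1 when equal).

**Module detection.** Modules are k-clique percolation communities:
maximal unions of k-cliques in which successive cliques share k−1 nodes.
Communities may overlap, which matters biologically — signalling proteins
genuinely belong to several complexes. k defaults to 3, the smallest and
canonical choice, and is configurable. Detection is delegated to
`networkx.community.k_clique_communities`; the wrapper imposes a
deterministic order (members sorted; communities by size descending, then
lexicographically) and is verified in the test suite against an
independent exhaustive oracle (enumerate all k-cliques, build the
clique-adjacency graph, take connected components) on random graphs of up
to 12 nodes.

**Module relevance score and permutation null.** A module's score is the
mean of its members' signed t-scores, S = (Σ tᵢ)/m. Members without an
expression measurement are excluded from both the numerator and the
denominator (m counts scored members), and the permutation draws match the
scored size, so observed and null scores live on the same scale. The null
resamples gene sets of size m without replacement from the universe of all
t-scored features (not only network genes — the universe is configurable
and logged) and the empirical P is the fraction of draws with score
*strictly greater* than S; an (x+1)/(n+1) bias-corrected variant exists
behind `add_one=True` but is off by default. The test is therefore
one-sided toward case-elevated modules, as the signed sum implies; a
symmetric screen on mean |t| is available behind `absolute=True`. Null
distributions depend only on module size, so one 10,000-draw null per
distinct size is generated and shared across same-size modules — each
module's P remains a valid n_perm-draw estimate, and determinism under a
fixed seed is preserved. Significant modules (P < 0.01, strict) are
selected and sorted by (P ascending, S descending, id).

**Topology.** Degrees default to the subgraph induced by the union of all
selected-module members — the module network itself — with whole-network
degree behind `scope="full"`. Scaled connectivity Kᵢ = kᵢ/k_max uses the
maximum degree among module genes; hubs are Kᵢ > 0.9, strict. Connecting
scores always use the full network (inter-module connectors lie outside
the induced subgraph by definition). An intra-module connector's CS counts
the distinct *other* modules containing at least one of its neighbors —
membership is not linkage, so a gene belonging to every module has CS 0.
An inter-module connector (a non-member) needs partners in at least
`min_modules` distinct modules (default 2: the definitional minimum for
"linking distinct modules", with the stricter reading available by
raising the parameter). Both lists sort by (CS desc, degree desc, symbol);
boundary ties in a top-n selection resolve by those secondary keys and are
logged.

**miRNA regulators.** The consensus map keeps a predicted (miRNA, gene)
pair when at least two distinct tools (of a declared vocabulary, default
PicTar/miRanda/MicroT/TargetScan) agree, and unions in experimentally
supported pairs unconditionally. Enrichment of a miRNA's targets in a
module is a one-sided (greater) Fisher exact test on the 2×2 table
(in-module × is-target) over a declared universe. The default universe is
the intersection of network genes and target-map genes: genes that cannot
structurally be targets would otherwise inflate significance. Because the
gene and miRNA samples are not matched, repression cannot be assessed by
per-sample correlation; instead each significant call carries a
direction-based flag — *anti-correlated* iff every in-module target with a
direction changes opposite to the miRNA. Mixed directions fail the flag; a
call with no directed target is marked not-evaluable rather than false.

## Synthetic benchmark

The generator emulates the statistical structure the analysis assumes,
with defaults chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| n_genes / n_mirnas | 1000 / 100 | desk-scale versions of a genome-wide array and a miRNA panel |
| n_samples_per_group | 25 | mid-sized two-group cohort; variance well estimated |
| n_planted_modules × size | 5 × 8 | within the 3–11 size range clique communities typically span |
| planted_effect_size | 3.0 (Cohen's d) | strong, clearly detectable shift (pooled-t power ≈ 1 at n = 25) |
| background_noise_sd | 1.0 | expression units; homoscedastic Gaussian, matching the pooled test |
| ppi_mean_degree | 4.0 | see below |
| intra_module_edge_prob | 0.9 | near-clique planted communities |
| targets_per_mirna | 12 | sparse map, ~1% of the gene universe per miRNA |
| planted_regulator_fraction | 0.1 | a minority of miRNAs are true repressors |

The background graph is Barabási–Albert preferential attachment rather
than Erdős–Rényi because scaled connectivity is only meaningful on a
heavy-tailed degree distribution, as real interactomes have. The mean
degree is deliberately below a real interactome's (~8): at n = 1000 a BA
background with mean degree ≥ 6 makes 3-clique percolation supercritical —
one giant community of hundreds of nodes absorbs every planted clique —
whereas curated interactomes sit in the subcritical regime of many small
overlapping communities. Mean degree 4 keeps the background subcritical so
the generator honors its own contract that planted communities are denser
than background and hence detectable.

Planted communities are disjoint and placed on uniformly chosen nodes (not
attachment-order hubs); their members are shifted *up* in the case group;
planted regulator miRNAs are shifted *down*, and draw ⌈targets_per_mirna/2⌉
of their targets from their intended community, the rest uniformly. Each
artifact (graph, gene expression, miRNA expression, target map) uses its
own RNG stream derived from the single seed by fixed offsets, so artifacts
regenerate independently and reproducibly.

What the generator does **not** model: array-platform and probe-level
artifacts, batch effects, heteroscedastic or correlated noise,
down-shifted modules, and sequence-based miRNA targeting biology. Passing
the recovery suites therefore shows the machinery is correct and
calibrated under its own assumptions, not that real lesion cohorts will
yield modules this cleanly.

**Recovery metric.** A planted community counts as recovered when some
selected module has Jaccard overlap ≥ 0.5 with it; a planted regulator
counts when it has a significant, anti-correlated call on a module that
recovers its intended community. Jaccard (not mere coverage) is used so a
spuriously giant community containing a planted set does not count.

## Numerical and degenerate-input choices

* Empirical P granularity is 1/n_perm; with strict-greater counting P = 0
  is possible and is reported as computed (the add-one option exists for
  users who need nonzero Ps).
* Module score equality with a direct mean recomputation is tested to
  1e-12; t-tests match the textbook pooled formula to 1e-10 relative.
* Self-loops and duplicate edges are dropped (and counted) at PPI read
  time; an empty edge file yields an empty network with a warning, and a
  malformed line is an error naming the line number.
* A module none of whose members carries a t-score is skipped with a
  warning; a universe smaller than a module is an error.
* knn imputation candidates must be observed at the target column;
  distance is the mean squared difference over co-observed columns (so
  rows with different overlaps are comparable), with a row-mean fallback
  when no candidate exists. This small utility is implemented in-package
  to keep exactly these documented semantics.

## Reference tables

The bundled TSVs transcribe a published thirteen-module oral-cancer
dataset (module memberships with DEG flags, a relevance-scored known-gene
list, hub degrees and connecting scores, miRNA/target change directions);
they are fixtures for the dataset-level recomputations, checksummed so any
edit is detected at load time. One internal inconsistency in the source
material (one miRNA described in prose with the opposite orientation to
its tabulated direction) is preserved as tabulated and noted in the
fixture header, not resolved. The printed connecting scores of the
reference dataset are not recomputable from the bundled tables alone
(they require the full underlying interactome), so the package asserts
its own explicit CS definition on synthetic data instead.

## Known limitations

* The one-sided signed score misses modules coherently *down* in cases;
  use `absolute=True` for a symmetric screen.
* Clique percolation is parameter-sensitive: k is exposed rather than
  asserted, and on dense graphs background percolation can merge
  communities (see the mean-degree discussion above).
* Direction-based anti-correlation is a weak surrogate for repression;
  with matched samples a correlation test would be stronger.
* The Fisher universe choice materially affects P-values; it is logged on
  every run and should be reported alongside results.
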