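# Methods

This note documents the models and procedures implemented in `gcnrefine`,
the numerical conventions they rely on, the design choices made where the
design was genuinely open, and what the simulator does and does not
emulate.

## Network construction

**Correlation.** Pearson by default; Spearman is available (ranks are
taken per gene, then the Pearson machinery applies). Genes with zero
variance are rejected with a named error rather than propagating NaNs.
Correlation needs at least 3 samples; network construction assumes at
least 2 genes.

**Adjacency.** For a correlation c and an integer soft threshold β ≥ 1:
unsigned `|c|^β`, signed `((1+c)/2)^β`. The signed map sends c = −1 to 0,
c = 0 to `2^−β` exactly, and c = 1 to 1, so anti-correlated genes get
near-zero adjacency instead of a strong edge. Diagonals are forced to 1.

**Soft-threshold selection.** For each candidate β (default 1..20) the
connectivity `k_i = Σ_{j≠i} adj(i,j)` is computed, discretized into 10
equal-width bins, and `log10(bin frequency)` is regressed on
`log10(bin mean k)`. The fit index is the signed R², `−sign(slope)·R²`, so
only decreasing connectivity distributions (the scale-free signature)
score positively. The chosen β is the smallest candidate reaching the cut
(default 0.85); if none does, the argmax with `met_cut=False`. Equal-width
binning is the convention of the reference implementation of this fit;
equal-count binning would make every bin frequency identical by
construction and the regression degenerate. Bin count, cut, and candidate
range are all parameters. The chosen β is always recorded in outputs,
since reasonable datasets can select anywhere in the range.

**Topological overlap.** For i ≠ j,

    TOM(i,j) = (L(i,j) + a(i,j)) / (min(k_i, k_j) + 1 − a(i,j)),
    L(i,j)   = Σ_{u≠i,j} a(i,u) a(u,j),

with diagonal 1; the clustering distance is `1 − TOM` with zero diagonal.
This is the standard unsigned TOM recurrence, applicable to signed
networks because signed adjacency is already non-negative. The matrix is
computed with blocked dense products (configurable block size); results
agree across block sizes to < 1e−12, and the implementation is tested
against an O(m³) triple-loop oracle at 1e−12. Dense desk-scale computation
is a deliberate scope bound — no block-wise approximate module detection
for very large gene sets.

## Module detection

**Clustering.** Average-linkage hierarchical clustering of `1 − TOM`
(scipy's linkage on the condensed distance). Merge heights are forced
monotone to absorb floating-point noise.

**Dendrogram cut.** Two variants, both parameterized by
`min_module_size` (default 30) and `cut_height` (default 0.99):

- `static`: flat cut at `cut_height`; components of at least
  `min_module_size` leaves become modules.
- `tree` (default): the same height threshold, followed by a recursive
  branch decomposition. A merge is split when it is a clear bifurcation —
  both child subtrees sit at least `split_gap` (default 0.05) below the
  merge height — or when one child hangs that far below with at least
  `min_module_size` leaves while its sibling continues a plateau of
  near-equal merge heights (the shape three or more equidistant clusters
  produce). Tight clusters, whose stray children are single leaves joining
  just below the cluster top, are not split. Branches smaller than
  `min_module_size` stay unassigned.

The `split_gap` default was chosen by inspecting average-linkage TOM
dendrograms of simulated modular data, where within-module merges are
separated from between-module merges by gaps an order of magnitude larger
than 0.05; it is exposed as a parameter. This decomposition is a
deliberately simple stand-in for the reference ecosystem's dynamic
tree-cut family: no PAM-like reassignment stage and no branch merging by
eigengene correlation. Genes the cut leaves unassigned can be given to
their best module by kME (`assign_unclustered`), which is also the
recommended preprocessing before refinement.

**Labels.** Modules are numbered 1..k by decreasing size; 0 is the
unassigned ("grey") label, serialized as `0` or, on request, `grey`.

**Eigengenes.** Member genes are standardized per gene (zero mean, unit
variance with the n−1 denominator), the first principal component score
vector across samples is taken from the SVD, standardized the same way,
and sign-flipped so the mean correlation with member genes is
non-negative. When that mean is exactly zero the solver's sign is kept and
the module is flagged in `sign_ambiguous`. Correlation PCA (standardized
genes) is used rather than covariance PCA because module membership is
defined through correlation. The explained-variance fraction is recorded
per module.

**Module membership and misplaced genes.** kME is the gene × module matrix
of Pearson correlations with the eigengenes. A gene in module i is
*misplaced* iff some other module j has strictly higher kME; ties never
misplace, and unassigned genes are never counted.

## The k-means refinement

Given a seed partition with k ≥ 2 modules:

1. compute eigengenes of the current partition (the centroids);
2. reassign every gene to the module whose eigengene minimizes the
   co-expression distance — signed `(1 − cor)/2`, unsigned `1 − |cor|`;
3. record diagnostics; repeat from 1 until no gene moves, a positive
   misplaced-gene target is reached, or `max_iterations` (default 20) is
   hit.

Conventions, each of which makes the loop a deterministic fixed-point
iteration:

- **Ties** keep the gene's current module when it is among the tied
  candidates, otherwise the lowest tied label wins.
- **Unassigned genes** contribute no centroid by default and are captured
  by the nearest real module in the first iteration; a config flag can
  instead fold them into a module of their own. Pre-assigning them by kME
  (`assign_unclustered`) before refining reproduces the standard protocol
  for grey genes.
- **Emptied modules** are dropped (k shrinks) and recorded in the trace;
  dropping below k = 2 raises. In practice a module can only empty when
  its members split across at least two distinct outside attractors,
  because the eigengene of a module tracks its members' shared signal and
  own-module kME is inflated by each member's own noise; the
  `empty_module_trap` fixture exercises exactly that geometry.
- **Centroids are recomputed from scratch each iteration**, never
  incrementally updated.
- With the default target of zero misplaced genes in signed mode, reaching
  the target coincides with the k-means fixed point (argmin-distance is
  argmax-kME), so the loop terminates through the no-moves condition; a
  positive target short-circuits earlier.

The iteration cap matters: a gene sitting almost exactly between two
eigengenes can oscillate in a 2-cycle, because moving it perturbs both
eigengenes enough to flip the preference. The cap bounds such runs; they
are rare (background noise genes at desk scale) and leave the bulk
assignment unaffected.

**Within-cluster distance.** `W(P) = Σ_k Σ_{p(i)=k} ‖ĝ_i − c_k‖²` is
computed on gene profiles and eigengenes standardized with the n−1
denominator, so that per gene `‖ĝ − c‖² = 2(n−1)(1 − cor(ĝ, c))` holds
exactly and W is affinely equivalent to the signed correlation distance
the assignment step optimizes. Unassigned genes contribute nothing.

**Trace.** Per iteration: moved-gene count, W(P), the mean kME of the
moved genes measured at their seed module against the *seed* partition's
eigengenes, the mean own-module kME of all genes, per-module Euclidean
drift between successive (sign-aligned) eigengenes, and any dropped
modules.

## Evaluation statistics

**Similarity indices.** From the contingency table of two partitions over
the same gene universe: pair-counting Rand `(a+d)/(a+b+c+d)` and Jaccard
`a/(a+b+c)`, plus a matching index — the fraction of genes captured by an
optimal one-to-one module matching, computed by maximum-weight bipartite
matching on the contingency table. The matching index is 1 exactly when
the partitions coincide up to relabeling. The unassigned label is treated
as a regular cluster, which keeps all three indices total and
label-permutation invariant; callers who want background genes excluded
can subset the partitions first. The matching index is this package's
concrete interpretation of the loosely specified "similarity index"
reported alongside Rand and Jaccard in the clustering literature.

**Enrichment.** One-sided Fisher exact tests (exact hypergeometric upper
tail) per (module, gene set) pair, Benjamini–Hochberg adjustment across
the whole batch, odds ratios with Haldane correction when a table cell is
zero. `s_GO` per module sums `−log10(p)` over results whose gated p-value
(BH-adjusted by default, raw by flag) clears alpha (default 0.05); the raw
p enters the sum by default, also switchable. `S_GO` sums over modules,
and the relative improvement of one partition over another is
`S_GO(after)/S_GO(before) − 1`. For cell-type marker analyses the same
path applies with a stricter gate (1e−4 on raw p) configured at the call
site. Term information content is `IC(t) = −ln P(t)` from a supplied
term → probability table (log base configurable; no ontology traversal —
gene sets arrive as GMT, frequencies as TSV).

**Random-reassignment null.** Genes whose module differs between a seed
and a refined partition are pooled and redistributed uniformly at random
subject to the refined module sizes; unchanged genes stay put. This
isolates how much of an enrichment gain is explained by module-size
changes alone. Deterministic given its RNG seed.

## The simulator

Each module is anchored by a latent eigengene profile — supplied, or
sampled as standard-normal vectors kept near-orthogonal (pairwise |cor| <
0.3) by rejection. A member gene with target correlation r (drawn
uniformly per gene from `within_module_cor_range`, default [0.6, 0.95]) is

    g = r·eg + sqrt(1 − r²)·ε,   ε iid standard normal,

so its marginal variance is 1 and its expected correlation with the
eigengene is exactly r. A configurable fraction of module genes is
anti-correlated (r sign-flipped) for unsigned fixtures; background genes
(default 10% of the pool) are pure noise and carry the unassigned truth
label. Defaults (150 samples, 600 genes, 6 modules with proportions 0.2
down to 0.1) produce planted structure that the full pipeline recovers
while leaving the soft-threshold scan, the cut, and the refinement
non-trivial work to do.

What the simulator does **not** emulate: correlated noise between modules,
heavy-tailed or count-distributed expression, batch structure, overlapping
module membership, and the maxCor→minCor gradient of the reference
simulator's within-module correlation schedule (a uniform draw replaces
it). Passing tests on simulated data therefore demonstrate correctness of
the algorithms under the stated generative model, not performance on real
microarray or RNA-seq data, where misplaced-gene counts and enrichment
gains are empirical questions.

Three canonical fixtures (`make_toy_fixture`) are used throughout the test
suite: `two_block` (two near-perfect 40-gene modules),
`five_module_scrambled` (five well-separated modules with 10% of true
labels moved, the refinement's showcase), and `empty_module_trap` (a seed
module carved from genes of two other modules, which refinement empties
and drops).

## Problem sizes and determinism

The acceptance script and test suite run at desk scale: oracle checks on
up to 12 genes (1,000 TOM draws, 500 partition pairs, 200 Fisher tables),
refinement studies on 250-gene / 5-module fixtures over 20 seeds, and
end-to-end pipeline studies on 600-gene / 150-sample / 6-module datasets
over 20 seeds. All randomness flows from explicit integer seeds; identical
seeds give bit-identical simulated data and partitions.

## Known limitations

- Dense O(m²) memory for correlation, adjacency and TOM; tens of
  thousands of genes need more RAM than a desk-scale analysis budget.
- The dynamic tree cut is a simplified branch decomposition (see above),
  not a reimplementation of the hybrid/PAM variants.
- No k search and no random restarts: k comes from the seed partition and
  only shrinks (dropped empty modules), per the method's design.
- Multiple-testing control is plain Benjamini–Hochberg; specialized
  ontology-aware corrections are out of scope, as is GO DAG handling.
- Covariate residualization is ordinary least squares per gene with a
  pre-encoded design; no surrogate-variable estimation.
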