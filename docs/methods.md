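# Methods

## Model

`netprop` scores genes for disease association in two stages.

**Stage 1 — propagation features.** An undirected PPI network with
adjacency A and diagonal degree matrix D is reduced to its main connected
component (deterministic tie-break: the component containing the
lexicographically smallest node). Each seed list of size *s* defines a
prior Y with mass 1/*s* on the seed genes present in the network (absent
genes are dropped with a warning and do not count toward *s*, so Y always
sums to 1). The diffusion

    F ← α W F + (1 − α) Y

is iterated from F = Y until the maximum absolute change falls below `tol`.
With the default symmetric operator W = D^(−1/2) A D^(−1/2) the spectral
radius of W is at most 1, the map is an α-contraction in the 2-norm, and
the fixed point equals the direct solve (1 − α)(I − αW)^(−1) Y; the test
suite verifies iterative/direct agreement to below 1e−6 on hundreds of
random graphs. A row-stochastic operator D^(−1) A is available as a
configuration alternative. α is the network-diffusion weight (restart
weight 1 − α), following the damping usage of PageRank-style walks; the
default is 0.8, i.e. most mass flows through the network.

**Degree-bias normalization.** Raw fixed-point scores correlate with degree
regardless of seed identity. Each raw score is divided by the score the same
node receives under the uniform seed (1/n everywhere) computed with the same
configuration. As α → 1 the uniform-seed fixed point converges to the
operator's dominant eigenvector, so this baseline is an eigenvector-
centrality-like profile of pure connectivity signal; division by it is the
package's concrete instantiation of centrality-based normalization, chosen
for being self-consistent with the propagation operator (no second method
with its own conventions) and swappable behind `normalize_scores`. On
heavy-tailed graphs the median |Spearman correlation with degree| over 200
single-node seeds drops roughly five-fold after normalization (measured by
`scripts/acceptance.py`).

**Stage 2 — classification.** The K normalized score vectors form a
genes × K feature matrix (genes outside the network's main component have no
features — a documented limitation: the classifier's universe is the
network). A random forest with 100 trees, unlimited depth and
`min_samples_split = 2` (scikit-learn defaults) is trained on curated
positives against an equal number of negatives sampled uniformly, once per
experiment, from network genes outside an exclusion list (the emulation of
"no evidence in the curated database"). The per-gene score is the forest's
positive-class vote fraction.

**Evaluation.** Stratified 5-fold cross-validation (stratification keeps the
1:1 class balance in every fold; the fold assignment is seeded) reports
per-fold AUROC/AUPRC, their arithmetic means, vertically averaged ROC/PR
curves on a common 101-point grid (for plotting; the scalar means are the
headline numbers), and pooled out-of-fold scores. Operating cutoffs are
selected by exhaustive search over all observed score values (plus +∞ for
the all-negative rule) under the inclusive rule "positive iff score ≥
cutoff", maximizing either specificity × sensitivity or precision + recall;
ties break toward the smallest cutoff. Candidate gene groups are compared
against an equally sized random draw from the scored universe (group
excluded) with a two-sided Wilcoxon test; the default is the rank-sum test
because the groups are independent samples, with the signed-rank variant
(pairing by sampled index) available, and optional degree-quantile-matched
control sampling (off by default).

**Negative control.** Degree-preserving randomization by double edge swaps,
(a,b),(c,d) → (a,c),(b,d), rejecting self-loops and duplicate edges, with
10 successful swaps per edge — the conventional burn-in for approximate
uniformity over the fixed-degree ensemble. Graphs with fewer than four nodes
admit no legal swap and are returned unchanged. The output may fragment;
the pipeline re-extracts the main component before propagation.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.8 | diffusion weight; higher = smoother, longer-range scores |
| `tol` / `max_iter` | 1e−8 / 1000 | fixed-point stopping rule; exceeding `max_iter` is a hard error, never silent truncation |
| `operator_norm` | symmetric | `row_stochastic` gives a probability-flow reading |
| `negative_ratio` | 1.0 | negatives per positive; 1:1 mirrors the curated-positives design |
| `n_trees` | 100 | forest size; scores are vote fractions, so granularity is 1/`n_trees` |
| `swaps_per_edge` | 10 | null-model burn-in; edge Jaccard to the input decreases monotonically in it |

## The synthetic benchmark

`generate_benchmark` builds a preferential-attachment network (default 2000
nodes, 3 edges per arriving node), chosen for its heavy-tailed degree
distribution — the property of real PPI networks that makes degree-bias
normalization consequential. A random `module_size`-node set is designated
the disease module; each of `n_seed_lists` seed lists draws
`seed_overlap_frac` of its members from the module and the rest from the
background; `n_positives` module genes are the training positives and the
whole module is the exclusion list. Defaults (10 lists of 60 genes, module
100, overlap 0.5, 50 positives) emulate the scale of a multi-study
integration at desk size.

Two generator options matter for the controls:

- `densify_p` adds module-internal edges with the given probability, making
  the module topologically coherent the way real disease modules are.
- `exclude_positives_from_seeds` keeps training positives out of every seed
  list, so they are recoverable only through network proximity.

The degree-null control experiment uses both (`densify_p = 0.1`, positives
excluded, overlap 0.75). This is deliberate: in the plain benchmark nearly
every positive appears in several seed lists, and direct seed membership
survives edge randomization by construction, so shuffled topology loses
essentially nothing. Only when the signal must flow through the network —
positives unseeded, module connected — does the degree-preserving null
measure what it is meant to measure; under that design randomization costs
0.15–0.3 AUROC.

What the generator does **not** emulate: correlated evidence between seed
lists beyond shared module membership, study-specific biases, noisy or
graded label quality, weighted interactions, and any real biology of the
gene identifiers. Passing tests therefore demonstrate that the pipeline
recovers a planted association structure through a heavy-tailed network —
not that any particular biological claim holds.

## Numerical and design choices

- Gene identifiers are opaque, case-sensitive strings; no symbol mapping.
- Edge weights are accepted on input and enter the degree matrix; the
  default networks are unweighted.
- Duplicate and reversed-duplicate edges collapse to one (first weight
  wins); self-loop rows are dropped with a warning.
- The chance control averages 10 label permutations: a single permutation
  of 100 labels has AUROC standard deviation ≈ 0.08, so one draw is not a
  meaningful chance estimate.
- Negative sampling happens once per experiment, not per fold, matching the
  fixed positive/negative design the classifier emulates.
- All randomness (graph generation, module placement, negative sampling,
  fold shuffling, forest bootstrap, edge swaps, control draws) is owned by
  explicit integer seeds; identical seeds give bit-identical outputs,
  including written files.
- Degenerate inputs fail loudly: empty files, empty or duplicate gene sets,
  seed sets fully absent from the network, one-class cutoff selection,
  control pools smaller than the tested group, non-convergence.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run at desk scale: solver/oracle
agreement on 100 graphs of 50–200 nodes at four damping values; bias
reduction with 200 single-node seeds on an ~800-node configuration-model
graph; benchmark recovery, chance control and the degree-null gap on the
2000-node default benchmark; overlap monotonicity over five generator seeds;
rank-test calibration over 400 null repetitions. These sizes make the full
suite run in about a minute while keeping every estimate's sampling error
well inside the asserted margins.

## Known limitations

- Genes outside the network's main component are never scored.
- The eigenvector-centrality normalization is one defensible instantiation;
  other centrality baselines would give different (rank-similar) features.
- The rank-sum default differs from the signed-rank name sometimes used for
  this comparison; both are implemented, and for independent group-vs-random
  comparisons the rank-sum test is the statistically appropriate one.
- Forest vote fractions are not calibrated probabilities; cutoffs chosen on
  out-of-fold scores transfer to full-model scores only approximately.
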