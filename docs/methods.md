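# Methods

## The problem and the approach

Likelihood-based tree search explores tree space by rearranging a current
tree and scoring the rearranged candidates. For an unrooted binary tree on
n taxa the subtree-prune-and-regraft (SPR) neighborhood contains
2(n−3)(2n−7) distinct topologies, and scoring each one honestly requires
re-optimizing branch lengths — by far the dominant cost of the search.
`sprank` trains a regressor to predict, from 19 cheap features of a
(tree, move) pair, how much a move would change the log-likelihood, and
uses the predicted ranking to evaluate true likelihoods for only a small
top fraction of the neighborhood at each hill-climbing step.

## Trees, moves, and the enumeration convention

Trees are unrooted and strictly binary (internal degree 3), with
non-negative branch lengths in expected substitutions per site and stable
integer branch ids. A rooted Newick input is unrooted by merging the two
root branches (lengths summed). Two-taxon trees are supported as a
degenerate case for closed-form checks.

An SPR move is a (directed pruned branch, regraft branch) pair: the pruned
subtree *b* is detached, the two branches flanking the detachment point are
merged (lengths summed), and *b* is reattached in the middle of the regraft
branch, which is split into two halves pending branch-length
re-optimization. Enumeration excludes the regraft positions that recreate
the starting topology and deduplicates by resulting topology (several
NNI-type move descriptions can yield the same neighbor), keeping the first
move in sorted order. This yields exactly 2(n−3)(2n−7) moves for every
binary shape, which the tests verify against a brute-force surgery oracle.

## The 19 features

For a move on tree *a* with pruned subtree *b*, remaining tree *c* and
regraft-branch sides *c1* (nearer the detachment point) and *c2*:

| # | name | definition |
|---|------|------------|
| 1 | `total_bl` | sum of branch lengths of *a* (move-invariant) |
| 2 | `longest_branch` | longest branch of *a* (move-invariant) |
| 3 | `pruned_bl` | length of the pruned branch |
| 4 | `regraft_bl` | length of the regraft branch |
| 5 | `topo_dist` | number of branches strictly between the pruned and regraft branches |
| 6 | `bl_dist` | summed length of those branches |
| 7 | `new_branch_bl` | length of the branch formed by the pruning (the merged pair) |
| 8–11 | `n_leaves_*` | leaf counts of *b*, *c*, *c1*, *c2* |
| 12–15 | `total_bl_*` | branch-length sums of the four subtrees |
| 16–19 | `longest_bl_*` | longest branches of the four subtrees |

Conventions that were genuinely open and are fixed here: the path for
features 5–6 is measured on the starting tree from the detachment node to
the nearer endpoint of the regraft branch, excluding both terminal
branches, so the nearest allowed regraft has `topo_dist = 1`; feature 7 is
defined as the merged-branch length — it is the only branch literally
created by the pruning and is computable in constant time; *b*'s totals
include its stub (the pruned branch itself) while *c1*/*c2* exclude the
regraft branch, so `total_bl_c1 + total_bl_c2 + regraft_bl = total_bl_c`
holds exactly.

`batch_features` computes all moves of a tree from shared directed-subtree
aggregates (two traversals) plus a short path walk per move. Branch-length
sums on both the batch and the per-move route go through one
correctly-rounded summation helper over canonically ordered branch sets, so
the two routes agree bit-for-bit and the equivalence test can demand exact
equality.

## Likelihood model and optimization

Likelihoods use Felsenstein's pruning algorithm over compressed site
patterns under GTR+I+G: six exchangeabilities (GT fixed at 1), stationary
frequencies taken from empirical counts, a proportion `p_inv` of invariant
sites, and discrete-gamma rate heterogeneity with 4 categories whose rates
are the means of the quantile intervals (mean 1). With invariant sites the
variable categories are rescaled by 1/(1−p_inv) so the expected rate over
all sites stays 1 and branch lengths remain in substitutions per site. Gap
and ambiguity characters contribute a partial likelihood of 1 (missing
data). Partial likelihood vectors are rescaled per node per (category,
pattern) with accumulated log factors.

Branch lengths are optimized coordinate-wise within [1e−8, 100]
substitutions/site: a depth-first sweep visits every branch, reduces the
likelihood to a one-dimensional function of that branch via the
eigendecomposition of the rate matrix (a fixed coefficient tensor dotted
with `exp(λ_m r_k t)`), and maximizes it by a safeguarded Newton iteration
on log t with analytic first and second derivatives (bounded golden-section
as fallback; a candidate worse than the current length is never accepted,
so sweeps are monotone). Downward partials are refreshed as the sweep
returns from each subtree, making the pass an exact Gauss–Seidel update.
Sweeps repeat until the per-sweep improvement falls below `tol` (default
1e−6 log-likelihood units, at most 20 sweeps).

Model fitting on the starting tree alternates bounded L-BFGS-B over
{log exchangeabilities, log gamma shape, p_inv} with branch-length sweeps
(two rounds). Because the gamma-shape direction is flat near homogeneity
and can under-converge, the returned model is the likelihood-best of the
full fit and its nested homogeneous and Jukes–Cantor special cases, each
scored after a short branch-length re-optimization. Model parameters are
fit once on the starting tree and held fixed for all neighbors and along
search chains; only branch lengths are re-optimized per neighbor.

## Targets, transform, and the forest

The label of a move is `target = (LL_neighbor − LL_start) / LL_start`,
where both likelihoods are branch-length-optimized under the fixed model.
`LL_start < 0`, so improving moves have negative targets; rankings sort by
predicted ΔLL = target·LL_start descending with ties broken by move id.
Targets are trained through `f(t) = 2^(t+1)` (strictly increasing, inverse
`log2(y) − 1`), which spreads the heavily concentrated raw ratios.

The ranker is scikit-learn's random-forest regressor with 70 trees and
ceil(k/3) features tried per split (7 of 19); tree depth and leaf sizes are
library defaults, recorded in the model's training metadata together with
the seed. All stochastic operations take explicit seeds and are
deterministic given them.

## Accuracy metrics and cross-validation

Per dataset: (1) Spearman ρ between true and predicted move scores (average
ranks for ties; +1 = perfect agreement); (2) the percentile rank
(100·rank/n, rank 1 best) of the empirically best move within the predicted
ranking; (3) the percentile of the predicted-best move within the true
ranking; and whether the predicted-best move truly improves the start.
Cross-validation folds partition whole datasets (a starting tree's moves
never span folds), with fold assignment shuffled deterministically by seed.

Feature studies: 19 single-feature forests scored by cross-validated mean
ρ, and backward stepwise elimination that repeatedly drops the
minimal-importance feature (impurity importances) and records each nested
set's mean ρ.

## Guided search

At each iteration all moves are enumerated and ranked; true likelihoods are
computed for the top ceil(top_fraction·n_moves) candidates (default 5%,
never fewer than `min_candidates = 5`), and the search moves to the best
evaluated candidate if it improves the current log-likelihood by more than
`accept_tol = 1e−3` (guarding against cycling on numerical noise); it stops
otherwise. Rankings are recomputed from scratch each iteration. A
`first-improvement` mode instead evaluates candidates in ranked order and
takes the first improving one. With a perfect oracle as the ranker the
guided chain provably retraces exhaustive hill-climbing, which the tests
assert.

## The synthetic corpus

The generator stands in for an empirical phylogeny collection. Topologies
are uniform over labelled binary trees (a Yule-like option exists); branch
lengths are i.i.d. exponential with mean 0.1 substitutions/site.
Substitution parameters span realistic ranges: exchangeabilities i.i.d.
lognormal(0, 0.5²) with GT = 1, frequencies Dirichlet(5,5,5,5), gamma shape
uniform on (0.5, 2), invariant proportion uniform on (0, 0.3). Sites evolve
with continuous gamma rates (rescaled by 1/(1−p_inv)), root states drawn
from the stationary distribution.

The study corpus used by the test suite and the acceptance script is 20
datasets with 7–16 taxa and 300–500 sites. These sizes are the package's
choice of a desk-scale experiment: the per-dataset labelling cost grows
roughly cubically with the taxon count (quadratically more neighbors, each
with linearly more branches to optimize), and 20 datasets at this size keep
the complete pipeline — corpus generation under two labelling models,
ten-fold cross-validation, feature studies, transfer experiment, and the
search comparison — runnable end to end in well under an hour on one core.
Labels use branch-length tolerance 1e−3 (8 sweeps) per neighbor and 1e−4
(10 sweeps) for the starting tree; the residual label noise (~0.01 LL
units) is far below typical between-move spacing.

What the generator does *not* emulate: alignment gap/indel structure
(sequences are ungapped; missing-data handling is exercised separately),
model misspecification beyond the JC-vs-GTR transfer design, linked or
partitioned loci, and the systematic distance-versus-likelihood conflicts
of real data. The last point matters for interpretation: on clean simulated
alignments the neighbor-joining starting tree frequently *is* the
maximum-likelihood topology, so many synthetic datasets have no improving
SPR neighbor at all — unlike empirical collections, where the NJ start is
essentially always improvable. Passing ranking-accuracy tests therefore
demonstrates that the features order candidate moves correctly, but the
fraction of datasets whose top-ranked move strictly improves the start is
structurally lower here than it would be on empirical data, and the
corresponding end-to-end check is expected to reflect that.

## Numerical and degenerate-input choices

Saturated distance pairs (p ≥ 3/4) and pairs with no comparable sites are
capped at a configurable maximum (default 10 substitutions/site) with a
logged warning; negative NJ branch estimates are clamped to zero. Newick
output is deterministic (rooted for serialization at the neighbor of the
alphabetically first taxon, children ordered by smallest leaf label) and
round-trips topology and lengths at 10 significant digits. Trees with
fewer than 4 taxa have an empty SPR neighborhood. Constant score vectors
make Spearman ρ undefined and return NaN with a warning rather than a
fabricated value.

## Known limitations

- The likelihood engine targets correctness and desk-scale speed, not
  PhyML/RAxML-NG throughput; the practical range is tens of taxa.
- Only nucleotide data and SPR moves are supported (no NNI/TBR, no
  amino-acid or codon models, no partitioned models).
- Base frequencies are empirical, not ML-optimized; per-neighbor
  optimization covers branch lengths only.
- Impurity-based feature importances are biased toward high-cardinality
  features; they are used only to order eliminations, not as effect sizes.
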