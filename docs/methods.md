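# Methods

This note documents the models, algorithms and design choices implemented
in `phylonj`, the assumptions they make, and what the test suite does and
does not demonstrate.

## Problem setting

Input: a DNA multiple sequence alignment (MSA) of `N` taxa and `L` aligned
sites over `{A, C, G, T, -}`. Output: an unrooted binary tree topology on
the `N` taxa. Branch lengths are a secondary quantity here — they are
estimated only where the likelihood machinery needs them — and topologies
are compared with the normalized Robinson–Foulds (RF) distance.

## Tree representation and metrics

Trees are stored as rooted structures (dendropy `Tree` objects) but always
*interpreted* unrooted: all comparisons go through the set of nontrivial
bipartitions (splits), which is invariant to the storage rooting. A split
is stored canonically as its smaller side (lexicographic tie-break), a
binary unrooted tree on `N` leaves has exactly `N − 3` of them, and

    RF_raw  = |splits(T1) Δ splits(T2)|
    RF_norm = RF_raw / (2 (N − 3))          (0 for N ≤ 3)

The `2(N − 3)` denominator is the maximum attainable symmetric difference
between two *binary* trees, which pins `RF_norm` to `[0, 1]`; non-binary
inputs would need the smaller resolvable-split denominator, which we do not
implement (all trees produced in this package are binary).

Classical neighbor joining follows Saitou–Nei: join the pair minimizing
`Q(i,j) = (k−2) d(i,j) − Σ_m d(i,m) − Σ_m d(j,m)`; ties break to the
smallest index pair so the construction is deterministic; negative
branch-length estimates are clamped to zero (this never changes the
topology, and lengths are not the evaluation target).

## Substitution model and likelihood

The GTR generator is `Q_ij = r_ij π_j` (i ≠ j) with the diagonal fixed by
zero row sums and the whole matrix scaled so `−Σ_i π_i Q_ii = 1`; branch
lengths are then expected substitutions per site. `P(t) = exp(Qt)` is
computed through the symmetric eigendecomposition
`diag(√π) Q diag(1/√π)`, with `P(0)` returned as the exact identity so
zero-length branches give exact indicator propagation.

Rate heterogeneity is the standard I+G mixture: a site is invariant with
probability `p_inv`, otherwise falls in one of `K = 4` equiprobable
discrete gamma categories. The category rates use the median-of-category
(quantile midpoint) discretization of Gamma(α, 1/α), renormalized to mean
1. A site's likelihood is

    L(site) = p_inv · [site potentially constant] · π_x
            + (1 − p_inv) · (1/K) Σ_k L_pruning(rate r_k)

where "potentially constant" means every non-gap observation shares state
`x` (an all-gap column contributes likelihood 1). Pruning uses per-node
max-rescaling with log accumulators, and category mixing happens in log
space via logsumexp; impossible data return exactly `−inf`.

Branch lengths for decoder topologies (which are topology-only) come in
two modes: `fixed` sets every branch to 0.1 — the cheap default used when
ranking sampled trees — and `optimize` runs round-robin per-branch bounded
scalar maximization (golden-section/Brent on [1e−8, 10]) for at most 5
sweeps or until a sweep improves the log-likelihood by < 1e−4. The
round-robin never accepts a worsening step, so the log-likelihood is
non-decreasing across sweeps.

## Simulation protocol

The synthetic-data generator is the package's study condition, not a test
fixture:

- **Topologies** are uniform over labelled binary shapes, realized by
  inserting each new leaf on a uniformly chosen existing edge of the
  current unrooted tree.
- **Branch lengths** are i.i.d. Exponential(λ) with one λ per tree drawn
  log-uniformly from [2, 5] (`u ~ U(log 2, log 5)`, `λ = e^u`), so mean
  branch lengths span 0.2–0.5 substitutions/site.
- **Site evolution** draws the root from π and propagates states down the
  tree with `P(r_c · t)` per branch, where `r_c` is the site's rate class.
  GTR+I+G parameters are sampled per alignment from broad priors chosen to
  span realistic ranges (the exact empirical distributions behind published
  protocols are not public): π ~ Dirichlet(5,5,5,5), exchangeabilities
  log-uniform on [0.1, 10] with `r_GT = 1` as reference, α ~ U(0.2, 5),
  `p_inv ~ U(0, 0.5)`. A Jukes–Cantor preset (equal rates, uniform π,
  no I+G) is available for controlled experiments.
- **Gaps** come from per-lineage deletion events with geometric lengths
  (mean 3); the Poisson event count is set so the expected deleted fraction
  per sequence equals the nominal rate. With the default rate grid
  {0, 0.01, 0.02, 0.03} the overall gap ratio stays far below 0.3 (the
  0.04 rate exists in the configurable grid but is not part of the default
  training condition). Only deletions are modelled — no insertions and no
  alignment error, so simulated columns are always correctly homologous,
  which real alignments are not.
- **Reproducibility**: each pair draws from a counter-derived substream
  (`default_rng([seed, counter])`), so a dataset is a pure function of
  (manifest, seed) and pairs are order-independent.

## Model architecture

Defaults: `d_model = 64`, 2 axial layers, 4 heads, MLP expansion 4, learned
site-position embeddings up to `max_len = 1024`. These are desk-scale
values chosen so CPU training of the full pipeline finishes in minutes;
every one is config-overridable. Blocks are pre-norm residual (stability at
small scale), ordered row-attention → column-attention → feed-forward.
There is deliberately no positional signal along the species axis, making
the encoder exactly species-permutation equivariant (tested end to end).
Tied row attention sums query–key logits over species scaled by
`1/√(N·d_head)`.

In the decoder, candidate pairs are canonicalized (lexicographically
smaller member set on the left) before the antisymmetric `h_l − h_r`
gating, so scores do not depend on enumeration order. The ancestral
cross-attention uses per-site queries from `h̃` against *site-mean-pooled*
keys/values of the other active subtrees: the pooling keeps the context
step at `O(k · L · d)` while still conditioning on every remaining subtree;
it is an implementation choice localized in `JoinScorer.context` and easily
replaced. Leaf subtree representations are the encoder outputs themselves;
an executed join's subtree inherits the estimated parent representation
`h_x`. Candidates are fully re-scored after every join (exactness first;
the cost is quadratic in active subtrees and fine at these scales).

With two subtrees left no context set exists, so the final join is forced
and unscored — hence `N − 2` scored decisions per construction.

## Training

**Supervised.** Teacher forcing reconstructs each reference tree: at every
step, a candidate is *correct* iff the union of its two member sets is a
clade side (split side, trivial sides included) of the reference tree;
among correct candidates the canonically smallest is executed, which always
exists along a reference-consistent path. The step loss is the hinge

    L_t = mean over (a, b) of max(m − (s_a − s_b), 0)

over correct `a` and the top-`K`-scoring incorrect `b` (selective negative
penalization, default `K = 4`; the hardest negatives carry the learning
signal and cap the pair count). Defaults `m = 1`, Adam at `lr = 1e−3` with
global gradient-norm clipping at 1.0 (a grid probe around these values at
desk scale showed 1e−3 stable and 3e−3 already degrading). The objective
averages over batch and steps; early stopping monitors mean normalized RF
of greedy construction on a validation split and restores the best weights
after `patience = 5` stagnant checks.

Zero loss with all negatives covered implies every correct candidate
outscores every incorrect one by ≥ m, so the greedy argmax is correct —
this margin-implies-argmax property is tested as a standalone theorem.

**Reinforced.** Per epoch, `M` trajectories are sampled from the softmax
policy `π(a|S) ∝ exp(s/γ)`; the reward is the pruning log-likelihood of
the finished topology (branch lengths per config, default `fixed`), the
baseline is the previous epoch's mean reward (first epoch: current batch
mean), and the update follows `−(1/M) Σ log p(τ|θ)(R − b)` with the
trajectory log-probability taken over the `N − 2` actual stochastic
decisions. The best-reward tree ever sampled is returned. Whether sampled
trees should be ranked under fixed or optimized branch lengths is exposed
as `branch_length_mode`; `fixed` is the default because ranking only needs
a consistent relative signal and optimization is ~50x more expensive.

## Numerical choices and degenerate inputs

- All neural computation is float64 on a hand-written reverse-mode autodiff
  engine (`phylonj.autodiff`); gradients of every primitive are verified
  against central finite differences, and the full supervised objective is
  checked to 1e−4 relative error.
- Softmax uses max-subtraction; masked entries get additive `−inf` and
  produce exact zeros.
- Ties in greedy selection and NJ go to the canonically/index smallest
  pair; `−inf` likelihoods compare equal.
- Trees with < 4 leaves have no nontrivial splits: RF is (0, 0.0) by
  convention; alignments require N ≥ 2 and L ≥ 1; IUPAC ambiguity codes
  and `N`/`?` are treated as missing (gap).

## What the tests show — and do not

The test suite demonstrates internal correctness (pruning equals exhaustive
enumeration, NJ consistency on additive distances, oracle-guided
reconstruction, gradient integrity) and *desk-scale* learnability: a
default model trained for ~2 epochs on 500 simulated 8-taxon, 128-nt JC
pairs beats the uniform random-join baseline by a wide RF margin. The
problem sizes (8–50 taxa, 16–512 nt, hundreds of training pairs) were
chosen as the package's own test conditions; they are far below the scales
at which published neural tree builders are trained (tens of thousands of
50-taxon pairs), so test results say nothing quantitative about accuracy on
empirical data, where model misspecification, alignment error and
non-uniform tree priors all matter. Insertions, amino-acid models,
partitioned models, BIONJ-style variance weighting and branch-length-aware
(weighted) RF are out of scope.
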