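# Methods

## Model

One component of the factorization solves

    minimize_{u,v,d}  ‖X − d·uvᵀ‖_F²
    s.t.  ‖u‖₂ ≤ 1,  λ‖u‖₁ + σ·uᵀLu ≤ c₁,  ‖v‖₂ ≤ 1,  ‖v‖₀ ≤ k_v,

with `L` the normalized Laplacian of the prior gene network.  Because
`‖X − d·uvᵀ‖_F²` with unit `u, v` is minimized exactly when `uᵀXv` is
maximized (and then `d = uᵀXv`), the solver works on the Lagrangian

    F(u, v) = −uᵀXv + λ‖u‖₁ + σ·uᵀLu,

never materializing `c₁`.  The Laplacian convention follows the
degree-normalized form: `L_ii = 1` for connected genes, `0` for
isolated ones, `L_ij = −A_ij/√(d_i d_j)` on edges.  Genes absent from
the network therefore contribute nothing to the penalty — they are
neither rewarded nor punished for their loadings, only the L1 term
acts on them.

Assumptions worth keeping in mind: the network is binary and
undirected (no edge weights); expression should be roughly continuous
(log-scale recommended) with no missing values at fit time; and the
signal of interest is low-rank with factor supports that align, at
least partially, with communities of the network.  When the network is
uninformative about the expression signal, σ > 0 only adds bias; the
cross-validation utility exists to detect exactly that (σ = 0 then
wins).

## Solver

* **u-step** — cyclic Gauss–Seidel coordinate descent on the
  u-subproblem: `u_j ← S(z_j + σ·W_j u, λ)` with `z = Xv`,
  `W = D^{-1/2} A D^{-1/2}` and `S` the soft-thresholding operator;
  each update sees the newest coordinates, sweeps run in fixed index
  order, and the result is L2-normalized once per outer iteration.
  The implied ridge scale is `η + σ = 1`: the fixed point satisfies
  `z_j + σW_j u − u_j − λ·sign(u_j) = 0` on its support (this is the
  stationarity system the unit tests verify against an independent
  convex solve).
* **v-step** — exact: keep the `k_v` largest-|·| entries of `Xᵀu`,
  zero the rest, normalize.  Ties at the k-th order statistic break
  toward the smallest index so results are deterministic.
* **Monotonicity safeguard** — the coordinate fixed-point map is a
  contraction only for σ < 1 (‖W‖₂ ≤ 1), so for strongly
  network-weighted fits the sweeps can diverge and the normalized
  candidate may fail to lower `F`.  Whenever that happens the outer
  loop re-solves the same convex u-subproblem (over the unit ball) by
  projected proximal gradient with step 1/(4σ) — a provably descending
  method — and keeps the better of the two candidates.  The recorded
  objective trace is therefore non-increasing for every (λ, σ), which
  the test suite asserts on a grid up to σ = 10.  When the safeguard
  leaves an interior iterate (‖u‖ < 1), only its direction is reported
  in the final factor; the v-step depends on u only through its
  direction, so iterates are unaffected.
* **Degeneracy** — if every coordinate thresholds to zero (λ beyond
  the data scale) the factor is returned as a flagged zero, not an
  exception, because λ-tuning probes such values routinely.
* **Sign convention** — `d = uᵀXv ≥ 0`, enforced by flipping `v`.
* **Stopping** — outer loop: `max(‖u_t − u_{t−1}‖, ‖v_t − v_{t−1}‖) <
  1e-6` (default), cap 200 iterations; inner sweeps: largest
  coordinate change relative to the iterate's sup-norm `< 1e-6`, cap
  50 sweeps.  Tests that compare against a dense SVD tighten these to
  1e-12 / 20000 because power-type iterations converge linearly with
  rate (σ₂/σ₁)².

With λ = σ = 0 and `k_v = n` the procedure reduces to alternating
power iteration, and the test suite checks agreement with a dense SVD
to 1e-8.  The inner sweeps are JIT-compiled with numba when available;
a pure-NumPy path with the identical update order is the fallback.

## Parameter selection

* **λ via support targeting** — the gene-sparsity level is specified
  as a desired number of nonzero gene loadings; λ is found by
  bisection on [0, λ_max] (λ_max empties the first iterate), with the
  upper bracket doubled until it also empties the *converged* support.
  The support count is only piecewise monotone in λ — the solver can
  switch fixed points, and network-coupled coordinates switch off in
  groups — so when bisection skips the target a coarse grid scan plus
  two rounds of local refinement look for an exact hit; otherwise the
  closest λ is returned with a warning.  Each probe re-solves from the
  same initial pair, making the count a reproducible function of λ.
* **σ via entry-holdout cross-validation** — all p·n entries are
  partitioned into 5 random disjoint folds; per fold the held-out
  entries are replaced by the row mean of the remaining entries, one
  factor is fitted, and the squared reconstruction error on the
  held-out entries is accumulated.  `best_sigma` minimizes the mean
  over folds.  The default grid is {0, 1, 10, 20, 40, 60, 80, 90,
  100, 150, 200}.
* **Multiple factors** — deflation: subtract `d·uvᵀ` and refit.  Each
  factor is the best of `n_restarts = 5` runs (smallest final `F`)
  from independent standard-normal initial pairs.  When a support
  target is active, λ is re-tuned per factor on the current residual
  (deflation changes its scale), and the init used for tuning joins
  the restart pool — the tuned λ is only guaranteed to produce the
  target support from that init, and at large λ the basin of
  attraction of the dominant factor can be small.

## Module extraction and statistics

* **z-score filter** — for the nonzero loadings of one factor column,
  `z = ||x| − μ|/σ` with μ, σ the mean and standard deviation
  (ddof = 1) of the absolute nonzero loadings; members with `z ≥
  threshold` are kept (default threshold 1.0).  If all magnitudes are
  equal (σ = 0) every nonzero member is kept; with fewer than two
  nonzeros the members pass through verbatim with a warning.  Note the
  filter is two-sided by construction: unusually *small* magnitudes
  also score high.
* **Modularity** — mean |Pearson r| over ordered gene pairs across the
  module's samples, diagonal forced to zero; lies in [0, 1], invariant
  to gene order and per-gene affine rescaling.  Zero-variance genes
  contribute zero correlations with a warning.
* **Modularity significance** — one-sided Wilcoxon signed-rank test of
  the module's score against ≥ 20 size-matched uniform random gene
  sets (same samples).  Caveat: the paired differences share the one
  module score, so this p-value is not calibrated as a frequentist
  test — under the null it behaves like a sharp threshold around the
  null median rather than a uniform variate.  It separates genuinely
  co-expressed modules (p ≪ 0.01) from typical random sets, and that
  discriminative property is what the tests assert.
* **Interaction enrichment** — right-tailed hypergeometric tail
  `P(K ≥ m_i)` for the module's induced edge count `m_i`, drawing
  `C(n_i, 2)` candidate pairs from `C(n, 2)` with the network's `m`
  edges as successes; `s = −log10(p)`, significant when `s > 1.3`
  (p < 0.05).  Verified against exhaustive enumeration on a 5-node
  universe.
* **Overlap between modules** — right-tailed hypergeometric tests on
  the gene-set and sample-set overlaps; a pair counts as overlapping
  when both p-values fall below 0.05.

## Simulation benchmark

`X = uvᵀ + γ·ε` with `u ∈ {0,1}^200`, `v ∈ {0,1}^100` (first 50
entries one), ε i.i.d. standard normal, and a planted two-block
network: within-support pairs connected with probability 0.3, all
others 0.1.  Everything is reproducible from (seed, replicate).
Recovered supports are scored by sensitivity, specificity and accuracy
for u and v separately.

Two points the benchmark makes explicit:

* With the 0/1 signal vectors the per-entry signal-to-noise ratio at
  γ ∈ [0.02, 0.06] is 17–50×, so support recovery sits at or near
  accuracy 1 for both the network-regularized fit and the plain L0
  sparse SVD baseline; the comparison at these settings is a
  tie-or-better check, not a separation experiment.
* "Forced to the same sparsity level" is enforced in the harness:
  after λ-tuning, a fitted gene loading that overshoots the target
  cardinality is L0-projected to exactly the target (its magnitude
  ranking is what the method asserts), and λ is relaxed and the fit
  repeated on undershoot or collapse.  Without this the L1 path's
  cardinality granularity, not selection quality, would drive the
  comparison.

The baseline (`l0svd_rank_one`) is the network-free reduction with
hard-thresholded power steps on both sides — exact cardinality by
construction.

## Differential co-expression pipeline

Preprocessing of matched two-condition data: drop features with more
than 70% zero/missing raw values (pooled over samples), `log2(x+1)`,
two-sided Wilcoxon rank-sum per feature with Bonferroni control
(`p·k < α`, default α = 0.05), then KNN imputation (scikit-learn's
KNNImputer, k = 10: nan-aware Euclidean distances between rows, which
rescale by the fraction of co-observed columns).  Condition-wise
Pearson gene × miRNA correlation matrices `X1, X2` are computed after
row centering/scaling (Pearson itself is invariant to that; the
scaling mirrors the preprocessing convention), and the solver runs on
`X = X1 − X2` with the Laplacian penalty on the gene rows and the L0
constraint on the miRNA columns.  Module stats: average adPCC (mean
|X| over the module submatrix), induced gene-edge count, singular
value.  The adPCC permutation test resamples same-shape submatrices
with uniform random row/column index sets and reports
`p = (1 + #{null ≥ observed})/(1 + n_perm)` (add-one smoothing keeps
it valid); under a signal-free null its 5% rejection rate is
calibrated, which the test suite checks over 200 replicates.

## Synthetic data: what it does and does not cover

The generators emulate the structural features the method targets —
a planted rank-one block, a support-aligned network community, a
condition-specific correlation block — with Gaussian noise and
independent Bernoulli edges.  They do not emulate heavy-tailed count
noise, batch effects, correlated backgrounds, scale-free network
topology, or annotation errors in real PPI networks.  Passing tests
therefore demonstrate correctness of the algorithms and their
contracts, not performance claims on real cohorts.

## Problem sizes used in the test suite

Unit tests run on matrices up to 300 × 80; the recovery benchmark uses
the full 200 × 100 design with 50 replicates per noise level; the
permutation-calibration check uses a 100 × 30 matrix with 199
permutations × 200 replicates.  These sizes keep the full suite around
half a minute on one core while leaving every statistical check at
meaningful replication.

## Known limitations

* The u-subproblem's coordinate update and the ball-constrained
  minimizer disagree when σ ≥ 1 (different implicit ridge scale); the
  safeguard guarantees descent but module content at very large σ
  depends on which candidate wins, and `nnz(λ)` becomes genuinely
  discontinuous there.
* λ-tuning targets a support size *given an init*; a different init
  can need a different λ.  The deflation loop accounts for this but
  user-supplied inits are on their own.
* The modularity significance procedure is not a calibrated p-value
  (see above).
* No edge weights, no missing-data fitting (impute first), no GPU or
  out-of-core paths.
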