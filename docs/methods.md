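# Methods

## Problem setting

A cell senses a discrete environmental input `U ∈ {u⁽¹⁾, …, u⁽q⁾}` (drawn
from a prior `p_U`, uniform by default) through a biochemical reaction
network whose rate constants depend on the input. The observable is the full
stochastic time course of molecule counts, `x(t)` on `[0, T]` — either the
exact event list (states and dwell times) or the same path sampled on a
uniform grid of `d` time points, as in single-cell microscopy. The quantity
of interest is the mutual information `I(X; U)` in bits: how well the
response trajectory distinguishes the inputs, for a single cell observing a
single presentation.

## Model-based "gold truth"

For a mass-action network with propensities `a_k(x) = θ_k ∏_i C(x_i, ν′_ik)`
the probability vector obeys the chemical master equation `ṗ = M p`. On a
finite truncation of the state lattice, `M` is an explicit matrix and two
exact likelihoods follow:

* **Continuous time.** A path visiting states `s_1 … s_r` with dwells
  `t_1 … t_r` has
  `log p(x|u) = log p(s_1) + Σ_i M_{s_i s_i} t_i + Σ_{i≥2} log M_{s_i s_{i−1}}`,
  i.e. one exponential survival factor per dwell and one jump rate per
  event; the final dwell contributes survival only. Piecewise-constant rate
  schedules split each survival term exactly across segments; the jump rate
  is evaluated in the segment containing the jump instant.
* **Discrete time.** With the propagator `W = expm(M Δt)` per grid step,
  `log p(x|u) = log p(x⁰) + Σ_{i=1}^{d} log W_{x^i x^{i−1}}` — one factor per
  grid step starting from the known initial state. (The alternative
  convention with `d−1` factors discards the informative first step and does
  not recover the continuous-time limit.) A step spanning a rate breakpoint
  uses the time-ordered product of segment propagators.

Monte-Carlo information: sample `N` paths per input with the exact SSA,
average `−log₂ p_X(x)` (marginal via log-sum-exp over inputs) for the
response entropy and `−log₂ p(x|u)` for the noise entropy; their difference
approximates `I(X;U)` with `O(1/√N)` error and no density-estimation bias.
Error bars are standard deviations over replicate re-runs with fresh paths
(default 20 replicates).

Impossible transitions carry an explicit `−∞` log-likelihood that propagates
safely through log-sum-exp; a dataset whose paths are impossible under every
input aborts with a diagnostic. All reported quantities are in bits.

## Decoding bounds

MAP decoding `û = argmax_u [log p(x|u) + log p_U(u)]` (ties to the lowest
label index, for reproducibility) turns each path into a decode; the joint
`q × q` confusion table `ε` between truth and decode gives the plug-in
information `I(Û;U)`, a lower bound on `I(X;U)` by the data-processing
inequality. The matching upper bound uses the per-decode error
`π_û = 1 − Pr(U=û | Û=û)` and the floor/ceiling construction

    φ(π) = α log₂⌊1/(1−π)⌋ + (1−α) log₂⌈1/(1−π)⌉,
    α(π) = ⌊1/(1−π)⌋((1−π)⌈1/(1−π)⌉ − 1),

with `I_UB = H(U) − Σ_û p_Û(û) φ(π_û)`. A degenerate decode column
(`π = 1`) caps `φ` at `log₂ q`. The bound is valid only for MAP decodes.

## Model-free estimators

All decoders are sklearn estimators consuming `(N, d)` trajectory matrices:

* **SVM** (linear and RBF): `C ∈ {0.1, 1, 10, 100}` and the RBF width
  `σ ∈ median pairwise distance × {0.25, 0.5, 1, 2, 4}` are chosen by 5-fold
  cross-validation on training data only. Multiclass problems use a
  dendrogram of binary SVMs whose topology is average-linkage clustering of
  the class-mean trajectories. libsvm iterations are capped at 2·10⁴ — on
  linearly inseparable data at large `C` the solver otherwise stalls for
  minutes while the decision function is chance-level regardless.
* **Gaussian decoder**: per-class mean and covariance with diagonal
  regularization `Σ + λI`; `λ` is picked from a log-spaced grid
  (`10⁻⁴ … 10` relative to the mean diagonal variance) by held-out
  validation log-likelihood.
* **MLP**: 300–200 hidden units, relu, Adam, batch 128, early stopping on a
  15% validation split, max 200 epochs. The reference description uses ELU
  activation with batch normalization and dropout; those are unavailable in
  sklearn's `MLPClassifier`, so relu with L2 and early stopping stand in.
  The architecture is a configurable parameter, not a claim of optimality.

The information estimate repeats a stratified 70/30 split `replicates`
(default 20) times, fits on train, decodes test, and applies the plug-in
formula; the mean ± std over replicates is reported. Identical
`random_state` gives identical splits, so estimator comparisons can be
paired. A `shuffle_labels` switch permutes labels per replicate as a
negative control — its estimate must be consistent with zero.

Two non-decoding baselines:

* **knn mutual information** (class-conditional neighbor counting): for each
  point, the Chebyshev distance to its k-th neighbor within its own class
  sets a radius; the number of points of the full sample inside that radius
  (ties counted inclusively) enters a digamma combination. The estimate is
  returned faithfully even when negative. On integer-valued molecule counts,
  distance ties are massive and the estimator can crash to large negative
  values; adding iid Gaussian jitter (default scale 10⁻³, any value ≪ 1
  works) breaks ties and repairs the estimate except in the hardest
  mean-matched case. The 1-D case is cross-checked exactly against an
  independent implementation (sklearn's `mutual_info_classif`).
* **Gaussian approximation**: analytic conditional entropy
  `½ log₂ det(2πeΣ(u))` plus a Monte-Carlo mixture entropy. It carries no
  bound guarantee and demonstrably overshoots the true information on
  count-valued data; it is included as a baseline, not a recommended
  estimator.

## Simulator and synthetic data

The SSA draws exact paths; a dwell proposal overshooting a rate breakpoint
advances the clock to the breakpoint and redraws under the new rates (valid
by memorylessness). Only piecewise-constant-in-time schedules are supported;
other time dependence is rejected. Sampling a path on a grid uses the
right-continuous convention (the value at a jump instant is the post-jump
state). Each trajectory consumes a deterministically derived substream of
the dataset seed, so datasets are reproducible and order-free.

The packaged examples are the three birth-death benchmarks with their
printed rates (steady-state mean readout; adapted transient with the
production switch at `t = 1000`; mean-matched autocorrelation readout with
`x(0) = 10`), horizon `T = 2000`, uniform binary inputs. The multilevel
variant tiles the pre-switch production rate at `α_i = 0.1·i/q` — the grid
excludes zero so that `q = 2` recovers the original example exactly.
Extrinsic noise perturbs each cell's degradation rate once
(`β′ = max(β + N(0, σ), 10⁻⁶)`) and holds it fixed, emulating cell-to-cell
variability. What the generator does **not** emulate: measurement noise,
fluorophore maturation/bleaching, partial observation of species, and
continuous-valued readouts — so a green test establishes correctness of the
estimators on fully observed count data, not robustness to instrument
effects.

## Numerical choices

* State-space truncation: cap at `ceil(μ) + 10√μ` over inputs and rate
  segments (`μ` the drift-balance point, `α/β` for birth-death), floored at
  `x0 + 20`. Poisson tails make the escaping probability mass negligible
  (< 10⁻⁸ along any trajectory started inside the bulk); the dropped
  boundary outflow is reported per state as a leak diagnostic. Columns of
  `W` over the occupied core are stochastic to 10⁻⁸; boundary columns
  necessarily leak and are excluded from that check.
* `expm` is evaluated once per (segment, step length) and cached; discrete
  likelihoods are vectorized gathers from the per-step `log₂ W`.
* Replicate counts default to 20 for error bars; the benchmark harness's
  scaled-down defaults (N = 300, d = 50, 5 replicates) keep a full
  comparison in CI time, with the full-scale settings available as flags.
* MAP ties break deterministically to the lowest label index; random
  tie-breaking would change `ε` by `O(ties/N)`.
* No small-sample debiasing of the plug-in confusion information: with
  `q ≤ 5` and hundreds of test paths the bias is `O((q−1)²/N)` and the
  shuffle controls verify it is negligible at packaged scales.

## Known limitations

* Multi-species state enumeration is a rectangular lattice product, so
  truncation cost grows geometrically with species count; only
  single-species networks are exercised by the packaged benchmarks.
* The exact machinery requires full observation of all species;
  marginalizing unobserved species is out of scope.
* The MAP-decoding information is not mathematically guaranteed maximal
  among all decoders (only its error probability is minimal); no packaged
  counterexample exists.
* Channel-capacity optimization over the input prior is not implemented;
  priors are fixed inputs.
* The knn estimator targets `I(X;U)` rather than decodable information, so
  it is not bounded by `I_MAP`; no ordering against the decoding estimators
  is asserted.
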