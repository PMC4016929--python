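# Methods

This note records the models implemented in `erpselect`, the numerical
choices behind them, and what the synthetic benchmark does and does not
establish.

## Objective and solver

All single-task estimators minimize

    F(w, b) = Σᵢ max(0, 1 − yᵢ(xᵢᵀw + b))² + λ Ω(w),

a squared-hinge (large-margin) data term **summed** over trials plus a
penalty on the weights only.  The squared hinge is convex and continuously
differentiable with a gradient Lipschitz constant L = 2 Σᵢ‖xᵢ‖²; we
compute L on the bias-augmented representation (a constant-1 coordinate
appended per trial) so one constant bounds the joint (w, b) gradient.
Whether the bias belongs in this bound is a convention; the augmented
choice is conservative and costs one unit of squared norm per trial.

Minimization uses forward-backward splitting,
w⁺ = prox_{τλΩ}(w − τ∇f₁), b⁺ = b − τ∇_b f₁, with fixed stepsize τ = 1/L —
no line search and no acceleration, so the objective trace is provably
non-increasing and fixed points are exactly the minimizers.  Iterations
stop when the relative objective decrease falls below `rel_tol`
(default 1e-8) or after `max_iter` (default 5000) iterations.  Plain fits
start from (w, b) = 0 for determinism; adaptive refits and
cross-validation paths warm-start from the previous solution, which
changes nothing about the fixed points and substantially reduces
iteration counts.

## Penalties and proximal operators

* ℓ2: prox is the shrink v/(1 + τλ); the fit agrees with direct smooth
  minimization (tested).
* ℓ1: soft thresholding.
* ℓ1–ℓ2 (group lasso over sensors): per-group block soft thresholding;
  a group vanishes exactly when ‖v_g‖₂ ≤ τλβ_g.
* ℓ1–ℓq, 1 < q < 2: no closed form.  The per-group prox is computed by a
  two-level bracketing scheme: the prox is zero iff ‖v_g‖_{q*} ≤ τλβ_g
  (dual-norm ball condition, 1/q + 1/q* = 1); otherwise an outer Brent
  iteration solves for the scalar s = ‖u‖_q while an inner safeguarded
  Newton-with-bisection solves the coordinatewise stationarity condition
  u + τλβ_g s^{1−q} u^{q−1} = |v| on [0, |v|].  Inner tolerance 1e-10,
  iteration cap 10 000; non-convergence raises an error carrying the group
  id.  Correctness rests on the oracle tests (direct numerical
  minimization of the prox objective on hundreds of random instances),
  not on the specific iteration.
* Adaptive reweighting: after a converged plain ℓ1–ℓq fit w*, groups are
  reweighted by β_g = 1/‖w*_g‖_q and refit.  A group whose first-stage
  norm is below 1e-10 × the largest group norm would get an effectively
  infinite weight; it is instead frozen at exactly zero in the refit.  An
  all-zero first stage is an error, not a silent fallback.

Per-group weights are folded into the prox threshold (τλβ_g per group)
rather than implemented by feature rescaling, so the weighted prox is
exact.

## Multitask model

For m subjects sharing one sensor layout, MGSVM minimizes the stacked
objective: per-subject squared hinges, plus λ_s Σ_t‖w_t − ŵ‖² pulling every
subject toward the mean classifier ŵ (equivalently m × the across-task
parameter variance), plus λ_r Σ_g‖W_g‖_F tying each sensor's r × m weight
block together so selection is joint across subjects.  The similarity term
is smooth and lives in the gradient step (its gradient for task t reduces
to 2λ_s(w_t − ŵ)); the group term lives in the prox (block soft
thresholding at τλ_r).  The stepsize uses the conservative bound
L = max_t 2Σᵢ‖x̃ᵢ,t‖² + 4λ_s (the task losses are block-separable, so the
maximum over tasks suffices; the similarity Hessian has spectral norm at
most 2λ_s); the bound is validated by sampled Lipschitz checks.  Biases
are excluded from both penalty terms, and task losses are unweighted sums
even when task sizes differ.

## Evaluation protocol

Performance is AUC (Mann–Whitney pair counting; tied pairs worth 1/2,
computed by the rank-sum formula).  Selection quality against a known
truth set uses the F-measure 2|C∩C*|/(|C|+|C*|) and the selection rate
100|C|/p.  A sensor counts as selected when its ℓ2 group norm exceeds
1e-8 × the largest group norm — "numerically nonzero"; block thresholding
produces exact zeros, so the result is insensitive to this threshold over
many orders of magnitude.

Hyperparameters come from nested stratified 3-fold cross-validation
maximizing mean validation AUC over a 13-point log-spaced grid
λ ∈ [10⁻³, 10¹] (and q ∈ {1, 1.2, …, 1.8, 2} for GSVM-q); ties break
toward the smaller λ, then the smaller q.  Both the grid and the
tie-break are configurable.  **λ scale:** because the data term is a sum
over trials, grid values are interpreted per-trial and multiplied by the
number of fitted trials.  This keeps one grid meaningful across fold and
training-set sizes and is the regime in which the grid actually spans the
dense-to-empty selection range at n = 1000; with literal grid values the
penalty would be negligible against a 1000-trial loss sum and no grid
point could deselect any sensor.  `lambda_scale="none"` restores literal
values.

The adaptive classifier is tuned in two stages, each with its own CV: the
plain ℓ1–ℓ2 model is tuned and refit, its solution fixes the adaptive
weights, then λ of the weighted refit is tuned on the same folds.  The
alternative — one λ shared by both stages of the pipeline — was evaluated
and rejected: it produces denser adaptive solutions and loses the
characteristic property that the adaptive refit is the sparsest and most
accurate selector.

The benchmark repeats {stratified random split (1000 training trials by
default), nested CV per method, test AUC and selection metrics} over
several runs (10 by default) and compares methods to a baseline by a
paired Wilcoxon signed-rank test.  The signed-rank test uses the
tie-inclusive (Pratt) treatment of zero differences; for up to 25 nonzero
pairs the null distribution of W⁺ is exact (a dynamic program over the
doubled midranks, equivalent to enumerating all 2ⁿ sign assignments),
beyond that a normal approximation with zero- and tie-corrections is
used.  Two-sided p-values are 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)) capped at 1;
a one-sided variant is available.

## Synthetic P300 generator

The generator emulates a 16-sensor oddball decoding problem: positive
trials carry a deterministic biphasic template (small negative deflection
near 30 % of the window, dominant positive peak near 65 % — an N200–P300
caricature, peak magnitude = amplitude a) added on the feature blocks of
8 designated sensors; negative trials carry nothing; i.i.d. Gaussian noise
(sd 0.2) is added to every feature of every trial.  Defaults: 11 000
trials, 8 features per sensor, 1000 training trials, balanced classes
(a rare-target preset is a one-line config change; AUC and group selection
are only mildly sensitive to the balance).  Everything is deterministic
given the seed.

The default amplitude a = 0.06 was fixed once by `calibrate_amplitude`:
the smallest value on a 0.01-spaced grid for which a CV-tuned ℓ2 baseline
reaches test AUC in [0.75, 0.85] — i.e. the realistically hard
single-trial regime in which sensor selection is neither trivial nor
hopeless.  The calibrated value is frozen; the routine ships for users who
change the noise model.

The multitask variant draws per-subject datasets with a relative template
amplitude jitter (lognormal-free, simple truncated Gaussian factor) and
optionally swaps some discriminative sensors per subject, making
cross-subject similarity tunable; with no swaps all subjects share the
truth set.

**What the generator does not model:** spatial covariance between sensors
(real EEG noise is strongly correlated across neighboring electrodes),
subject-specific waveform shapes and latencies, artifacts, and
non-stationarity.  Consequently the benchmark validates the estimators and
the protocol — recovery of a known sensor subset under i.i.d. noise at a
calibrated SNR — not performance on real recordings.  In particular, with
independent noise an ℓ1 classifier can exploit sparsity more effectively
than on real data, so its selection rate here is lower than is typical on
real ERP recordings; group-level and adaptive comparisons (ordering of
selection rates, the adaptive method's F-measure advantage) are the
portable conclusions.

## Preprocessing operators

Band-pass filtering designs a Butterworth or Chebyshev type I (0.5 dB
ripple) band-pass as second-order sections and applies it forward-backward
(zero phase) along time, preserving component latencies.  Decimation picks
r uniformly spaced existing samples in the requested post-stimulus window
(no interpolation; the band-pass doubles as the anti-alias filter for
these bands) and flattens channel-major.  Reading vendor EEG file formats
is out of scope by design: the input contract is an epoched
(sensors × time × trials) array with its sampling rate.

## Problem sizes and runtimes

Oracle suites run on deliberately small instances (groups of ≤ 6
coordinates, fits with n ≤ 50, d ≤ 12, m ≤ 3) where direct numerical
minimization and zero-pattern enumeration are exact references.  The
simulated study runs the full 10-repetition protocol at the default
16 × 8 layout with 1000/10 000 splits; one full benchmark of the three
sparse methods takes on the order of two minutes on a single CPU.  The
multitask comparison uses 5 subjects × 100 training trials over 5 seeds.

## Known limitations

* Fixed-stepsize forward-backward is robust but not the fastest option;
  acceleration (FISTA) was deliberately omitted to keep the monotone
  trace and simple convergence diagnostics.
* The ℓq prox iteration cap is generous; pathological q ≈ 1 with huge
  thresholds converge through the closed-form dispatch at q = 1, not the
  iteration.
* Overlapping groups, q outside [1, 2], per-task penalties and asymmetric
  multitask coupling are out of scope.
* Exact signed-rank p-values are limited to 25 nonzero pairs; beyond that
  the normal approximation is used without continuity correction.
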