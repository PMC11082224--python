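# Methods

## Setting and model

A fixed classifier g(·) is evaluated on a pool of N i.i.d. records whose
covariates (or at least scores) are observed but whose outcomes are not.
Labels are bought sequentially: at step s, each still-unlabeled record is
selected independently (Poisson sampling) with probability
π = P{δˢ=1 | gˢ(X)}, so the realized batch size n*ₛ is random with mean
nₛ. Records labeled earlier are retained with probability one. The
targets are the mean loss M = E[L{g(X),Y}] and ratio metrics
D = E[d1]/E[d2] defined by component functions at a risk cutoff c
(strict `>` indicator; a score exactly at the cutoff counts as "not
above"). The F1-type entry uses d1 = I(z1>c)·z2, d2 = I(z1>c) + z2; its
ratio equals half the conventional F1, and `conventional_f1` exposes the
doubling.

## Sampling design

Entropy sampling scores each unlabeled record by the expected
cross-entropy of g under plug-in outcome probabilities p:
−[p log g + (1−p) log(1−g)] (binary) or −Σ_c p_c log g_c. The plug-in is
the model's own score ("Ori"), an auxiliary covariate model ("RF",
pluggable, defaults to a random forest), the recalibrated model ("Rec"),
or constant ("Uniform"). Scores are scaled to probabilities summing to
nₛ with iterative capping at 1 — equivalent to p = min(1, α·score) for a
single final scale α — then floored at ε = 10⁻³ to bound
inverse-probability weights. The stored (α, ε) make each step's realized
probability a closed-form function of the raw score, which powers the
exact inclusion recursion used as a testing oracle. A
sampling-without-replacement scheme is provided; its stored inclusion
probabilities are the first-order approximation nₛ·score/Σscore.

## Weight estimation

Per-step selection probabilities (AILUR) and cumulative inclusion
expectations (AIIPW) are estimated by Nadaraya–Watson regression of the
corresponding 0/1 indicator on a scalar score covariate, evaluated at
each record's own covariate value and clipped to [ε, 1]. Choices that
matter:

- **Conditioning covariate.** The AILUR smoother conditions on the
  current plug-in model's score gˢ(X); the AIIPW smoother on the
  original score g(X) (valid because every supported scheme's
  probability is a function of g). For multiclass models the scalar
  covariate is the expected self-entropy of the score vector — a
  deterministic function of g(X) standing in for the vector score.
- **Kernel and bandwidth.** Gaussian kernel (always-positive
  denominator); bandwidth by Silverman's reference rule
  0.9·min(sd, IQR/1.34)·m^(−1/5) on the support, recomputed each step.
  Degenerate (zero-spread) supports fall back to a constant 10⁻² with a
  warning. The *experiment harness* scales the reference bandwidth by 3:
  the smoothed curve enters the estimators inversely, so estimation
  noise produces bias of order 1/(m·b) while the curvature bias of these
  smooth probability curves grows only mildly in b; oversmoothing
  measurably removes the residual bias of AILUR/AIIPW at the packaged
  pool sizes and also tightens agreement with the exact recursion.
- **Self-inclusion weight.** When the fitted value at a record's own
  position is inverted into its sampling weight, full self-inclusion
  correlates the estimate with the record's own indicator (biasing the
  inverse weight down), while leaving the record out exposes the Jensen
  convexity of x ↦ 1/x (biasing it up, with occasional near-zero
  estimates). The two leading-order terms cancel when the self term
  enters the kernel sums with weight ∫K²/K(0) (1/√2 for the Gaussian
  kernel, 0.8 for Epanechnikov). The harness uses this matched weight;
  direct calls default to the plain sums, which preserve the exact
  flat-kernel and constant-covariate identities.
- **Grid evaluation.** For large supports the regression is evaluated on
  256 equispaced points spanning the support and linearly interpolated
  (numerator and denominator separately), an O(m·256) approximation
  whose error is far below the statistical noise; exact evaluation is
  the default for direct calls.

The exact recursion E{δˢ|g} = E{δˢ⁻¹|g} + qₛ(g)·Π_{j<s}[1 − q_j(g)]
(with E{δ¹|g} = q₁(g)) is implemented from the stored per-step
probability functions and serves as the oracle for the kernel estimate
and for the IPW-oracle estimator.

## Estimators

LUR/AILUR compute (1/(sN)) Σ_j w_j [Σ_{selected at j} L/π + Σ_{selected
before j} L], exploiting π = 1 for previously labeled records, so storage
is one scalar probability per labeled record. The round weights
w_j = N(N−s)/{(N−j)(N−j+1)} use step indices exactly as defined; for
N ≫ S they are ≈ 1. AIIPW computes (1/N) Σ δˢ L/Ê and consumes only the
current indicator and weights. Ratio metrics weight the d1 and d2 sums
identically (AIIPW form); a LUR-form ratio applying the step-weighted sum
to each component separately is provided as the natural extension for
the LUR/AILUR family. Weighted AUC sweeps cutoffs at the distinct
labeled scores plus {0,1} and integrates TPR against FPR by trapezoid
(equal to the weighted pairwise-concordance statistic at a census);
AUPRC integrates PPV against TPR with ties ordered by descending
precision and the curve extended to TPR = 0 at the PPV of the
highest-score cutoff.

## Recalibration

The single-slope estimating equation Σ δˢ g(X)[Y − h(θ·g(X))]/Ê = 0 is
solved by Brent root finding on [−20, 20]; the residual is continuous
and strictly decreasing for the logistic link, so any sign change
brackets the unique root to residual ≤ 10⁻⁸. One-class labeled sets
have no finite root and return the signed cap with `fallback_used` set.
The link acts on the probability-scale score by default. Note a real
limitation of that family: with θ > 0 and g ∈ (0,1), h(θg) > 1/2
always, so it cannot invert a pure slope miscalibration — it sharpens
the *ordering* used for sampling rather than the calibration curve. A
logit-scale variant (`input_scale="logit"`), which contains the exact
inverse of slope miscalibration, is exposed as a non-default option and
is the per-class link in the one-vs-rest multiclass stand-in (so
calibrated score vectors are a fixed point; a class unseen in the
labeled data passes through unchanged).

## Synthetic data

The generator draws covariates X ~ N(0, I_p), true probabilities from a
logistic (or softmax) model with default coefficients
(1.0, −0.8, 0.6, −0.4), outcomes from those probabilities, and evaluated
scores through the logit-scale distortion score = σ(a + b·logit(p)).
The packaged benchmark pool uses N = 2000, b = 0.6 (an under-confident
model), a = 0. It emulates a smooth, well-specified score distribution;
it does not emulate covariate shift between training and test pools,
discrete or clumped score distributions, or label noise — conclusions
from passing tests transfer to real data only to the extent those
features are absent. An 8-record deterministic fixture with
hand-computed benchmark values backs the exact unit tests.

## Experiment harness and problem sizes

Repetition experiments fix the pool (sampling randomness only) by
default, with a switch to regenerate pools per repetition; all
randomness derives from per-(seed, repetition, step) substreams, so runs
are bit-reproducible. "RMSE" is the square root of the repetition-mean
squared deviation from the full-data benchmark; relative efficiency is
RE = MSE(reference method, reference step)/MSE(method, step), so RE > 1
means the method reaches the reference's precision with fewer labeling
steps. The packaged benchmark experiments use N = 2000, S = 3 steps of
nₛ = 100, and 500 repetitions (200 for the fixed-budget sweep over
(6, 50), (3, 100), (2, 150)); the oracle-agreement check uses a single
N = 5000 run plus 200 repetitions. The stopping rule is a fixed S with a
pool-exhaustion guard.

## Known limitations

- AILUR/AIIPW are asymptotically unbiased; at small pools or tiny
  per-step probabilities residual smoothing bias can exceed Monte-Carlo
  noise despite the corrections above.
- The AIIPW weight precondition (sampling probability a function of
  g(·)) excludes the RF updating scheme for AIIPW, which the
  configuration layer enforces.
- Without-replacement inclusion probabilities are first-order
  approximations; no joint-inclusion computation is attempted.
- No variance or confidence-interval estimation for the estimators is
  provided.
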