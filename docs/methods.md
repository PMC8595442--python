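# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `nlcc`.

## Framework

We model a feedforward chain `(s, ν) → r → R(r) → ŝ`: a task-relevant
stimulus `s` and nuisance `ν` drive a population response `r` (spike
counts in a window); downstream circuits compute nonlinear statistics
`R(r)`; the behavioral estimate is a linear readout `ŝ = w·R(r) + c`.
For an exponential-family response model the sufficient statistics carry
all stimulus information, and polynomial statistics up to cubic order
(`r_i`, `r_i r_j`, `r_i r_j r_k`) are the working basis throughout.

Signal and noise of the statistics are summarized by the sensitivity
`F′ = ∂⟨R|s⟩/∂s` (fine tasks) or the category difference `ΔF` (coarse
tasks), and by the stimulus-conditioned covariance `Γ = Cov(R|s)` or its
category average `Γ̄`. The optimal readout is `w ∝ Γ⁻¹F′`, its Fisher
information `J = F′ᵀΓ⁻¹F′`, its estimator variance `1/J`. Per-statistic
discriminability is `d′_k = F′_k Δs / sqrt(Γ_kk)`.

The optimality test: for a fixed stimulus, correlate each statistic with
the behavioral estimate. Under optimal decoding

    C_k = Corr(R_k, ŝ | s) = d′_k / d′,

and the choice correlation of a known linear readout has the closed form
`C_k = (Γw)_k / sqrt(Γ_kk wᵀΓw)`. For coarse tasks (noise statistics
change across the category range) the NACCC replaces the per-condition
Pearson correlation by category-averaged conditional moments; it is
bounded by 1 and reduces to `C_k` when the conditional distributions
stop depending on the category. The slope between measured and
predicted-optimal choice correlations across statistics is the decoding
efficiency `α = ε/σ²_ŝ`, the information-limited share of the estimator
variance.

## Encoding models

**XOR.** Two binary units; the stimulus is their exclusive-or (equal
responses → s = −1, opposite → s = +1), decodable only from the product
`−r₁r₂`. `flip_prob` corrupts each unit independently.

**Gabor populations.** Unit-energy Gabor receptive fields on a 32×32
pixel grid (defaults: spatial frequency 0.15 cyc/px, envelope σ = 6 px;
the grid size is our choice — nothing in the analysis depends on it as
long as the filters fit). Images are Gabors of orientation `s` with
either a random spatial phase on [0, 2π) or a random polarity ±1;
responses are the filter overlaps plus white Gaussian noise of variance
`noise_var`. Phase/polarity averaging cancels mean tuning exactly (each
phase pairs with its opposite), so orientation information moves into
the response covariance, which obeys the law of total covariance
(verified numerically in the tests).

**Quadratic codes.** Gaussian responses with constant mean and smooth
stimulus-dependent covariance `Σ(s)`; `rotating_covariance` provides the
canonical two-neuron example whose principal axis rotates with `s`.

**Cubic codes.** The pure-cubic density
`p(z|s) ∝ exp(−‖z‖⁴ + γ s z₁z₂z₃)` is never normalized in closed form;
we sample its standard four-Gaussian surrogate: unit-covariance
components at the vertices of a regular tetrahedron of circumradius
`scale`. Rotating the tetrahedron about the z-axis by ψ carries it into
its mirror image, and the mean triple product varies as cos 2ψ; choosing
`cos 2ψ = tanh(γs)` makes

    ⟨z₁z₂z₃⟩ = (scale/√3)³ · tanh(γ s)

smooth and sign-correct in `γs` while the mixture mean stays exactly 0
and the covariance exactly isotropic for every `s` — the stimulus
dependence is confined to third-order statistics, which is the point of
the construction. A hard sign-flip of the tetrahedron orientation would
satisfy the same symmetry but make the third moment discontinuous in
`s`, destroying the local Fisher information; the smooth rotation is our
design choice. For N > 3 only disjoint triplets are coupled (N must be
divisible by 3). The affine stage `r = f(s) + Σ^{1/2}(s) z` adds linear
and quadratic information; defaults (`scale = 1.5`, `γ = 1.5`, mean
slope 0.4, relative SD slope 0.25, stimulus range ±0.4) were chosen so
the three polynomial orders carry comparable information shares
(roughly 31% linear, 52% quadratic, 17% cubic of `J_opt`).

**Information limits.** `inject_information_limit` re-renders every
trial at `s + ds`, `ds ~ N(0, ε)` — noise indistinguishable from a
stimulus change, capping the Fisher information at `1/ε` regardless of
population size (`J = 1/(1/J∞ + 1/J₀)`). A linearized feature-space
variant adds `ds·F′` to the statistic vectors; it is exact only to first
order and flagged as approximate.

## Features and residualization

Polynomial feature sets carry explicit term identities (neuron index
tuples). To isolate nonlinear information in data analysis, responses
are residualized against the optimal *linear* stimulus estimate:
`δr_i = r_i − ⟨r_i|ŝ₁⟩`, with the conditional mean modeled by linear
regression of `r_i` on `ŝ₁` pooled over trials (the conditioning is on
the estimate alone; per-category and binned-mean variants are options).
Quadratic statistics are then built from `δr`. Zero-variance statistics
are flagged degenerate with `d′ = 0` rather than producing NaNs.

Covariance inversion uses a ridge of `1e-6·tr(Γ)/dim` by default. For
session-scale data with many heavy-tailed polynomial terms,
`fit_coarse_decoder_shrunk` standardizes the features and estimates the
per-category covariances with Ledoit–Wolf shrinkage — without
standardization the shrinkage target is dominated by the largest-scale
terms and the readout degrades badly.

## The network decoder

The generic decoder is a fully connected ReLU regression network (two
hidden layers, 30 units each) trained by backpropagation (Adam,
learning rate 1e-3, batch 200, ≤400 epochs with a 20-epoch patience
window; non-decreasing loss is reported, not silently accepted), via
scikit-learn's `MLPRegressor`. Decoder quality is measured as an
information fraction: `J = gain²/Var(residual)` of the estimate
regressed on the true stimulus over held-out trials (invariant to affine
miscalibration; `estimator_information` also offers a polynomial
calibration for locally resolved measurements), divided by the optimal
decoder's `J` measured identically on the same held-out trials so that
shared sampling noise cancels in the ratio. On the default cubic code, a network
trained on 20,000 pairs extracts ≈ 92–95% of the optimal information (seed SD ≈ 4–5 points;
`scripts/acceptance.py` recomputes this as a 10-seed average).

## The variance-discrimination task

Task: binary category `s± = σ±²` (defaults σ₊ = 15°, σ₋ = 3°),
orientation `φ = sqrt(s)·ν` with `ν ~ N(0,1)`. The ideal observer
thresholds `φ²` where the category likelihoods cross,
`θ²_opt = (log s₊ − log s₋)/(s₋⁻¹ − s₊⁻¹)` (≈ 5.49° for the defaults),
giving fraction correct
`[erfc(θ/sqrt(2s₊)) + 1 − erfc(θ/sqrt(2s₋))]/2 = 0.82`.

**Generator.** Neurons are von-Mises orientation-tuned with period 180°
(preferred orientations uniform, gains 6–14, baselines 0.5–2, widths
κ 1–3) and Poisson spiking; an optional shared multiplicative gain
plants internal noise correlations. Defaults: 8 neurons, 4000 trials
per session, so trials exceed the 44 analysis statistics by two orders
of magnitude. The simulated subject fits its decoder on a private
100,000-trial calibration set — an overtrained observer, as animals
are after months of training — using exactly the analysis feature
pipeline (linear decode → pooled residualization → quadratic terms →
shrinkage readout). With these conditions the optimal subject performs
≈ 0.69 (ideal 0.82). An orientation-energy observer (linear `φ̂`,
squared and thresholded) is available as `decoder_kind='phi-squared'`.

**Planted efficiency.** `alpha < 1` adds zero-mean Gaussian noise to the
decision variable with variance `ε = V_u (1−α)/α`, where `V_u` is the
category-averaged conditional variance of the noiseless decision
variable — so the information-limited share of the estimator variance
is exactly `α`.

## Efficiency estimation for binary choices

Binarizing the choice attenuates choice correlations in a way that
scalar Gaussian-latent corrections do not capture for this task: the
decision variable is a heavy-tailed mixture over the nuisance, and the
attenuation acts on the within-nuisance noise scale rather than the
total variance. Measured per-term attenuation in simulation is ≈ 0.62
where the equal-variance signal-detection model predicts ≈ 0.89. Two
estimators address this:

1. **Optimal-observer probe** (`analyze_session`, default). The trials
   are split into three folds; a full feature-and-readout pipeline is
   fit on each fold alone, and every trial is decoded by the two
   pipelines that never saw it (no leakage, including through the
   feature construction). The probe decision variable is binarized at a
   threshold matching the subject's choice rate, and its per-term NACCC
   on the same trials is the optimal prediction — every binarization and
   task-shape effect is baked in per term. The prediction is rescaled by
   the probe/subject behavioral-d′ ratio and divided by the probe's
   fit-noise attenuation `Vc/(Vc+ε_fit)`, where the clean variance `Vc`
   is the covariance of the two independent readouts and `ε_fit` their
   excess variance. The efficiency slope is the principal-axis
   (total-least-squares) angle of the measured-vs-predicted scatter —
   appropriate because both axes are correlations on a common scale with
   comparable noise — with a percentile bootstrap over statistic terms
   (100 resamples). Scalar corrections (equal-variance signal detection
   from the hit rates; probit regression of choice on `φ²`; the constant
   `δ = 1.2` convention; none) remain available via `correction=`.

2. **Noise matching** (`recover_efficiency`). The raw slope is a biased
   estimator of `ε/σ²` for degraded binarized subjects (validated biases
   up to ~15% at intermediate efficiencies). The calibrated estimator
   adds noise to the probe decision variable until the binarized probe
   reproduces the subject's behavioral d′ (root-finding on a simulated
   d′-vs-noise curve, interpolated linearly in 1/d′²; extrapolation
   allows behavior better than the noiseless probe), then reports
   `α = Vc/(Vc + ε_fit + ε̂)`. Uncertainty combines a trial bootstrap
   (robust IQR scale — weak codes give heavy-tailed resamples) with the
   spread over three independent probe splits (t quantile with 2 df).
   In validation with planted α ∈ {0.25, 0.5, 0.75, 1.0} (10 sessions
   each), the means were 0.24/0.49/0.73/1.00 and the planted value fell
   inside the 95% CI in 40/40 sessions; the acceptance suite repeats
   this with 20 sessions per level.

## Shuffle controls and significance

Both controls permute responses per neuron independently within strata,
preserving every per-neuron conditional marginal exactly. Matching on
(category, choice, orientation within ±1.5° — fixed bins of width 3°)
removes internal noise correlations while keeping nuisance-driven ones;
matching on (category, choice) alone removes the nuisance correlations
too. Singleton strata are passed through and counted. On a
nuisance-driven synthetic session, the nuisance shuffle collapses the
cross-term measured-vs-predicted relationship while the nuisance-matched
shuffle preserves it; linear terms are exactly invariant. The collapse
is partial at our scale: with few, individually informative units a
residual relationship survives through choice-conditional response
means (the shuffle matches on choice by construction), an effect that is
negligible for weakly informative multiunit populations but visible for
strong synthetic units — the shuffle demonstration therefore uses a
low-gain population.

Shuffle nulls for per-term significance permute choices within stimulus
conditions (or stimulus labels across trials), fit a zero-mean Gaussian
to the null statistics, and report the two-sided tail
`erfc(|x|/(√2 σ))`, which is uniform under the null; the one-sided form
(0.5 at x = 0) is available via `two_sided=False`.

Session-level screening keeps sessions at or above a behavioral
performance threshold and marks sessions with non-positive coefficient
of determination of the CC scatter as unreliable-slope (excluded from
slope aggregation, retained in the data).

## What the synthetic data do and do not show

The generators reproduce the statistical structure that the analysis
targets — nuisance-induced nonlinear codes, Poisson-like variability,
binary choices from a thresholded internal variable — and are the
ground-truth bed for parameter recovery. They do not emulate multiunit
contamination, contrast as a second nuisance, temporal dynamics,
session-to-session nonstationarity, or realistic internal-state
fluctuations; absolute information levels are not calibrated to any
recorded dataset. Passing the recovery tests shows the estimators are
calibrated under the model class they assume, not that real cortical
data satisfy that class.

## Numerical conventions

Orientations in degrees, variances in deg²; binary categories coded
−1/+1 with +1 the wide (large-variance) category; exact threshold ties
go to the narrow category (probability zero for continuous variables).
Statistics are oriented so per-term discriminability is nonnegative
(statistic and measured correlation sign-flipped jointly), which makes
all optimal predictions nonnegative without changing the scatter
geometry. All simulators take explicit integer seeds; identical seeds
give identical tables.
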