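"""Coarse 2AFC variance-discrimination task: ideal observer, synthetic
V1-like sessions, and the end-to-end choice-correlation analysis.

Task model: on each trial a category ``s`` (the orientation variance,
``s_+ = sigma_wide**2`` or ``s_- = sigma_narrow**2`` in deg^2) is drawn
with equal probability; the shown orientation is ``phi = sqrt(s) * nu``
with a standard-normal multiplicative nuisance ``nu``. An ideal observer
thresholds ``phi**2`` at ``theta_opt**2`` where the two category
likelihoods cross. With the default sigmas of 15 and 3 degrees the ideal
fraction correct is 0.82.

The synthetic generator emulates a session: orientation-tuned Poisson
units respond to ``phi``; a simulated subject decodes a decision
variable from the population (the optimal linear readout of polynomial
statistics by default, or a quadratic orientation-energy observer) and
emits a binary choice. A planted efficiency ``alpha`` degrades the
decision variable with calibrated additive noise so that parameter
recovery can be validated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfc, ndtri
from scipy.stats import norm

from . import choice_stats as cs
from .decoders import decode, fit_coarse_decoder_shrunk
from .features import (
    FeatureSet,
    polynomial_features,
    residualize,
    signal_noise_summary,
)
from .inference import EfficiencyReport, efficiency_slope
from .trials import TrialTable

__all__ = [
    "VarianceTaskSpec",
    "optimal_threshold",
    "ideal_fraction_correct",
    "generate_session",
    "analyze_session",
    "recover_efficiency",
    "fraction_correct",
    "binary_choice_corrections",
]


# ----------------------------------------------------------------------
# ideal observer
# ----------------------------------------------------------------------
def optimal_threshold(s_plus: float, s_minus: float) -> float:
    """Orientation threshold where the two category likelihoods cross.

    For zero-mean Gaussian orientation distributions with variances
    ``s_plus > s_minus``,

        theta_opt**2 = (log s_plus - log s_minus) / (1/s_minus - 1/s_plus)

    which satisfies ``p(theta | s_plus) = p(theta | s_minus)`` and is the
    optimal decision boundary when the categories are equally probable.
    """
    if s_minus <= 0 or s_plus <= s_minus:
        raise ValueError("need s_plus > s_minus > 0")
    theta2 = (np.log(s_plus) - np.log(s_minus)) / (1.0 / s_minus - 1.0 / s_plus)
    return float(np.sqrt(theta2))


def ideal_fraction_correct(s_plus: float, s_minus: float) -> float:
    """Fraction correct of the ideal observer of the orientation itself.

    ``0.5 * [erfc(theta/sqrt(2 s_plus)) + 1 - erfc(theta/sqrt(2 s_minus))]``
    at the optimal threshold; 0.82 for the 15/3-degree task.
    """
    theta = optimal_threshold(s_plus, s_minus)
    p_plus = erfc(theta / np.sqrt(2.0 * s_plus))
    p_minus = 1.0 - erfc(theta / np.sqrt(2.0 * s_minus))
    return float(0.5 * (p_plus + p_minus))


def fraction_correct(table: TrialTable) -> float:
    """Observed fraction of correct choices (+1 = wide category)."""
    if table.choice is None:
        raise ValueError("table has no choices")
    s_hi = table.s == table.s.max()
    correct = np.where(s_hi, table.choice > 0, table.choice < 0)
    return float(np.mean(correct))


# ----------------------------------------------------------------------
# synthetic session generator
# ----------------------------------------------------------------------
@dataclass
class VarianceTaskSpec:
    """Parameters of a synthetic variance-discrimination session.

    Orientation tuning is von-Mises-like with period pi (180 deg);
    per-neuron parameters are drawn once from the stated ranges. The
    subject is configured by ``decoder_kind``:

    - ``'optimal'``: optimal linear readout of the analysis statistics
      (linear responses plus residualized quadratics), the theory's
      reference decoder;
    - ``'phi-squared'``: estimates orientation linearly, squares it, and
      thresholds — an orientation-energy observer.

    ``alpha`` plants a decoding efficiency: zero-mean Gaussian noise is
    added to the decision variable, calibrated so the information-limiting
    share of its variance is ``alpha`` (1.0 = no degradation).
    """

    sigma_wide: float = 15.0  # deg
    sigma_narrow: float = 3.0  # deg
    n_trials: int = 4000
    n_neurons: int = 8
    noise_model: str = "poisson"
    decoder_kind: str = "optimal"
    alpha: float = 1.0
    gain_range: tuple[float, float] = (6.0, 14.0)
    baseline_range: tuple[float, float] = (0.5, 2.0)
    kappa_range: tuple[float, float] = (1.0, 3.0)
    internal_corr: float = 0.0  # SD of a shared multiplicative gain
    n_calibration: int = 100000  # trials used to fit the subject's decoder

    def __post_init__(self) -> None:
        if not self.sigma_wide > self.sigma_narrow > 0:
            raise ValueError("need sigma_wide > sigma_narrow > 0")
        if np.any(np.asarray(self.gain_range) < 0):
            raise ValueError("gains must be nonnegative")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.noise_model not in ("poisson", "gaussian"):
            raise ValueError("noise_model must be 'poisson' or 'gaussian'")
        if self.decoder_kind not in ("optimal", "phi-squared"):
            raise ValueError("decoder_kind must be 'optimal' or 'phi-squared'")

    @property
    def s_plus(self) -> float:
        return self.sigma_wide**2

    @property
    def s_minus(self) -> float:
        return self.sigma_narrow**2


def _draw_tuning(spec: VarianceTaskSpec, rng: np.random.Generator) -> dict:
    n = spec.n_neurons
    return {
        "pref": rng.uniform(-90.0, 90.0, size=n),
        "gain": rng.uniform(*spec.gain_range, size=n),
        "baseline": rng.uniform(*spec.baseline_range, size=n),
        "kappa": rng.uniform(*spec.kappa_range, size=n),
    }


def _rates(phi_deg: np.ndarray, tuning: dict) -> np.ndarray:
    """Mean spike counts: von-Mises orientation tuning with period pi."""
    d = np.deg2rad(phi_deg[:, None] - tuning["pref"][None, :])
    return tuning["baseline"][None, :] + tuning["gain"][None, :] * np.exp(
        tuning["kappa"][None, :] * (np.cos(2.0 * d) - 1.0)
    )


def _spike_counts(
    phi: np.ndarray, tuning: dict, spec: VarianceTaskSpec, rng: np.random.Generator
) -> np.ndarray:
    rates = _rates(phi, tuning)
    if spec.internal_corr > 0:
        g = 1.0 + spec.internal_corr * rng.standard_normal(phi.shape[0])
        rates = rates * np.clip(g, 0.1, None)[:, None]
    if spec.noise_model == "poisson":
        return rng.poisson(rates).astype(float)
    return rates + rng.normal(scale=np.sqrt(rates))


def _draw_stimuli(
    spec: VarianceTaskSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    s = rng.choice([spec.s_minus, spec.s_plus], size=n)
    nu = rng.standard_normal(n)
    phi = np.sqrt(s) * nu
    return s, phi


def analysis_features(table: TrialTable) -> tuple[FeatureSet, np.ndarray]:
    """Analysis statistics: raw linear terms + residualized quadratics.

    The linear stimulus estimate ``s1_hat`` comes from the optimal
    linear (in r) decoder; responses are residualized against it and
    the quadratic terms are built from the residuals. Returns the
    combined feature set and ``s1_hat``.
    """
    lin = polynomial_features(table, max_degree=1)
    lin_dec = fit_coarse_decoder_shrunk(lin, table)
    s1_hat = decode(lin_dec, lin)
    resid = residualize(table, s1_hat)
    quad_all = polynomial_features(resid, max_degree=2)
    quad = quad_all.select(quad_all.degrees == 2)
    return lin.concat(quad), s1_hat


def _subject_decision_variable(
    spec: VarianceTaskSpec, tuning: dict, rng: np.random.Generator
):
    """Fit the subject's decoder on a private calibration set.

    Returns a function mapping (responses, phi) -> decision variable u
    (an estimate of the orientation variance), the decision threshold,
    and the average conditional variance of u (for planting alpha).
    """
    n = spec.n_calibration
    s, phi = _draw_stimuli(spec, n, rng)
    r = _spike_counts(phi, tuning, spec, rng)
    calib = TrialTable(s=s, r=r, nu=phi)
    if spec.decoder_kind == "optimal":
        # linear stage and a pooled conditional-mean model, both frozen
        # at calibration time so the subject applies one fixed mapping;
        # the construction mirrors the analysis statistics exactly
        lin_cal = polynomial_features(calib, max_degree=1)
        lin_dec = fit_coarse_decoder_shrunk(lin_cal, calib)
        s1_cal = decode(lin_dec, lin_cal)
        lin_cond = _fit_linear_conditional(calib.r, s1_cal)

        def u_fn(resp: np.ndarray) -> np.ndarray:
            t = TrialTable(s=np.zeros(resp.shape[0]), r=resp)
            lin_f = polynomial_features(t, max_degree=1)
            s1 = decode(lin_dec, lin_f)
            delta = _apply_linear_conditional(resp, s1, lin_cond)
            quad_all = polynomial_features(t, max_degree=2, responses=delta)
            quad = quad_all.select(quad_all.degrees == 2)
            return decode(dec, lin_f.concat(quad))

        # optimal readout of the combined statistics, fit on calibration
        delta_cal = _apply_linear_conditional(calib.r, s1_cal, lin_cond)
        quad_cal = polynomial_features(calib, max_degree=2, responses=delta_cal)
        feats_cal = lin_cal.concat(quad_cal.select(quad_cal.degrees == 2))
        dec = fit_coarse_decoder_shrunk(feats_cal, calib)
        u_cal = u_fn(calib.r)
        threshold = float(dec.threshold)
    else:  # phi-squared observer
        X = np.column_stack([r, np.ones(n)])
        coef, *_ = np.linalg.lstsq(X, phi, rcond=None)

        def u_fn(resp: np.ndarray) -> np.ndarray:
            phi_hat = resp @ coef[:-1] + coef[-1]
            return phi_hat**2

        u_cal = u_fn(r)
        # threshold from the fitted Gaussian variances of phi_hat
        ph = r @ coef[:-1] + coef[-1]
        v_plus = float(np.var(ph[s == spec.s_plus]))
        v_minus = float(np.var(ph[s == spec.s_minus]))
        threshold = optimal_threshold(v_plus, v_minus) ** 2
    v_u = 0.5 * (
        float(np.var(u_cal[s == spec.s_plus]))
        + float(np.var(u_cal[s == spec.s_minus]))
    )
    return u_fn, threshold, v_u


def _fit_linear_conditional(r: np.ndarray, s1: np.ndarray):
    """Per-neuron linear model r_i ~ a_i + b_i * s1 (pooled)."""
    x = np.column_stack([np.ones_like(s1), s1])
    coef, *_ = np.linalg.lstsq(x, r, rcond=None)
    return coef  # (2, n_neurons)


def _apply_linear_conditional(r, s1, coef):
    return r - (coef[0][None, :] + np.outer(s1, coef[1]))


def generate_session(spec: VarianceTaskSpec, seed: int = 0) -> TrialTable:
    """Simulate one behavioral session of the variance task.

    The trial table records the category ``s`` (variance, deg^2), the
    shown orientation as the nuisance ``nu`` (deg), Poisson (or
    Gaussian) spike counts, and the subject's binary choice (+1 = wide).
    ``meta`` carries the full ground truth, including the planted
    efficiency.
    """
    rng = np.random.default_rng(seed)
    tuning = _draw_tuning(spec, rng)
    u_fn, threshold, v_u = _subject_decision_variable(spec, tuning, rng)
    s, phi = _draw_stimuli(spec, spec.n_trials, rng)
    r = _spike_counts(phi, tuning, spec, rng)
    u = u_fn(r)
    eps_u = v_u * (1.0 - spec.alpha) / spec.alpha
    if eps_u > 0:
        u = u + rng.normal(scale=np.sqrt(eps_u), size=u.shape)
    choice = np.where(u > threshold, 1.0, -1.0)
    meta = {
        "model": "v1-variance-task",
        "seed": seed,
        "planted_alpha": spec.alpha,
        "decoder_kind": spec.decoder_kind,
        "epsilon_u": eps_u,
        "var_u": v_u,
        "threshold": threshold,
        "sigma_wide": spec.sigma_wide,
        "sigma_narrow": spec.sigma_narrow,
        "tuning": {k: v.tolist() for k, v in tuning.items()},
    }
    return TrialTable(s=s, r=r, nu=phi, choice=choice, meta=meta)


# ----------------------------------------------------------------------
# binary-choice corrections
# ----------------------------------------------------------------------
def binary_choice_corrections(
    table: TrialTable,
    method: str = "probit",
    n_mc: int = 200_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Correction factors (zeta, delta) for binary choices.

    The optimality prediction ``B_opt = d'_k / d'`` refers to a
    continuous internal estimate; observed choices are binary. Modeling
    the choice as a thresholded latent Gaussian decision variable gives
    two order-1 factors: ``zeta`` (attenuation of the measured
    conditional covariance by binarization) and ``delta`` (mismatch
    between the behavioral d' recovered from binary choices and the
    latent continuous d'), applied as

        predicted_k = (d'_k / d'_binary) * zeta * delta.

    Methods:

    - ``'probit'``: probit regression of the choice on the squared
      orientation fits the latent model including its dependence on the
      nuisance; moments of the latent variable are then computed by
      Monte Carlo under the task distribution (requires ``table.nu``).
    - ``'gaussian'``: equal-variance signal-detection model identified
      from the two hit rates alone.
    - ``'constant'``: zeta = 1, delta = 1/1.2 (a typical value for this
      task's conditions).
    - ``'none'``: both factors 1.
    """
    if method == "none":
        return 1.0, 1.0
    if method == "constant":
        return 1.0, 1.0 / 1.2
    if table.choice is None:
        raise ValueError("table has no choices")
    b = table.choice > 0
    s_hi = table.s == table.s.max()
    q_plus = float(np.mean(b[s_hi]))
    q_minus = float(np.mean(b[~s_hi]))
    d_binary = _dprime_binary(q_plus, q_minus)
    if method == "gaussian":
        z_p, z_m = ndtri(np.clip([q_plus, q_minus], 1e-6, 1 - 1e-6))
        d_latent = z_p - z_m
        dens = 0.5 * (norm.pdf(z_p) + norm.pdf(z_m))
        spread = np.sqrt(
            0.5 * (q_plus * (1 - q_plus) + q_minus * (1 - q_minus))
        )
        zeta = float(dens / spread)
        delta = float(d_binary / d_latent) if d_latent > 0 else 1.0
        return zeta, delta
    if method != "probit":
        raise ValueError(f"unknown correction method {method!r}")
    if table.nu is None:
        raise ValueError("probit correction needs the recorded orientation")
    import statsmodels.api as sm

    phi2 = np.asarray(table.nu, dtype=float) ** 2
    X = sm.add_constant(phi2 / phi2.std())
    fit = sm.GLM(
        b.astype(float), X, family=sm.families.Binomial(sm.families.links.Probit())
    ).fit()
    b0, b1 = float(fit.params[0]), float(fit.params[1]) / phi2.std()
    # Monte Carlo under the fitted latent model u = b0 + b1 phi^2 + N(0,1):
    # zeta is the NACCC between the latent variable and its own
    # binarized choice (a redundant-code proxy for every statistic)
    rng = np.random.default_rng(seed)
    svals = np.unique(table.s)
    mu, tau2, cov_ub, var_b, q = [], [], [], [], []
    for sv in svals:
        phi_mc = np.sqrt(sv) * rng.standard_normal(n_mc // 2)
        m = b0 + b1 * phi_mc**2
        u_mc = m + rng.standard_normal(m.size)
        b_mc = np.where(u_mc > 0, 1.0, -1.0)
        mu.append(float(m.mean()))
        tau2.append(float(u_mc.var()))
        cov_ub.append(float(np.cov(u_mc, b_mc)[0, 1]))
        var_b.append(float(b_mc.var()))
        q.append(float(np.mean(b_mc > 0)))
    tau_bar2 = 0.5 * (tau2[0] + tau2[1])
    d_latent = abs(mu[1] - mu[0]) / np.sqrt(tau_bar2)
    zeta = float(
        0.5 * (cov_ub[0] + cov_ub[1])
        / np.sqrt(tau_bar2 * 0.5 * (var_b[0] + var_b[1]))
    )
    delta = float(d_binary / d_latent) if d_latent > 0 else 1.0
    return zeta, delta


def _dprime_binary(q_plus: float, q_minus: float) -> float:
    """Eq.-20-style behavioral d' from the two hit rates."""
    mean_b = q_plus + q_minus - 1.0
    var_b = 1.0 - mean_b**2
    if var_b <= 0:
        raise ValueError("choices are constant")
    D = (q_plus - q_minus) / np.sqrt(var_b)
    D = float(np.clip(D, -0.999999, 0.999999))
    return 2.0 * D / np.sqrt(1.0 - D**2)


# ----------------------------------------------------------------------
# end-to-end analysis
# ----------------------------------------------------------------------
class _FoldPipeline:
    """Full analysis pipeline (linear decode -> residualize -> quadratic
    statistics -> coarse readout) fit on one subset of trials, applicable
    to new responses. Used to build leakage-free optimal-observer probes."""

    def __init__(self, table: TrialTable):
        lin = polynomial_features(table, max_degree=1)
        self.lin_dec = fit_coarse_decoder_shrunk(lin, table)
        s1 = decode(self.lin_dec, lin)
        self.cond = _fit_linear_conditional(table.r, s1)
        delta = _apply_linear_conditional(table.r, s1, self.cond)
        qa = polynomial_features(table, max_degree=2, responses=delta)
        feats = lin.concat(qa.select(qa.degrees == 2))
        self.dec = fit_coarse_decoder_shrunk(feats, table)

    def decision_variable(self, r: np.ndarray) -> np.ndarray:
        t = TrialTable(s=np.zeros(r.shape[0]), r=r)
        lin = polynomial_features(t, max_degree=1)
        s1 = decode(self.lin_dec, lin)
        delta = _apply_linear_conditional(r, s1, self.cond)
        qa = polynomial_features(t, max_degree=2, responses=delta)
        feats = lin.concat(qa.select(qa.degrees == 2))
        return decode(self.dec, feats)


def _build_probe(table: TrialTable, seed: int = 0):
    """Two independent optimal-observer decision variables per trial.

    The trials are split into three folds; a full pipeline is fit on
    each fold alone, and every trial is decoded by the two pipelines
    that never saw it. The covariance of the two out-of-sample readouts
    isolates the clean (population) decision-variable variance from
    weight-estimation noise.
    """
    rng = np.random.default_rng(seed)
    n = table.n_trials
    perm = rng.permutation(n)
    folds = np.array_split(perm, 3)
    pipes = [
        _FoldPipeline(TrialTable(s=table.s[f], r=table.r[f])) for f in folds
    ]
    u1, u2 = np.empty(n), np.empty(n)
    for i in range(3):
        o = [j for j in range(3) if j != i]
        u1[folds[i]] = pipes[o[0]].decision_variable(table.r[folds[i]])
        u2[folds[i]] = pipes[o[1]].decision_variable(table.r[folds[i]])
    return u1, u2


def _probe_moments(u1: np.ndarray, u2: np.ndarray, s: np.ndarray):
    """Clean variance and (averaged) fit-noise variance of the probe."""
    v_clean, v_each = 0.0, 0.0
    svals = np.unique(s)
    for sv in svals:
        m = s == sv
        v_clean += float(np.cov(u1[m], u2[m])[0, 1]) / svals.size
        v_each += (
            0.5 * (np.var(u1[m], ddof=1) + np.var(u2[m], ddof=1)) / svals.size
        )
    eps_fit = max(v_each - v_clean, 0.0) / 2.0  # u = (u1+u2)/2 halves it
    return v_clean, eps_fit


def _optimal_probe_prediction(
    table: TrialTable,
    feats: FeatureSet,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Predicted-optimal NACCCs from a binarized optimal-observer probe.

    The probe decision variable is binarized at a threshold matching the
    subject's overall choice rate and its per-term NACCC measured on the
    same trials, which bakes every binarization and task-shape effect
    into the prediction term by term. The result is rescaled by the
    ratio of probe to subject behavioral d' (the optimality prediction
    divides by the subject's own discriminability) and divided by the
    probe's fit-noise attenuation ``Vc / (Vc + eps_fit)``.
    """
    u1, u2 = _build_probe(table, seed=seed)
    u_probe = 0.5 * (u1 + u2)
    v_clean, eps_fit = _probe_moments(u1, u2, table.s)
    atten = v_clean / (v_clean + eps_fit) if v_clean > 0 else 1.0
    p_plus = float(np.mean(table.choice > 0))
    thr = float(np.quantile(u_probe, 1.0 - p_plus))
    b_probe = np.where(u_probe > thr, 1.0, -1.0)
    s_hi = table.s == table.s.max()
    d_probe = _dprime_binary(
        float(np.mean(b_probe[s_hi] > 0)), float(np.mean(b_probe[~s_hi] > 0))
    )
    b = table.choice
    d_act = _dprime_binary(
        float(np.mean(b[s_hi] > 0)), float(np.mean(b[~s_hi] > 0))
    )
    pred = cs.naccc(feats, b_probe, table) * (d_probe / d_act) / atten
    info = {
        "d_probe": d_probe,
        "d_behav": d_act,
        "probe_attenuation": atten,
        "v_clean": v_clean,
        "eps_fit": eps_fit,
        "probe_threshold": thr,
    }
    return pred, info


def _binarized_dprime_curve(
    u: np.ndarray,
    s_hi: np.ndarray,
    p_plus: float,
    zs: list[np.ndarray],
    eps_grid: np.ndarray,
) -> np.ndarray:
    """Behavioral d' of ``sign(u + sqrt(eps) z - theta)`` along a noise grid."""
    out = np.empty(eps_grid.shape[0])
    for i, e in enumerate(eps_grid):
        dd = []
        for z in zs:
            ue = u + np.sqrt(e) * z
            thr = np.quantile(ue, 1.0 - p_plus)
            be = ue > thr
            dd.append(
                _dprime_binary(
                    max(float(np.mean(be[s_hi])), 1e-9),
                    max(float(np.mean(be[~s_hi])), 1e-9),
                )
            )
        out[i] = np.mean(dd)
    return out


def _invert_dprime_curve(
    eps_grid: np.ndarray, dvals: np.ndarray, d_target: float
) -> float:
    """Noise variance at which the simulated d' matches the target.

    Interpolates linearly in 1/d'^2 (near-linear in the noise variance),
    extrapolating at both ends — a negative result means the observed
    behavior beats the noiseless probe.
    """
    y = 1.0 / dvals**2
    yt = 1.0 / d_target**2
    slope_lo = (eps_grid[1] - eps_grid[0]) / (y[1] - y[0])
    slope_hi = (eps_grid[-1] - eps_grid[-2]) / (y[-1] - y[-2])
    return float(
        np.interp(
            yt,
            y,
            eps_grid,
            left=eps_grid[0] + (yt - y[0]) * slope_lo,
            right=eps_grid[-1] + (yt - y[-1]) * slope_hi,
        )
    )


def recover_efficiency(
    table: TrialTable,
    seed: int = 0,
    n_splits: int = 3,
    n_boot: int = 40,
    n_sim: int = 8,
) -> EfficiencyReport:
    """Decoding efficiency of a binary-choice session by noise matching.

    The estimator builds the optimal-observer probe, then finds the
    additive noise variance ``eps_hat`` at which the binarized, noisy
    probe reproduces the subject's behavioral d'. The efficiency is the
    clean decision-variable share of the matched total variance,

        alpha = Vc / (Vc + eps_fit + eps_hat),

    which reduces to Eq.-9-style ``1 - eps/sigma^2`` bookkeeping while
    staying exact under choice binarization (the matching happens in the
    binarized domain). Uncertainty combines a trial bootstrap with the
    spread across ``n_splits`` independent probe splits (random-effects
    style); the report's ``alpha`` is the split average.
    """
    if table.choice is None:
        raise ValueError("table has no choices")
    s = table.s
    b = table.choice
    s_hi = s == s.max()
    p_plus = float(np.mean(b > 0))
    d_act = _dprime_binary(
        float(np.mean(b[s_hi] > 0)), float(np.mean(b[~s_hi] > 0))
    )
    ahats, boots = [], []
    for k in range(n_splits):
        u1, u2 = _build_probe(table, seed=seed * 97 + k)
        u_a = 0.5 * (u1 + u2)
        v_clean, eps_fit = _probe_moments(u1, u2, s)
        rng = np.random.default_rng(seed + 31 + k)
        zs = [rng.standard_normal(table.n_trials) for _ in range(n_sim)]
        v_tot = 0.5 * (np.var(u_a[s_hi]) + np.var(u_a[~s_hi]))
        grid = np.linspace(0.0, 4.0 * v_tot, 9)
        dvals = _binarized_dprime_curve(u_a, s_hi, p_plus, zs, grid)
        eps_hat = _invert_dprime_curve(grid, dvals, d_act)
        ahats.append(v_clean / (v_clean + eps_fit + eps_hat))
        for _ in range(n_boot):
            idx = rng.integers(0, table.n_trials, table.n_trials)
            shi_b = s_hi[idx]
            if shi_b.all() or not shi_b.any():
                continue
            vc_b, ef_b = _probe_moments(u1[idx], u2[idx], s[idx])
            d_b = _dprime_binary(
                max(float(np.mean(b[idx][shi_b] > 0)), 1e-9),
                max(float(np.mean(b[idx][~shi_b] > 0)), 1e-9),
            )
            zsb = [z[idx] for z in zs[: max(n_sim // 2, 2)]]
            dv_b = _binarized_dprime_curve(u_a[idx], shi_b, p_plus, zsb, grid)
            e_b = _invert_dprime_curve(grid, dv_b, d_b)
            denom = vc_b + ef_b + e_b
            if denom > 0:
                boots.append(float(np.clip(vc_b / denom, -1.0, 3.0)))
    alpha = float(np.mean(ahats))
    # two variance components: trial bootstrap (robust scale — weak codes
    # give heavy-tailed resamples) and the spread over probe splits, which
    # with few splits gets a t quantile
    from scipy.stats import t as t_dist

    boots = np.asarray(boots)
    q25, q75 = np.percentile(boots, [25, 75])
    sd_boot = max((q75 - q25) / 1.349, 1e-6)
    t_q = t_dist.ppf(0.975, df=max(n_splits - 1, 1))
    var_split = (1.0 + 1.0 / n_splits) * np.var(ahats, ddof=1)
    hw = float(np.sqrt(1.96**2 * sd_boot**2 + t_q**2 * var_split))
    return EfficiencyReport(
        alpha=alpha,
        ci=(alpha - hw, alpha + hw),
        n_boot=n_boot * n_splits,
        correlation=float("nan"),
        r_squared=float("nan"),
        session_id=None,
        performance=fraction_correct(table),
    )


def analyze_session(
    table: TrialTable,
    correction: str = "probe",
    n_boot: int = 100,
    seed: int = 0,
    session_id=None,
) -> tuple[cs.CCResult, EfficiencyReport]:
    """Measured vs predicted-optimal NACCCs and the efficiency slope.

    Pipeline: optimal linear decoder -> residualization -> polynomial
    statistics (linear + residual quadratics) -> measured NACCC against
    the binary choice vs the predicted-optimal NACCC, and the
    principal-axis efficiency slope with a bootstrap CI over terms.

    ``correction='probe'`` (default) predicts via the binarized
    optimal-observer probe (:func:`_optimal_probe_prediction`), which
    handles all binary-choice corrections per term. The other methods
    ('gaussian', 'probit', 'constant', 'none') use the analytic
    prediction ``(d'_k/d') * zeta * delta`` with scalar corrections from
    :func:`binary_choice_corrections`.
    """
    if table.choice is None:
        raise ValueError("table has no choices; run a decoder first")
    feats, _ = analysis_features(table)
    summary = signal_noise_summary(feats, table, mode="coarse")
    measured = cs.naccc(feats, table.choice, table)
    b = table.choice > 0
    s_hi = table.s == table.s.max()
    d_behav = _dprime_binary(float(np.mean(b[s_hi])), float(np.mean(b[~s_hi])))
    flip = np.where(summary.d_prime_terms < 0, -1.0, 1.0)
    if correction == "probe":
        pred, info = _optimal_probe_prediction(table, feats, seed=seed)
        result = cs.CCResult(
            terms=list(summary.terms),
            measured=measured * flip,
            predicted=pred * flip,
            d_prime_terms=summary.d_prime_terms * flip,
            behavioral_dprime=d_behav,
            zeta=1.0,
            delta=1.0,
            meta={"correction": "probe", "session_id": session_id, **info},
        )
    else:
        zeta, delta = binary_choice_corrections(table, method=correction, seed=seed)
        result = cs.make_cc_result(
            summary,
            measured,
            behavioral_dprime=d_behav,
            zeta=zeta,
            delta=delta,
            meta={"correction": correction, "session_id": session_id},
        )
    keep = ~summary.degenerate
    report = efficiency_slope(
        result.predicted[keep],
        result.measured[keep],
        n_boot=n_boot,
        seed=seed,
        degrees=result.degrees[keep],
    )
    report.session_id = session_id
    report.performance = fraction_correct(table)
    return result, report
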