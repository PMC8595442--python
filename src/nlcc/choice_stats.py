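"""Choice correlations: measured, predicted-optimal, and discriminability.

The central quantity is the choice correlation of a response statistic
R_k: the Pearson correlation between R_k and the behavioral estimate at
a fixed stimulus (fine tasks), or the normalized average conditional
choice correlation (NACCC) built from category-averaged conditional
covariances (coarse tasks). Optimal decoding predicts

    C_k(opt) = d'_k / d'

— each statistic's choice correlation equals its own discriminability
relative to the behavioral discriminability. Measuring the slope of
measured against predicted choice correlations across statistics then
reads out the decoding efficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureSet, SignalNoiseSummary
from .trials import TrialTable

__all__ = [
    "CCResult",
    "choice_correlation_fine",
    "cc_closed_form",
    "naccc",
    "dprime_from_total_correlation",
    "behavioral_dprime_fine",
    "predict_optimal_cc",
    "equivalent_ratios",
    "fisher_information",
    "make_cc_result",
]


def _check_choices(choices: np.ndarray, n: int) -> np.ndarray:
    choices = np.asarray(choices, dtype=float)
    if choices.shape[0] != n:
        raise ValueError("choices length does not match trial count")
    return choices


def choice_correlation_fine(
    features: FeatureSet, choices: np.ndarray, table: TrialTable
) -> np.ndarray:
    """Per-term Corr(R_k, s_hat | s), trial-weighted across conditions.

    The correlation is computed within each fixed stimulus condition
    (so stimulus-driven covariation never contributes) and averaged over
    conditions with weights proportional to trial counts.
    """
    choices = _check_choices(choices, table.n_trials)
    svals = np.unique(table.s)
    R = features.values
    out = np.zeros(features.n_terms)
    total = 0
    for sv in svals:
        idx = np.flatnonzero(table.s == sv)
        if idx.size < 2:
            raise ValueError(f"need >= 2 trials per condition (s={sv})")
        Rc = R[idx] - R[idx].mean(axis=0)
        cc = choices[idx] - choices[idx].mean()
        sd_c = np.sqrt(cc @ cc)
        sd_R = np.sqrt((Rc**2).sum(axis=0))
        if sd_c == 0:
            raise ValueError("choice has zero variance within a condition")
        bad = sd_R == 0
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} zero-variance feature(s) in condition s={sv}",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (Rc.T @ cc) / (sd_R * sd_c)
        corr[bad] = 0.0
        out += idx.size * corr
        total += idx.size
    return out / total


def cc_closed_form(Gamma: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Choice correlations of a linear readout: (Gamma w)_k / sqrt(...).

    Exact for any fixed weights when the estimate is ``w . R + c``:
    ``C_k = (Gamma w)_k / sqrt(Gamma_kk w^T Gamma w)``.
    """
    Gamma = np.atleast_2d(np.asarray(Gamma, dtype=float))
    w = np.asarray(w, dtype=float)
    gw = Gamma @ w
    return gw / np.sqrt(np.diagonal(Gamma) * float(w @ gw))


def naccc(
    features: FeatureSet,
    choices: np.ndarray,
    table: TrialTable,
    weighting: str = "category",
) -> np.ndarray:
    """Normalized average conditional choice correlation (coarse tasks).

    B_k = <Cov(R_k, s_hat | s)>_s / sqrt(<Var(R_k|s)>_s <Var(s_hat|s)>_s)

    with the conditional moments computed per stimulus category and then
    averaged — unweighted over categories by default
    (``weighting='trials'`` weights by trial counts instead). Bounded in
    absolute value by 1; converges to the fine choice correlation when
    the conditional distributions stop depending on the category.
    """
    choices = _check_choices(choices, table.n_trials)
    svals = np.unique(table.s)
    if svals.size < 2:
        raise ValueError("NACCC needs at least two stimulus categories")
    R = features.values
    covs, var_R, var_c, wts = [], [], [], []
    for sv in svals:
        idx = np.flatnonzero(table.s == sv)
        if idx.size < 2:
            raise ValueError(f"category s={sv} has fewer than 2 trials")
        Rc = R[idx] - R[idx].mean(axis=0)
        cc = choices[idx] - choices[idx].mean()
        covs.append((Rc.T @ cc) / (idx.size - 1))
        var_R.append((Rc**2).sum(axis=0) / (idx.size - 1))
        var_c.append(float(cc @ cc) / (idx.size - 1))
        wts.append(idx.size if weighting == "trials" else 1.0)
    wts = np.asarray(wts, dtype=float)
    wts /= wts.sum()
    cov = np.einsum("c,ck->k", wts, np.asarray(covs))
    vR = np.einsum("c,ck->k", wts, np.asarray(var_R))
    vc = float(wts @ np.asarray(var_c))
    if vc == 0:
        raise ValueError("choice has zero variance within every category")
    bad = vR == 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} zero-variance feature(s); NACCC set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        B = cov / np.sqrt(vR * vc)
    B[bad] = 0.0
    return B


def dprime_from_total_correlation(x: np.ndarray, s: np.ndarray) -> float:
    """Discriminability from the total correlation with a binary stimulus.

    With D = Corr(x, s) for a binary, balanced stimulus label,
    ``d' = 2 / sqrt(D^-2 - 1) = 2 D / sqrt(1 - D^2)`` (signed by D;
    approximately 2D for small D). |D| = 1 would mean infinite
    discriminability and raises.
    """
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.unique(s).size != 2:
        raise ValueError("stimulus must be binary")
    D = float(np.corrcoef(x, s)[0, 1])
    return dprime_from_D(D)


def dprime_from_D(D: float) -> float:
    if not np.isfinite(D) or abs(D) >= 1.0:
        raise ValueError(f"|D| must be < 1 (got {D})")
    return 2.0 * D / np.sqrt(1.0 - D**2)


def behavioral_dprime_fine(
    estimates: np.ndarray, s: np.ndarray, ds: float = 1.0
) -> float:
    """Behavioral discriminability of a continuous estimate, per step ds.

    ``d' = |d<s_hat>/ds| * ds / sd(residual)`` — robust to affine
    miscalibration of the estimate.
    """
    s = np.asarray(s, dtype=float)
    est = np.asarray(estimates, dtype=float)
    sc = s - s.mean()
    denom = float(sc @ sc)
    if denom == 0:
        raise ValueError("stimulus has no variation")
    slope = float(sc @ (est - est.mean())) / denom
    resid = est - est.mean() - slope * sc
    sd = np.sqrt(float(resid @ resid) / max(resid.size - 2, 1))
    if sd == 0:
        raise ValueError("estimate has zero residual variance")
    return abs(slope) * ds / sd


def predict_optimal_cc(
    summary: SignalNoiseSummary,
    behavioral_dprime: float,
    zeta: float = 1.0,
    delta: float = 1.0,
) -> np.ndarray:
    """Predicted choice correlations under optimal decoding: d'_k / d'.

    ``zeta`` and ``delta`` are order-1 correction factors for binary
    (rather than continuous) choices; both default to 1. Predictions
    exceeding 1 in magnitude are flagged with a warning, not clipped.
    """
    if behavioral_dprime <= 0:
        raise ValueError("behavioral d' must be positive")
    pred = summary.d_prime_terms / behavioral_dprime * zeta * delta
    if np.any(np.abs(pred) > 1.0):
        warnings.warn(
            f"{int((np.abs(pred) > 1).sum())} predicted choice correlation(s) "
            "exceed 1 in magnitude (corrections > 1?)",
            stacklevel=2,
        )
    return pred


def equivalent_ratios(
    dprime_pair: tuple[float, float] | None = None,
    threshold_pair: tuple[float, float] | None = None,
    variance_pair: tuple[float, float] | None = None,
    fisher_pair: tuple[float, float] | None = None,
) -> float:
    """The optimal choice-correlation prediction from any information ratio.

    All four measured-quantity forms are equivalent:

        C_opt = d'_k / d' = theta / theta_k
              = sqrt(sigma^2 / sigma_k^2) = sqrt(J_k / J)

    Exactly one pair may be supplied: ``(d'_k, d')``,
    ``(theta, theta_k)``, ``(sigma2, sigma2_k)`` or ``(J_k, J)``.
    """
    given = [
        p
        for p in (dprime_pair, threshold_pair, variance_pair, fisher_pair)
        if p is not None
    ]
    if len(given) != 1:
        raise ValueError("supply exactly one quantity pair")
    a, b = (float(v) for v in given[0])
    if dprime_pair is not None or threshold_pair is not None:
        if b == 0:
            raise ValueError("denominator quantity is zero")
        return a / b
    if b == 0:
        raise ValueError("denominator quantity is zero")
    return float(np.sqrt(a / b))


def fisher_information(
    summary: SignalNoiseSummary, ridge: float | None = None
) -> float:
    """Nonlinear Fisher information of the statistics: J = F'^T Gamma^-1 F'.

    With an information limit of variance ``eps = 1/J_inf`` folded into
    ``Gamma = Gamma_0 + eps F' F'^T``, this obeys the saturation law
    ``J = 1 / (1/J_inf + 1/J_0)``.
    """
    F = summary.F_prime / (summary.ds if summary.mode == "coarse" else 1.0)
    Gamma = np.atleast_2d(summary.Gamma)
    if ridge:
        Gamma = Gamma + ridge * np.eye(Gamma.shape[0])
    try:
        sol = np.linalg.solve(Gamma, F)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular feature covariance") from err
    J = float(F @ sol)
    return max(J, 0.0)


@dataclass
class CCResult:
    """Tidy per-term record of the optimality test.

    Terms are oriented so that each statistic's discriminability is
    nonnegative (a statistic tuned downward is sign-flipped together
    with its measured correlation), which makes every optimal prediction
    nonnegative without changing the geometry of the scatter.
    """

    terms: list[tuple[int, ...]]
    measured: np.ndarray
    predicted: np.ndarray
    d_prime_terms: np.ndarray
    behavioral_dprime: float
    zeta: float = 1.0
    delta: float = 1.0
    p_measured: np.ndarray | None = None
    p_predicted: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(t) for t in self.terms])

    def to_frame(self) -> pd.DataFrame:
        from .features import term_name

        df = pd.DataFrame(
            {
                "term": [term_name(t) for t in self.terms],
                "degree": self.degrees,
                "measured_cc": self.measured,
                "predicted_cc": self.predicted,
                "d_prime": self.d_prime_terms,
            }
        )
        if self.p_measured is not None:
            df["p_measured"] = self.p_measured
        if self.p_predicted is not None:
            df["p_predicted"] = self.p_predicted
        return df


def make_cc_result(
    summary: SignalNoiseSummary,
    measured: np.ndarray,
    behavioral_dprime: float,
    zeta: float = 1.0,
    delta: float = 1.0,
    meta: dict | None = None,
) -> CCResult:
    """Assemble an oriented measured-vs-predicted record."""
    pred = predict_optimal_cc(summary, behavioral_dprime, zeta=zeta, delta=delta)
    flip = np.where(summary.d_prime_terms < 0, -1.0, 1.0)
    return CCResult(
        terms=list(summary.terms),
        measured=np.asarray(measured) * flip,
        predicted=pred * flip,
        d_prime_terms=summary.d_prime_terms * flip,
        behavioral_dprime=behavioral_dprime,
        zeta=zeta,
        delta=delta,
        meta=meta or {},
    )
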