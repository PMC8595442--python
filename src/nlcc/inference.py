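"""Population-level efficiency estimation, significance, and controls.

The decoding efficiency ``alpha`` is the slope between measured and
predicted-optimal choice correlations across response statistics,
estimated as the angle of the principal axis of the bivariate scatter
(total least squares — both axes carry comparable estimation noise).
``alpha = 1`` is the optimal-decoding prediction; information-limiting
noise of variance ``eps`` pins ``alpha`` at ``eps / sigma_hat^2``.

Two permutation controls localize the origin of nonlinear information:
shuffling responses across trials matched on (stimulus, nuisance,
choice) removes internal noise correlations while preserving
nuisance-driven ones; dropping the nuisance matching removes the
nuisance correlations as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc

from .choice_stats import naccc
from .features import FeatureSet
from .trials import TrialTable

__all__ = [
    "EfficiencyReport",
    "efficiency_slope",
    "shuffle_null_pvalues",
    "shuffle_internal_noise",
    "shuffle_nuisance",
    "session_filter",
]


@dataclass
class EfficiencyReport:
    """Efficiency slope with bootstrap uncertainty for one session."""

    alpha: float
    ci: tuple[float, float]
    n_boot: int
    correlation: float
    r_squared: float
    slope_by_degree: dict[int, float] = field(default_factory=dict)
    session_id: str | int | None = None
    performance: float | None = None

    @property
    def reliable_slope(self) -> bool:
        return self.r_squared > 0


def _principal_axis_slope(x: np.ndarray, y: np.ndarray, center: bool) -> float:
    if center:
        x = x - x.mean()
        y = y - y.mean()
    m = np.array([[x @ x, x @ y], [x @ y, y @ y]])
    evals, evecs = np.linalg.eigh(m)
    v = evecs[:, np.argmax(evals)]
    if v[0] < 0:
        v = -v
    if v[0] == 0:
        return np.inf
    return float(v[1] / v[0])


def efficiency_slope(
    predicted: np.ndarray,
    measured: np.ndarray,
    n_boot: int = 100,
    seed: int = 0,
    center: bool = True,
    degrees: np.ndarray | None = None,
) -> EfficiencyReport:
    """Efficiency slope alpha from the measured-vs-predicted CC scatter.

    The slope is the tangent of the first principal-component angle of
    the bivariate data (predicted on x, measured on y); the confidence
    interval is a percentile bootstrap over statistic terms (100
    resamples by default, seeded). ``center=False`` constrains the axis
    through the origin. ``degrees`` (per-term polynomial degree) adds a
    per-degree slope breakdown.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("predicted and measured must be 1-d of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 statistic terms")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite choice correlations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("degenerate scatter: all points identical")
    alpha = _principal_axis_slope(x, y, center)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, x.size, size=x.size)
        if np.ptp(x[idx]) == 0 and np.ptp(y[idx]) == 0:
            boots[b] = alpha
        else:
            boots[b] = _principal_axis_slope(x[idx], y[idx], center)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo, hi = min(lo, alpha), max(hi, alpha)  # CI always contains the estimate
    if np.ptp(x) > 0 and np.ptp(y) > 0:
        correlation = float(np.corrcoef(x, y)[0, 1])
    else:
        correlation = 0.0
    fit = y.mean() + alpha * (x - x.mean()) if center else alpha * x
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(((y - fit) ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
    by_degree: dict[int, float] = {}
    if degrees is not None:
        degrees = np.asarray(degrees)
        for d in np.unique(degrees):
            sel = degrees == d
            if sel.sum() >= 3 and (np.ptp(x[sel]) > 0 or np.ptp(y[sel]) > 0):
                by_degree[int(d)] = _principal_axis_slope(x[sel], y[sel], center)
    return EfficiencyReport(
        alpha=alpha,
        ci=(float(lo), float(hi)),
        n_boot=n_boot,
        correlation=correlation,
        r_squared=r2,
        slope_by_degree=by_degree,
    )


# ----------------------------------------------------------------------
# shuffle nulls and p-values
# ----------------------------------------------------------------------
def gaussian_tail_p(x: np.ndarray, sigma: np.ndarray, two_sided: bool = True):
    """Tail probability of |x| under a zero-mean Gaussian null.

    Default is the calibrated two-sided tail ``erfc(|x| / (sqrt(2) sigma))``
    (uniform under the null). ``two_sided=False`` gives the one-sided
    tail ``1 - erfc(-|x|/(sqrt(2) sigma))/2``, which equals 0.5 at x = 0.
    """
    x = np.abs(np.asarray(x, dtype=float))
    sigma = np.asarray(sigma, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sigma > 0, x / (np.sqrt(2.0) * sigma), np.inf)
    p = erfc(t)
    return p if two_sided else 0.5 * p


def shuffle_null_pvalues(
    features: FeatureSet,
    table: TrialTable,
    choices: np.ndarray,
    which: str = "choice",
    n_shuffles: int = 100,
    seed: int = 0,
    statistic=None,
    two_sided: bool = True,
) -> np.ndarray:
    """Per-term p-values against a shuffle null.

    ``which='choice'`` permutes the behavioral choices within each
    stimulus condition (null for the *measured* choice correlations);
    ``which='stimulus'`` permutes the stimulus labels across trials
    (null for the per-term stimulus information). Correlations between
    neural responses are untouched. A zero-mean Gaussian is fit to the
    null statistics and the Gaussian tail probability returned.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    if table.n_trials < 4:
        raise ValueError("too few trials to shuffle")
    if statistic is None:
        statistic = lambda f, t, c: naccc(f, c, t)  # noqa: E731
    choices = np.asarray(choices, dtype=float)
    observed = np.asarray(statistic(features, table, choices), dtype=float)
    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles, observed.shape[0]))
    for b in range(n_shuffles):
        if which == "choice":
            perm_c = choices.copy()
            for sv in np.unique(table.s):
                idx = np.flatnonzero(table.s == sv)
                perm_c[idx] = choices[idx[rng.permutation(idx.size)]]
            null[b] = statistic(features, table, perm_c)
        elif which == "stimulus":
            perm = rng.permutation(table.n_trials)
            t2 = TrialTable(
                s=table.s[perm], r=table.r, nu=table.nu, choice=table.choice
            )
            null[b] = statistic(features, t2, choices)
        else:
            raise ValueError("which must be 'choice' or 'stimulus'")
    sigma = np.sqrt(np.mean(null**2, axis=0))  # zero-mean Gaussian fit
    return gaussian_tail_p(observed, sigma, two_sided=two_sided)


# ----------------------------------------------------------------------
# permutation controls
# ----------------------------------------------------------------------
def _strata_keys(
    table: TrialTable, use_nuisance: bool, tolerance: float
) -> np.ndarray:
    """Integer stratum id per trial from (s, choice[, nuisance bin])."""
    if table.choice is None:
        raise ValueError("table has no recorded choices")
    cols = [table.s, table.choice]
    if use_nuisance:
        if table.nu is None:
            raise ValueError("table has no recorded nuisance values")
        if tolerance <= 0 or not np.isfinite(tolerance):
            pass  # infinite tolerance: no nuisance stratification
        else:
            # fixed bins of width 2 * tolerance
            cols.append(np.floor(table.nu / (2.0 * tolerance)))
    key = np.stack([np.asarray(c, dtype=float) for c in cols], axis=1)
    _, ids = np.unique(key, axis=0, return_inverse=True)
    return ids


def _shuffle_within_strata(
    table: TrialTable, ids: np.ndarray, seed: int
) -> TrialTable:
    rng = np.random.default_rng(seed)
    r = table.r.copy()
    singleton = 0
    for g in np.unique(ids):
        idx = np.flatnonzero(ids == g)
        if idx.size < 2:
            singleton += idx.size  # left unshuffled
            continue
        # each neuron permuted independently: kills cross-neuron noise
        # correlations, preserves every per-neuron conditional marginal
        for k in range(table.n_neurons):
            r[idx, k] = table.r[idx[rng.permutation(idx.size)], k]
    out = table.with_responses(r)
    out.meta = {**table.meta, "unshuffled_trials": singleton}
    return out


def shuffle_internal_noise(
    table: TrialTable, nuisance_tolerance: float = 1.5, seed: int = 0
) -> TrialTable:
    """Remove internal noise correlations, keep nuisance correlations.

    For each neuron independently, responses are permuted among trials
    matched on stimulus category, choice, and nuisance value (within
    bins of width ``2 * nuisance_tolerance``). Cross-neuron correlations
    at fixed nuisance are destroyed; correlations induced by shared
    nuisance variation survive because the matching keeps the nuisance
    (almost) fixed. Strata with a single trial are passed through and
    counted in ``meta['unshuffled_trials']``.
    """
    ids = _strata_keys(table, use_nuisance=True, tolerance=nuisance_tolerance)
    out = _shuffle_within_strata(table, ids, seed)
    if out.meta["unshuffled_trials"]:
        warnings.warn(
            f"{out.meta['unshuffled_trials']} trial(s) in singleton strata "
            "left unshuffled",
            stacklevel=2,
        )
    return out


def shuffle_nuisance(table: TrialTable, seed: int = 0) -> TrialTable:
    """Remove nuisance *and* internal noise correlations between neurons.

    Responses are permuted per neuron among trials matched only on
    stimulus category and choice — different trials mean different
    nuisance values, so cross-neuron correlations inherited from shared
    nuisance variation are destroyed, while each neuron's conditional
    marginal (and hence its own variance tuning) is preserved.
    """
    ids = _strata_keys(table, use_nuisance=False, tolerance=np.inf)
    return _shuffle_within_strata(table, ids, seed)


def session_filter(
    sessions: list[EfficiencyReport], min_performance: float
) -> list[EfficiencyReport]:
    """Drop sessions below the behavioral-performance threshold.

    Sessions at or above ``min_performance`` are kept; among those,
    sessions with non-positive coefficient of determination keep their
    data but are marked unreliable (``reliable_slope`` False) and should
    be excluded from slope aggregation.
    """
    kept = []
    for rep in sessions:
        if rep.performance is None:
            raise ValueError(f"session {rep.session_id} has no performance")
        if not 0.0 <= rep.performance <= 1.0:
            raise ValueError("performance must be in [0, 1]")
        if rep.performance >= min_performance:
            kept.append(rep)
    return kept
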