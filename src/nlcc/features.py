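"""Nonlinear response statistics R(r) and their signal/noise summaries.

The decoding theory works on a vector of statistics of the recorded
responses — here polynomial terms ``r_i``, ``r_i r_j``, ``r_i r_j r_k``
— together with their stimulus sensitivity (``F' = d<R|s>/ds`` for fine
tasks, ``dF = <R|s+> - <R|s->`` for coarse ones) and their
stimulus-conditioned covariance (``Gamma`` at a reference stimulus, or
the category-averaged ``Gamma_bar``).

``residualize`` removes the conditional mean given the *linear* stimulus
estimate from each response, so that quadratic statistics built from the
residuals carry only information beyond the linear code.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trials import TrialTable

__all__ = [
    "FeatureSet",
    "SignalNoiseSummary",
    "polynomial_features",
    "residualize",
    "signal_noise_summary",
    "inject_information_limit_features",
]


def term_name(term: tuple[int, ...]) -> str:
    """Column name for a polynomial term: r_i, q_i_j, c_i_j_k."""
    prefix = {1: "r", 2: "q", 3: "c"}[len(term)]
    return prefix + "_" + "_".join(str(i) for i in term)


@dataclass
class FeatureSet:
    """Per-trial matrix of named nonlinear statistics.

    ``terms[k]`` is a tuple of neuron indices; its length is the
    polynomial degree of column ``k`` of ``values``.
    """

    terms: list[tuple[int, ...]]
    values: np.ndarray  # (n_trials, n_terms)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.terms):
            raise ValueError("values must be (n_trials, n_terms)")
        seen = set()
        for t in self.terms:
            key = (len(t), tuple(sorted(t)))
            if key in seen:
                raise ValueError(f"duplicate term {t}")
            seen.add(key)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(t) for t in self.terms])

    @property
    def names(self) -> list[str]:
        return [term_name(t) for t in self.terms]

    def concat(self, other: "FeatureSet") -> "FeatureSet":
        return FeatureSet(
            terms=self.terms + other.terms,
            values=np.hstack([self.values, other.values]),
            meta={**self.meta, **other.meta},
        )

    def select(self, mask: np.ndarray) -> "FeatureSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return FeatureSet(
            terms=[self.terms[i] for i in idx],
            values=self.values[:, idx],
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)


def polynomial_features(
    table: TrialTable,
    max_degree: int = 2,
    include_cross_terms: bool = True,
    responses: np.ndarray | None = None,
) -> FeatureSet:
    """Polynomial statistics of the responses up to ``max_degree``.

    Degree 1 is the raw responses; degree 2 adds squares ``r_i**2`` and
    (with cross terms) products ``r_i r_j`` for ``i < j``; degree 3 adds
    the distinct triple products. ``responses`` overrides ``table.r``
    (e.g. to build quadratic terms from residualized responses).
    """
    if max_degree not in (1, 2, 3):
        raise ValueError("max_degree must be 1, 2, or 3")
    r = table.r if responses is None else np.asarray(responses, dtype=float)
    n = r.shape[1]
    terms: list[tuple[int, ...]] = [(i,) for i in range(n)]
    cols = [r]
    if max_degree >= 2:
        pairs = [(i, i) for i in range(n)]
        if include_cross_terms:
            pairs += list(itertools.combinations(range(n), 2))
        terms += pairs
        cols.append(np.column_stack([r[:, i] * r[:, j] for i, j in pairs]))
    if max_degree >= 3:
        triples = [(i, i, i) for i in range(n)]
        if include_cross_terms:
            triples = list(
                itertools.combinations_with_replacement(range(n), 3)
            )
        terms += triples
        cols.append(
            np.column_stack([r[:, i] * r[:, j] * r[:, k] for i, j, k in triples])
        )
    return FeatureSet(terms=terms, values=np.hstack(cols))


def residualize(
    table: TrialTable,
    linear_estimate: np.ndarray,
    method: str = "pooled",
    n_bins: int = 10,
) -> TrialTable:
    """Remove the conditional mean given the linear estimate ``s1_hat``.

    Returns a table whose responses are ``dr_i = r_i - <r_i | s1_hat>``,
    the fluctuation of each neuron around its expectation given the
    optimal *linear* stimulus estimate. Quadratic statistics of ``dr``
    then isolate information beyond the linear code.

    The conditional mean model is linear regression of ``r_i`` on
    ``s1_hat`` pooled over all trials (default; the conditioning is on
    the estimate alone, which a downstream decoder could also compute),
    the same regression fit separately per stimulus condition
    (``'per-category'``), or binned means (``'binned'``).
    """
    s1 = np.asarray(linear_estimate, dtype=float)
    if s1.shape[0] != table.n_trials:
        raise ValueError("linear_estimate length does not match trial count")

    def _regress_out(idx: np.ndarray) -> None:
        x = s1[idx]
        xc = x - x.mean()
        denom = np.dot(xc, xc)
        y = table.r[idx]
        if denom > 0:
            slopes = (xc @ (y - y.mean(axis=0))) / denom
        else:
            slopes = np.zeros(table.n_neurons)
        delta[idx] = y - y.mean(axis=0) - np.outer(xc, slopes)

    delta = np.empty_like(table.r)
    if method == "pooled":
        _regress_out(np.arange(table.n_trials))
    elif method == "per-category":
        for sv in np.unique(table.s):
            _regress_out(np.flatnonzero(table.s == sv))
    elif method == "binned":
        edges = np.quantile(s1, np.linspace(0, 1, n_bins + 1))
        which = np.clip(np.searchsorted(edges, s1, side="right") - 1, 0, n_bins - 1)
        for b in np.unique(which):
            sel = np.flatnonzero(which == b)
            delta[sel] = table.r[sel] - table.r[sel].mean(axis=0)
    else:
        raise ValueError("method must be 'pooled', 'per-category', or 'binned'")
    out = table.with_responses(delta)
    out.meta = {**table.meta, "residualized": method}
    return out


@dataclass
class SignalNoiseSummary:
    """Signal slope, noise covariance, and per-term discriminability.

    ``mode='fine'``: ``F_prime`` is dF/ds by central difference (or an
    analytic derivative) and ``Gamma`` the covariance at the reference
    stimulus. ``mode='coarse'``: ``F_prime`` holds the category mean
    difference dF and ``Gamma`` the unweighted average of the two
    conditional covariances (Gamma_bar). ``d_prime_terms`` is the signed
    per-term discriminability; degenerate (zero-variance) terms get
    ``d' = 0`` and are flagged.
    """

    terms: list[tuple[int, ...]]
    F_prime: np.ndarray
    Gamma: np.ndarray
    d_prime_terms: np.ndarray
    mode: str
    ds: float
    degenerate: np.ndarray
    conditions: np.ndarray | None = None
    F_ref: np.ndarray | None = None  # mean feature vector at the reference
    s_ref: float = 0.0  # reference stimulus (fine) or category midpoint

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(t) for t in self.terms])


def signal_noise_summary(
    features: FeatureSet,
    table: TrialTable,
    mode: str = "fine",
    ds: float | None = None,
) -> SignalNoiseSummary:
    """Estimate F' (or dF), Gamma (or Gamma_bar), and per-term d'."""
    svals = np.unique(table.s)
    R = features.values
    if mode == "fine":
        if svals.size < 2:
            raise ValueError("fine mode needs at least two stimulus values")
        # central difference over the two nearest stimulus values
        order = np.argsort(svals)
        svals = svals[order]
        mid = svals.size // 2
        lo, hi = svals[mid - 1], svals[mid]
        step = hi - lo
        m_lo = R[table.s == lo].mean(axis=0)
        m_hi = R[table.s == hi].mean(axis=0)
        F = (m_hi - m_lo) / step
        covs = [np.cov(R[table.s == sv], rowvar=False) for sv in svals]
        Gamma = np.mean(covs, axis=0)
        F_ref = 0.5 * (m_lo + m_hi)
        s_ref = 0.5 * (lo + hi)
        if ds is None:
            ds = step
    elif mode == "coarse":
        if svals.size != 2:
            raise ValueError("coarse mode needs exactly two category labels")
        lo, hi = svals
        m_lo = R[table.s == lo].mean(axis=0)
        m_hi = R[table.s == hi].mean(axis=0)
        F = m_hi - m_lo
        covs = [np.cov(R[table.s == sv], rowvar=False) for sv in svals]
        Gamma = 0.5 * (covs[0] + covs[1])  # unweighted category average
        F_ref = 0.5 * (m_lo + m_hi)
        s_ref = 0.5 * (lo + hi)
        ds = float(hi - lo)
    else:
        raise ValueError("mode must be 'fine' or 'coarse'")
    Gamma = np.atleast_2d(Gamma)
    var = np.diagonal(Gamma).copy()
    degenerate = var <= 1e-12 * max(var.max(), 1.0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} degenerate (zero-variance) feature(s); "
            "their d' is set to 0",
            stacklevel=2,
        )
    # fine: d' = F' * ds / sqrt(Gamma_kk) for a stimulus step ds;
    # coarse: F already holds the category difference dF, so d' = dF / sqrt
    dscale = ds if mode == "fine" else 1.0
    dprime = np.zeros_like(F)
    ok = ~degenerate
    dprime[ok] = F[ok] * dscale / np.sqrt(var[ok])
    return SignalNoiseSummary(
        terms=list(features.terms),
        F_prime=F,
        Gamma=Gamma,
        d_prime_terms=dprime,
        mode=mode,
        ds=float(ds),
        degenerate=degenerate,
        conditions=svals,
        F_ref=F_ref,
        s_ref=float(s_ref),
    )


def inject_information_limit_features(
    features: FeatureSet,
    F_prime: np.ndarray,
    epsilon: float,
    seed: int = 0,
) -> FeatureSet:
    """Feature-space information limit: shift each trial along ``F'``.

    Linearized shortcut to re-rendering at ``s + ds``: adds
    ``ds * F'`` to every trial's feature vector with
    ``ds ~ N(0, epsilon)``, producing the rank-one covariance component
    ``epsilon * F' F'^T`` that caps the Fisher information at
    ``1/epsilon``. Approximate — exact only to first order in ``ds``.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    rng = np.random.default_rng(seed)
    ds = rng.normal(scale=np.sqrt(epsilon), size=features.values.shape[0])
    values = features.values + np.outer(ds, np.asarray(F_prime, dtype=float))
    return FeatureSet(
        terms=list(features.terms),
        values=values,
        meta={**features.meta, "info_limit_eps": epsilon},
    )
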