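"""Decoders: from response statistics (or raw responses) to estimates.

The locally optimal linear readout of a statistic vector R has weights
``w proportional to Gamma^{-1} F'`` (fine estimation) or
``Gamma_bar^{-1} dF`` (coarse discrimination); its estimator variance is
``(F'^T Gamma^{-1} F')^{-1}``, the inverse Fisher information of the
statistics. Controlled suboptimal decoders — weights aligned with the
signal but blind to correlations, or with a fraction of signs flipped —
provide reference points for the choice-correlation optimality test.

A generic trained-network decoder (fully connected ReLU regression
network) stands in for an unknown downstream nonlinearity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.neural_network import MLPRegressor

from .features import FeatureSet, SignalNoiseSummary
from .trials import TrialTable

__all__ = [
    "Decoder",
    "fit_optimal_decoder",
    "make_suboptimal_decoder",
    "decode",
    "binary_threshold_choice",
    "fit_network_decoder",
    "estimator_information",
    "information_fraction",
]


@dataclass
class Decoder:
    """Linear readout ``s_hat = w . R + c`` or a trained network.

    For linear kinds ``terms`` records the feature identities the
    weights refer to; ``sigma2_opt`` stores the closed-form optimal
    estimator variance when known. ``threshold`` (optional) turns the
    continuous estimate into a binary choice.
    """

    weights: np.ndarray | None = None
    offset: float = 0.0
    kind: str = "optimal"
    terms: list[tuple[int, ...]] | None = None
    threshold: float | None = None
    sigma2_opt: float | None = None
    model: object | None = None  # trained network for kind='network'
    meta: dict = field(default_factory=dict)

    def save(self, path) -> None:
        """Serialize a linear decoder to a JSON config+weights file."""
        import json

        if self.kind == "network":
            raise ValueError("network decoders are not JSON-serializable")
        payload = {
            "kind": self.kind,
            "weights": np.asarray(self.weights).tolist(),
            "offset": self.offset,
            "terms": [list(t) for t in (self.terms or [])],
            "threshold": self.threshold,
            "sigma2_opt": self.sigma2_opt,
            "meta": {k: v for k, v in self.meta.items() if _jsonable(v)},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "Decoder":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            weights=np.asarray(payload["weights"], dtype=float),
            offset=float(payload["offset"]),
            kind=payload["kind"],
            terms=[tuple(t) for t in payload["terms"]] or None,
            threshold=payload["threshold"],
            sigma2_opt=payload["sigma2_opt"],
            meta=payload.get("meta", {}),
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.kind == "network":
            return np.asarray(self.model.predict(X), dtype=float)
        if self.weights is None:
            raise ValueError("decoder has no weights")
        if X.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"input has {X.shape[1]} columns, decoder expects "
                f"{self.weights.shape[0]}"
            )
        return X @ self.weights + self.offset


def _jsonable(v) -> bool:
    return isinstance(v, (str, int, float, bool, type(None), list, tuple))


def _ridge_inverse_solve(
    Gamma: np.ndarray, b: np.ndarray, ridge: float | None
) -> np.ndarray:
    Gamma = np.atleast_2d(np.asarray(Gamma, dtype=float))
    dim = Gamma.shape[0]
    if ridge is None:
        ridge = 1e-6 * np.trace(Gamma) / dim
    try:
        return np.linalg.solve(Gamma + ridge * np.eye(dim), b)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular covariance; increase ridge") from err


def fit_optimal_decoder(
    summary: SignalNoiseSummary, ridge: float | None = None
) -> Decoder:
    """Minimum-variance unbiased linear readout of the statistics.

    Fine mode: ``w = Gamma^{-1} F' / (F'^T Gamma^{-1} F')`` so that
    ``<s_hat|s> = s`` to first order around the reference; the resulting
    estimator variance is the inverse Fisher information. Coarse mode:
    ``w`` along ``Gamma_bar^{-1} dF`` scaled so the category means of
    ``s_hat`` sit at the category labels, with the decision threshold
    midway between them.
    """
    F = summary.F_prime
    w0 = _ridge_inverse_solve(summary.Gamma, F, ridge)
    gain = float(F @ w0)
    if gain <= 0:
        raise ValueError("signal has no decodable component")
    w = w0 / gain * summary.ds if summary.mode == "coarse" else w0 / gain
    # unbiased at the reference: <w.R + c | s_ref> = s_ref
    c = summary.s_ref - float(w @ summary.F_ref)
    threshold = summary.s_ref if summary.mode == "coarse" else None
    sigma2 = 1.0 / gain if summary.mode == "fine" else summary.ds**2 / gain
    return Decoder(
        weights=w,
        offset=c,
        kind="optimal",
        terms=list(summary.terms),
        threshold=threshold,
        sigma2_opt=sigma2,
        meta={"mode": summary.mode, "ridge": ridge},
    )


def make_suboptimal_decoder(
    summary: SignalNoiseSummary,
    kind: str = "signal-aligned",
    flip_fraction: float = 0.0,
    seed: int = 0,
) -> Decoder:
    """Controlled suboptimal readouts.

    ``signal-aligned``: weights proportional to the signal ``F'`` but
    blind to the noise covariance. ``sign-flipped``: the same weights
    with ``flip_fraction`` of the entries negated at random — a decoder
    that actively reads some statistics the wrong way.
    """
    if kind not in ("signal-aligned", "sign-flipped"):
        raise ValueError(f"unknown kind {kind!r}")
    if not 0.0 <= flip_fraction <= 1.0:
        raise ValueError("flip_fraction must be in [0, 1]")
    w = summary.F_prime.copy()
    if kind == "sign-flipped" and flip_fraction > 0:
        rng = np.random.default_rng(seed)
        n_flip = int(round(flip_fraction * w.shape[0]))
        idx = rng.choice(w.shape[0], size=n_flip, replace=False)
        w[idx] = -w[idx]
    gain = float(summary.F_prime @ w)
    if gain != 0:
        w = w / gain * (summary.ds if summary.mode == "coarse" else 1.0)
    c = summary.s_ref - float(w @ summary.F_ref)
    threshold = summary.s_ref if summary.mode == "coarse" else None
    return Decoder(
        weights=w,
        offset=c,
        kind=kind,
        terms=list(summary.terms),
        threshold=threshold,
        meta={"mode": summary.mode, "flip_fraction": flip_fraction, "seed": seed},
    )


def decode(decoder: Decoder, features: FeatureSet | np.ndarray) -> np.ndarray:
    """Apply a decoder to a feature set (or raw responses for networks)."""
    if isinstance(features, FeatureSet):
        if decoder.terms is not None and list(features.terms) != list(decoder.terms):
            raise ValueError("feature terms do not match decoder terms")
        X = features.values
    else:
        X = np.asarray(features, dtype=float)
    return decoder.predict(X)


def binary_threshold_choice(estimates: np.ndarray, threshold: float) -> np.ndarray:
    """Binary category from a continuous magnitude estimate.

    Returns +1 ("wide"/large-variance category) where
    ``estimate**2 > threshold**2`` and -1 otherwise; exact ties go to the
    narrow category (-1).
    """
    estimates = np.asarray(estimates, dtype=float)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.where(estimates**2 > threshold**2, 1.0, -1.0)


def fit_coarse_decoder_shrunk(features: FeatureSet, table: TrialTable) -> Decoder:
    """Coarse decoder ``w ~ Gamma_bar^{-1} dF`` with shrinkage covariance.

    For session-scale data with many polynomial terms the sample
    category covariance is noisy and heavy-tailed; features are
    standardized and the per-category covariances estimated with
    Ledoit-Wolf shrinkage before averaging and inverting. The readout is
    calibrated so the category means of ``s_hat`` sit at the category
    labels, with the threshold midway between them.
    """
    from sklearn.covariance import LedoitWolf

    svals = np.unique(table.s)
    if svals.size != 2:
        raise ValueError("coarse decoder needs exactly two categories")
    R = features.values
    mu, sd = R.mean(axis=0), R.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Rz = (R - mu) / sd
    lo, hi = svals
    dFz = Rz[table.s == hi].mean(axis=0) - Rz[table.s == lo].mean(axis=0)
    G = 0.5 * (
        LedoitWolf().fit(Rz[table.s == lo]).covariance_
        + LedoitWolf().fit(Rz[table.s == hi]).covariance_
    )
    wz = np.linalg.solve(G, dFz)
    w = wz / sd
    dF = R[table.s == hi].mean(axis=0) - R[table.s == lo].mean(axis=0)
    gain = float(w @ dF)
    if gain <= 0:
        raise ValueError("signal has no decodable component")
    w = w * (hi - lo) / gain
    m_mid = 0.5 * (R[table.s == hi].mean(axis=0) + R[table.s == lo].mean(axis=0))
    c = 0.5 * (hi + lo) - float(w @ m_mid)
    return Decoder(
        weights=w,
        offset=c,
        kind="optimal",
        terms=list(features.terms),
        threshold=0.5 * (hi + lo),
        meta={"mode": "coarse", "estimator": "ledoit-wolf"},
    )


# ----------------------------------------------------------------------
# generic network decoder
# ----------------------------------------------------------------------
def fit_network_decoder(
    table: TrialTable,
    hidden_layers: Sequence[int] = (30, 30),
    n_train: int | None = 20000,
    seed: int = 0,
    max_iter: int = 400,
    learning_rate_init: float = 1e-3,
    batch_size: int = 200,
    tol: float = 1e-6,
) -> Decoder:
    """Train a fully connected ReLU regression network on (r, s) pairs.

    The network is trained by backpropagation (Adam) to minimize squared
    error of the stimulus estimate. Training that fails to reduce the
    loss over its patience window is reported with a warning rather than
    silently accepted.
    """
    if any(h < 1 for h in hidden_layers):
        raise ValueError("hidden layer sizes must be >= 1")
    if n_train is None:
        n_train = table.n_trials
    if n_train > table.n_trials:
        raise ValueError("n_train exceeds available trials")
    X, y = table.r[:n_train], table.s[:n_train]
    net = MLPRegressor(
        hidden_layer_sizes=tuple(hidden_layers),
        activation="relu",
        solver="adam",
        learning_rate_init=learning_rate_init,
        batch_size=min(batch_size, n_train),
        max_iter=max_iter,
        tol=tol,
        n_iter_no_change=20,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings handled below
        net.fit(X, y)
    losses = np.asarray(net.loss_curve_)
    if losses.size >= 20 and losses[-1] >= losses[max(0, losses.size - 20)]:
        warnings.warn(
            "network training loss did not decrease over the last 20 epochs",
            stacklevel=2,
        )
    return Decoder(
        kind="network",
        model=net,
        meta={
            "hidden_layers": tuple(hidden_layers),
            "n_train": n_train,
            "seed": seed,
            "final_loss": float(losses[-1]),
            "n_epochs": int(losses.size),
            "optimizer": "adam",
            "learning_rate_init": learning_rate_init,
        },
    )


def estimator_information(
    estimates: np.ndarray, s: np.ndarray, degree: int = 1, s_ref: float | None = None
) -> float:
    """Fisher-style information of an estimator: gain^2 / residual variance.

    Fits a polynomial calibration of the estimate against the true
    stimulus and returns ``slope(s_ref)**2 / Var(residual)`` — invariant
    to monotone recalibration of the estimator, and equal to
    ``1/sigma_hat^2`` for an unbiased one. ``degree=1`` (default) is the
    plain regression form; a higher degree measures the *local*
    information at ``s_ref`` (default: the mean stimulus) without
    counting calibration curvature over the stimulus range as noise.
    """
    s = np.asarray(s, dtype=float)
    estimates = np.asarray(estimates, dtype=float)
    if np.ptp(s) == 0:
        raise ValueError("stimulus has no variation")
    if s_ref is None:
        s_ref = float(s.mean())
    coefs = np.polyfit(s, estimates, degree)
    slope = float(np.polyder(np.poly1d(coefs))(s_ref))
    resid = estimates - np.polyval(coefs, s)
    var = float(resid @ resid) / max(resid.size - degree - 1, 1)
    if var == 0:
        return np.inf
    return slope**2 / var


def information_fraction(
    decoder: Decoder, heldout: TrialTable, sigma2_opt: float
) -> float:
    """Fraction of the optimal information a decoder extracts.

    Ratio of the decoder's effective inverse variance (measured on
    held-out trials, with affine calibration absorbed) to the optimal
    decoder's inverse variance ``1/sigma2_opt``.
    """
    est = decoder.predict(heldout.r)
    J = estimator_information(est, heldout.s)
    return float(J * sigma2_opt)
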