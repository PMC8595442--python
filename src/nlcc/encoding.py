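"""Simulators of nonlinear population codes.

Each generator produces a :class:`~nlcc.trials.TrialTable` in which the
task-relevant information lives partly or wholly in *nonlinear* response
statistics: stimulus-dependent correlations (XOR, quadratic codes),
nuisance-induced covariance tuning (Gabor populations with unknown phase
or polarity), or third-order statistics (cubic codes built from a
four-Gaussian mixture with tetrahedral symmetry).

Information-limiting noise — correlated fluctuations equivalent to a
perturbation of the stimulus itself, with variance ``epsilon = 1/J_inf``
— can be injected by re-rendering each trial at ``s + ds`` (exact) or by
shifting decoded statistics along their signal direction (linearized).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import sqrtm

from .trials import TrialTable

__all__ = [
    "GaborPopulationSpec",
    "QuadraticCodeSpec",
    "CubicCodeSpec",
    "InfoLimitSpec",
    "GaborEncoder",
    "QuadraticEncoder",
    "CubicEncoder",
    "simulate_xor",
    "simulate_gabor_population",
    "simulate_quadratic_code",
    "simulate_cubic_code",
    "inject_information_limit",
    "tetrahedral_mixture_means",
]

# regular tetrahedron vertices (rows), |v|^2 = 3, sum of outer products = 4 I,
# product of coordinates = +1 at every vertex
_TETRA = np.array(
    [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
)


# ----------------------------------------------------------------------
# XOR code
# ----------------------------------------------------------------------
def simulate_xor(n_trials: int, flip_prob: float = 0.0, seed: int = 0) -> TrialTable:
    """Two binary neurons whose *correlation* carries the stimulus.

    The stimulus is the exclusive-or of the two responses: when the
    responses agree ``s = -1``, when they are opposite ``s = +1``, so a
    noiseless quadratic readout recovers it as ``s_hat = -r1*r2``.
    ``flip_prob`` independently corrupts each response after the fact.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not 0.0 <= flip_prob < 0.5:
        raise ValueError("flip_prob must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    r = rng.choice([-1.0, 1.0], size=(n_trials, 2))
    s = -r[:, 0] * r[:, 1]  # equal responses -> s = -1, opposite -> s = +1
    flips = rng.random(size=r.shape) < flip_prob
    r = np.where(flips, -r, r)
    return TrialTable(s=s, r=r, meta={"model": "xor", "flip_prob": flip_prob, "seed": seed})


# ----------------------------------------------------------------------
# Gabor population with phase / polarity nuisance
# ----------------------------------------------------------------------
@dataclass
class GaborPopulationSpec:
    """Population of linear Gabor filters (idealized simple cells).

    Responses are ``r ~ N(f(s, nu), noise_var * I)`` where the mean is
    the overlap of each unit-energy receptive field with a rendered
    Gabor image of orientation ``s`` and nuisance ``nu`` (spatial phase
    on [0, 2pi) or polarity in {-1, +1}).
    """

    n_neurons: int = 8
    image_size: int = 32
    spatial_freq: float = 0.15  # cycles per pixel
    envelope_sigma: float = 6.0  # pixels
    noise_var: float = 0.05
    preferred_orientation: np.ndarray | None = None  # radians in [0, pi)
    preferred_phase: np.ndarray | None = None  # radians in [0, 2pi)
    image_contrast: float = 1.0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.noise_var <= 0:
            raise ValueError("noise_var must be positive")
        if self.preferred_orientation is None:
            self.preferred_orientation = (
                np.arange(self.n_neurons) * np.pi / self.n_neurons
            )
        if self.preferred_phase is None:
            # quadrature pairs: alternate 0 and pi/2 phases
            self.preferred_phase = (np.arange(self.n_neurons) % 2) * (np.pi / 2)


def _gabor_image(
    size: int, sf: float, sigma: float, orientation: float, phase: float
) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    x, y = np.meshgrid(ax, ax)
    u = x * np.cos(orientation) + y * np.sin(orientation)
    env = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    return env * np.cos(2.0 * np.pi * sf * u - phase)


class GaborEncoder:
    """Renders Gabor images and projects them on the receptive fields."""

    def __init__(self, spec: GaborPopulationSpec, nuisance: str = "phase"):
        if nuisance not in ("phase", "polarity"):
            raise ValueError("nuisance must be 'phase' or 'polarity'")
        self.spec = spec
        self.nuisance = nuisance
        rfs = []
        for k in range(spec.n_neurons):
            rf = _gabor_image(
                spec.image_size,
                spec.spatial_freq,
                spec.envelope_sigma,
                float(spec.preferred_orientation[k]),
                float(spec.preferred_phase[k]),
            ).ravel()
            rfs.append(rf / np.linalg.norm(rf))  # unit energy
        self._rf = np.array(rfs)  # (N, pixels)

    def draw_nuisance(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.nuisance == "phase":
            return rng.uniform(0.0, 2.0 * np.pi, size=n)
        return rng.choice([-1.0, 1.0], size=n)

    def mean(self, s: float, nu: float) -> np.ndarray:
        """Noise-free response f(s, nu) of every neuron."""
        sp = self.spec
        if self.nuisance == "phase":
            img = _gabor_image(sp.image_size, sp.spatial_freq, sp.envelope_sigma, s, nu)
        else:
            img = nu * _gabor_image(sp.image_size, sp.spatial_freq, sp.envelope_sigma, s, 0.0)
        return sp.image_contrast * (self._rf @ img.ravel())

    def sample(
        self, s: np.ndarray, rng: np.random.Generator, nu: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        s = np.asarray(s, dtype=float)
        if nu is None:
            nu = self.draw_nuisance(s.shape[0], rng)
        means = np.array([self.mean(si, ni) for si, ni in zip(s, nu)])
        r = means + rng.normal(
            scale=np.sqrt(self.spec.noise_var), size=means.shape
        )
        return r, nu


def simulate_gabor_population(
    spec: GaborPopulationSpec,
    s_values,
    nuisance: str = "phase",
    n_trials: int = 1000,
    seed: int = 0,
) -> TrialTable:
    """Simulate orientation trials with an unknown phase or polarity.

    Each trial draws an orientation uniformly from ``s_values`` and a
    fresh nuisance value, renders the Gabor image, projects it onto the
    receptive fields, and adds white Gaussian noise. Averaged over the
    nuisance, the mean tuning cancels and orientation information moves
    into the response covariance.
    """
    s_values = np.atleast_1d(np.asarray(s_values, dtype=float))
    if s_values.size == 0:
        raise ValueError("s_values must be non-empty")
    enc = GaborEncoder(spec, nuisance)
    rng = np.random.default_rng(seed)
    s = rng.choice(s_values, size=n_trials)
    r, nu = enc.sample(s, rng)
    return TrialTable(
        s=s, r=r, nu=nu, meta={"model": f"gabor-{nuisance}", "seed": seed}
    )


# ----------------------------------------------------------------------
# Quadratic code: constant mean, stimulus-dependent covariance
# ----------------------------------------------------------------------
@dataclass
class QuadraticCodeSpec:
    """Gaussian responses with flat mean and smoothly tuned covariance."""

    n_neurons: int
    cov_fn: Callable[[float], np.ndarray]
    mean: np.ndarray | None = None
    s_ref: float = 0.0

    def __post_init__(self) -> None:
        if self.mean is None:
            self.mean = np.zeros(self.n_neurons)
        self.mean = np.asarray(self.mean, dtype=float)


def _checked_sqrt_cov(cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance is not positive-definite") from err


class QuadraticEncoder:
    def __init__(self, spec: QuadraticCodeSpec):
        self.spec = spec
        self._chol_cache: dict[float, np.ndarray] = {}

    def _chol(self, s: float) -> np.ndarray:
        key = float(s)
        if key not in self._chol_cache:
            self._chol_cache[key] = _checked_sqrt_cov(self.spec.cov_fn(key))
        return self._chol_cache[key]

    def sample(
        self, s: np.ndarray, rng: np.random.Generator, nu=None
    ) -> tuple[np.ndarray, None]:
        s = np.asarray(s, dtype=float)
        n = s.shape[0]
        r = np.empty((n, self.spec.n_neurons))
        z = rng.standard_normal((n, self.spec.n_neurons))
        for si in np.unique(s):
            idx = s == si
            r[idx] = self.spec.mean + z[idx] @ self._chol(si).T
        return r, None


def simulate_quadratic_code(
    spec: QuadraticCodeSpec, s_values, n_trials: int = 1000, seed: int = 0
) -> TrialTable:
    """Sample ``r ~ N(mean, Sigma(s))`` with the mean flat in ``s``."""
    s_values = np.atleast_1d(np.asarray(s_values, dtype=float))
    if s_values.size == 0:
        raise ValueError("s_values must be non-empty")
    rng = np.random.default_rng(seed)
    s = rng.choice(s_values, size=n_trials)
    enc = QuadraticEncoder(spec)
    r, _ = enc.sample(s, rng)
    return TrialTable(s=s, r=r, meta={"model": "quadratic", "seed": seed})


def rotating_covariance(
    s: float, base: float = 1.0, aniso: float = 0.6, rate: float = 1.0
) -> np.ndarray:
    """Two-neuron covariance whose principal axis rotates with ``s``.

    A convenient smooth ``cov_fn`` for :class:`QuadraticCodeSpec`:
    eigenvalues ``base*(1 +/- aniso)`` with the major axis at angle
    ``rate * s``.
    """
    c, sn = np.cos(rate * s), np.sin(rate * s)
    rot = np.array([[c, -sn], [sn, c]])
    return rot @ np.diag([base * (1 + aniso), base * (1 - aniso)]) @ rot.T


# ----------------------------------------------------------------------
# Cubic code: four-Gaussian tetrahedral mixture + affine transform
# ----------------------------------------------------------------------
def tetrahedral_mixture_means(gamma_s: float, scale: float) -> np.ndarray:
    """Component means of the four-Gaussian cubic mixture.

    The four unit-covariance components sit at the vertices of a regular
    tetrahedron of circumradius ``scale``. Rotating the tetrahedron by
    ``psi`` about the z-axis carries it from the orientation where every
    vertex has positive coordinate product to its mirror image, and the
    mean triple product varies as ``cos(2 psi)``. Choosing
    ``cos(2 psi) = tanh(gamma_s)`` makes the third moment

        <z1 z2 z3> = (scale/sqrt(3))**3 * tanh(gamma_s)

    a smooth, sign-correct, monotone function of ``gamma * s``, while the
    mixture mean stays exactly zero and the covariance stays exactly
    isotropic (``(1 + scale**2/3) I``) for every stimulus.
    """
    psi = 0.5 * np.arccos(np.clip(np.tanh(gamma_s), -1.0, 1.0))
    c, sn = np.cos(psi), np.sin(psi)
    rot = np.array([[c, -sn, 0.0], [sn, c, 0.0], [0.0, 0.0, 1.0]])
    return (scale / np.sqrt(3.0)) * (_TETRA @ rot.T)


@dataclass
class CubicCodeSpec:
    """Cubic exponential-family code approximated by a Gaussian mixture.

    Each disjoint triplet of variables carries a third-order statistic
    ``<z_i z_j z_k>`` monotone in ``gamma * s`` at the pure-cubic stage;
    an affine transform ``r = mean_fn(s) + sqrt(cov_fn(s)) z`` then adds
    linear and quadratic information.
    """

    n_triplets: int = 1
    gamma: float = 1.5
    scale: float = 1.5  # tetrahedron circumradius of the mixture
    mean_fn: Callable[[float], np.ndarray] | None = None
    cov_fn: Callable[[float], np.ndarray] | None = None
    lin_slope: float = 0.4  # default mean_fn slope per coordinate
    quad_slope: float = 0.25  # default relative SD slope

    def __post_init__(self) -> None:
        if self.n_triplets < 1:
            raise ValueError("n_triplets must be >= 1")
        n = 3 * self.n_triplets
        if self.mean_fn is None:
            slope = self.lin_slope
            self.mean_fn = lambda s: slope * s * np.ones(n)
        if self.cov_fn is None:
            q = self.quad_slope
            self.cov_fn = lambda s: (1.0 + q * s) ** 2 * np.eye(n)

    @property
    def n_neurons(self) -> int:
        return 3 * self.n_triplets


class CubicEncoder:
    def __init__(self, spec: CubicCodeSpec):
        self.spec = spec
        self._sqrt_cache: dict[float, np.ndarray] = {}

    def sample_pure(
        self, s: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """Sample the pure-cubic variables z (before the affine map)."""
        sp = self.spec
        n = s.shape[0]
        z = np.empty((n, sp.n_neurons))
        comp = rng.integers(0, 4, size=(n, sp.n_triplets))
        noise = rng.standard_normal((n, sp.n_neurons))
        for si in np.unique(s):
            idx = np.flatnonzero(s == si)
            means = tetrahedral_mixture_means(sp.gamma * si, sp.scale)
            for t in range(sp.n_triplets):
                cols = slice(3 * t, 3 * t + 3)
                z[idx, cols] = means[comp[idx, t]] + noise[idx, cols]
        return z

    def _sqrt_cov(self, s: float) -> np.ndarray:
        key = float(s)
        if key not in self._sqrt_cache:
            cov = np.asarray(self.spec.cov_fn(key), dtype=float)
            if np.allclose(cov, np.diag(np.diagonal(cov))):
                d = np.diagonal(cov)
                if np.any(d <= 0):
                    raise ValueError("covariance is not positive-definite")
                root = np.diag(np.sqrt(d))
            else:
                _checked_sqrt_cov(cov)  # PD check
                root = np.real(sqrtm(cov))
            self._sqrt_cache[key] = root
        return self._sqrt_cache[key]

    def sample(
        self, s: np.ndarray, rng: np.random.Generator, nu=None
    ) -> tuple[np.ndarray, None]:
        s = np.asarray(s, dtype=float)
        z = self.sample_pure(s, rng)
        r = np.empty_like(z)
        for si in np.unique(s):
            idx = s == si
            r[idx] = self.spec.mean_fn(si) + z[idx] @ self._sqrt_cov(si).T
        return r, None


def simulate_cubic_code(
    spec: CubicCodeSpec, s_values, n_trials: int = 1000, seed: int = 0
) -> TrialTable:
    """Sample the cubic code at the listed stimulus values."""
    s_values = np.atleast_1d(np.asarray(s_values, dtype=float))
    if s_values.size == 0:
        raise ValueError("s_values must be non-empty")
    rng = np.random.default_rng(seed)
    s = rng.choice(s_values, size=n_trials)
    enc = CubicEncoder(spec)
    r, _ = enc.sample(s, rng)
    return TrialTable(s=s, r=r, meta={"model": "cubic", "seed": seed})


# ----------------------------------------------------------------------
# Information-limiting correlations
# ----------------------------------------------------------------------
@dataclass
class InfoLimitSpec:
    """Information-limiting noise of variance ``epsilon = 1/J_inf``.

    ``mode='input'`` re-renders every trial at ``s + ds`` with
    ``ds ~ N(0, epsilon)`` — the defining construction. ``mode='feature'``
    is a linearized shortcut that shifts feature vectors along their
    signal direction ``F'`` (see
    :func:`inject_information_limit_features`).
    """

    epsilon: float
    mode: str = "input"

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        if self.mode not in ("input", "feature"):
            raise ValueError("mode must be 'input' or 'feature'")


def inject_information_limit(
    table: TrialTable, spec: InfoLimitSpec, encoder=None, seed: int = 0
) -> TrialTable:
    """Re-render each trial at a stimulus jittered by ``ds ~ N(0, eps)``.

    The nominal stimulus labels are unchanged — the jitter is noise the
    downstream observer cannot distinguish from a real stimulus change,
    which caps the Fisher information at ``1/epsilon``.
    """
    if spec.mode != "input":
        raise ValueError(
            "use inject_information_limit_features for feature-space mode"
        )
    if encoder is None:
        raise ValueError("input-mode injection requires the generating encoder")
    rng = np.random.default_rng(seed)
    if spec.epsilon == 0:
        ds = np.zeros(table.n_trials)
    else:
        ds = rng.normal(scale=np.sqrt(spec.epsilon), size=table.n_trials)
    out = encoder.sample(table.s + ds, rng)
    r = out[0] if isinstance(out, tuple) else out
    meta = dict(table.meta)
    meta.update({"info_limit_eps": spec.epsilon, "info_limit_seed": seed})
    return TrialTable(s=table.s, r=r, nu=table.nu, choice=table.choice, meta=meta)
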