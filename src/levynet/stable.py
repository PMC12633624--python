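"""Symmetric Lévy alpha-stable sampling for heavy-tailed network connectivity.

All weights in this package follow the symmetric, centered alpha-stable law
``L_alpha(sigma)`` defined by its characteristic function

    E[exp(i k X)] = exp(-|sigma * k|**alpha),      0 < alpha <= 2.

This convention is locked throughout the package: under it ``alpha = 2`` is a
Gaussian with variance ``2 * sigma**2`` (not ``sigma**2``) and ``alpha = 1``
is the Cauchy law with half-width ``sigma``.  For ``alpha < 2`` the density
has power-law tails ``~ |x|**(-1 - alpha)``, so rare, extremely large entries
("mega-synapses") dominate many sample statistics; no truncation is applied
by default.

Sampling uses the Chambers–Mallows–Stuck construction (a uniform angle plus
an independent exponential), with the Gaussian and Cauchy endpoints handled
by their dedicated generators.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numba
import numpy as np

__all__ = [
    "StableSpec",
    "NetworkConfig",
    "sample_standard_stable",
    "sample_stable",
    "sample_weight_matrix",
    "empirical_cf",
    "CFEstimate",
    "save_weight_matrix",
    "load_weight_matrix",
]


def _check_alpha(alpha: float) -> None:
    if not (0.0 < alpha <= 2.0):
        raise ValueError(f"stability index alpha must lie in (0, 2], got {alpha}")


@dataclass(frozen=True)
class StableSpec:
    """Stability index and scale of a symmetric alpha-stable law.

    Parameters
    ----------
    alpha:
        Stability index in ``(0, 2]``; smaller values mean heavier tails.
    scale:
        Scale ``sigma > 0`` in the characteristic-function convention
        ``exp(-|sigma k|**alpha)``.
    """

    alpha: float
    scale: float

    def __post_init__(self) -> None:
        _check_alpha(self.alpha)
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    def characteristic_function(self, k) -> np.ndarray:
        """Exact characteristic function ``exp(-|scale * k|**alpha)``."""
        k = np.asarray(k, dtype=float)
        return np.exp(-np.abs(self.scale * k) ** self.alpha)


@dataclass(frozen=True)
class NetworkConfig:
    """Size, tail index, gain and seed of a random recurrent network.

    The induced weight scale is ``gain / n_units**(1/alpha)``, so the gain
    ``g`` is the single control parameter of the quiescent-to-chaotic
    transition.
    """

    n_units: int
    alpha: float
    gain: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_units, (int, np.integer)) and self.n_units >= 1):
            raise ValueError(f"n_units must be a positive integer, got {self.n_units}")
        _check_alpha(self.alpha)
        if not self.gain >= 0:
            raise ValueError(f"gain must be nonnegative, got {self.gain}")

    @property
    def scale(self) -> float:
        """Induced per-weight scale ``gain / n_units**(1/alpha)``."""
        return self.gain / self.n_units ** (1.0 / self.alpha)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def replace(self, **kwargs) -> "NetworkConfig":
        d = asdict(self)
        d.update(kwargs)
        return NetworkConfig(**d)


@numba.njit(cache=False)
def _cauchy_fill(rng, out):  # pragma: no cover - exercised via sample_standard_stable
    """Standard Cauchy draws as a ratio of independent standard normals."""
    for i in range(out.size):
        d = rng.standard_normal()
        while d == 0.0:
            d = rng.standard_normal()
        out[i] = rng.standard_normal() / d


def sample_standard_stable(alpha: float, count, rng: np.random.Generator) -> np.ndarray:
    """Draw i.i.d. unit-scale symmetric alpha-stable variates.

    ``count`` may be an int or a shape tuple.  Uses the Chambers–Mallows–Stuck
    transform; ``alpha = 2`` reduces to ``sqrt(2) * N(0, 1)`` and ``alpha = 1``
    to the standard Cauchy, generated as a ratio of two independent standard
    normals (equal in distribution to the tangent of a uniform angle, and the
    fastest exact route — weight-matrix generation at alpha = 1 dominates the
    cost of large annealed simulations).
    """
    _check_alpha(alpha)
    if alpha == 2.0:
        return math.sqrt(2.0) * rng.standard_normal(count)
    if alpha == 1.0:
        out = np.empty(count)
        _cauchy_fill(rng, out.ravel())
        return out
    u = rng.uniform(-np.pi / 2.0, np.pi / 2.0, count)
    e = rng.standard_exponential(count)
    # CMS for the symmetric case: sin(a u)/cos(u)^(1/a) * (cos((1-a)u)/e)^((1-a)/a)
    x = np.sin(alpha * u) / np.cos(u) ** (1.0 / alpha)
    x *= (np.cos((1.0 - alpha) * u) / e) ** ((1.0 - alpha) / alpha)
    return x


def sample_stable(spec: StableSpec, size, rng: np.random.Generator) -> np.ndarray:
    """Draw from ``L_alpha(scale)`` by rescaling unit draws (stable laws are
    closed under scaling: ``sigma * X`` has scale ``sigma``)."""
    return spec.scale * sample_standard_stable(spec.alpha, size, rng)


def sample_weight_matrix(
    config: NetworkConfig,
    rng: np.random.Generator | None = None,
    clip: float | None = None,
) -> np.ndarray:
    """Draw an ``N x N`` synaptic weight matrix with i.i.d. ``L_alpha(g / N^(1/alpha))`` entries.

    Reproducible: with ``rng=None`` the stream is seeded from ``config.seed``.
    ``clip``, if given, truncates entries to ``[-clip, clip]``; it is off by
    default because the heavy-tail phenomenology is driven by the outliers.
    """
    if rng is None:
        rng = config.rng()
    n = config.n_units
    if config.gain == 0.0:
        return np.zeros((n, n))
    w = config.scale * sample_standard_stable(config.alpha, (n, n), rng)
    if clip is not None:
        np.clip(w, -clip, clip, out=w)
    return w


@dataclass(frozen=True)
class CFEstimate:
    """Monte-Carlo estimate of a characteristic function on a grid of k."""

    k_values: np.ndarray
    estimate: np.ndarray  # complex, mean of exp(i k x)
    stderr_real: np.ndarray
    stderr_imag: np.ndarray


def empirical_cf(samples, k_values) -> CFEstimate:
    """Empirical characteristic function ``mean(exp(i k x))`` with standard errors.

    The standard errors of the real and imaginary parts are the sample
    standard deviations of ``cos(k x)`` and ``sin(k x)`` divided by
    ``sqrt(len(samples))``.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empirical_cf requires a nonempty sample")
    k = np.atleast_1d(np.asarray(k_values, dtype=float))
    kx = np.outer(k, x)
    c = np.cos(kx)
    s = np.sin(kx)
    n = x.size
    est = c.mean(axis=1) + 1j * s.mean(axis=1)
    se_r = c.std(axis=1, ddof=1) / math.sqrt(n) if n > 1 else np.zeros_like(k)
    se_i = s.std(axis=1, ddof=1) / math.sqrt(n) if n > 1 else np.zeros_like(k)
    return CFEstimate(k_values=k, estimate=est, stderr_real=se_r, stderr_imag=se_i)


def save_weight_matrix(path, matrix: np.ndarray, config: NetworkConfig) -> None:
    """Dump a weight matrix as a ``.npy`` array with a JSON sidecar recording
    ``(N, alpha, gain, seed)``."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), matrix)
    sidecar = {
        "n_units": int(config.n_units),
        "alpha": float(config.alpha),
        "gain": float(config.gain),
        "seed": int(config.seed),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_weight_matrix(path) -> tuple[np.ndarray, NetworkConfig]:
    path = Path(path)
    matrix = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return matrix, NetworkConfig(**meta)
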