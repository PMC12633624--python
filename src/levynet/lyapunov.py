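"""Lyapunov spectra of the RNN via the Benettin QR method.

An orthonormal frame of tangent vectors is co-evolved with the trajectory
under the exact per-step Jacobian ``diag(1 - x(t+1)^2) @ W`` and
re-orthonormalized by QR decomposition at every step; the logarithms of the
diagonal of R, accumulated after a warmup during which the state evolves but
nothing is accumulated, converge to the Lyapunov exponents.  A positive
maximal exponent indicates chaos, a negative one convergence to a fixed
point or limit cycle; near zero the network sits at the edge of chaos.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import _draw_inputs, random_initial_state
from .stable import NetworkConfig, sample_weight_matrix

__all__ = [
    "LyapunovResult",
    "SweepResult",
    "MaxLyapunovEstimate",
    "lyapunov_spectrum",
    "max_lyapunov",
    "estimate_transition_gain",
    "edge_of_chaos_width",
    "kaplan_yorke",
]

# per-step floor on ln R_ii: a fully contracted direction (e.g. gain 0) hits
# exact 0 in floating point; clamping at ln(machine epsilon) keeps estimates
# finite, and the result is flagged as floored.
_LOG_FLOOR = math.log(np.finfo(float).eps)


@dataclass
class LyapunovResult:
    """Time-averaged Lyapunov exponents, sorted nonincreasing."""

    exponents: np.ndarray
    n_tracked: int
    warmup: int
    accumulation_steps: int
    n_trials: int = 1
    per_trial_exponents: np.ndarray | None = None
    floored: bool = False
    trajectory: np.ndarray | None = None


@dataclass
class SweepResult:
    """Maximal exponent versus gain: trial mean/SD and crossing estimates.

    ``crossing_gain`` is the zero crossing of the trial-mean curve;
    ``realization_crossings`` (when per-trial curves are available) holds the
    per-realization first crossings, whose average is the better-behaved
    transition estimator near a flat (marginal) post-instability regime.
    """

    gain_grid: np.ndarray
    mle_mean: np.ndarray
    mle_sd: np.ndarray
    n_trials: int
    crossing_gain: float | None = None
    per_trial_mle: np.ndarray | None = None  # (n_trials, n_gains)
    realization_crossings: list | None = None

    def __post_init__(self) -> None:
        self.gain_grid = np.asarray(self.gain_grid, dtype=float)
        self.mle_mean = np.asarray(self.mle_mean, dtype=float)
        self.mle_sd = np.asarray(self.mle_sd, dtype=float)
        if not (len(self.gain_grid) == len(self.mle_mean) == len(self.mle_sd)):
            raise ValueError("gain grid and MLE arrays must have equal length")
        if np.any(np.diff(self.gain_grid) <= 0):
            raise ValueError("gain grid must be strictly increasing")

    def mean_realization_crossing(self) -> float | None:
        """Average of the per-realization first zero crossings (uncrossed
        realizations are excluded); None without per-trial curves or if no
        realization crosses."""
        if self.realization_crossings is None:
            return None
        vals = [c for c in self.realization_crossings if c is not None]
        return float(np.mean(vals)) if vals else None


@dataclass
class MaxLyapunovEstimate:
    mean: float
    sd: float
    values: np.ndarray
    floored: bool = False

    def __iter__(self):  # unpack as (mean, sd)
        return iter((self.mean, self.sd))


def lyapunov_spectrum(
    config: NetworkConfig,
    horizon: int,
    warmup: int,
    n_exponents: int | None = None,
    input_spec=None,
    rng: np.random.Generator | None = None,
    weights: np.ndarray | None = None,
    linear: bool = False,
    initial: np.ndarray | None = None,
    frame: np.ndarray | None = None,
    keep_trajectory: bool = False,
) -> LyapunovResult:
    """QR (Benettin) Lyapunov spectrum of one network realization.

    Parameters
    ----------
    config:
        Network size, tail index, gain, seed; the weight matrix is drawn
        from it unless ``weights`` is given explicitly.
    horizon, warmup:
        Total steps and the initial stretch excluded from accumulation
        (``horizon > warmup`` required); exponents average ``ln R_ii`` over
        the remaining ``horizon - warmup`` steps.
    n_exponents:
        Size of the tangent frame (``m <= N``).  Defaults to the full
        spectrum for ``N <= 1000`` and the top 100 otherwise (the full-frame
        cost is O(N^3) per step).
    linear:
        Test hook replacing tanh by the identity, so the Jacobian is the
        constant matrix ``W`` and the exponents converge to
        ``ln |eig(W)|`` (the state is not evolved in this mode).
    frame:
        Optional initial tangent frame with orthonormal columns; estimates
        are invariant to this choice up to convergence error.
    keep_trajectory:
        Store the state sequence (for downstream covariance analysis).
    """
    if horizon <= warmup:
        raise ValueError("horizon must exceed warmup")
    if warmup < 0:
        raise ValueError("warmup must be nonnegative")
    if rng is None:
        rng = config.rng()
    n = config.n_units
    if weights is None:
        weights = sample_weight_matrix(config, rng)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (n, n):
            raise ValueError("weights must be N x N")
    if n_exponents is None:
        n_exponents = n if n <= 1000 else 100
    if not (1 <= n_exponents <= n):
        raise ValueError(f"n_exponents must be in [1, {n}], got {n_exponents}")

    if frame is None:
        q, _ = np.linalg.qr(rng.standard_normal((n, n_exponents)))
    else:
        q = np.array(frame, dtype=float)
        if q.shape != (n, n_exponents):
            raise ValueError("frame must have shape (N, n_exponents)")

    if initial is None:
        x = random_initial_state(n, rng)
    else:
        x = np.asarray(initial, dtype=float)
        if x.shape != (n,):
            raise ValueError(f"initial state must have shape ({n},)")
    inputs, _ = _draw_inputs(input_spec, n, horizon, rng)

    accum = np.zeros(n_exponents)
    floored = False
    traj = np.empty((horizon + 1, n)) if keep_trajectory else None
    if keep_trajectory:
        traj[0] = x

    single = n_exponents == 1
    # preallocated buffers: one fused matmul per step reads W only once
    if not linear:
        xq = np.empty((n, n_exponents + 1), order="F")
        out = np.empty_like(xq)
        xq[:, 0] = x
        xq[:, 1:] = q
        gain_col = np.empty(n)
    for t in range(horizon):
        if linear:
            v = weights @ q
        else:
            np.matmul(weights, xq, out=out)
            pre = out[:, 0]
            if inputs is not None:
                pre += inputs[t]
            x = np.tanh(pre, out=xq[:, 0])
            if not np.all(np.isfinite(x)):
                raise RuntimeError(f"non-finite network state at step {t}")
            np.multiply(x, x, out=gain_col)
            np.subtract(1.0, gain_col, out=gain_col)
            v = out[:, 1:]
            v *= gain_col[:, None]
            if keep_trajectory:
                traj[t + 1] = x
        if single:
            norm = float(np.linalg.norm(v))
            if norm > 0:
                q = v / norm
                log_r = np.array([math.log(norm)])
            else:
                q = rng.standard_normal((n, 1))
                q /= np.linalg.norm(q)
                log_r = np.array([-math.inf])
        else:
            q, r = np.linalg.qr(v)
            diag = np.diagonal(r).copy()
            sign = np.sign(diag)
            sign[sign == 0.0] = 1.0
            q = q * sign  # enforce positive diagonal of R
            with np.errstate(divide="ignore"):
                log_r = np.log(np.abs(diag))
        if not linear:
            xq[:, 1:] = q
        if t >= warmup:
            clipped = np.maximum(log_r, _LOG_FLOOR)
            if np.any(clipped != log_r):
                floored = True
            accum += clipped

    k = horizon - warmup
    exponents = np.sort(accum / k)[::-1]
    return LyapunovResult(
        exponents=exponents,
        n_tracked=n_exponents,
        warmup=warmup,
        accumulation_steps=k,
        floored=floored,
        trajectory=traj,
    )


def max_lyapunov(
    config: NetworkConfig,
    horizon: int,
    warmup: int,
    n_trials: int,
    input_spec=None,
    rng: np.random.Generator | None = None,
    fresh_weights: bool = True,
    weights: np.ndarray | None = None,
) -> MaxLyapunovEstimate:
    """Mean and SD of the maximal exponent across trials.

    By default each trial draws a fresh weight matrix, initial condition and
    input stream (realization averaging, appropriate for autonomous sweeps).
    With ``fresh_weights=False`` (or an explicit ``weights``) the matrix is
    shared and only initial conditions/inputs vary between trials
    (input-stream averaging).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = config.rng()
    if weights is not None:
        fresh_weights = False
        weights = np.asarray(weights, dtype=float)
    elif not fresh_weights:
        weights = sample_weight_matrix(config, rng)
    values = np.empty(n_trials)
    floored = False
    for i, child in enumerate(rng.spawn(n_trials)):
        res = lyapunov_spectrum(
            config,
            horizon,
            warmup,
            n_exponents=1,
            input_spec=input_spec,
            rng=child,
            weights=None if fresh_weights else weights,
        )
        values[i] = res.exponents[0]
        floored |= res.floored
    sd = float(values.std(ddof=1)) if n_trials > 1 else 0.0
    return MaxLyapunovEstimate(
        mean=float(values.mean()), sd=sd, values=values, floored=floored
    )


def estimate_transition_gain(sweep: SweepResult) -> float | None:
    """Gain where the mean maximal exponent first crosses zero from below.

    Linear interpolation between the bracketing grid points; returns the
    first grid gain if the curve starts nonnegative, and None if the mean
    exponent never reaches zero on the grid.
    """
    g = sweep.gain_grid
    m = sweep.mle_mean
    if len(g) < 2:
        raise ValueError("need at least 2 grid points")
    if m[0] >= 0:
        return float(g[0])
    for i in range(1, len(g)):
        if m[i] >= 0:
            # bracketed sign change between i-1 and i
            frac = -m[i - 1] / (m[i] - m[i - 1])
            return float(g[i - 1] + frac * (g[i] - g[i - 1]))
    return None


def _upcross(g: np.ndarray, m: np.ndarray, level: float) -> float | None:
    """First upward crossing of ``level`` by linear interpolation."""
    if m[0] >= level:
        return float(g[0])
    for i in range(1, len(g)):
        if m[i] >= level > m[i - 1]:
            frac = (level - m[i - 1]) / (m[i] - m[i - 1])
            return float(g[i - 1] + frac * (g[i] - g[i - 1]))
    return None


def edge_of_chaos_width(sweep: SweepResult, band: float = 0.05) -> float:
    """Width of the gain interval where ``|mean MLE| <= band``.

    Measured between the interpolated upward crossings of ``-band`` and
    ``+band``; censored at the grid edges when a crossing lies outside the
    grid (the returned width is then a lower bound).
    """
    g, m = sweep.gain_grid, sweep.mle_mean
    lo = _upcross(g, m, -band)
    if lo is None:
        return 0.0
    hi = _upcross(g, m, band)
    if hi is None:
        hi = float(g[-1])
    return max(0.0, hi - lo)


def kaplan_yorke(exponents) -> float:
    """Kaplan–Yorke (Lyapunov) dimension from a sorted spectrum.

    With ``k`` the largest index keeping the cumulative sum of exponents
    nonnegative, returns ``k + (sum_{i<=k} lambda_i) / |lambda_{k+1}|``.
    Conventions for the edge cases the definition leaves open: 0 when the
    leading exponent is negative (no expanding or marginal directions), and
    the spectrum length when the full sum is still nonnegative (no
    ``lambda_{k+1}`` exists).
    """
    lam = np.asarray(exponents, dtype=float)
    if lam.ndim != 1 or lam.size == 0:
        raise ValueError("exponents must be a nonempty 1-D sequence")
    if np.any(np.diff(lam) > 1e-12):
        raise ValueError("exponents must be sorted nonincreasing")
    if lam[0] < 0:
        return 0.0
    c = np.cumsum(lam)
    nonneg = np.nonzero(c >= 0)[0]
    k = int(nonneg[-1]) + 1  # count, 1-based
    if k == lam.size:
        return float(k)
    return float(k + c[k - 1] / abs(lam[k]))
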