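"""Steady-state covariance and participation ratio of network activity.

The participation ratio PR = (sum lambda)^2 / sum lambda^2 over covariance
eigenvalues counts the effective number of orthogonal directions carrying
variance: 1 when all variance sits in one mode, N when it is spread
uniformly.  It is a linear (second-order) notion of dimensionality,
complementary to the Kaplan–Yorke dimension computed from Lyapunov spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dynamics import Trajectory

__all__ = ["CovarianceSummary", "empirical_covariance", "participation_ratio"]

# relative floor below which covariance eigenvalues are treated as numerical
# noise from rank-deficient regimes
_EIG_REL_TOL = 1e-12


@dataclass
class CovarianceSummary:
    """Empirical covariance of retained states with its (clipped) spectrum."""

    matrix: np.ndarray
    eigenvalues: np.ndarray  # nonincreasing, >= 0
    n_samples: int
    mean_state: np.ndarray


def empirical_covariance(trajectory, retain: int) -> CovarianceSummary:
    """Mean-centered covariance of the last ``retain`` states (divisor K-1).

    ``trajectory`` may be a :class:`~levynet.dynamics.Trajectory` or a plain
    ``(T, N)`` state array; the first ``T - retain`` rows are discarded as
    warmup.  A warning (not an error) is issued when ``retain <= N``, where
    the covariance is necessarily rank deficient.  Eigenvalues are clipped
    at zero after checking they are no more negative than numerical noise.
    """
    states = trajectory.states if isinstance(trajectory, Trajectory) else np.asarray(
        trajectory, dtype=float
    )
    if states.ndim != 2:
        raise ValueError("states must be a (T, N) array")
    if retain < 2:
        raise ValueError("retain must be >= 2")
    if retain > states.shape[0]:
        raise ValueError("retain exceeds trajectory length")
    n = states.shape[1]
    if retain <= n:
        warnings.warn(
            f"retain = {retain} <= N = {n}: covariance is rank deficient; "
            "prefer retaining more than N steps",
            stacklevel=2,
        )
    x = states[-retain:]
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / (retain - 1)
    cov = 0.5 * (cov + cov.T)
    eig = np.linalg.eigvalsh(cov)[::-1]
    scale = max(eig[0], 0.0)
    if eig[-1] < -max(1e-8, 1e-10 * scale):
        raise FloatingPointError("covariance produced a significantly negative eigenvalue")
    eig = np.clip(eig, 0.0, None)
    return CovarianceSummary(matrix=cov, eigenvalues=eig, n_samples=retain, mean_state=mean)


def participation_ratio(eigenvalues) -> float:
    """``(sum lambda)^2 / sum lambda^2`` over nonnegative covariance eigenvalues.

    Eigenvalues below ``1e-12`` times the largest are clipped to zero first
    (numerical noise in rank-deficient regimes).  Raises on an all-zero
    spectrum, where the ratio is undefined.
    """
    lam = np.asarray(eigenvalues, dtype=float).ravel()
    if lam.size == 0:
        raise ValueError("empty eigenvalue list")
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be nonnegative")
    top = lam.max()
    if top == 0.0:
        raise ValueError("participation ratio undefined for an all-zero spectrum")
    lam = lam / top  # exact scale invariance, no under/overflow in the sums
    lam = np.where(lam < _EIG_REL_TOL, 0.0, lam)
    s1 = lam.sum()
    s2 = np.square(lam).sum()
    return float(s1 * s1 / s2)
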