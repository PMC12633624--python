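"""Annealed finite-size transition theory: the critical gain g*(N, alpha).

With weights redrawn independently at every step, the linearized dynamics
around the quiescent state form a Kesten-type random linear recursion whose
per-step log-growth of the alpha-norm is exactly

    ln g + Xi_step,     Xi_step = (1/alpha) * ln( (1/N) * sum_j |z_j|**alpha ),

with ``z_j`` i.i.d. unit-scale symmetric alpha-stable.  Perturbations decay
iff the mean per-step log-growth is negative, so the critical gain is

    g*(N, alpha) = exp(-Xi_{N,alpha}),
    Xi_{N,alpha} = E[(1/alpha) * ln((1/N) * sum_j |z_j|**alpha)].

The expectation is taken OUTSIDE the logarithm: with it inside, E[|z|^alpha]
diverges for alpha < 2 and the expression would be undefined; the outside
reading also reproduces the Gaussian closed form below and the stated
``g* ~ (ln N)^(-1/alpha)`` asymptotics.

Gaussian closed form (alpha = 2): ``(1/N) sum z_j^2`` is ``(2/N) * chi2_N``
in distribution and ``E[ln chi2_N] = ln 2 + digamma(N/2)``, hence

    Xi_{N,2} = (digamma(N/2) + ln(4/N)) / 2   -->   ln sqrt(2)  as N -> inf,

so g*(inf, 2) = 1/sqrt(2), recovering the classical Gaussian edge-of-chaos
condition N * E[W^2] = 1 (the variance of L_2(sigma) is 2 sigma^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma

from .stable import _check_alpha, sample_standard_stable

__all__ = [
    "TheoryPrediction",
    "xi_gaussian_exact",
    "xi_monte_carlo",
    "critical_gain",
    "asymptotic_gain_check",
    "theory_table",
]

# cap on elements generated per Monte-Carlo batch (memory control)
_BATCH_ELEMS = 1 << 24


@dataclass(frozen=True)
class TheoryPrediction:
    """Estimate of the log-growth correction Xi_{N,alpha} and the derived g*."""

    n_units: int
    alpha: float
    xi: float
    xi_stderr: float
    g_star: float
    n_samples: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not math.isclose(self.g_star, math.exp(-self.xi), rel_tol=1e-12):
            raise ValueError("g_star must equal exp(-xi)")


def xi_gaussian_exact(n_units: int | None = None) -> float:
    """Closed-form Xi_{N,2}; ``n_units=None`` gives the N -> infinity limit ln sqrt(2)."""
    if n_units is None:
        return 0.5 * math.log(2.0)
    return 0.5 * (digamma(n_units / 2.0) + math.log(4.0 / n_units))


def _xi_step_samples(
    n_units: int, alpha: float, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """``n_samples`` i.i.d. draws of (1/alpha) ln((1/N) sum |z_j|^alpha)."""
    out = np.empty(n_samples)
    per_batch = max(1, _BATCH_ELEMS // n_units)
    done = 0
    while done < n_samples:
        m = min(per_batch, n_samples - done)
        z = sample_standard_stable(alpha, (m, n_units), rng)
        np.abs(z, out=z)
        if alpha != 1.0:
            z **= alpha
        out[done : done + m] = np.log(z.mean(axis=1)) / alpha
        done += m
    return out


def xi_monte_carlo(
    n_units: int,
    alpha: float,
    n_samples: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> TheoryPrediction:
    """Monte-Carlo estimate of Xi_{N,alpha} with standard error.

    Averages ``(1/alpha) ln((1/N) sum_j |z_j|^alpha)`` over ``n_samples``
    independent N-vectors of unit-scale symmetric stable draws.
    """
    _check_alpha(alpha)
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    vals = _xi_step_samples(n_units, alpha, n_samples, rng)
    xi = float(vals.mean())
    stderr = float(vals.std(ddof=1) / math.sqrt(n_samples))
    return TheoryPrediction(
        n_units=int(n_units),
        alpha=float(alpha),
        xi=xi,
        xi_stderr=stderr,
        g_star=math.exp(-xi),
        n_samples=int(n_samples),
        seed=seed,
    )


def critical_gain(
    n_units: int,
    alpha: float,
    n_samples: int = 10_000,
    rng: np.random.Generator | int | None = None,
    method: str = "auto",
) -> float:
    """Critical gain ``g*(N, alpha) = exp(-Xi_{N,alpha})``.

    ``method='auto'`` uses the exact digamma closed form for ``alpha = 2``
    (no Monte-Carlo noise) and Monte Carlo otherwise; ``'mc'`` forces Monte
    Carlo, e.g. to cross-validate the Gaussian closed form.
    """
    _check_alpha(alpha)
    if method not in ("auto", "mc", "exact"):
        raise ValueError(f"unknown method {method!r}")
    if alpha == 2.0 and method in ("auto", "exact"):
        return math.exp(-xi_gaussian_exact(n_units))
    if method == "exact":
        raise ValueError("closed form only available for alpha = 2")
    return xi_monte_carlo(n_units, alpha, n_samples, rng).g_star


def asymptotic_gain_check(
    alpha: float,
    n_grid,
    n_samples=2_000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Fitted slope of ``ln g*(N)`` against ``ln ln N`` over ``n_grid``.

    For heavy tails (``alpha < 2``) the predicted decay is
    ``g* ~ (ln N)^(-1/alpha)``, i.e. a slope near ``-1/alpha``; slowly
    varying corrections make the fitted slope approach that value only
    gradually, so grids should span several decades.

    ``n_samples`` may be an int or a per-N sequence (useful to keep runtime
    bounded at very large N, where each replicate costs O(N)).
    """
    _check_alpha(alpha)
    n_grid = [int(n) for n in n_grid]
    if len(n_grid) < 3:
        raise ValueError("n_grid must contain at least 3 sizes spanning >= 3 decades")
    if np.isscalar(n_samples):
        n_samples = [int(n_samples)] * len(n_grid)
    if len(n_samples) != len(n_grid):
        raise ValueError("n_samples sequence must match n_grid length")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    log_g = []
    for n, ns in zip(n_grid, n_samples):
        if alpha == 2.0:
            log_g.append(-xi_gaussian_exact(n))
        else:
            log_g.append(-xi_monte_carlo(n, alpha, ns, rng).xi)
    slope, _ = np.polyfit(np.log(np.log(np.asarray(n_grid, dtype=float))), log_g, 1)
    return float(slope)


def theory_table(
    n_grid,
    alpha_grid,
    n_samples: int = 10_000,
    seed: int = 0,
):
    """Tidy table of (N, alpha, xi, xi_stderr, g_star, n_samples, seed).

    The data behind the critical-gain-versus-size curves; each (N, alpha)
    cell uses an independent child stream spawned from ``seed``.
    """
    import pandas as pd

    rows = []
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(n_grid) * len(alpha_grid))
    i = 0
    for alpha in alpha_grid:
        for n in n_grid:
            pred = xi_monte_carlo(n, alpha, n_samples, np.random.default_rng(streams[i]))
            i += 1
            rows.append(
                {
                    "n_units": n,
                    "alpha": alpha,
                    "xi": pred.xi,
                    "xi_stderr": pred.xi_stderr,
                    "g_star": pred.g_star,
                    "n_samples": n_samples,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)
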