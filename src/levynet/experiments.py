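"""Experiment battery: transition sweeps, MLE-vs-gain sweeps, dimensionality
analysis, mega-synapse ablation, and a delayed-XOR reservoir task.

Each experiment is a plain function taking a config dataclass and returning
tidy pandas tables with provenance columns (seed, config hash), so runs are
reproducible end to end; the CLI in :mod:`levynet.cli` is a thin wrapper
writing the same tables to CSV/JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import theory
from .dimensionality import empirical_covariance, participation_ratio
from .dynamics import (
    GaussianInput,
    order_parameter_gain_sweep,
    simulate_linear,
)
from .lyapunov import (
    SweepResult,
    estimate_transition_gain,
    kaplan_yorke,
    lyapunov_spectrum,
)
from .stable import NetworkConfig, sample_standard_stable, sample_weight_matrix

__all__ = [
    "GainGrid",
    "ExperimentConfig",
    "ReservoirTaskSpec",
    "TransitionResult",
    "run_transition_experiment",
    "run_mle_sweep",
    "run_dimensionality_experiment",
    "ablate_top_weights",
    "run_ablation_experiment",
    "run_xor_reservoir",
    "run_xor_experiment",
]


@dataclass(frozen=True)
class GainGrid:
    """Gain grid specification (linear or log spacing)."""

    start: float
    stop: float
    num: int
    spacing: str = "linear"

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError("gain grid requires start < stop")
        if self.num < 2:
            raise ValueError("gain grid needs at least 2 points")
        if self.spacing not in ("linear", "log"):
            raise ValueError("spacing must be 'linear' or 'log'")

    def values(self) -> np.ndarray:
        if self.spacing == "log":
            if self.start <= 0:
                raise ValueError("log spacing requires positive start")
            return np.geomspace(self.start, self.stop, self.num)
        return np.linspace(self.start, self.stop, self.num)


@dataclass
class ExperimentConfig:
    """Parameter bundle shared by the experiment drivers.

    Defaults are desk-runnable (N of a few hundred, 10 trials); the same
    config carries paper-scale sizes unchanged.
    """

    experiment: str
    alpha_grid: tuple = (1.0, 1.5, 2.0)
    n_grid: tuple = (500,)
    gain_grid: GainGrid | None = None
    n_trials: int = 10
    horizon: int = 3000
    warmup: int = 500
    k_accum: int = 100
    input_spec: GaussianInput | None = None
    epsilon: float = 0.1
    depth: int = 100
    n_exponents: int | None = None
    seed: int = 0

    _KNOWN = ("transition", "mle_sweep", "dimensionality", "ablation", "xor")

    def __post_init__(self) -> None:
        if self.experiment not in self._KNOWN:
            raise ValueError(f"experiment must be one of {self._KNOWN}")
        if not self.alpha_grid or not self.n_grid:
            raise ValueError("alpha_grid and n_grid must be nonempty")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")

    def config_hash(self) -> str:
        d = asdict(self)
        d["input_spec"] = None if self.input_spec is None else asdict(self.input_spec)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class TransitionResult:
    """Order-parameter curves plus the annealed theory overlay."""

    curves: pd.DataFrame
    theory: pd.DataFrame


def run_transition_experiment(cfg: ExperimentConfig) -> TransitionResult:
    """Order parameter of the linearized dynamics across a gain grid.

    For every (alpha, N) and realization, one unit-gain annealed path and one
    unit-gain quenched matrix are simulated for ``cfg.depth`` steps; the whole
    gain grid is then evaluated exactly from each shared realization (the
    linear map is homogeneous in the gain, so a quenched matrix drawn from
    ``L_alpha(N^(-1/alpha))`` and rescaled by g — and equally an annealed
    product path — serves every g).  The theory overlay holds the annealed
    critical-gain prediction per (alpha, N).
    """
    if cfg.experiment != "transition":
        raise ValueError("config.experiment must be 'transition'")
    if cfg.gain_grid is None:
        raise ValueError("transition experiment requires a gain grid")
    gains = cfg.gain_grid.values()
    chash = cfg.config_hash()
    rows = []
    theory_rows = []
    cell_rngs = _spawn_rngs(cfg.seed, 2 * len(cfg.alpha_grid) * len(cfg.n_grid))
    i = 0
    for alpha in cfg.alpha_grid:
        for n in cfg.n_grid:
            theory_rng = cell_rngs[i]
            run_rng = cell_rngs[i + 1]
            i += 2
            g_star = theory.critical_gain(n, alpha, rng=theory_rng)
            theory_rows.append(
                {"alpha": alpha, "n_units": n, "g_star": g_star, "seed": cfg.seed}
            )
            base_cfg = NetworkConfig(n_units=n, alpha=alpha, gain=1.0)
            for mode in ("annealed", "quenched"):
                for r, trial_rng in enumerate(run_rng.spawn(cfg.n_trials)):
                    base = simulate_linear(
                        base_cfg, mode, cfg.depth, rng=trial_rng, track_alpha_norm=False
                    )
                    fr = order_parameter_gain_sweep(base, gains, cfg.epsilon)
                    for g, f in zip(gains, fr):
                        rows.append(
                            {
                                "alpha": alpha,
                                "n_units": n,
                                "gain": g,
                                "mode": mode,
                                "realization": r,
                                "order_parameter": f,
                                "seed": cfg.seed,
                                "config_hash": chash,
                            }
                        )
    return TransitionResult(curves=pd.DataFrame(rows), theory=pd.DataFrame(theory_rows))


def run_mle_sweep(cfg: ExperimentConfig):
    """Maximal-exponent-versus-gain sweeps with crossing-gain estimates.

    Protocol: evolve for ``cfg.horizon`` steps and accumulate the exponent
    over the last ``cfg.k_accum`` steps (warmup = horizon - k_accum).  Each
    trial is one realization: a fresh base matrix drawn from
    ``L_alpha(N^(-1/alpha))`` is shared across the whole gain grid (rescaled
    by each g, the same protocol as the quenched transition sweeps), with
    fresh initial conditions and input streams per gain.  This yields
    coherent per-realization exponent curves, whose individual first zero
    crossings average to the transition-gain estimate; the trial-mean curve
    and its crossing are also recorded.

    Returns ``(sweeps, table)`` where ``sweeps[(alpha, n)]`` is a
    :class:`~levynet.lyapunov.SweepResult`.
    """
    if cfg.experiment != "mle_sweep":
        raise ValueError("config.experiment must be 'mle_sweep'")
    if cfg.gain_grid is None:
        raise ValueError("mle_sweep requires a gain grid")
    gains = cfg.gain_grid.values()
    warmup = cfg.horizon - cfg.k_accum
    if warmup < 0:
        raise ValueError("k_accum exceeds horizon")
    chash = cfg.config_hash()
    sweeps: dict[tuple, SweepResult] = {}
    rows = []
    cell_rngs = _spawn_rngs(cfg.seed, len(cfg.alpha_grid) * len(cfg.n_grid))
    i = 0
    for alpha in cfg.alpha_grid:
        for n in cfg.n_grid:
            rng = cell_rngs[i]
            i += 1
            unit_scale = n ** (-1.0 / alpha)
            per_trial = np.empty((cfg.n_trials, len(gains)))
            for r, trial_rng in enumerate(rng.spawn(cfg.n_trials)):
                base = unit_scale * sample_standard_stable(alpha, (n, n), trial_rng)
                for j, g in enumerate(gains):
                    net = NetworkConfig(n_units=n, alpha=alpha, gain=float(g))
                    res = lyapunov_spectrum(
                        net,
                        cfg.horizon,
                        warmup,
                        n_exponents=1,
                        input_spec=cfg.input_spec,
                        rng=trial_rng,
                        weights=g * base,
                    )
                    per_trial[r, j] = res.exponents[0]
            means = per_trial.mean(axis=0)
            sds = (
                per_trial.std(axis=0, ddof=1)
                if cfg.n_trials > 1
                else np.zeros(len(gains))
            )
            sweep = SweepResult(
                gains, means, sds, cfg.n_trials, per_trial_mle=per_trial
            )
            sweep.crossing_gain = estimate_transition_gain(sweep)
            sweep.realization_crossings = [
                estimate_transition_gain(
                    SweepResult(gains, row, np.zeros(len(gains)), 1)
                )
                for row in per_trial
            ]
            sweeps[(alpha, n)] = sweep
            for j, g in enumerate(gains):
                rows.append(
                    {
                        "alpha": alpha,
                        "n_units": n,
                        "gain": float(g),
                        "mle_mean": means[j],
                        "mle_sd": sds[j],
                        "n_trials": cfg.n_trials,
                        "seed": cfg.seed,
                        "config_hash": chash,
                    }
                )
    return sweeps, pd.DataFrame(rows)


def run_dimensionality_experiment(cfg: ExperimentConfig, gains_by_alpha=None):
    """Lyapunov spectra, Kaplan–Yorke dimension and participation ratio.

    At each requested gain (either ``cfg.gain_grid`` for all alphas or a
    ``{alpha: [gains]}`` mapping, e.g. each alpha's estimated crossing gain),
    runs ``cfg.n_trials`` independent networks, tracking a top-``m`` tangent
    frame (``cfg.n_exponents``); per trial records the maximal exponent, the
    Kaplan–Yorke dimension from the tracked spectrum, and the participation
    ratio of the post-warmup states.
    """
    if cfg.experiment != "dimensionality":
        raise ValueError("config.experiment must be 'dimensionality'")
    if gains_by_alpha is None:
        if cfg.gain_grid is None:
            raise ValueError("provide gain_grid or gains_by_alpha")
        gains_by_alpha = {a: cfg.gain_grid.values() for a in cfg.alpha_grid}
    retain = cfg.horizon - cfg.warmup
    chash = cfg.config_hash()
    rows = []
    spectra = {}
    cell_rngs = _spawn_rngs(cfg.seed, len(gains_by_alpha) * len(cfg.n_grid))
    i = 0
    for alpha, gains in gains_by_alpha.items():
        for n in cfg.n_grid:
            rng = cell_rngs[i]
            i += 1
            m = cfg.n_exponents or min(100, n)
            for g in np.atleast_1d(gains):
                trial_exps = []
                for trial, child in enumerate(rng.spawn(cfg.n_trials)):
                    net = NetworkConfig(n_units=n, alpha=alpha, gain=float(g))
                    res = lyapunov_spectrum(
                        net,
                        cfg.horizon,
                        cfg.warmup,
                        n_exponents=m,
                        input_spec=cfg.input_spec,
                        rng=child,
                        keep_trajectory=True,
                    )
                    trial_exps.append(res.exponents)
                    cov = empirical_covariance(res.trajectory, retain)
                    try:
                        pr = participation_ratio(cov.eigenvalues)
                    except ValueError:  # fully quiescent trial
                        pr = float("nan")
                    rows.append(
                        {
                            "alpha": alpha,
                            "n_units": n,
                            "gain": float(g),
                            "trial": trial,
                            "mle": float(res.exponents[0]),
                            "d_ky": kaplan_yorke(res.exponents),
                            "pr": pr,
                            "seed": cfg.seed,
                            "config_hash": chash,
                        }
                    )
                spectra[(alpha, n, float(g))] = np.vstack(trial_exps)
    return pd.DataFrame(rows), spectra


def ablate_top_weights(weights: np.ndarray, n_remove: int) -> np.ndarray:
    """Zero out the ``n_remove`` largest-magnitude entries (the "mega-synapses").

    Ties are broken in row-major order.  Returns a copy.
    """
    w = np.array(weights, dtype=float)
    if not (0 <= n_remove <= w.size):
        raise ValueError(f"n_remove must be in [0, {w.size}]")
    if n_remove == 0:
        return w
    flat = w.ravel()
    order = np.argsort(-np.abs(flat), kind="stable")
    flat[order[:n_remove]] = 0.0
    return flat.reshape(w.shape)


def run_ablation_experiment(
    cfg: ExperimentConfig, gain: float, n_remove: int
) -> pd.DataFrame:
    """Maximal exponent before vs after removing the top weights.

    For each seed, one matrix is drawn and the exponent is measured with the
    same initial condition and inputs on the intact and ablated matrix.
    """
    if cfg.experiment != "ablation":
        raise ValueError("config.experiment must be 'ablation'")
    warmup = cfg.horizon - cfg.k_accum
    chash = cfg.config_hash()
    rows = []
    cell_rngs = _spawn_rngs(cfg.seed, len(cfg.alpha_grid) * len(cfg.n_grid))
    i = 0
    for alpha in cfg.alpha_grid:
        for n in cfg.n_grid:
            rng = cell_rngs[i]
            i += 1
            for trial, child in enumerate(rng.spawn(cfg.n_trials)):
                net = NetworkConfig(n_units=n, alpha=alpha, gain=gain)
                w = sample_weight_matrix(net, child)
                w_ablated = ablate_top_weights(w, n_remove)
                state_seed = child.integers(2**31)
                for label, mat in (("intact", w), ("ablated", w_ablated)):
                    res = lyapunov_spectrum(
                        net,
                        cfg.horizon,
                        warmup,
                        n_exponents=1,
                        input_spec=cfg.input_spec,
                        rng=np.random.default_rng(state_seed),
                        weights=mat,
                    )
                    rows.append(
                        {
                            "alpha": alpha,
                            "n_units": n,
                            "gain": gain,
                            "trial": trial,
                            "condition": label,
                            "n_removed": n_remove,
                            "removed_fraction": n_remove / (n * n),
                            "mle": float(res.exponents[0]),
                            "seed": cfg.seed,
                            "config_hash": chash,
                        }
                    )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReservoirTaskSpec:
    """Delayed-XOR reservoir task: predict XOR of two past input bits.

    The target at time t is XOR of the inputs at lags ``delay`` and
    ``delay + 1``; the readout is a ridge regression on reservoir states.
    All values are artifact choices exposed for configuration.
    """

    delay: int = 1
    train_steps: int = 2000
    test_steps: int = 1000
    ridge_penalty: float = 1e-4
    input_scale: float = 0.5
    bias_scale: float = 0.2
    washout: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise ValueError("delay must be nonnegative")
        if self.train_steps <= self.delay or self.test_steps <= self.delay:
            raise ValueError("train/test windows must exceed the delay")
        if self.ridge_penalty < 0:
            raise ValueError("ridge penalty must be nonnegative")


def _xor_targets(u: np.ndarray, t_index: np.ndarray, delay: int) -> np.ndarray:
    """XOR of the +-1 inputs at lags (delay, delay+1) relative to state time."""
    a = u[t_index - delay]
    b = u[t_index - delay - 1]
    return (a * b < 0).astype(float)


def run_xor_reservoir(
    net: NetworkConfig, task: ReservoirTaskSpec, rng: np.random.Generator | None = None
) -> float:
    """Held-out accuracy of a ridge readout on the delayed-XOR task.

    The network is driven by a random +-1 stream through a fixed random input
    vector plus a static random bias; states after a washout are regressed
    onto the binary targets and accuracy is evaluated on a held-out
    continuation of the same run.

    The bias is essential, not cosmetic: with symmetric +-1 inputs, zero
    initial state and an odd activation, the state is an odd function of the
    input history, whereas XOR of two bits is even — a linear readout of a
    bias-free tanh reservoir is provably stuck at chance on this task.
    """
    if rng is None:
        rng = np.random.default_rng(task.seed)
    n = net.n_units
    w = sample_weight_matrix(net, rng)
    w_in = task.input_scale * rng.uniform(-1.0, 1.0, n)
    bias = task.bias_scale * rng.uniform(-1.0, 1.0, n)
    total = task.washout + task.train_steps + task.test_steps
    u = np.where(rng.random(total) < 0.5, -1.0, 1.0)
    states = np.empty((total + 1, n))
    states[0] = 0.0
    x = states[0]
    for t in range(total):
        x = np.tanh(w @ x + w_in * u[t] + bias)
        states[t + 1] = x
    # state x(t) has seen inputs up to u(t-1); targets use lags >= delay
    first = max(task.washout, task.delay + 2)
    train_idx = np.arange(first, first + task.train_steps)
    test_idx = np.arange(
        first + task.train_steps, min(first + task.train_steps + task.test_steps, total)
    )
    y_train = _xor_targets(u, train_idx, task.delay)
    y_test = _xor_targets(u, test_idx, task.delay)
    if len(np.unique(y_train)) < 2 or len(np.unique(y_test)) < 2:
        raise ValueError("degenerate task: all targets equal")
    phi = np.column_stack((states[train_idx], np.ones(len(train_idx))))
    gram = phi.T @ phi + task.ridge_penalty * np.eye(phi.shape[1])
    beta = np.linalg.solve(gram, phi.T @ y_train)
    phi_test = np.column_stack((states[test_idx], np.ones(len(test_idx))))
    pred = phi_test @ beta > 0.5
    return float(np.mean(pred == y_test.astype(bool)))


def run_xor_experiment(cfg: ExperimentConfig, task: ReservoirTaskSpec) -> pd.DataFrame:
    """Accuracy-versus-gain table of the delayed-XOR task per (alpha, N)."""
    if cfg.experiment != "xor":
        raise ValueError("config.experiment must be 'xor'")
    if cfg.gain_grid is None:
        raise ValueError("xor experiment requires a gain grid")
    gains = cfg.gain_grid.values()
    chash = cfg.config_hash()
    rows = []
    cell_rngs = _spawn_rngs(cfg.seed, len(cfg.alpha_grid) * len(cfg.n_grid))
    i = 0
    for alpha in cfg.alpha_grid:
        for n in cfg.n_grid:
            rng = cell_rngs[i]
            i += 1
            for g in gains:
                for trial, child in enumerate(rng.spawn(cfg.n_trials)):
                    net = NetworkConfig(n_units=n, alpha=alpha, gain=float(g))
                    acc = run_xor_reservoir(net, task, child)
                    rows.append(
                        {
                            "alpha": alpha,
                            "n_units": n,
                            "gain": float(g),
                            "trial": trial,
                            "accuracy": acc,
                            "delay": task.delay,
                            "seed": cfg.seed,
                            "config_hash": chash,
                        }
                    )
    return pd.DataFrame(rows)
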