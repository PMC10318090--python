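"""Positivity-preserving Euler-Maruyama integration of the two-patch SDE.

The toxicant forcing is never discretised: body burden and environmental
concentration are evaluated on the time grid with the exact closed form of
:mod:`toxpatch.toxicant`, with the post-pulse environmental value used for
stepping across a pulse instant (the recorded value at the instant itself is
the pre-pulse one).  Two schemes advance the population states:

``ppt-em``
    Standard Euler-Maruyama on (x1, x2) followed by truncation at a small
    positive floor; the default and the simplest positivity-preserving
    truncation.
``log-em``
    Euler-Maruyama on (ln x1, ln x2) with Ito-corrected drifts; exactly
    positive, no floor ever binds.

The time grid is uniform with step ``dt`` and must contain every pulse instant
exactly (``gamma/dt`` integer), so the pulse is always aligned with a grid
node.  Ensembles run independent paths whose Gaussian streams are seeded
deterministically as ``seed + path_index``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .coefficients import ModelParams, mean_growth, migration_rate, sigma_t
from .toxicant import ToxicantParams, ToxicantState, toxicant_on_grid
from . import summaries as _summaries

__all__ = [
    "SimConfig",
    "Trajectory",
    "SimulationDivergedError",
    "simulate_path",
    "simulate_ensemble",
    "simulate_unpolluted",
]

_DENSITY_CAP = 1e6  # drift is strongly dissipative; a breach means a bug or absurd parameters


class SimulationDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Numerical configuration of one simulation run.

    dt defaults should be chosen so that gamma/dt is an integer (checked at
    simulation time against the model's pulse period); record_stride thins the
    stored output without affecting the integration step.
    """

    t_end: float
    dt: float
    n_paths: int = 1
    seed: int = 0
    scheme: str = "ppt-em"
    floor: float = 1e-10
    record_stride: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_end < self.dt:
            raise ValueError("t_end must be at least dt")
        if self.n_paths < 1:
            raise ValueError("n_paths must be at least 1")
        if self.scheme not in ("ppt-em", "log-em"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.floor <= 0:
            raise ValueError("floor must be positive")
        if self.record_stride < 1:
            raise ValueError("record_stride must be at least 1")

    def n_steps(self) -> int:
        n = round(self.t_end / self.dt)
        if abs(n * self.dt - self.t_end) > 1e-9 * max(1.0, self.t_end):
            raise ValueError("t_end must be an integer multiple of dt")
        return n

    def check_alignment(self, tox: ToxicantParams) -> None:
        ratio = tox.gamma / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"pulse period gamma={tox.gamma} must be an integer multiple of dt={self.dt}"
            )


@dataclass(frozen=True)
class Trajectory:
    """One recorded sample path (populations plus exact toxicant forcing)."""

    t: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    c_o: np.ndarray
    c_e: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("x1", "x2", "c_o", "c_e"):
            if len(getattr(self, name)) != n:
                raise ValueError("trajectory arrays must share one length")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.t, "x1": self.x1, "x2": self.x2, "c_o": self.c_o, "c_e": self.c_e}
        )


def _toxicant_grids(model: ModelParams, tox0: ToxicantState, t: np.ndarray):
    """Recorded (pre-pulse at instants) and stepping (post-pulse) toxicant grids."""
    tox = model.toxicant
    co, ce = toxicant_on_grid(tox, tox0, t)
    ce_step = ce.copy()
    stride = round(tox.gamma / (t[1] - t[0]))
    pulse_idx = np.arange(stride, len(t), stride)
    ce_step[pulse_idx] += tox.b
    return co, ce, ce_step


def _draw_increments(seed: int, n_steps: int, dt: float) -> np.ndarray:
    """Gaussian increments (n_steps, 2) for one path from its own seeded stream."""
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_steps, 2)) * math.sqrt(dt)


def _integrate(
    model: ModelParams,
    t: np.ndarray,
    co_step: np.ndarray,
    ce_step: np.ndarray,
    x0: np.ndarray,
    dW: np.ndarray,
    scheme: str,
    floor: float,
    rec_idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance ``n_paths`` population states through all steps.

    x0: (n_paths, 2) initial densities; dW: (n_steps, n_paths, 2) Brownian
    increments.  Returns recorded (n_paths, n_rec) arrays for x1 and x2.
    """
    p1, p2 = model.patch1, model.patch2
    mig = model.migration
    n_steps = len(t) - 1
    # coefficient profiles shared by every path (evaluated at step left ends)
    r1t = np.asarray(mean_growth(p1, t[:-1]), dtype=float) - model.delta * co_step[:-1]
    r2t = np.asarray(mean_growth(p2, t[:-1]), dtype=float)
    s1t = np.asarray(sigma_t(p1, t[:-1]), dtype=float)
    s2t = np.asarray(sigma_t(p2, t[:-1]), dtype=float)
    d12t = np.asarray(migration_rate(mig, ce_step[:-1]), dtype=float)
    d21 = mig.d21
    a1, a2 = p1.a, p2.a
    dt = t[1] - t[0]

    x1 = np.array(x0[:, 0], dtype=float)
    x2 = np.array(x0[:, 1], dtype=float)
    n_paths = len(x1)
    rec_set = np.zeros(len(t), dtype=bool)
    rec_set[rec_idx] = True
    out1 = np.empty((n_paths, len(rec_idx)))
    out2 = np.empty((n_paths, len(rec_idx)))
    j = 0
    if rec_set[0]:
        out1[:, 0], out2[:, 0] = x1, x2
        j = 1
    use_log = scheme == "log-em"
    if use_log:
        y1, y2 = np.log(x1), np.log(x2)
    with np.errstate(over="ignore", invalid="ignore"):
        for k in range(n_steps):
            if use_log:
                ratio12 = x2 / x1
                ratio21 = x1 / x2
                y1 = y1 + (r1t[k] - a1 * x1 - d12t[k] + d21 * ratio12 - 0.5 * s1t[k] ** 2) * dt \
                    + s1t[k] * dW[k, :, 0]
                y2 = y2 + (r2t[k] - a2 * x2 - d21 + d12t[k] * ratio21 - 0.5 * s2t[k] ** 2) * dt \
                    + s2t[k] * dW[k, :, 1]
                x1, x2 = np.exp(y1), np.exp(y2)
            else:
                drift1 = x1 * (r1t[k] - a1 * x1) + d21 * x2 - d12t[k] * x1
                drift2 = x2 * (r2t[k] - a2 * x2) + d12t[k] * x1 - d21 * x2
                x1 = np.maximum(x1 + drift1 * dt + s1t[k] * x1 * dW[k, :, 0], floor)
                x2 = np.maximum(x2 + drift2 * dt + s2t[k] * x2 * dW[k, :, 1], floor)
            if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))) or np.any(
                x1 + x2 > _DENSITY_CAP
            ):
                raise SimulationDivergedError(
                    f"simulation diverged at step {k + 1} (t={t[k + 1]:.6g})"
                )
            if rec_set[k + 1]:
                out1[:, j], out2[:, j] = x1, x2
                j += 1
    return out1, out2


def _prepare(model: ModelParams, config: SimConfig, tox0: ToxicantState):
    config.check_alignment(model.toxicant)
    n_steps = config.n_steps()
    t = np.arange(n_steps + 1) * config.dt
    co, ce, ce_step = _toxicant_grids(model, tox0, t)
    rec_idx = np.arange(0, n_steps + 1, config.record_stride)
    if rec_idx[-1] != n_steps:
        rec_idx = np.append(rec_idx, n_steps)
    return t, co, ce, ce_step, rec_idx


def simulate_path(
    model: ModelParams,
    config: SimConfig,
    x0: tuple[float, float],
    tox0: ToxicantState,
) -> Trajectory:
    """Simulate one sample path; reproducible from the seed alone."""
    if min(x0) <= 0:
        raise ValueError("initial densities must be positive")
    t, co, ce, ce_step, rec_idx = _prepare(model, config, tox0)
    dW = _draw_increments(config.seed, len(t) - 1, config.dt)[:, None, :]
    x1, x2 = _integrate(
        model, t, co, ce_step, np.array([x0]), dW, config.scheme, config.floor, rec_idx
    )
    return Trajectory(
        t=t[rec_idx], x1=x1[0], x2=x2[0], c_o=co[rec_idx], c_e=ce[rec_idx], seed=config.seed
    )


def simulate_ensemble(
    model: ModelParams,
    config: SimConfig,
    x0: tuple[float, float],
    tox0: ToxicantState,
    window: tuple[float, float] | None = None,
    extinction_threshold: float = 0.01,
    dwell: float | None = None,
    pmoment_p: float = 2.0,
    chunk: int = 100,
):
    """Run ``n_paths`` independent paths and summarise them.

    Path ``p`` uses the Gaussian stream seeded with ``seed + p``, so an
    ensemble contains :func:`simulate_path` run with ``seed`` as its first
    path.  Paths are integrated in vectorised chunks; the summary statistics
    are those of :mod:`toxpatch.summaries`.
    """
    if min(x0) <= 0:
        raise ValueError("initial densities must be positive")
    t, co, ce, ce_step, rec_idx = _prepare(model, config, tox0)
    n_steps = len(t) - 1
    n_rec = len(rec_idx)
    n_paths = config.n_paths
    X1 = np.empty((n_paths, n_rec))
    X2 = np.empty((n_paths, n_rec))
    for start in range(0, n_paths, chunk):
        stop = min(start + chunk, n_paths)
        dW = np.stack(
            [_draw_increments(config.seed + p, n_steps, config.dt) for p in range(start, stop)],
            axis=1,
        )
        x0_block = np.tile(np.asarray(x0, dtype=float), (stop - start, 1))
        try:
            X1[start:stop], X2[start:stop] = _integrate(
                model, t, co, ce_step, x0_block, dW, config.scheme, config.floor, rec_idx
            )
        except SimulationDivergedError as err:
            raise SimulationDivergedError(f"{err} (path block {start}:{stop})") from err
    return _summaries.summarize_ensemble(
        t=t[rec_idx],
        x1=X1,
        x2=X2,
        window=window,
        extinction_threshold=extinction_threshold,
        dwell=dwell,
        pmoment_p=pmoment_p,
        seed=config.seed,
    )


def simulate_unpolluted(
    model: ModelParams, config: SimConfig, x0: tuple[float, float]
) -> Trajectory:
    """Simulate the clean two-patch model: delta = rho = b = 0 enforced.

    Identical machinery to :func:`simulate_path` under that substitution, so a
    run matches a polluted run with those parameters zeroed bit for bit.
    """
    clean = replace(
        model,
        delta=0.0,
        migration=replace(model.migration, rho=0.0),
        toxicant=replace(model.toxicant, b=0.0),
    )
    return simulate_path(clean, config, x0, ToxicantState(0.0, 0.0))
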