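"""Trajectory and ensemble statistics for the survival notions.

The survival definitions are asymptotic (extinction: x(t) -> 0; strong
persistence in the mean: liminf of the running time average positive;
stochastic permanence: confinement within positive bounds with high
probability).  On a finite horizon they are replaced by documented
surrogates: extinction is a sub-threshold dwell over the final stretch of the
trajectory, persistence is a positive windowed time average, and permanence is
reported descriptively through quantile bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnsembleSummary",
    "time_average",
    "trajectory_averages",
    "extinction_flag",
    "empirical_pmoment",
    "summarize_ensemble",
]

DEFAULT_EXTINCTION_THRESHOLD = 0.01
DEFAULT_DWELL_FRACTION = 0.2  # dwell span as a fraction of the horizon


def _window_slice(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    if t1 <= t0:
        raise ValueError("window must have positive length (or be a single grid point)")
    if t0 < t[0] - 1e-12 or t1 > t[-1] + 1e-12:
        raise ValueError("window must lie within the trajectory span")
    return (t >= t0 - 1e-12) & (t <= t1 + 1e-12)


def time_average(t: np.ndarray, y: np.ndarray, window: tuple[float, float]) -> float:
    """Trapezoid-rule time average of ``y`` over ``window = (t0, t1)``.

    With window (0, t_end) this is the running-average operator
    <y> = t^{-1} int_0^t y(s) ds evaluated at the horizon.  A window collapsed
    onto a single grid point returns the value there.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    t0, t1 = window
    if t0 == t1:
        k = int(np.argmin(np.abs(t - t0)))
        if abs(t[k] - t0) > 1e-9:
            raise ValueError("point window must coincide with a grid time")
        return float(y[..., k])
    mask = _window_slice(t, t0, t1)
    tw = t[mask]
    if tw.size < 2:
        raise ValueError("window contains fewer than two grid points")
    return float(np.trapezoid(y[..., mask], tw, axis=-1) / (tw[-1] - tw[0]))


def trajectory_averages(traj, window: tuple[float, float]) -> dict[str, float]:
    """Windowed time averages of every recorded variable of a trajectory."""
    return {
        name: time_average(traj.t, getattr(traj, name), window)
        for name in ("x1", "x2", "c_o", "c_e")
    }


def extinction_flag(
    t: np.ndarray,
    total: np.ndarray,
    threshold: float = DEFAULT_EXTINCTION_THRESHOLD,
    dwell: float | None = None,
) -> bool | np.ndarray:
    """Finite-horizon extinction surrogate.

    True iff the series stays below ``threshold`` at every recorded time in
    the final ``dwell`` span (default: 20% of the horizon).  ``total`` may be
    one series or a (paths, times) matrix; a boolean per path is returned in
    the latter case.
    """
    t = np.asarray(t, dtype=float)
    total = np.asarray(total, dtype=float)
    span = t[-1] - t[0]
    if dwell is None:
        dwell = DEFAULT_DWELL_FRACTION * span
    if dwell > span + 1e-12:
        raise ValueError("dwell exceeds the trajectory span")
    mask = t >= t[-1] - dwell - 1e-12
    flags = np.all(total[..., mask] < threshold, axis=-1)
    return bool(flags) if flags.ndim == 0 else flags


def empirical_pmoment(total_at_t: np.ndarray, p: float) -> tuple[float, float]:
    """Monte-Carlo estimate of E[(x1+x2)^p] at a fixed time, with its SE."""
    if p <= 1:
        raise ValueError("p must exceed 1")
    v = np.asarray(total_at_t, dtype=float) ** p
    se = 0.0 if v.size < 2 else float(v.std(ddof=1) / np.sqrt(v.size))
    return float(v.mean()), se


@dataclass(frozen=True)
class EnsembleSummary:
    """Pointwise and per-path statistics of a simulated ensemble."""

    t: np.ndarray
    x1: np.ndarray  # (n_paths, n_times)
    x2: np.ndarray
    mean_x1: np.ndarray
    mean_x2: np.ndarray
    median_x1: np.ndarray
    median_x2: np.ndarray
    q05_x1: np.ndarray
    q95_x1: np.ndarray
    q05_x2: np.ndarray
    q95_x2: np.ndarray
    window: tuple[float, float]
    avg_x1: np.ndarray  # per-path time averages over window
    avg_x2: np.ndarray
    avg_total: np.ndarray
    extinction_threshold: float
    dwell: float
    extinct: np.ndarray        # per-path flags on x1 + x2
    extinct_x1: np.ndarray     # per-patch flags
    extinct_x2: np.ndarray
    extinction_fraction: float
    pmoment_p: float
    pmoment_value: float
    pmoment_se: float
    seed: int = 0

    @property
    def n_paths(self) -> int:
        return self.x1.shape[0]

    def to_dict(self) -> dict:
        """JSON-ready summary (scalars and window only, not the raw paths)."""
        return {
            "n_paths": self.n_paths,
            "window": list(self.window),
            "averages": {
                "x1": float(self.avg_x1.mean()),
                "x2": float(self.avg_x2.mean()),
                "total": float(self.avg_total.mean()),
            },
            "extinction_fraction": self.extinction_fraction,
            "extinction_threshold": self.extinction_threshold,
            "dwell": self.dwell,
            "pmoment": {"p": self.pmoment_p, "value": self.pmoment_value, "se": self.pmoment_se},
            "seed": self.seed,
        }


def summarize_ensemble(
    t: np.ndarray,
    x1: np.ndarray,
    x2: np.ndarray,
    window: tuple[float, float] | None = None,
    extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD,
    dwell: float | None = None,
    pmoment_p: float = 2.0,
    seed: int = 0,
) -> EnsembleSummary:
    """Build an :class:`EnsembleSummary` from recorded path matrices.

    Default averaging window is the second half of the horizon; default dwell
    for the extinction flag is 20% of the horizon.
    """
    t = np.asarray(t, dtype=float)
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    total = x1 + x2
    if window is None:
        window = (0.5 * (t[0] + t[-1]), t[-1])
    span = t[-1] - t[0]
    if dwell is None:
        dwell = DEFAULT_DWELL_FRACTION * span
    mask = _window_slice(t, *window)
    tw = t[mask]
    width = tw[-1] - tw[0]
    avg_x1 = np.trapezoid(x1[:, mask], tw, axis=1) / width
    avg_x2 = np.trapezoid(x2[:, mask], tw, axis=1) / width
    avg_total = avg_x1 + avg_x2
    extinct = extinction_flag(t, total, extinction_threshold, dwell)
    extinct_x1 = extinction_flag(t, x1, extinction_threshold, dwell)
    extinct_x2 = extinction_flag(t, x2, extinction_threshold, dwell)
    pm, pm_se = empirical_pmoment(total[:, -1], pmoment_p)
    q = np.quantile
    return EnsembleSummary(
        t=t,
        x1=x1,
        x2=x2,
        mean_x1=x1.mean(axis=0),
        mean_x2=x2.mean(axis=0),
        median_x1=np.median(x1, axis=0),
        median_x2=np.median(x2, axis=0),
        q05_x1=q(x1, 0.05, axis=0),
        q95_x1=q(x1, 0.95, axis=0),
        q05_x2=q(x2, 0.05, axis=0),
        q95_x2=q(x2, 0.95, axis=0),
        window=window,
        avg_x1=avg_x1,
        avg_x2=avg_x2,
        avg_total=avg_total,
        extinction_threshold=extinction_threshold,
        dwell=dwell,
        extinct=np.atleast_1d(extinct),
        extinct_x1=np.atleast_1d(extinct_x1),
        extinct_x2=np.atleast_1d(extinct_x2),
        extinction_fraction=float(np.mean(extinct)),
        pmoment_p=pmoment_p,
        pmoment_value=pm,
        pmoment_se=pm_se,
        seed=seed,
    )
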