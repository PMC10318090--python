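"""Impulsive toxicant subsystem: exact solution, periodic orbit, period averages.

The environmental toxicant concentration ``c_e`` decays exponentially at rate
``h`` and receives an instantaneous pulse of size ``b`` at every multiple of the
period ``gamma``.  The organismal body burden ``c_o`` takes toxicant up from the
environment at rate ``f`` and loses it by egestion (``g``) and metabolism
(``m``).  Both equations are linear, so the flow between pulses has a closed
form and the pulsed system possesses a unique, globally attracting
``gamma``-periodic orbit.  All survival thresholds of the full stochastic model
are built from the extrema and period averages of that orbit, so this module is
exact (no numerical ODE integration anywhere).

Conventions
-----------
Pulses occur at ``t = n*gamma`` for integer ``n >= 1``.  States reported *at* a
pulse instant are the pre-pulse (left-limit) values, matching the jump
definition ``Delta c_e(t) = c_e(t+) - c_e(t)``.  An initial state handed to
:func:`solve_toxicant` is the state at ``t = 0`` (no pulse is applied at 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ToxicantParams",
    "ToxicantState",
    "PeriodicToxicantSolution",
    "solve_toxicant",
    "periodic_solution",
    "mean_co",
    "mean_holling_ce",
]

# below this, |h - (g+m)| is treated as a degenerate (equal-rate) case and the
# analytic limit with s*exp(-h*s) terms is used instead of the generic formula
_DEGENERACY_TOL = 1e-12


class ValidationError(ValueError):
    """A parameter set violates a model invariant."""


@dataclass(frozen=True)
class ToxicantParams:
    """Toxicokinetic constants of the pulsed toxicant subsystem.

    Parameters
    ----------
    f : uptake rate of environmental toxicant by organisms (per time).
    g : egestion rate of body burden (per time).
    m : metabolic loss rate of body burden (per time).
    h : environmental loss rate (degradation, volatilisation; per time).
    b : pulse input amount, a concentration in [0, 1].
    gamma : pulse period (time).

    Concentrations must stay in [0, 1]; that forces ``f <= g + m`` and
    ``b <= 1 - exp(-h*gamma)``, which are enforced here.
    """

    f: float
    g: float
    m: float
    h: float
    b: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.f, self.g, self.m) < 0:
            raise ValidationError("f, g, m must be nonnegative")
        if self.h <= 0:
            raise ValidationError("h must be positive")
        if self.gamma <= 0:
            raise ValidationError("gamma must be positive")
        if self.b < 0:
            raise ValidationError("b must be nonnegative")
        if self.f > self.g + self.m + 1e-15:
            raise ValidationError(
                f"concentration bound requires f <= g + m (got f={self.f}, g+m={self.g + self.m})"
            )
        b_max = 1.0 - math.exp(-self.h * self.gamma)
        if self.b > b_max + 1e-15:
            raise ValidationError(
                f"concentration bound requires b <= 1 - exp(-h*gamma) = {b_max:.6g} (got b={self.b})"
            )

    @property
    def gm(self) -> float:
        """Total body-burden loss rate g + m."""
        return self.g + self.m


@dataclass(frozen=True)
class ToxicantState:
    """Instantaneous (c_o, c_e) pair; both dimensionless concentrations."""

    c_o: float
    c_e: float

    def __post_init__(self) -> None:
        if self.c_o < 0 or self.c_e < 0:
            raise ValidationError("concentrations must be nonnegative")


@dataclass(frozen=True)
class PeriodicToxicantSolution:
    """The globally attracting periodic orbit of the pulsed subsystem.

    ``co0`` and ``ce0`` are the orbit values just after a pulse; ``ce0`` is the
    environmental maximum b/(1-exp(-h*gamma)).  Extrema are taken over one
    period; the body-burden minimum is attained at the pulse instants and the
    maximum either at an interior critical point or at an endpoint.  ``eta`` is
    the period average of the saturating (Holling type-III) toxicant response
    c_e^2/(1 + alpha*c_e^2) and is stored with the ``alpha`` it was computed
    with, because alpha belongs to the migration response rather than to the
    toxicokinetics.
    """

    params: ToxicantParams
    co0: float
    ce0: float
    co_min: float
    co_max: float
    ce_min: float
    ce_max: float
    mean_co: float
    eta: float
    alpha: float
    argmax_s: float = field(default=float("nan"))

    def co_at(self, s):
        """Periodic body burden at phase ``s`` in [0, gamma) after a pulse."""
        return _co_between_pulses(self.params, self.co0, self.ce0, np.asarray(s, dtype=float))

    def ce_at(self, s):
        """Periodic environmental concentration at phase ``s`` after a pulse."""
        return self.ce0 * np.exp(-self.params.h * np.asarray(s, dtype=float))


def _co_between_pulses(params: ToxicantParams, co_start, ce_start, s):
    """Exact body burden a phase ``s`` into an inter-pulse interval.

    Solves dc_o/ds = f*ce_start*exp(-h*s) - (g+m)*c_o with c_o(0)=co_start.
    """
    gm = params.gm
    h = params.h
    f = params.f
    if abs(h - gm) < _DEGENERACY_TOL:
        # equal decay rates: resonant term s*exp(-h*s)
        return (co_start + f * ce_start * s) * np.exp(-h * s)
    forced = f * ce_start * (np.exp(-gm * s) - np.exp(-h * s)) / (h - gm)
    return co_start * np.exp(-gm * s) + forced


def solve_toxicant(
    params: ToxicantParams,
    init: ToxicantState,
    times: Sequence[float],
) -> list[ToxicantState]:
    """Evaluate the exact pulsed-toxicant solution on an increasing time grid.

    At ``t = n*gamma`` (n >= 1) the reported state is the pre-pulse value;
    times strictly inside an interval reflect the post-pulse environmental
    concentration of the interval they fall in.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D grid")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    gamma = params.gamma
    h = params.h
    tol = 1e-9 * max(1.0, gamma)
    out: list[ToxicantState] = []
    # walk pulse intervals, carrying the post-pulse state at the left endpoint
    co_n, ce_n = float(init.c_o), float(init.c_e)  # state at n*gamma^+ (t=0: initial)
    n = 0
    for tk in t:
        k = round(tk / gamma)
        if k >= 1 and abs(tk - k * gamma) <= tol:
            target, s = k - 1, gamma  # pre-pulse value at the pulse instant
        else:
            target = int(math.floor(tk / gamma))
            s = tk - target * gamma
        while n < target:
            co_n = float(_co_between_pulses(params, co_n, ce_n, gamma))
            ce_n = ce_n * math.exp(-h * gamma) + params.b
            n += 1
        co = float(_co_between_pulses(params, co_n, ce_n, s))
        ce = ce_n * math.exp(-h * s)
        out.append(ToxicantState(c_o=max(co, 0.0), c_e=max(ce, 0.0)))
    return out


def toxicant_on_grid(
    params: ToxicantParams, init: ToxicantState, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised variant of :func:`solve_toxicant` returning (c_o, c_e) arrays."""
    states = solve_toxicant(params, init, times)
    co = np.array([s.c_o for s in states])
    ce = np.array([s.c_e for s in states])
    return co, ce


def mean_co(params: ToxicantParams) -> float:
    """Period average of the periodic body burden: f*b / (h*(g+m)*gamma)."""
    gm = params.gm
    if gm == 0:
        if params.f > 0:
            raise ValidationError("g + m = 0 with f > 0: body burden has no steady average")
        return 0.0
    return params.f * params.b / (params.h * gm * params.gamma)


def mean_holling_ce(params: ToxicantParams, alpha: float) -> float:
    """Period average of c_e^2/(1 + alpha*c_e^2) along the periodic orbit.

    Closed form: ln of a ratio of quadratic expressions in b, divided by
    2*h*gamma*alpha.  Equals the long-run time average of the saturating
    migration response to environmental toxicant.
    """
    if alpha <= 0:
        raise ValidationError("alpha must be positive")
    if params.b == 0:
        return 0.0
    q = 1.0 - math.exp(-params.h * params.gamma)
    num = q * q + alpha * params.b**2
    den = q * q + alpha * params.b**2 * math.exp(-2.0 * params.h * params.gamma)
    return math.log(num / den) / (2.0 * params.h * params.gamma * alpha)


def _co_extrema(params: ToxicantParams, co0: float, ce0: float) -> tuple[float, float, float]:
    """Extrema of the periodic body burden over one period.

    Returns (co_min, co_max, argmax_phase).  Candidates are the endpoints and
    the unique interior stationary point of A*exp(-(g+m)s) + B*exp(-h*s); a
    dense grid cross-check guards the closed form.
    """
    gamma = params.gamma
    gm = params.gm
    h = params.h
    f = params.f
    cands = [0.0, gamma]
    if abs(h - gm) >= _DEGENERACY_TOL:
        A = co0 + f * ce0 / (h - gm)
        B = -f * ce0 / (h - gm)
        # d/ds [A e^{-gm s} + B e^{-h s}] = 0  =>  e^{(h-gm)s} = -hB/(gm A)
        if gm > 0 and A != 0.0:
            ratio = -h * B / (gm * A)
            if ratio > 0:
                s_star = math.log(ratio) / (h - gm)
                if 0.0 < s_star < gamma:
                    cands.append(s_star)
    else:
        # (co0 + f*ce0*s) e^{-h s}: stationary at s = f*ce0 - h*co0) / (h*f*ce0)
        if f * ce0 > 0:
            s_star = (f * ce0 - h * co0) / (h * f * ce0)
            if 0.0 < s_star < gamma:
                cands.append(s_star)
    vals = _co_between_pulses(params, co0, ce0, np.array(cands))
    co_min = float(vals.min())
    co_max = float(vals.max())
    argmax_s = float(np.array(cands)[int(vals.argmax())])
    # dense-grid fallback: guards against a missed candidate
    grid = np.linspace(0.0, gamma, 10_001)
    gv = _co_between_pulses(params, co0, ce0, grid)
    co_min = min(co_min, float(gv.min()))
    if float(gv.max()) > co_max + 1e-9:  # closed form should never lose by more
        co_max = float(gv.max())
        argmax_s = float(grid[int(gv.argmax())])
    return co_min, co_max, argmax_s


def periodic_solution(params: ToxicantParams, alpha: float) -> PeriodicToxicantSolution:
    """Closed-form periodic orbit with extrema and period averages.

    ``b = 0`` yields the all-zero solution.  The degenerate case ``h = g + m``
    is handled by the analytic limit, never by division by zero.
    """
    if alpha <= 0:
        raise ValidationError("alpha must be positive")
    if params.b == 0:
        return PeriodicToxicantSolution(
            params=params, co0=0.0, ce0=0.0, co_min=0.0, co_max=0.0,
            ce_min=0.0, ce_max=0.0, mean_co=0.0, eta=0.0, alpha=alpha, argmax_s=0.0,
        )
    gamma = params.gamma
    gm = params.gm
    h = params.h
    f = params.f
    b = params.b
    qh = 1.0 - math.exp(-h * gamma)
    ce0 = b / qh
    if gm == 0:
        # no body-burden loss: only consistent with f = 0 (validated above)
        co0 = 0.0
    elif abs(h - gm) < _DEGENERACY_TOL:
        co0 = f * ce0 * gamma * math.exp(-h * gamma) / (1.0 - math.exp(-h * gamma))
    else:
        qgm = 1.0 - math.exp(-gm * gamma)
        co0 = f * b * (math.exp(-gm * gamma) - math.exp(-h * gamma)) / ((h - gm) * qh * qgm)
    co_min, co_max, argmax_s = _co_extrema(params, co0, ce0)
    return PeriodicToxicantSolution(
        params=params,
        co0=co0,
        ce0=ce0,
        co_min=co_min,
        co_max=co_max,
        ce_min=ce0 * math.exp(-h * gamma),
        ce_max=ce0,
        mean_co=mean_co(params),
        eta=mean_holling_ce(params, alpha),
        alpha=alpha,
        argmax_s=argmax_s,
    )
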