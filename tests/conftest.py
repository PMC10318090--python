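"""Shared fixtures and independent numerical oracles.

The oracles here deliberately avoid the package's closed forms: the pulsed
toxicant subsystem is integrated with an adaptive Runge-Kutta scheme segment
by segment between pulses, and period averages are obtained by adaptive
quadrature of the orbit.  They exist to cross-check the analytic code paths.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from toxpatch import ToxicantParams, ToxicantState, fixture


@pytest.fixture
def tox_example() -> ToxicantParams:
    """The toxicokinetic constants shared by both published parameter sets."""
    return ToxicantParams(f=0.5, g=0.3, m=0.2, h=0.3, b=0.1, gamma=1.0)


@pytest.fixture
def set40a():
    return fixture("set40-fig1a")


@pytest.fixture
def set40b():
    return fixture("set40-fig1b")


def rk4_toxicant(
    params: ToxicantParams, init: ToxicantState, t_end: float, n_eval: int = 2001
):
    """Reference integration of the pulsed toxicant ODE with event-free segments.

    Integrates each inter-pulse interval with an adaptive RK scheme and applies
    the pulse jump by hand; returns (times, c_o, c_e) with pre-pulse values at
    the pulse instants.
    """

    def rhs(_t, y):
        c_o, c_e = y
        return [params.f * c_e - (params.g + params.m) * c_o, -params.h * c_e]

    gamma = params.gamma
    ts, cos, ces = [], [], []
    y = np.array([init.c_o, init.c_e], dtype=float)
    t0 = 0.0
    while t0 < t_end - 1e-12:
        t1 = min(t0 + gamma, t_end)
        t_eval = np.linspace(t0, t1, max(2, int(n_eval * (t1 - t0) / t_end)))
        sol = solve_ivp(rhs, (t0, t1), y, t_eval=t_eval, rtol=1e-11, atol=1e-13)
        ts.append(sol.t)
        cos.append(sol.y[0])
        ces.append(sol.y[1])
        y = sol.y[:, -1].copy()
        if abs((t1 / gamma) - round(t1 / gamma)) < 1e-9 and t1 < t_end - 1e-12:
            y[1] += params.b  # pulse
        t0 = t1
    return np.concatenate(ts), np.concatenate(cos), np.concatenate(ces)


def orbit_average_quadrature(orbit, func) -> float:
    """Adaptive quadrature of func(c_o, c_e) along one period of the orbit."""
    gamma = orbit.params.gamma
    val, _ = quad(
        lambda s: func(float(orbit.co_at(s)), float(orbit.ce_at(s))),
        0.0,
        gamma,
        epsabs=1e-12,
        epsrel=1e-12,
        limit=200,
    )
    return val / gamma


def random_remark1_params(rng: np.random.Generator) -> ToxicantParams:
    """Draw a valid parameter set satisfying both concentration bounds."""
    g = rng.uniform(0.05, 0.6)
    m = rng.uniform(0.05, 0.6)
    f = rng.uniform(0.0, g + m)
    h = rng.uniform(0.1, 1.0)
    gamma = rng.uniform(0.3, 3.0)
    b = rng.uniform(0.0, 1.0 - np.exp(-h * gamma))
    return ToxicantParams(f=f, g=g, m=m, h=h, b=b, gamma=gamma)
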