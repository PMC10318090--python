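"""Analytic survival thresholds for the two-patch stochastic model.

All criteria are built from a small set of derived constants: the extrema of
the periodic toxicant orbit evaluated through the effective growth rate
(r_1^* at minimum body burden, (r_1)_* at maximum) and the migration rate
(d_12^* at maximum environmental toxicant, (d_12)_* at minimum), together with
two aggregated noise intensities,

    sigma^2     = xi1^2 xi2^2 / (2 mu1 xi2^2 + 2 mu2 xi1^2)   (extinction),
    sigma_hat^2 = max(xi1^2/2mu1, xi2^2/2mu2)                 (persistence).

Extinction and persistence-in-mean each split into three cases by the sign of
the effective growth-rate difference with patch 2; every criterion is reported
as a signed margin (expression minus its noise threshold) so that the sign
alone carries the verdict.  All conditions are sufficient, not necessary: all
verdicts may be False simultaneously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .coefficients import ModelParams, migration_rate
from .toxicant import periodic_solution

__all__ = [
    "DerivedConstants",
    "ThresholdReport",
    "derived_constants",
    "extinction_check",
    "noise_free_extinction",
    "stochastic_permanence_check",
    "persistence_mean_check",
    "mean_lower_bounds",
    "pmoment_bound",
    "unpolluted_thresholds",
    "classify",
]

_CASE_TOL = 1e-12  # equality tie between effective growth rates -> case "i"


@dataclass(frozen=True)
class DerivedConstants:
    """Constants entering every survival criterion (see module docstring)."""

    r1_up: float        # r_1^*  = r_1e - delta * c_o^m
    r1_low: float       # (r_1)_* = r_1e - delta * c_o^M
    d12_up: float       # d_12^*  evaluated at c_e^M
    d12_low: float      # (d_12)_* evaluated at c_e^m
    sigma2: float
    sigma_hat2: float
    mean_co: float
    eta: float
    co_min: float
    co_max: float
    ce_min: float
    ce_max: float


@dataclass(frozen=True)
class ThresholdReport:
    """Outcome of every sufficient criterion, with its signed margin."""

    constants: DerivedConstants
    extinction_case: str
    extinction_functional: float
    extinction_verdict: bool
    noise_free_extinction: bool
    stochastic_permanence_verdict: bool
    persistence_case: str
    persistence_functional: float
    persistence_verdict: bool
    mean_bound_x1: float
    mean_bound_x2: float
    mean_bounds_applicable: bool
    summary: str

    def to_dict(self) -> dict:
        d = asdict(self)
        d["constants"] = asdict(self.constants)
        return d


def derived_constants(model: ModelParams) -> DerivedConstants:
    """Evaluate all derived constants from the periodic toxicant orbit."""
    mig = model.migration
    orbit = periodic_solution(model.toxicant, mig.alpha)
    p1, p2 = model.patch1, model.patch2
    xi1sq, xi2sq = p1.xi**2, p2.xi**2
    denom = 2.0 * p1.mu * xi2sq + 2.0 * p2.mu * xi1sq
    sigma2 = 0.0 if denom == 0 else xi1sq * xi2sq / denom
    sigma_hat2 = max(p1.sigma_inf2, p2.sigma_inf2)
    return DerivedConstants(
        r1_up=p1.r_e - model.delta * orbit.co_min,
        r1_low=p1.r_e - model.delta * orbit.co_max,
        d12_up=migration_rate(mig, orbit.ce_max),
        d12_low=migration_rate(mig, orbit.ce_min),
        sigma2=sigma2,
        sigma_hat2=sigma_hat2,
        mean_co=orbit.mean_co,
        eta=orbit.eta,
        co_min=orbit.co_min,
        co_max=orbit.co_max,
        ce_min=orbit.ce_min,
        ce_max=orbit.ce_max,
    )


def _two_patch_rate(r1: float, r2: float, d12: float, d21: float) -> float:
    """Dominant growth rate of the coupled linear comparison system.

    (r1 + r2 - d12 - d21) + sqrt((r1 - r2 + d21 - d12)^2 + 4 d12 d21); this is
    twice the larger eigenvalue of the 2x2 matrix [[r1-d12, d21],[d12, r2-d21]].
    """
    return (r1 + r2 - d12 - d21) + math.sqrt((r1 - r2 + d21 - d12) ** 2 + 4.0 * d12 * d21)


def extinction_check(model: ModelParams) -> tuple[str, float, bool]:
    """Sufficient extinction criterion; margin negative => extinction.

    Case selection by sign of r_1^* - r_2e: "i" (equal, within tolerance) uses
    r_1^* + r_2e - sigma^2; "ii" (r_1^* < r_2e) uses d_12^*; "iii" uses
    (d_12)_*.  The margin is the case expression minus sigma^2.
    """
    c = derived_constants(model)
    r2e = model.patch2.r_e
    d21 = model.migration.d21
    diff = c.r1_up - r2e
    if abs(diff) <= _CASE_TOL:
        case, expr = "i", c.r1_up + r2e
    elif diff < 0:
        case, expr = "ii", _two_patch_rate(c.r1_up, r2e, c.d12_up, d21)
    else:
        case, expr = "iii", _two_patch_rate(c.r1_up, r2e, c.d12_low, d21)
    margin = expr - c.sigma2
    return case, margin, margin < 0


def noise_free_extinction(model: ModelParams) -> bool:
    """Noise-independent extinction: r_1^* < 0 and
    d_12^* r_2e + r_1^* d_21 - r_1^* r_2e < 0."""
    c = derived_constants(model)
    r2e = model.patch2.r_e
    d21 = model.migration.d21
    return c.r1_up < 0 and (c.d12_up * r2e + c.r1_up * d21 - c.r1_up * r2e) < 0


def stochastic_permanence_check(model: ModelParams) -> bool:
    """Stochastic permanence: min(r_1e - delta c_o^M, r_2e) > 0.5 sigma_hat^2."""
    c = derived_constants(model)
    return min(c.r1_low, model.patch2.r_e) > 0.5 * c.sigma_hat2


def persistence_mean_check(model: ModelParams) -> tuple[str, float, bool]:
    """Sufficient strong-persistence-in-mean criterion; margin positive =>
    persistent.

    Mirrors the extinction cases with (r_1)_* in place of r_1^* and the starred
    migration rates swapped: case "ii" uses (d_12)_*, case "iii" uses d_12^*.
    The margin is the case expression minus sigma_hat^2.
    """
    c = derived_constants(model)
    r2e = model.patch2.r_e
    d21 = model.migration.d21
    diff = c.r1_low - r2e
    if abs(diff) <= _CASE_TOL:
        case, expr = "i", c.r1_low + r2e
    elif diff < 0:
        case, expr = "ii", _two_patch_rate(c.r1_low, r2e, c.d12_low, d21)
    else:
        case, expr = "iii", _two_patch_rate(c.r1_low, r2e, c.d12_up, d21)
    margin = expr - c.sigma_hat2
    return case, margin, margin > 0


def mean_lower_bounds(model: ModelParams) -> tuple[float, float, bool]:
    """Lower bounds on the per-patch long-run time averages.

    bound_x1 = (r_1e - delta*f*b/(h*(g+m)*gamma) - d12*(1 + rho*eta)) / a1,
    bound_x2 = (r_2e - d21) / a2; applicable iff both numerators are positive.
    """
    c = derived_constants(model)
    p1, p2 = model.patch1, model.patch2
    mig = model.migration
    num1 = p1.r_e - model.delta * c.mean_co - mig.d12 * (1.0 + mig.rho * c.eta)
    num2 = p2.r_e - mig.d21
    return num1 / p1.a, num2 / p2.a, (num1 > 0 and num2 > 0)


def pmoment_bound(model: ModelParams, p: float) -> float:
    """Asymptotic bound K(p) on E[(x1 + x2)^p], p > 1.

    K(p) = (r/a)^p with r = p*max(r_1e+r_10, r_2e+r_20) +
    0.5*p*(p-1)*max(xi_i^2/(2*mu_i)) and a = p*min(a1, a2)/2.
    """
    if p <= 1:
        raise ValueError("p must exceed 1")
    p1, p2 = model.patch1, model.patch2
    r = p * max(p1.r_e + p1.r_0, p2.r_e + p2.r_0) + 0.5 * p * (p - 1) * max(
        p1.sigma_inf2, p2.sigma_inf2
    )
    a = p * min(p1.a, p2.a) / 2.0
    return (r / a) ** p


def unpolluted_thresholds(model: ModelParams) -> tuple[float, float, bool, bool]:
    """Criteria for the clean two-patch model (no toxicant, raw d12, d21).

    Returns (extinction margin vs sigma^2, persistence margin vs sigma_hat^2,
    extinct verdict, persistent verdict); the shared expression is the
    dominant rate of the clean coupled system.
    """
    c = derived_constants(model)
    p1, p2 = model.patch1, model.patch2
    mig = model.migration
    expr = _two_patch_rate(p1.r_e, p2.r_e, mig.d12, mig.d21)
    ext = expr - c.sigma2
    per = expr - c.sigma_hat2
    return ext, per, ext < 0, per > 0


def classify(model: ModelParams) -> ThresholdReport:
    """Evaluate every criterion and produce an auditable report.

    Summary precedence: extinction conditions first, then stochastic
    permanence, then persistence in mean; "inconclusive" when no sufficient
    condition fires.
    """
    c = derived_constants(model)
    ext_case, ext_fun, ext_verdict = extinction_check(model)
    nf = noise_free_extinction(model)
    perm = stochastic_permanence_check(model)
    per_case, per_fun, per_verdict = persistence_mean_check(model)
    b1, b2, applicable = mean_lower_bounds(model)
    if ext_verdict:
        summary = f"extinction (case {ext_case})"
    elif nf:
        summary = "extinction (noise-free criterion)"
    elif perm:
        summary = "stochastically permanent"
        if per_verdict:
            summary += f"; persistent in mean (case {per_case})"
    elif per_verdict:
        summary = f"persistent in mean (case {per_case})"
    else:
        summary = "inconclusive"
    return ThresholdReport(
        constants=c,
        extinction_case=ext_case,
        extinction_functional=ext_fun,
        extinction_verdict=ext_verdict,
        noise_free_extinction=nf,
        stochastic_permanence_verdict=perm,
        persistence_case=per_case,
        persistence_functional=per_fun,
        persistence_verdict=per_verdict,
        mean_bound_x1=b1,
        mean_bound_x2=b2,
        mean_bounds_applicable=applicable,
        summary=summary,
    )
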