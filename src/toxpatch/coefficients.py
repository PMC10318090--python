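"""Time-varying drift and diffusion coefficients of the two-patch SDE.

Each patch's intrinsic growth rate follows an Ornstein-Uhlenbeck process
reverting to the asymptotic mean ``r_e`` at speed ``mu`` with noise intensity
``xi``.  Substituting the pathwise OU solution into the population equations
gives a deterministic transient ``r_e + (r_0 - r_e) e^{-mu t}`` plus
multiplicative white noise with the time-varying amplitude
``sigma(t) = xi / sqrt(2 mu) * sqrt(1 - e^{-2 mu t})``; the growth rate is never
simulated as a separate state.  Emigration from the polluted patch is amplified
by a saturating (Holling type-III) response to the environmental toxicant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .toxicant import ToxicantParams, ToxicantState, ValidationError

__all__ = [
    "PatchParams",
    "MigrationParams",
    "ModelParams",
    "mean_growth",
    "sigma_t",
    "migration_rate",
    "drift_diffusion",
]


@dataclass(frozen=True)
class PatchParams:
    """Growth and competition parameters of one patch.

    r_e: asymptotic mean growth rate (per time), positive.
    r_0: initial growth rate (per time).
    mu: OU reversion speed (per time), positive.
    xi: OU noise intensity, nonnegative.
    a: intraspecific competition coefficient (per density per time), positive.
    """

    r_e: float
    r_0: float
    mu: float
    xi: float
    a: float

    def __post_init__(self) -> None:
        if self.r_e <= 0:
            raise ValidationError("r_e must be positive")
        if self.mu <= 0:
            raise ValidationError("mu must be positive")
        if self.xi < 0:
            raise ValidationError("xi must be nonnegative")
        if self.a <= 0:
            raise ValidationError("a must be positive")
        if self.r_0 < 0:
            raise ValidationError("r_0 must be nonnegative")

    @property
    def sigma_inf2(self) -> float:
        """Asymptotic noise variance xi^2 / (2 mu)."""
        return self.xi**2 / (2.0 * self.mu)


@dataclass(frozen=True)
class MigrationParams:
    """Baseline migration rates and the toxicant-driven amplification.

    d12: baseline migration rate patch 1 -> patch 2 (per time).
    d21: migration rate patch 2 -> patch 1 (per time).
    rho: toxicant-driven amplification of d12 (dimensionless).
    alpha: saturation constant of the type-III response (dimensionless).
    """

    d12: float
    d21: float
    rho: float
    alpha: float

    def __post_init__(self) -> None:
        if min(self.d12, self.d21, self.rho) < 0:
            raise ValidationError("d12, d21, rho must be nonnegative")
        if self.alpha <= 0:
            raise ValidationError("alpha must be positive")


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of the two-patch model with pulsed toxicant.

    ``delta`` is the lethality coefficient: the body burden reduces patch-1
    growth by ``delta * c_o(t)``.  Patch 2 is unpolluted.
    """

    patch1: PatchParams
    patch2: PatchParams
    migration: MigrationParams
    toxicant: ToxicantParams
    delta: float

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValidationError("delta must be nonnegative")


def mean_growth(patch: PatchParams, t) -> np.ndarray | float:
    """Deterministic part of the OU growth rate: r_e + (r_0 - r_e) e^{-mu t}."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    out = patch.r_e + (patch.r_0 - patch.r_e) * np.exp(-patch.mu * t)
    return float(out) if out.ndim == 0 else out


def sigma_t(patch: PatchParams, t) -> np.ndarray | float:
    """Time-varying noise amplitude xi/sqrt(2 mu) * sqrt(1 - e^{-2 mu t}).

    Monotone nondecreasing in t with limit xi/sqrt(2 mu).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    out = patch.xi / math.sqrt(2.0 * patch.mu) * np.sqrt(-np.expm1(-2.0 * patch.mu * t))
    return float(out) if out.ndim == 0 else out


def migration_rate(mig: MigrationParams, c_e) -> np.ndarray | float:
    """Toxicant-modulated emigration rate d12 * (1 + rho c_e^2/(1+alpha c_e^2)).

    Bounded between d12 (clean environment) and d12*(1+rho) (saturation).
    """
    c_e = np.asarray(c_e, dtype=float)
    if np.any(c_e < 0):
        raise ValueError("c_e must be nonnegative")
    ce2 = c_e**2
    out = mig.d12 * (1.0 + mig.rho * ce2 / (1.0 + mig.alpha * ce2))
    return float(out) if out.ndim == 0 else out


def drift_diffusion(
    model: ModelParams,
    t: float,
    x1,
    x2,
    tox: ToxicantState | tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Drift and diffusion vectors of the population SDE at time ``t``.

    drift_1 = x1 (r1(t) - a1 x1) + d21 x2 - d12(t) x1 with
    r1(t) = r_1e + (r_10 - r_1e) e^{-mu1 t} - delta c_o(t); patch 2 mirrors it
    without the toxicity term.  Diffusion_i = sigma_i(t) x_i.  The migration
    terms cancel in the sum of the two drifts (flux conservation).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any(x1 < 0) or np.any(x2 < 0):
        raise ValueError("densities must be nonnegative")
    c_o = tox.c_o if isinstance(tox, ToxicantState) else float(tox[0])
    c_e = tox.c_e if isinstance(tox, ToxicantState) else float(tox[1])
    p1, p2 = model.patch1, model.patch2
    r1 = mean_growth(p1, t) - model.delta * c_o
    r2 = mean_growth(p2, t)
    d12t = migration_rate(model.migration, c_e)
    d21 = model.migration.d21
    drift1 = x1 * (r1 - p1.a * x1) + d21 * x2 - d12t * x1
    drift2 = x2 * (r2 - p2.a * x2) + d12t * x1 - d21 * x2
    diff1 = sigma_t(p1, t) * x1
    diff2 = sigma_t(p2, t) * x2
    return np.asarray([drift1, drift2]), np.asarray([diff1, diff2])
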