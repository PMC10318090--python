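"""Derived constants and every analytic survival criterion."""

import math
from dataclasses import replace

import numpy as np
import pytest

from toxpatch import (
    MigrationParams,
    ModelParams,
    PatchParams,
    ToxicantParams,
    classify,
    derived_constants,
    extinction_check,
    fixture,
    mean_lower_bounds,
    noise_free_extinction,
    persistence_mean_check,
    pmoment_bound,
    stochastic_permanence_check,
    unpolluted_thresholds,
)


def _with_noise(model: ModelParams, mu: float, xi: float) -> ModelParams:
    return replace(
        model,
        patch1=replace(model.patch1, mu=mu, xi=xi),
        patch2=replace(model.patch2, mu=mu, xi=xi),
    )


class TestDerivedConstants:
    def test_set40_high_noise(self, set40a):
        c = derived_constants(set40a.model)
        assert c.sigma2 == pytest.approx(0.4, rel=1e-12)
        assert c.r1_up == pytest.approx(0.036640, abs=2e-5)
        assert c.sigma_hat2 == pytest.approx(0.8, rel=1e-12)

    def test_low_noise_sigma_hat(self, set40b):
        c = derived_constants(set40b.model)
        assert c.sigma_hat2 == pytest.approx(0.05, rel=1e-12)
        assert c.sigma2 == pytest.approx(0.025, rel=1e-12)

    def test_decoupled_toxicant_collapse(self, set40a):
        model = replace(set40a.model, delta=0.0, migration=replace(set40a.model.migration, rho=0.0))
        c = derived_constants(model)
        assert c.r1_up == c.r1_low == model.patch1.r_e
        assert c.d12_up == c.d12_low == model.migration.d12

    def test_ordering_invariants(self, set40a):
        c = derived_constants(set40a.model)
        assert c.r1_low <= c.r1_up
        assert c.d12_low <= c.d12_up
        p1, p2 = set40a.model.patch1, set40a.model.patch2
        assert c.sigma2 <= min(p1.sigma_inf2, p2.sigma_inf2) <= c.sigma_hat2


class TestExtinction:
    def test_high_noise_margin(self, set40a):
        case, margin, verdict = extinction_check(set40a.model)
        assert case == "ii"
        assert margin == pytest.approx(-0.20922, abs=2e-4)
        assert verdict

    def test_slow_reversion_margin(self):
        model = fixture("set40-fig1c").model
        case, margin, verdict = extinction_check(model)
        assert case == "ii" and verdict
        assert margin == pytest.approx(-0.05922, abs=2e-4)

    def test_pulse_schedule_margin(self):
        model = fixture("set40-fig1d").model
        c = derived_constants(model)
        assert c.r1_up - model.patch2.r_e == pytest.approx(-0.5112, abs=2e-3)
        case, margin, verdict = extinction_check(model)
        assert case == "ii" and verdict
        assert margin == pytest.approx(-0.0482, abs=2e-3)

    def test_symmetric_decoupled_reduces_to_scalar_logistic(self):
        p = PatchParams(r_e=0.1, r_0=0.1, mu=0.1, xi=0.4, a=0.1)
        model = ModelParams(
            patch1=p,
            patch2=replace(p, a=0.5),
            migration=MigrationParams(d12=0.0, d21=0.0, rho=0.0, alpha=0.2),
            toxicant=ToxicantParams(f=0.5, g=0.3, m=0.2, h=0.3, b=0.0, gamma=1.0),
            delta=0.0,
        )
        case, margin, verdict = extinction_check(model)
        assert case == "i"
        sigma2 = derived_constants(model).sigma2
        assert margin == pytest.approx(2 * 0.1 - sigma2, rel=1e-12)
        assert verdict  # sigma2 = 0.4 > 0.2

    def test_margin_decreases_with_noise(self, set40b):
        # larger xi shrinks sigma2's denominator advantage -> more extinction-prone
        margins = [
            extinction_check(_with_noise(set40b.model, 0.1, xi))[1]
            for xi in (0.05, 0.1, 0.2, 0.4)
        ]
        assert all(a > b for a, b in zip(margins, margins[1:]))

    def test_case_functionals_continuous_at_boundary(self):
        # with rho=0 and d12=d21=d the case expressions join at r1* = r2e
        tox = ToxicantParams(f=0.5, g=0.3, m=0.2, h=0.3, b=0.0, gamma=1.0)
        mig = MigrationParams(d12=0.3, d21=0.3, rho=0.0, alpha=0.2)
        p2 = PatchParams(r_e=0.2, r_0=0.2, mu=0.1, xi=0.1, a=0.5)
        margins = []
        for eps in (-1e-6, 0.0, 1e-6):
            p1 = PatchParams(r_e=0.2 + eps, r_0=0.2, mu=0.1, xi=0.1, a=0.1)
            m = ModelParams(patch1=p1, patch2=p2, migration=mig, toxicant=tox, delta=0.0)
            margins.append(extinction_check(m)[1])
        assert margins[0] == pytest.approx(margins[1], abs=1e-5)
        assert margins[2] == pytest.approx(margins[1], abs=1e-5)


class TestNoiseFreeExtinction:
    def test_fires_for_strong_pulses(self):
        model = fixture("set40-fig1d").model  # r1* = -0.361 < 0
        c = derived_constants(model)
        expected = c.r1_up < 0 and (
            c.d12_up * 0.15 + c.r1_up * 0.6 - c.r1_up * 0.15
        ) < 0
        assert noise_free_extinction(model) == expected
        assert expected  # this fixture does satisfy the criterion

    def test_positive_effective_growth_never_fires(self, set40a):
        assert derived_constants(set40a.model).r1_up > 0
        assert not noise_free_extinction(set40a.model)

    def test_no_toxicity_never_fires(self, set40a):
        assert not noise_free_extinction(replace(set40a.model, delta=0.0))


class TestStochasticPermanence:
    def test_low_noise_permanent(self, set40b):
        # min(0.3 - 0.8*c_o^M, 0.15) ~ 0.0317 > 0.025
        assert stochastic_permanence_check(set40b.model)

    def test_high_noise_not_permanent(self, set40a):
        assert not stochastic_permanence_check(set40a.model)

    def test_noiseless_clean_model_permanent(self, set40b):
        model = replace(
            _with_noise(set40b.model, 0.1, 1e-6), delta=0.0
        )
        assert stochastic_permanence_check(model)


class TestPersistenceInMean:
    def test_low_noise_margin(self, set40b):
        case, margin, verdict = persistence_mean_check(set40b.model)
        assert case == "ii" and verdict
        assert margin == pytest.approx(0.1323, abs=2e-4)

    def test_migration_rescue_margin(self):
        model = fixture("set41-fig2b").model
        c = derived_constants(model)
        assert c.r1_low - model.patch2.r_e == pytest.approx(-0.2722, abs=2e-3)
        case, margin, verdict = persistence_mean_check(model)
        assert case == "ii" and verdict
        assert margin == pytest.approx(0.2492, abs=2e-3)

    def test_symmetric_decoupled_reduction(self):
        p = PatchParams(r_e=0.2, r_0=0.2, mu=0.1, xi=0.1, a=0.1)
        model = ModelParams(
            patch1=p,
            patch2=replace(p, a=0.5),
            migration=MigrationParams(d12=0.0, d21=0.0, rho=0.0, alpha=0.2),
            toxicant=ToxicantParams(f=0.5, g=0.3, m=0.2, h=0.3, b=0.0, gamma=1.0),
            delta=0.0,
        )
        case, margin, _ = persistence_mean_check(model)
        assert case == "i"
        assert margin == pytest.approx(2 * 0.2 - 0.05, rel=1e-12)

    def test_margin_decreases_with_noise(self, set40b):
        margins = [
            persistence_mean_check(_with_noise(set40b.model, 0.1, xi))[1]
            for xi in (0.05, 0.1, 0.2)
        ]
        assert all(a > b for a, b in zip(margins, margins[1:]))

    def test_rho_zero_collapse_uses_plain_migration_rate(self, set40b):
        model = replace(set40b.model, migration=replace(set40b.model.migration, rho=0.0))
        c = derived_constants(model)
        d12, d21 = 0.5, 0.6
        r1l, r2e = c.r1_low, model.patch2.r_e
        expected = (
            (r1l + r2e - d12 - d21)
            + math.sqrt((r1l - r2e + d21 - d12) ** 2 + 4 * d12 * d21)
            - c.sigma_hat2
        )
        assert persistence_mean_check(model)[1] == pytest.approx(expected, rel=1e-12)


class TestMeanLowerBounds:
    def test_positive_bound_variant(self, set40b):
        model = replace(
            set40b.model, patch1=replace(set40b.model.patch1, r_e=0.8), delta=0.2
        )
        b1, b2, applicable = mean_lower_bounds(model)
        assert b1 == pytest.approx(1.6768, abs=2e-3)
        assert not applicable  # d21=0.6 >= r2e=0.15 on this fixture

    def test_inapplicable_when_return_migration_dominates(self, set40b):
        _, _, applicable = mean_lower_bounds(set40b.model)
        assert not applicable

    def test_logistic_level_when_decoupled(self):
        p1 = PatchParams(r_e=0.3, r_0=0.3, mu=0.1, xi=0.1, a=0.1)
        p2 = PatchParams(r_e=0.15, r_0=0.15, mu=0.1, xi=0.1, a=0.5)
        model = ModelParams(
            patch1=p1,
            patch2=p2,
            migration=MigrationParams(d12=0.0, d21=0.0, rho=0.0, alpha=0.2),
            toxicant=ToxicantParams(f=0.5, g=0.3, m=0.2, h=0.3, b=0.0, gamma=1.0),
            delta=0.0,
        )
        b1, b2, applicable = mean_lower_bounds(model)
        assert applicable
        assert b1 == pytest.approx(3.0) and b2 == pytest.approx(0.3)


class TestPMomentBound:
    def test_second_moment_fixture(self, set40b):
        assert pmoment_bound(set40b.model, 2.0) == pytest.approx(342.25, rel=1e-9)

    def test_noiseless_limit(self, set40b):
        model = _with_noise(set40b.model, 0.1, 0.0)
        expected = (2 * max(0.9, 0.45) / 0.1) ** 2
        assert pmoment_bound(model, 2.0) == pytest.approx(expected, rel=1e-12)

    def test_exponent_must_exceed_one(self, set40b):
        with pytest.raises(ValueError):
            pmoment_bound(set40b.model, 1.0)


class TestUnpolluted:
    def test_expression_value(self, set40a):
        ext, per, ext_v, per_v = unpolluted_thresholds(set40a.model)
        expr = -0.65 + math.sqrt(0.0625 + 1.2)
        assert ext == pytest.approx(expr - 0.4, abs=1e-6)
        assert not ext_v  # 0.4736 > sigma^2 = 0.4

    def test_decoupled_collapse(self):
        p1 = PatchParams(r_e=0.3, r_0=0.3, mu=0.1, xi=0.1, a=0.1)
        p2 = PatchParams(r_e=0.15, r_0=0.15, mu=0.1, xi=0.1, a=0.5)
        model = ModelParams(
            patch1=p1,
            patch2=p2,
            migration=MigrationParams(d12=0.0, d21=0.0, rho=0.0, alpha=0.2),
            toxicant=ToxicantParams(f=0.5, g=0.3, m=0.2, h=0.3, b=0.0, gamma=1.0),
            delta=0.0,
        )
        ext, per, _, _ = unpolluted_thresholds(model)
        assert ext + derived_constants(model).sigma2 == pytest.approx(2 * 0.3, rel=1e-12)

    def test_symmetric_collapse(self):
        p = PatchParams(r_e=0.2, r_0=0.2, mu=0.1, xi=0.1, a=0.1)
        model = ModelParams(
            patch1=p,
            patch2=p,
            migration=MigrationParams(d12=0.3, d21=0.3, rho=0.0, alpha=0.2),
            toxicant=ToxicantParams(f=0.5, g=0.3, m=0.2, h=0.3, b=0.0, gamma=1.0),
            delta=0.0,
        )
        ext, _, _, _ = unpolluted_thresholds(model)
        assert ext + derived_constants(model).sigma2 == pytest.approx(2 * 0.2, rel=1e-12)


class TestClassify:
    def test_high_noise_verdict_is_extinction(self, set40a):
        rep = classify(set40a.model)
        assert rep.summary.startswith("extinction")
        assert rep.extinction_case == "ii"

    def test_low_noise_verdict_includes_persistence(self, set40b):
        rep = classify(set40b.model)
        assert "persistent in mean" in rep.summary

    def test_inconclusive_when_nothing_fires(self):
        # asymmetric noise: sigma^2 = 0.047 < 2r = 0.4 < sigma_hat^2 = 0.8,
        # so neither the extinction nor the persistence criterion can decide
        p1 = PatchParams(r_e=0.2, r_0=0.2, mu=0.1, xi=0.4, a=0.1)
        p2 = PatchParams(r_e=0.2, r_0=0.2, mu=0.1, xi=0.1, a=0.5)
        model = ModelParams(
            patch1=p1,
            patch2=p2,
            migration=MigrationParams(d12=0.0, d21=0.0, rho=0.0, alpha=0.2),
            toxicant=ToxicantParams(f=0.5, g=0.3, m=0.2, h=0.3, b=0.0, gamma=1.0),
            delta=0.0,
        )
        rep = classify(model)
        assert rep.summary == "inconclusive"
        assert not rep.extinction_verdict and not rep.persistence_verdict

    def test_report_round_trips_to_dict(self, set40a):
        d = classify(set40a.model).to_dict()
        assert isinstance(d["constants"]["sigma2"], float)
        assert d["extinction_verdict"] is True
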