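"""Growth-increment likelihood, fitting and model selection."""

import dataclasses
from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reefshark.growth import (
    FrancisFit,
    FrancisParams,
    compare_models,
    expected_increment,
    fit,
    neg_log_likelihood,
    residual_diagnostics,
    seasonal_time,
    to_vbgf,
)
from reefshark.simulate import SyntheticTruth, simulate_increments
from reefshark.tagging import DAYS_PER_YEAR, IncrementDataset, TagRecord

from .conftest import make_record

BEST = FrancisParams(g_alpha=3.33, g_beta=1.75)


class TestSeasonalTime:
    def test_no_seasonality_is_identity(self):
        t = np.linspace(0, 10, 7)
        assert np.allclose(seasonal_time(t, 0.0, 0.3), t)

    def test_quarter_phase(self):
        # sine at quarter phase: t' = t + u / (2 pi)
        assert seasonal_time(0.25, 1.0, 0.0) == pytest.approx(0.25 + 1 / (2 * np.pi))

    @given(
        t=st.floats(0, 50),
        u=st.floats(0, 1),
        w=st.floats(0, 1),
        years=st.integers(1, 10),
    )
    def test_whole_year_increments_unaffected(self, t, u, w, years):
        d1 = seasonal_time(t + years, u, w) - seasonal_time(t, u, w)
        assert d1 == pytest.approx(years, abs=1e-9)


class TestExpectedIncrement:
    def test_reference_length_definitions(self):
        assert expected_increment(100.0, 1.0, BEST) == pytest.approx(3.33, abs=1e-9)
        assert expected_increment(130.0, 1.0, BEST) == pytest.approx(1.75, abs=1e-9)

    def test_zero_growth_at_asymptote(self):
        vb = to_vbgf(BEST)
        for dt in (0.5, 1.0, 5.0):
            assert expected_increment(vb.l_inf, dt, BEST) == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_equal_increments(self):
        with pytest.raises(ValueError, match="degenerate|g_alpha"):
            expected_increment(100.0, 1.0, FrancisParams(g_alpha=2.0, g_beta=2.0))

    @given(
        ga=st.floats(1.0, 8.0),
        ratio=st.floats(0.1, 0.9),
        alpha=st.floats(80, 110),
        span=st.floats(10, 60),
    )
    def test_conversion_consistency(self, ga, ratio, alpha, span):
        """Converting to (L_inf, k) and back gives g_alpha, g_beta exactly."""
        p = FrancisParams(g_alpha=ga, g_beta=ga * ratio, alpha=alpha, beta=alpha + span)
        assert expected_increment(alpha, 1.0, p) == pytest.approx(ga, abs=1e-9)
        assert expected_increment(alpha + span, 1.0, p) == pytest.approx(ga * ratio, abs=1e-9)


class TestToVBGF:
    def test_best_model_conversion(self):
        vb = to_vbgf(BEST)
        assert vb.l_inf == pytest.approx(163.3, rel=0.01)
        assert vb.k == pytest.approx(0.054, rel=0.01)

    def test_simplest_model_conversion(self):
        vb = to_vbgf(FrancisParams(g_alpha=3.46, g_beta=1.75))
        assert vb.l_inf == pytest.approx(160.71, abs=0.05)
        assert vb.k == pytest.approx(0.059, abs=0.001)

    def test_equal_increment_limit_k_to_zero(self):
        k = [to_vbgf(FrancisParams(g_alpha=2.0, g_beta=2.0 - e)).k for e in (1e-3, 1e-6)]
        assert k[1] < k[0] < 1e-4

    def test_reversed_order_refused(self):
        with pytest.raises(ValueError, match="g_alpha > g_beta"):
            to_vbgf(FrancisParams(g_alpha=1.0, g_beta=2.0))


def _single_record_dataset(increment, dt_years=1.0, tl1=100.0):
    days = int(round(dt_years * DAYS_PER_YEAR))
    return IncrementDataset.from_records(
        [make_record("x", tl1=tl1, tl2=tl1 + increment, days=days)]
    )


class TestLikelihood:
    def test_standard_normal_mode_density(self):
        p = BEST.with_values(s=1.0, m=0.5)
        dt = 365 / DAYS_PER_YEAR  # elapsed time of a 365-day record
        mu = expected_increment(100.0, dt, p)
        ds = _single_record_dataset(mu + 0.5, dt_years=dt)
        assert neg_log_likelihood(ds, p) == pytest.approx(np.log(np.sqrt(2 * np.pi)), abs=1e-9)

    def test_pure_outlier_component(self, s1_dataset):
        p = BEST.with_values(p=1.0)
        R = float(np.ptp(s1_dataset.increments))
        assert neg_log_likelihood(s1_dataset, p) == pytest.approx(len(s1_dataset) * np.log(R))

    def test_zero_spread_names_record(self):
        ds = _single_record_dataset(5.0)
        with pytest.raises(ValueError, match="x"):
            neg_log_likelihood(ds, BEST)  # nu = s = 0: zero density off the mode

    def test_nesting_monotonicity(self, s1_dataset):
        """Freeing a frozen parameter can only improve the optimum."""
        simple = fit(s1_dataset, free=("g_alpha", "g_beta", "s"), seed=0, n_starts=2)
        richer = fit(s1_dataset, free=("g_alpha", "g_beta", "nu", "s"), seed=0, n_starts=2)
        richest = fit(s1_dataset, free=("g_alpha", "g_beta", "nu", "s", "m"), seed=0, n_starts=2)
        assert richer.loglik >= simple.loglik - 1e-6
        assert richest.loglik >= richer.loglik - 1e-6


def _noise_free_dataset(params, n=30):
    start = date(2008, 1, 1)
    records = []
    rng = np.random.default_rng(5)
    for i in range(n):
        tl1 = rng.uniform(80, 150)
        dt_days = int(rng.integers(200, 2000))
        dt = dt_days / DAYS_PER_YEAR
        tl2 = tl1 + expected_increment(tl1, dt, params)
        records.append(
            TagRecord(
                individual_id=f"n{i}",
                sex="female",
                release_date=start,
                release_tl=tl1,
                recapture_date=start + timedelta(days=dt_days),
                recapture_tl=tl2,
            )
        )
    return IncrementDataset.from_records(records)


class TestFit:
    def test_noise_free_exact_recovery(self):
        ds = _noise_free_dataset(BEST)
        f = fit(ds, free=("g_alpha", "g_beta"), fixed={"s": 0.5}, seed=0, n_starts=3)
        assert f.params.g_alpha == pytest.approx(3.33, abs=1e-4)
        assert f.params.g_beta == pytest.approx(1.75, abs=1e-4)

    def test_parameter_recovery_within_2se(self, default_truth):
        ds = simulate_increments(default_truth, 118, seed=42)
        f = fit(ds, free=("g_alpha", "g_beta", "nu", "s"), seed=0, n_starts=3)
        for name, truth in (("g_alpha", 3.33), ("g_beta", 1.75), ("s", 2.87)):
            se = f.se[name]
            assert abs(getattr(f.params, name) - truth) < 2 * se, name

    def test_reference_length_insensitivity(self, s1_dataset):
        """Reference lengths only relabel the curve: derived (L_inf, k) from
        fits at (100, 130) and at shifted references must agree."""
        base = fit(s1_dataset, free=("g_alpha", "g_beta", "nu", "s"), seed=0, n_starts=2)
        alt = fit(
            s1_dataset,
            free=("g_alpha", "g_beta", "nu", "s"),
            alpha=95.0,
            beta=145.0,
            seed=0,
            n_starts=2,
        )
        assert alt.vbgf.l_inf == pytest.approx(base.vbgf.l_inf, rel=0.01)
        assert alt.vbgf.k == pytest.approx(base.vbgf.k, rel=0.02)
        assert alt.loglik == pytest.approx(base.loglik, abs=0.05)

    def test_male_only_refused_when_scarce(self, s1_dataset):
        with pytest.raises(ValueError, match="male-only"):
            fit(s1_dataset, sex="male")

    def test_requires_reference_increments_free(self, s1_dataset):
        with pytest.raises(ValueError, match="must be free"):
            fit(s1_dataset, free=("g_alpha", "nu"))


def _fake_fit(free, loglik, aic, key=("k",)):
    params = FrancisParams(g_alpha=3.3, g_beta=1.7)
    return FrancisFit(
        params=params,
        se={},
        loglik=loglik,
        aic=aic,
        n=118,
        free=tuple(free),
        vbgf=to_vbgf(params),
        residuals=np.zeros(1),
        expected=np.zeros(1),
        release_tl=np.zeros(1),
        converged=True,
        data_key=key,
    )


class TestModelSelection:
    def test_growth_variability_model_preferred(self):
        # reported model 1 vs model 2 (both sexes): gain 24.7 >> 1.92
        m1 = _fake_fit(("g_alpha", "g_beta", "s"), -334.9, 675.8)
        m2 = _fake_fit(("g_alpha", "g_beta", "nu", "s"), -310.2, 628.3)
        rep = compare_models([m1, m2])
        pair = rep["lrt_pairs"][0]
        assert pair["loglik_gain"] == pytest.approx(24.7)
        assert pair["richer_preferred"]
        assert rep["best_index"] == 1

    def test_small_aic_gain_rejected(self):
        m2 = _fake_fit(("g_alpha", "g_beta", "nu", "s"), -310.2, 628.3)
        m4 = _fake_fit(("g_alpha", "g_beta", "nu", "s", "m", "p"), -309.2, 630.3)
        rep = compare_models([m2, m4])
        assert rep["table"][1]["delta_aic"] == pytest.approx(2.0)
        assert rep["best_index"] == 0  # gain 1.0 < 3.0 for two extra params

    def test_identical_fits_no_preference(self):
        m = _fake_fit(("g_alpha", "g_beta", "s"), -300.0, 606.0)
        rep = compare_models([m, m])
        assert rep["best_index"] == 0 and not rep["lrt_pairs"]

    def test_different_data_rejected(self):
        a = _fake_fit(("g_alpha", "g_beta", "s"), -300.0, 606.0, key=("a",))
        b = _fake_fit(("g_alpha", "g_beta", "nu", "s"), -290.0, 588.0, key=("b",))
        with pytest.raises(ValueError, match="identical"):
            compare_models([a, b])


class TestResidualDiagnostics:
    def test_growth_variability_signature(self, default_truth):
        ds = simulate_increments(default_truth, 400, seed=7)
        f = fit(ds, free=("g_alpha", "g_beta", "nu", "s"), seed=0, n_starts=2)
        d = residual_diagnostics(f)
        assert d["rho_absresid_predicted"] > 0  # spread grows with expected growth

    def test_homoskedastic_control(self):
        truth = SyntheticTruth(growth=FrancisParams(g_alpha=3.33, g_beta=1.75, nu=0.0, s=3.0))
        ds = simulate_increments(truth, 400, seed=8)
        f = fit(ds, free=("g_alpha", "g_beta", "s"), seed=0, n_starts=2)
        d = residual_diagnostics(f)
        assert abs(d["rho_absresid_predicted"]) < 0.15

    def test_zero_noise_zero_residuals(self):
        ds = _noise_free_dataset(BEST)
        f = fit(ds, free=("g_alpha", "g_beta"), fixed={"s": 0.5}, seed=0, n_starts=2)
        assert np.allclose(f.residuals, 0.0, atol=1e-3)
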