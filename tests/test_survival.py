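"""Capture-history construction, the Jolly-Seber sampler, convergence stats."""

import numpy as np
import pandas as pd
import pytest

from reefshark.simulate import SurvivalTruth, SyntheticTruth, simulate_capture_histories
from reefshark.survival import (
    CaptureHistoryMatrix,
    JSModelConfig,
    build_histories,
    fit_js,
    gelman_rubin,
    survival_to_mortality,
)

YEARS = tuple(range(2006, 2015))


def small_cfg(seed=1, **kw):
    defaults = dict(seed=seed, chains=2, iterations=1500, burn_in=300, augment_factor=3)
    defaults.update(kw)
    return JSModelConfig(**defaults)


class TestBuildHistories:
    def test_direct_binning(self):
        ev = pd.DataFrame({"individual_id": ["s1", "s1"], "date": ["2006-03-01", "2009-07-12"]})
        chm = build_histories(ev, YEARS)
        assert "".join(map(str, chm.y[0])) == "100100000"

    def test_within_year_collapse(self):
        ev = pd.DataFrame({"individual_id": ["s1", "s1"], "date": ["2007-03-01", "2007-11-30"]})
        chm = build_histories(ev, YEARS)
        assert chm.y.sum() == 1

    def test_event_outside_span_rejected(self):
        ev = pd.DataFrame({"individual_id": ["s1"], "date": ["2016-01-01"]})
        with pytest.raises(ValueError, match="outside"):
            build_histories(ev, YEARS)

    def test_round_trip_with_simulator_truth(self, default_truth):
        chm, truth = simulate_capture_histories(default_truth, seed=11)
        # rebuild from an event log and compare to the simulator's matrix
        rows = []
        for i, iid in enumerate(chm.individual_ids):
            for j in np.flatnonzero(chm.y[i]):
                rows.append({"individual_id": iid, "date": chm.occasion_dates[j]})
        rebuilt = build_histories(pd.DataFrame(rows), chm.occasion_dates)
        assert np.array_equal(rebuilt.y, chm.y)
        assert np.array_equal(chm.y, truth["y_full"][truth["detected"]])


class TestCaptureHistoryMatrix:
    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="at least one detection"):
            CaptureHistoryMatrix(y=np.zeros((2, 4), dtype=int), occasion_dates=(1, 2, 3, 4))

    def test_occasions_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            CaptureHistoryMatrix(y=np.ones((1, 2), dtype=int), occasion_dates=(2008, 2008))


class TestSurvivalToMortality:
    def test_reported_survival(self):
        annual, z = survival_to_mortality(0.739)
        assert annual == pytest.approx(0.261)
        assert z == pytest.approx(-np.log(0.739))

    def test_certain_survival(self):
        assert survival_to_mortality(1.0) == (0.0, 0.0)

    def test_unit_instantaneous_rate(self):
        _, z = survival_to_mortality(np.exp(-1.0))
        assert z == pytest.approx(1.0)

    def test_zero_survival_rejected(self):
        with pytest.raises(ValueError):
            survival_to_mortality(0.0)


class TestGelmanRubin:
    def test_identical_chains_near_one(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=500)
        assert gelman_rubin(np.stack([chain, chain])) == pytest.approx(1.0, abs=0.01)

    def test_divergent_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert gelman_rubin(chains) > 1.1

    def test_iid_chains_converge(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(4, 20_000))
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestFitJS:
    @pytest.fixture(scope="class")
    def small_study(self):
        truth = SyntheticTruth(
            survival=SurvivalTruth(phi=0.7, p_detect=0.5, n_occasions=6, superpopulation=300)
        )
        chm, latent = simulate_capture_histories(truth, seed=3)
        return truth, chm, latent

    @pytest.fixture(scope="class")
    def posterior(self, small_study):
        _, chm, _ = small_study
        return fit_js(chm, small_cfg())

    def test_recovers_survival(self, small_study, posterior):
        # smoke-level recovery on one small study; calibrated coverage over
        # many replicates is asserted in the acceptance suite
        truth, _, _ = small_study
        assert abs(posterior.mean("phi") - truth.survival.phi) < 0.15
        assert posterior.summary.loc["phi", "rhat"] < 1.1

    def test_probabilities_and_rhat_reported(self, posterior):
        for name, arr in posterior.draws.items():
            assert np.all((arr >= 0) & (arr <= 1)) or name == "N_super"
        assert posterior.summary["rhat"].notna().all()

    def test_no_reentry_after_death(self, posterior):
        z = posterior.z_sample
        for row in z:
            alive = np.flatnonzero(row == 1)
            if alive.size:
                # alive occasions are contiguous: entry once, death absorbing
                assert np.all(np.diff(alive) == 1)
                assert not np.any(row[: alive[0]] == 2)

    def test_perfect_detection_matches_empirical_survival(self):
        truth = SyntheticTruth(
            survival=SurvivalTruth(phi=0.75, p_detect=1.0, n_occasions=6, superpopulation=400)
        )
        chm, latent = simulate_capture_histories(truth, seed=4)
        z = latent["z"]
        at = z[:, :-1] == 1
        empirical = (at & (z[:, 1:] == 1)).sum() / at.sum()
        post = fit_js(chm, small_cfg(seed=5))
        assert post.mean("phi") == pytest.approx(empirical, abs=0.03)

    def test_prior_predictive_flat_survival(self):
        # with detection pinned at 0 the all-zero histories carry no
        # information, so the survival posterior must return its U(0,1) prior
        chm = CaptureHistoryMatrix(y=np.zeros((0, 5), dtype=int), occasion_dates=tuple(range(5)))
        post = fit_js(chm, small_cfg(seed=6, iterations=3000, burn_in=500, fix_p=0.0),
                      allow_no_observations=True)
        assert post.mean("phi") == pytest.approx(0.5, abs=0.08)
        assert post.draws["phi"].std() == pytest.approx(np.sqrt(1 / 12), abs=0.05)

    def test_degenerate_inputs_rejected(self, small_study):
        _, chm, _ = small_study
        with pytest.raises(ValueError, match="no observed"):
            fit_js(
                CaptureHistoryMatrix(y=np.zeros((0, 5), dtype=int), occasion_dates=tuple(range(5))),
                small_cfg(),
            )
        with pytest.raises(ValueError, match="occasions"):
            fit_js(
                CaptureHistoryMatrix(y=np.ones((25, 2), dtype=int), occasion_dates=(2006, 2007)),
                small_cfg(),
            )

    def test_matches_enumerated_posterior_on_tiny_problem(self):
        """Posterior mean of phi against an exact oracle.

        For two observed histories (100, 011) plus two augmented zero rows
        over three occasions, the posterior mean of survival under U(0,1)
        priors is 0.52545, computed by enumerating every latent trajectory
        combination and integrating the Beta terms analytically.
        """
        chm = CaptureHistoryMatrix(
            y=np.array([[1, 0, 0], [0, 1, 1]], dtype=np.int8), occasion_dates=(1, 2, 3)
        )
        post = fit_js(
            chm,
            JSModelConfig(seed=3, chains=3, iterations=20000, burn_in=4000, augment_factor=1.0),
            allow_no_observations=True,
        )
        assert post.mean("phi") == pytest.approx(0.52545, abs=0.01)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="burn_in"):
            JSModelConfig(seed=1, iterations=100, burn_in=100)
        with pytest.raises(ValueError, match="augment"):
            JSModelConfig(seed=1, augment_factor=0.5)
        with pytest.raises(ValueError, match="seed"):
            JSModelConfig(seed=None)
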