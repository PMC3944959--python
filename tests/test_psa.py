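"""Probabilistic sensitivity analysis: distributions, Monte Carlo, CEAC."""

import numpy as np
import pandas as pd
import pytest

from eyecare_cea.markov import CataractParams, RefractionParams, run_cataract_model
from eyecare_cea.psa import (
    CEAC,
    PSAResult,
    ParamDistribution,
    beta_from_moments,
    ceac,
    default_threshold_grid,
    gamma_from_moments,
    probability_cost_effective,
    run_cataract_psa,
    run_refraction_psa,
    summarize_psa,
)


class TestMethodOfMoments:
    def test_symmetric_uniform(self):
        # nu = 2 -> alpha = beta = 1
        se = np.sqrt(0.5 * 0.5 / 3.0)
        a, b = beta_from_moments(0.5, se)
        assert a == pytest.approx(1.0) and b == pytest.approx(1.0)

    def test_baseline_utility_shapes(self):
        a, b = beta_from_moments(0.782, 0.017)
        assert a == pytest.approx(460.5, abs=0.5)
        assert b == pytest.approx(128.4, abs=0.5)
        # round-trip implied moments
        assert a / (a + b) == pytest.approx(0.782, abs=1e-12)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert np.sqrt(var) == pytest.approx(0.017, abs=1e-12)

    def test_infeasible_beta_se_rejected(self):
        with pytest.raises(ValueError, match="se"):
            beta_from_moments(0.5, 0.6)

    @pytest.mark.parametrize(
        "mean,se,shape,scale",
        [(1, 1, 1.0, 1.0), (92, 3.4, 732.2, 0.1256), (72, 7.8, 85.2, 0.845)],
    )
    def test_gamma_shapes(self, mean, se, shape, scale):
        got_shape, got_scale = gamma_from_moments(mean, se)
        assert got_shape == pytest.approx(shape, rel=1e-3)
        assert got_scale == pytest.approx(scale, rel=1e-3)
        assert got_shape * got_scale == pytest.approx(mean, abs=1e-12)

    def test_gamma_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            gamma_from_moments(0, 1)

    @pytest.mark.parametrize(
        "family,mean,se",
        [("beta", 0.782, 0.017), ("beta", 0.04, 0.01), ("gamma", 92, 3.4)],
    )
    def test_sampling_round_trip(self, family, mean, se):
        """1e5 draws from the fitted distribution recover the target mean
        and SD within 3 Monte Carlo standard errors."""
        n = 100_000
        rng = np.random.default_rng(11)
        draws = ParamDistribution("x", family, mean, se).sample(rng, n)
        assert draws.mean() == pytest.approx(mean, abs=3 * se / np.sqrt(n))
        # SE of the sample SD ~ sd / sqrt(2n) for near-normal shapes
        assert draws.std(ddof=1) == pytest.approx(se, abs=4 * se / np.sqrt(2 * n))


class TestMonteCarlo:
    def test_all_fixed_reduces_to_deterministic(self, calibrated_life_table):
        params = CataractParams(life_table=calibrated_life_table)
        det = run_cataract_model(params)
        fixed = {
            name: ParamDistribution(name, "fixed", mean)
            for name, mean in [
                ("cost", 92.0), ("u_base", 0.782), ("u_post", 0.832),
                ("p_deteriorate", 0.04),
            ]
        }
        res = run_cataract_psa(params, n_iter=5, seed=0, distributions=fixed)
        assert np.allclose(res.inc_cost, det.inc_cost)
        assert np.allclose(res.inc_qaly, det.inc_qalys, atol=1e-12)

    def test_mean_incremental_cost_recovers_pooled_mean(self, calibrated_life_table):
        res = run_cataract_psa(
            CataractParams(life_table=calibrated_life_table), n_iter=10_000, seed=2
        )
        assert res.inc_cost.mean() == pytest.approx(92.0, abs=1.0)

    def test_seed_determinism_bit_identical(self, calibrated_life_table):
        params = CataractParams(life_table=calibrated_life_table)
        a = run_cataract_psa(params, n_iter=500, seed=9)
        b = run_cataract_psa(params, n_iter=500, seed=9)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        c = run_cataract_psa(params, n_iter=500, seed=10)
        assert not a.draws["inc_qaly"].equals(c.draws["inc_qaly"])

    def test_single_iteration(self, calibrated_life_table):
        res = run_cataract_psa(
            CataractParams(life_table=calibrated_life_table), n_iter=1, seed=3
        )
        assert len(res.draws) == 1

    def test_refraction_schedule_endpoint_pinned_per_draw(self, calibrated_life_table):
        """Drawn first-cycle loss probabilities vary but every iteration's
        schedule still ends at the fixed 90% final-cycle value."""
        params = RefractionParams(life_table=calibrated_life_table)
        res = run_refraction_psa(params, n_iter=200, seed=4)
        p1 = res.draws["loss_p1"].to_numpy()
        assert p1.std() > 0
        assert np.all((p1 > 0) & (p1 < 1))

    def test_mean_increments_converge_to_deterministic(self, calibrated_life_table):
        """The model is nearly linear in its parameters, so PSA means
        approach the deterministic increments at large n."""
        params = CataractParams(life_table=calibrated_life_table)
        det = run_cataract_model(params)
        res = run_cataract_psa(params, n_iter=100_000, seed=5)
        assert res.inc_qaly.mean() == pytest.approx(det.inc_qalys, abs=0.01)
        assert res.inc_cost.mean() == pytest.approx(det.inc_cost, abs=0.5)


class TestCeac:
    def _degenerate(self, inc_cost, inc_qaly, n=100):
        df = pd.DataFrame(
            {
                "iteration": np.arange(1, n + 1),
                "comparator_cost": 0.0,
                "comparator_qalys": 1.0,
                "intervention_cost": inc_cost,
                "intervention_qalys": 1.0 + inc_qaly,
                "inc_cost": inc_cost,
                "inc_qaly": inc_qaly,
            }
        )
        return PSAResult(draws=df, n_iter=n, seed=0, intervention="toy")

    def test_step_at_icer(self):
        res = self._degenerate(92.0, 92.0 / 259.0)
        curve = ceac(res, thresholds=[0, 258, 260, 2000])
        assert list(curve.probability) == [0.0, 0.0, 1.0, 1.0]

    def test_zero_threshold_with_positive_costs(self):
        res = self._degenerate(10.0, 0.5)
        assert ceac(res, thresholds=[0.0]).probability[0] == 0.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ceac(self._degenerate(1.0, 0.1), thresholds=[])

    def test_default_grid_contains_gni_benchmark(self):
        grid = default_threshold_grid()
        assert np.any(np.isclose(grid, 1160.0))
        assert grid[0] == 0.0 and grid[-1] == 2000.0

    def test_monotone_when_all_gains_positive(self, calibrated_life_table):
        res = run_cataract_psa(
            CataractParams(life_table=calibrated_life_table), n_iter=2000, seed=6
        )
        keep = res.inc_qaly > 0
        df = res.draws[keep].reset_index(drop=True)
        sub = PSAResult(draws=df, n_iter=int(keep.sum()), seed=6, intervention="cataract")
        curve = ceac(sub)
        assert np.all(np.diff(curve.probability) >= 0)

    def test_limit_at_large_threshold(self, calibrated_life_table):
        res = run_cataract_psa(
            CataractParams(life_table=calibrated_life_table), n_iter=2000, seed=7
        )
        p_inf = ceac(res, thresholds=[1e9]).probability[0]
        assert p_inf == pytest.approx((res.inc_qaly > 0).mean(), abs=1e-9)


class TestSummary:
    def test_two_iteration_hand_averages(self):
        df = pd.DataFrame(
            {
                "iteration": [1, 2],
                "comparator_cost": [0.0, 0.0],
                "comparator_qalys": [7.0, 8.0],
                "intervention_cost": [90.0, 94.0],
                "intervention_qalys": [7.3, 8.5],
                "inc_cost": [90.0, 94.0],
                "inc_qaly": [0.3, 0.5],
            }
        )
        res = PSAResult(draws=df, n_iter=2, seed=0, intervention="toy")
        s = summarize_psa(res)
        assert s["inc_cost"] == pytest.approx(92.0)
        assert s["inc_qaly"] == pytest.approx(0.4)
        assert s["icer"] == pytest.approx(92.0 / 0.4)
        s2 = summarize_psa(res, mean_of_ratios=True)
        assert s2["icer"] == pytest.approx((300 + 188) / 2.0)

    def test_probabilistic_summary_near_published_values(self, calibrated_life_table):
        res = run_cataract_psa(
            CataractParams(life_table=calibrated_life_table), n_iter=10_000, seed=8
        )
        s = summarize_psa(res)
        assert s["inc_qaly"] == pytest.approx(0.356, abs=0.02)
        assert s["inc_cost"] == pytest.approx(92.0, abs=1.0)
        assert probability_cost_effective(res) == pytest.approx(0.95, abs=0.03)
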