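"""State-transition engine: schedules, traces, oracles, ICERs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eyecare_cea.life_tables import LifeTable, flat_life_table
from eyecare_cea.markov import (
    CataractParams,
    RefractionParams,
    compute_icer,
    loss_probability,
    run_arm,
    run_cataract_model,
    run_refraction_model,
)


def enumerate_paths_oracle(qx, u_T, u_D, p_td, rate, start_in_T):
    """Brute-force oracle: enumerate every state path over the horizon.

    States: 0=T, 1=D, 2=M. Within cycle t: die with probability qx[t-1]
    (accruing nothing), otherwise accrue the utility of the state held
    during the cycle discounted at (1+rate)^-t, then apply the T->D
    transition. Returns expected discounted QALYs.
    """
    H = len(qx)
    total = 0.0
    stack = [(0 if start_in_T else 1, 1, 1.0, 0.0)]  # (state, cycle, prob, qalys)
    while stack:
        state, t, prob, qalys = stack.pop()
        if t > H or state == 2:
            total += prob * qalys
            continue
        q = qx[t - 1]
        # death during cycle t
        if state in (0, 1) and q > 0:
            stack.append((2, t + 1, prob * q, qalys))
        survive = prob * (1 - q)
        if survive > 0:
            disc = (1 + rate) ** (-t)
            if state == 0:
                accrued = qalys + disc * u_T
                p = p_td(t) if callable(p_td) else p_td
                if p > 0:
                    stack.append((1, t + 1, survive * p, accrued))
                if p < 1:
                    stack.append((0, t + 1, survive * (1 - p), accrued))
            else:
                stack.append((1, t + 1, survive, qalys + disc * u_D))
    return total


class TestLossSchedule:
    def test_endpoints_pinned(self):
        p = RefractionParams(life_table=flat_life_table(0.0))
        assert loss_probability(1, p) == pytest.approx(0.05)
        assert loss_probability(5, p) == pytest.approx(0.90)

    def test_geometric_midpoint(self):
        p = RefractionParams(life_table=flat_life_table(0.0))
        assert loss_probability(3, p) == pytest.approx(0.05 * 18**0.5, abs=1e-4)
        assert loss_probability(3, p) == pytest.approx(0.2121, abs=1e-4)

    def test_out_of_range_cycle_rejected(self):
        p = RefractionParams(life_table=flat_life_table(0.0))
        with pytest.raises(ValueError, match="cycle"):
            loss_probability(6, p)

    def test_cumulative_reading_reconstructs_curve(self):
        p = RefractionParams(life_table=flat_life_table(0.0), cumulative_schedule=True)
        # surviving-in-T fraction after cycle t equals 1 - cumulative curve
        remaining = 1.0
        for t in range(1, 6):
            remaining *= 1.0 - loss_probability(t, p)
            curve = 0.05 * (0.90 / 0.05) ** ((t - 1) / 4)
            assert remaining == pytest.approx(1.0 - curve, abs=1e-12)


class TestCataractModel:
    def test_no_mortality_no_deterioration_closed_form(self):
        lt = flat_life_table(0.0, terminal_age=20)
        params = CataractParams(
            life_table=lt, p_deteriorate=0.0, discount_rate=0.0, start_age=0
        )
        res = run_cataract_model(params)
        H = 21  # ages 0..20 inclusive; final cycle extinguishes the cohort
        # everyone survives until the terminal cycle, then dies
        assert res.inc_qalys == pytest.approx((0.832 - 0.782) * (H - 1), abs=1e-10)

    def test_discounted_closed_form_limit(self):
        lt = flat_life_table(0.0, terminal_age=30)
        params = CataractParams(
            life_table=lt, p_deteriorate=0.0, discount_rate=0.03, start_age=0
        )
        res = run_cataract_model(params)
        annuity = sum(1.03 ** (-t) for t in range(1, 31))
        assert res.inc_qalys == pytest.approx(0.05 * annuity, abs=1e-10)

    def test_comparator_reproduces_published_lifetime_qalys(self, calibrated_life_table):
        res = run_cataract_model(CataractParams(life_table=calibrated_life_table))
        assert res.comparator.qalys == pytest.approx(7.519, abs=1e-3)
        assert res.comparator.cost == 0.0
        assert res.intervention.cost == pytest.approx(92.0)

    def test_three_cycle_toy_against_path_enumeration(self):
        qx = [0.1, 0.1, 0.1]
        lt = LifeTable(np.array([0, 1, 2, 3]), np.array([0.1, 0.1, 0.1, 1.0]))
        params = CataractParams(
            life_table=lt, p_deteriorate=0.5, discount_rate=0.0, start_age=0,
            u_base=0.7, u_post=0.9,
        )
        res = run_cataract_model(params)
        for arm, start_in_T in (("intervention", True), ("comparator", False)):
            expected = enumerate_paths_oracle(
                [0.1, 0.1, 0.1, 1.0], 0.9, 0.7,
                0.5 if start_in_T else 0.0, 0.0, start_in_T,
            )
            assert getattr(res, arm).qalys == pytest.approx(expected, abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        qx=st.lists(st.floats(0.0, 0.9), min_size=4, max_size=4),
        p_det=st.floats(0.0, 1.0),
        rate=st.floats(0.0, 0.1),
        u_base=st.floats(0.1, 0.8),
        du=st.floats(0.0, 0.2),
    )
    def test_engine_equals_oracle_on_short_horizons(self, qx, p_det, rate, u_base, du):
        u_post = min(u_base + du, 1.0)
        lt = LifeTable(np.arange(5), np.append(qx, 1.0))
        _, qalys, _ = run_arm(
            life_table=lt, start_age=0, horizon=4, u_T=u_post, u_D=u_base,
            p_td=p_det, discount_rate=rate, entry_cost=0.0, start_in_T=True,
        )
        expected = enumerate_paths_oracle(qx, u_post, u_base, p_det, rate, True)
        assert float(qalys) == pytest.approx(expected, abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        q=st.floats(0.0, 0.5),
        p_det=st.floats(0.0, 1.0),
        rate=st.floats(0.0, 0.1),
    )
    def test_trace_conservation_and_absorbing_death(self, q, p_det, rate):
        lt = flat_life_table(q, terminal_age=30)
        params = CataractParams(
            life_table=lt, p_deteriorate=p_det, discount_rate=rate, start_age=0
        )
        res = run_cataract_model(params)
        for arm in (res.comparator, res.intervention):
            df = arm.trace.df
            occ = df[["state_T", "state_D", "state_M"]].to_numpy()
            assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(np.diff(df["state_M"].to_numpy()) >= -1e-15)

    def test_inc_qalys_decrease_with_deterioration_and_discounting(
        self, calibrated_life_table
    ):
        base = CataractParams(life_table=calibrated_life_table)
        res = run_cataract_model(base)
        more_det = run_cataract_model(
            CataractParams(life_table=calibrated_life_table, p_deteriorate=0.10)
        )
        more_disc = run_cataract_model(
            CataractParams(life_table=calibrated_life_table, discount_rate=0.06)
        )
        assert more_det.inc_qalys < res.inc_qalys
        assert more_disc.inc_qalys < res.inc_qalys
        assert res.inc_qalys > 0


class TestRefractionModel:
    def test_certain_first_cycle_loss_leaves_single_cycle_gain(self):
        lt = flat_life_table(0.0)
        params = RefractionParams(
            life_table=lt, loss_p1=1.0, loss_pH=1.0, discount_rate=0.03
        )
        res = run_refraction_model(params)
        assert res.inc_qalys == pytest.approx(0.075 / 1.03, abs=1e-10)

    def test_term_by_term_hand_computation(self):
        """No mortality, 3% discounting, published utilities: the engine
        matches the hand-accumulated geometric loss schedule."""
        lt = flat_life_table(0.0)
        res = run_refraction_model(RefractionParams(life_table=lt))
        in_T = 1.0
        expected = 0.0
        for t in range(1, 6):
            expected += 1.03 ** (-t) * in_T * 0.075
            in_T *= 1.0 - 0.05 * 18 ** ((t - 1) / 4)
        assert res.inc_qalys == pytest.approx(expected, abs=1e-12)

    def test_single_cycle_horizon(self):
        lt = flat_life_table(0.0)
        params = RefractionParams(life_table=lt, horizon=1)
        res = run_refraction_model(params)
        assert res.inc_qalys == pytest.approx(0.075 / 1.03, abs=1e-12)
        assert len(res.intervention.trace.df) == 2

    def test_comparator_matches_baseline_utility_annuity(self, calibrated_life_table):
        from eyecare_cea.life_tables import discounted_life_annuity

        res = run_refraction_model(RefractionParams(life_table=calibrated_life_table))
        annuity = discounted_life_annuity(calibrated_life_table, 39, 0.03, horizon=5)
        assert res.comparator.qalys == pytest.approx(0.850 * annuity, abs=1e-12)


class TestIcer:
    @pytest.mark.parametrize(
        "inc_cost,inc_qaly,expected",
        [(92, 0.355, 259), (72, 0.192, 375), (128, 0.355, 361), (88, 0.192, 458)],
    )
    def test_ratio_to_nearest_dollar(self, inc_cost, inc_qaly, expected):
        assert round(compute_icer(inc_cost, inc_qaly).value) == expected

    def test_free_effective_intervention(self):
        icer = compute_icer(0.0, 0.5)
        assert icer.value == 0.0 and icer.status == "ratio"

    def test_dominant(self):
        icer = compute_icer(-10.0, 0.5)
        assert icer.value < 0 and icer.status == "dominant"

    def test_dominated(self):
        icer = compute_icer(10.0, -0.5)
        assert np.isnan(icer.value) and icer.status == "dominated"

    def test_both_zero_undefined(self):
        assert compute_icer(0.0, 0.0).status == "undefined"
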