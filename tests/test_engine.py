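"""Cohort engine: relapse conversion, traces, discounting, pooling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scdcea.engine import (
    WaningSpec,
    annual_relapse_probability,
    build_model_inputs,
    initial_state_vector,
    pooled_result,
    run_cohort,
)
from scdcea.rewards import utility_weight


class TestRelapseConversion:
    @pytest.mark.parametrize(
        "p_T,T,expected",
        [(0.50, 10, 0.06697), (0.50, 20, 0.03406), (0.50, 1, 0.50)],
    )
    def test_exponential_rate_conversion(self, p_T, T, expected):
        assert annual_relapse_probability(p_T, T) == pytest.approx(expected, abs=5e-6)

    def test_certain_relapse_rejected(self):
        with pytest.raises(ValueError, match="p_T"):
            annual_relapse_probability(1.0, 10)

    def test_waning_spec_modes(self):
        assert WaningSpec.lifetime().p_annual == 0.0
        assert WaningSpec.median(10).p_annual == pytest.approx(0.06697, abs=5e-6)


class TestInitialState:
    def test_dt_arm_starts_cured(self, inputs):
        np.testing.assert_array_equal(
            initial_state_vector("dt", "female", inputs), [1, 0, 0, 0, 0]
        )

    @pytest.mark.parametrize(
        "gender,expected",
        [("female", (0.508, 0.221, 0.271)), ("male", (0.483, 0.231, 0.287))],
    )
    def test_soc_arm_starts_at_observed_severity(self, inputs, gender, expected):
        v = initial_state_vector("soc", gender, inputs)
        assert v[0] == 0 == v[4]
        assert v[1:4] == pytest.approx(expected, abs=5e-4)


class TestRunCohort:
    def test_degenerate_no_death_no_relapse(self, params, immortal_table):
        zero_r = build_model_inputs(params.with_values(discount_rate=0.0))
        res = run_cohort(
            "dt", "female", zero_r, (immortal_table, immortal_table), WaningSpec.lifetime()
        )
        expected_qaly = sum(
            utility_weight(zero_r.utilities, "healthy", a, "female") for a in range(100)
        )
        assert res.ly_undisc == pytest.approx(100.0)
        assert res.qaly_undisc == pytest.approx(expected_qaly)
        assert res.trace.occupancy[-1, 0] == pytest.approx(1.0)

    def test_zero_rate_discounted_equals_undiscounted(self, params, tables):
        zero_r = build_model_inputs(params.with_values(discount_rate=0.0))
        for arm in ("dt", "soc"):
            res = run_cohort(arm, "male", zero_r, tables)
            assert res.cost_disc == pytest.approx(res.cost_undisc)
            assert res.qaly_disc == pytest.approx(res.qaly_undisc)
            assert res.ly_disc == pytest.approx(res.ly_undisc)

    def test_discounted_below_undiscounted_at_positive_rate(self, base_results):
        for arm in ("dt", "soc"):
            r = base_results[arm]["pooled"]
            assert r.qaly_disc < r.qaly_undisc
            assert r.ly_disc < r.ly_undisc

    def test_soc_life_years_match_calibrated_expectancy(self, base_results):
        assert base_results["soc"]["pooled"].ly_undisc == pytest.approx(54.9, abs=0.5)
        assert base_results["dt"]["pooled"].ly_undisc == pytest.approx(75.8, abs=0.5)

    def test_upfront_price_charged_once_undiscounted(self, inputs, tables):
        dt = run_cohort("dt", "female", inputs, tables)
        soc = run_cohort("soc", "female", inputs, tables)
        assert dt.cost_disc > inputs.dt_price
        assert soc.cost_disc < inputs.dt_price  # no upfront charge in SOC

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        relapse_T=st.one_of(st.none(), st.floats(1.5, 40)),
        rate=st.floats(0, 0.1),
        arm=st.sampled_from(["dt", "soc"]),
        gender=st.sampled_from(["female", "male"]),
    )
    def test_trace_conserved_and_death_monotone(self, params, tables, relapse_T, rate, arm, gender):
        waning = WaningSpec.lifetime() if relapse_T is None else WaningSpec.median(relapse_T)
        inputs = build_model_inputs(params.with_values(discount_rate=rate))
        res = run_cohort(arm, gender, inputs, tables, waning)
        occ = res.trace.occupancy
        np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-10)
        assert (np.diff(occ[:, 4]) >= -1e-12).all()

    def test_full_absorption_with_terminal_mortality(self, inputs, tables, params):
        # horizon 101 uses the terminal qx = 1 row: nobody survives the table
        from dataclasses import replace

        long_inputs = replace(inputs, horizon=101)
        res = run_cohort("soc", "female", long_inputs, tables)
        assert res.trace.occupancy[-1, 4] == pytest.approx(1.0, abs=1e-12)

    def test_qalys_decrease_with_relapse_and_discounting(self, params, tables):
        inputs = build_model_inputs(params)
        qalys = [
            run_cohort("dt", "female", inputs, tables, w).qaly_disc
            for w in (WaningSpec.lifetime(), WaningSpec.median(20), WaningSpec.median(10))
        ]
        assert qalys[0] > qalys[1] > qalys[2]
        high_r = build_model_inputs(params.with_values(discount_rate=0.05))
        assert (
            run_cohort("dt", "female", high_r, tables).qaly_disc
            < run_cohort("dt", "female", inputs, tables).qaly_disc
        )

    def test_arms_differ_only_by_price_when_rewards_equalised(self, params, tables):
        # SCD utilities = control 1-44 weight, SCD costs = control costs,
        # shared life table: the cure then buys nothing but the price tag.
        eq = params.with_values(
            utility_scd_1_18=0.89,
            utility_scd_19_plus=0.89,
            utility_control_f_45_54=0.89,
            utility_control_f_55_64=0.89,
            utility_control_f_65_74=0.89,
            utility_control_f_75_plus=0.89,
            cost_f_mild=0.0,
            cost_f_moderate=0.0,
            cost_f_severe=0.0,
            cost_f_mild_age=0.0,
            cost_f_moderate_age=0.0,
            cost_f_severe_age=0.0,
        )
        inputs = build_model_inputs(eq)
        shared = (tables[0], tables[0])
        dt = run_cohort("dt", "female", inputs, shared)
        soc = run_cohort("soc", "female", inputs, shared)
        assert dt.qaly_disc == pytest.approx(soc.qaly_disc, rel=1e-12)
        assert dt.cost_disc - soc.cost_disc == pytest.approx(inputs.dt_price, rel=1e-9)

    def test_half_cycle_correction_shrinks_life_years(self, inputs, tables):
        full = run_cohort("soc", "male", inputs, tables)
        half = run_cohort("soc", "male", inputs, tables, half_cycle=True)
        # averaging start/end occupancy credits half a year in the death year
        assert half.ly_undisc < full.ly_undisc
        np.testing.assert_allclose(
            half.trace.occupancy, full.trace.occupancy
        )  # trace itself unchanged


class TestPooling:
    def test_degenerate_weights(self, base_results):
        f = base_results["dt"]["female"]
        m = base_results["dt"]["male"]
        assert pooled_result(f, m, 1.0).cost_disc == f.cost_disc
        assert pooled_result(f, m, 0.0).qaly_disc == m.qaly_disc
        assert pooled_result(f, m, 0.5).cost_disc == pytest.approx(
            (f.cost_disc + m.cost_disc) / 2
        )

    def test_published_gender_increments_pool_to_base_case(self):
        # published per-gender incremental discounted costs pooled at 47% female
        pooled = 0.47 * 1_279_485 + 0.53 * 1_123_195
        assert pooled == pytest.approx(2_372_482 - 1_175_566, rel=0.01)

    def test_invalid_weight_rejected(self, base_results):
        with pytest.raises(ValueError, match="percent_female"):
            pooled_result(base_results["dt"]["female"], base_results["dt"]["male"], 1.2)
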