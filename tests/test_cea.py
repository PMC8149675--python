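"""ICER, net monetary benefit, threshold pricing, CEAC/CEAF/EVPI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from scdcea.cea import DEFAULT_LAMBDA_GRID, ceac_ceaf, evpi, icer, nmb, threshold_price
from scdcea.engine import ArmResult
from scdcea.sensitivity import PSASampleSet


def _arm(cost, qaly, ly=0.0):
    return ArmResult(cost, cost, qaly, qaly, ly, ly)


def _sample_set(cost_dt, qaly_dt, cost_soc, qaly_soc):
    z = np.zeros(len(cost_dt))
    return PSASampleSet(
        seed=0,
        draws=pd.DataFrame(),
        cost_dt=np.asarray(cost_dt, float),
        qaly_dt=np.asarray(qaly_dt, float),
        ly_dt=z,
        cost_soc=np.asarray(cost_soc, float),
        qaly_soc=np.asarray(qaly_soc, float),
        ly_soc=z,
    )


class TestIcer:
    def test_published_per_arm_values(self):
        res = icer(_arm(2_372_482, 26.4, 29.9), _arm(1_175_566, 17.9, 26.2))
        assert res.delta_cost == 1_196_916
        assert res.delta_qaly == pytest.approx(8.5)
        assert res.delta_ly == pytest.approx(3.7)
        assert res.icer == pytest.approx(1_196_916 / 8.5)

    def test_quotient_oracle_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            c_dt, c_soc = rng.uniform(1e5, 5e6, 2)
            q_dt = rng.uniform(10, 30)
            q_soc = q_dt - rng.uniform(0.1, 10)
            res = icer(_arm(c_dt, q_dt), _arm(c_soc, q_soc))
            if res.icer is not None:
                assert res.icer == (c_dt - c_soc) / (q_dt - q_soc)

    def test_identical_arms_indeterminate(self):
        res = icer(_arm(1e6, 20.0), _arm(1e6, 20.0))
        assert res.icer is None and res.dominance == "none"

    def test_equal_qalys_different_cost_flagged(self):
        res = icer(_arm(2e6, 20.0), _arm(1e6, 20.0))
        assert res.icer is None and res.dominance == "indeterminate"

    def test_dominance_quadrants(self):
        assert icer(_arm(1e6, 25.0), _arm(2e6, 20.0)).dominance == "dt_dominant"
        assert icer(_arm(2e6, 15.0), _arm(1e6, 20.0)).dominance == "dt_dominated"


class TestNmb:
    def test_zero_wtp_is_negative_cost(self):
        assert nmb(_arm(1e6, 20.0), 0.0) == -1e6

    def test_published_base_case_value(self):
        assert nmb(_arm(2_372_482, 26.4), 150_000) == pytest.approx(1_587_518)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        c_dt=st.floats(1e5, 5e6),
        c_soc=st.floats(1e5, 5e6),
        q_dt=st.floats(10, 30),
        dq=st.floats(0.01, 10),
        lam=st.floats(0, 5e5),
    )
    def test_nmb_crossing_equivalent_to_icer_threshold(self, c_dt, c_soc, q_dt, dq, lam):
        """With a QALY gain, DT wins on NMB exactly when its ICER is below λ."""
        from hypothesis import assume

        dt, soc = _arm(c_dt, q_dt), _arm(c_soc, q_dt - dq)
        ratio = (c_dt - c_soc) / dq
        # exclude knife-edge cases where λ·ΔQ and ΔC agree to rounding error
        assume(abs(lam * dq - (c_dt - c_soc)) > 1e-6 * max(1.0, abs(c_dt - c_soc)))
        assert (nmb(dt, lam) > nmb(soc, lam)) == (ratio < lam)


class TestThresholdPrice:
    def test_fixed_point_at_own_icer(self):
        base = icer(_arm(2_372_482, 26.4), _arm(1_175_566, 17.9))
        assert threshold_price(base, 2.1e6, base.icer) == pytest.approx(2.1e6)

    def test_requires_qaly_gain(self):
        base = icer(_arm(2e6, 15.0), _arm(1e6, 20.0))
        with pytest.raises(ValueError, match="QALY-gaining"):
            threshold_price(base, 2.1e6, 150_000)


class TestVoiCurves:
    def test_zero_lambda_counts_cheaper_arm(self):
        # DT strictly cheaper once; the cost tie goes to the incumbent SOC
        psa = _sample_set([10, 30, 20], [5, 5, 5], [20, 20, 20], [4, 4, 4])
        curves = ceac_ceaf(psa, np.array([0.0]))
        assert curves.ceac_dt[0] == pytest.approx(1 / 3)
        assert curves.ceac_soc[0] == pytest.approx(2 / 3)

    def test_ceac_sums_to_one_and_step_for_identical_iterations(self):
        psa = _sample_set([2e6] * 4, [25.0] * 4, [1e6] * 4, [20.0] * 4)
        curves = ceac_ceaf(psa, DEFAULT_LAMBDA_GRID)
        np.testing.assert_allclose(curves.ceac_dt + curves.ceac_soc, 1.0)
        common_icer = 1e6 / 5.0
        assert set(np.unique(curves.ceac_dt)) == {0.0, 1.0}
        assert (curves.ceac_dt[curves.lambda_grid > common_icer] == 1.0).all()
        assert (curves.ceac_dt[curves.lambda_grid < common_icer] == 0.0).all()

    def test_ceac_monotone_when_every_iteration_gains_qalys(self):
        rng = np.random.default_rng(2)
        n = 500
        psa = _sample_set(
            rng.normal(2.3e6, 3e5, n),
            rng.normal(26, 2, n),
            rng.normal(1.2e6, 3e5, n),
            rng.normal(18, 1, n),
        )
        assert (psa.qaly_dt > psa.qaly_soc).all()
        curves = ceac_ceaf(psa, DEFAULT_LAMBDA_GRID)
        assert (np.diff(curves.ceac_dt) >= 0).all()

    def test_counting_rule_matches_nmb_rule_in_tradeoff_quadrant(self):
        rng = np.random.default_rng(3)
        n = 400
        psa = _sample_set(
            rng.uniform(2e6, 3e6, n),
            rng.uniform(24, 28, n),
            rng.uniform(1e6, 1.5e6, n),
            rng.uniform(16, 20, n),
        )
        a = ceac_ceaf(psa, DEFAULT_LAMBDA_GRID, rule="nmb")
        b = ceac_ceaf(psa, DEFAULT_LAMBDA_GRID, rule="icer_threshold")
        np.testing.assert_allclose(a.ceac_dt, b.ceac_dt)

    def test_empty_sample_set_rejected(self):
        psa = _sample_set([], [], [], [])
        with pytest.raises(ValueError, match="empty"):
            ceac_ceaf(psa)


class TestEvpi:
    def test_two_draw_hand_calculation(self):
        # NMB pairs (A=10, B=5) and (A=0, B=8) at wtp=0 via costs -NMB
        psa = _sample_set([-10, 0], [0, 0], [-5, -8], [0, 0])
        assert evpi(psa, 0.0) == pytest.approx(2.5)

    def test_zero_when_one_arm_always_dominates(self):
        psa = _sample_set([1e6, 1.1e6], [25, 26], [2e6, 2.1e6], [20, 21])
        assert evpi(psa, 150_000) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        nmbs=arrays(
            np.float64,
            (2, 10),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
        )
    )
    def test_never_negative(self, nmbs):
        psa = _sample_set(-nmbs[0], np.zeros(10), -nmbs[1], np.zeros(10))
        assert evpi(psa, 0.0) >= -1e-9

    def test_peak_near_ceac_crossing(self):
        rng = np.random.default_rng(4)
        n = 2000
        psa = _sample_set(
            rng.normal(2.4e6, 2e5, n),
            rng.normal(26, 1.5, n),
            rng.normal(1.2e6, 2e5, n),
            rng.normal(18, 1.0, n),
        )
        curves = ceac_ceaf(psa, DEFAULT_LAMBDA_GRID)
        # brute-force scan: λ of max EVPI vs λ where CEAC crosses one half
        peak = curves.lambda_grid[np.argmax(curves.evpi)]
        crossing = curves.lambda_grid[np.argmin(np.abs(curves.ceac_dt - 0.5))]
        assert abs(peak - crossing) <= 10_000  # within two grid steps
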