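import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bchicea.event_rates import ReoperationSplit
from bchicea.markov_engine import (
    ArmOutcomes,
    ArmParameters,
    ConfigurationError,
    ConstructionError,
    CostSet,
    LifeTable,
    ModelConfig,
    S,
    STATES,
    UtilitySchedule,
    accrue_outcomes,
    build_transition_matrix,
    compute_icer,
    run_arm,
    run_cohort,
    run_model,
    trace_to_frame,
    utility_for,
)
from bchicea.synthetic_data import make_life_table

COSTS = CostSet(
    device=15125,
    replacement_sound_processor=7166,
    surgery=1002,
    hospitalisation=5415,
    ae_management=138,
)


def quiet_arm(
    utilities=UtilitySchedule(0.76, 0.0, 0.0),
    reop=0.0,
    split=ReoperationSplit(0.0, 1.0, 0.0),
    ae=0.0,
    costs=COSTS,
    name="test",
):
    return ArmParameters(
        name=name,
        costs=costs,
        utilities=utilities,
        reop_rate_monthly=reop,
        reop_split=split,
        ae_rate_monthly=ae,
    )


class TestTransitionMatrix:
    def test_zero_rates_keep_cohort_aided(self):
        m = build_transition_matrix(0, 0, 0, 0)
        assert m[S["AIDED_FIRST"], S["AIDED_FIRST"]] == 1.0
        assert np.allclose(m.sum(axis=1), 1.0)

    def test_dead_row_absorbing(self):
        m = build_transition_matrix(0.01, 0.02, 0.03, 0.1)
        expected = np.zeros(len(STATES))
        expected[S["DEAD"]] = 1.0
        assert np.array_equal(m[S["DEAD"]], expected)

    def test_mortality_applies_to_every_alive_state(self):
        q = 0.07
        m = build_transition_matrix(0.01, 0.02, 0.03, q)
        assert np.allclose(m[: S["DEAD"], S["DEAD"]], q)

    def test_half_half_split_gives_equal_destinations(self):
        p = 1 - (1 - 4 / 1296) ** 3
        m = build_transition_matrix(0.0, p / 2, p / 2, 0.0)
        assert m[S["AIDED_FIRST"], S["UNAIDED_EXPLANTED"]] == pytest.approx(
            m[S["AIDED_FIRST"], S["TUNNEL_REIMPLANT_Q1"]]
        )

    def test_hand_built_matrix_oracle(self):
        # independent oracle: write the 9x9 matrix out by hand
        p_rev, p_exp, p_reimp, q = 0.01, 0.02, 0.03, 0.005
        s = 1 - q
        oracle = np.zeros((9, 9))
        oracle[0, 0] = s * (1 - p_rev - p_exp - p_reimp)
        oracle[0, 1] = s * p_rev
        oracle[0, 7] = s * p_exp
        oracle[0, 2] = s * p_reimp
        oracle[1, 1] = s * (1 - p_exp - p_reimp)
        oracle[1, 7] = s * p_exp
        oracle[1, 2] = s * p_reimp
        oracle[2, 3] = oracle[3, 4] = oracle[4, 5] = oracle[5, 6] = s
        oracle[6, 6] = s * (1 - p_exp - p_reimp)
        oracle[6, 7] = s * (p_exp + p_reimp)
        oracle[7, 7] = s
        oracle[:, 8] = q
        oracle[8, :] = 0
        oracle[8, 8] = 1
        m = build_transition_matrix(p_rev, p_exp, p_reimp, q)
        assert np.allclose(m, oracle, atol=1e-15)

    def test_second_explantation_is_terminal(self):
        m = build_transition_matrix(0.0, 0.01, 0.02, 0.0)
        assert m[S["AIDED_SECOND"], S["TUNNEL_REIMPLANT_Q1"]] == 0.0
        assert m[S["AIDED_SECOND"], S["UNAIDED_EXPLANTED"]] == pytest.approx(0.03)

    @given(
        p_rev=st.floats(0, 0.3),
        p_exp=st.floats(0, 0.3),
        p_reimp=st.floats(0, 0.3),
        q=st.floats(0, 1),
    )
    @settings(max_examples=80, deadline=None)
    def test_rows_sum_to_one(self, p_rev, p_exp, p_reimp, q):
        m = build_transition_matrix(p_rev, p_exp, p_reimp, q)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_invalid_probabilities(self):
        with pytest.raises(ConstructionError):
            build_transition_matrix(0.5, 0.5, 0.5, 0.0)
        with pytest.raises(ConstructionError):
            build_transition_matrix(-0.1, 0.0, 0.0, 0.0)


class TestRunCohort:
    def test_zero_everything_stays_aided(self, immortal):
        config = ModelConfig(horizon_years=10.0, discount_annual=0.0)
        trace = run_cohort(quiet_arm(), config, immortal)
        assert trace.n_cycles == 40
        assert np.all(trace.occupancy[:, S["AIDED_FIRST"]] == 1.0)

    def test_constant_mortality_matches_closed_form(self):
        q = 0.02
        lt = make_life_table("constant", q=q)
        config = ModelConfig(start_age=50.0, horizon_years=10.0)
        trace = run_cohort(quiet_arm(), config, lt)
        for years in (1, 5, 10):
            assert trace.alive[4 * years] == pytest.approx((1 - q) ** years, rel=1e-12)

    def test_explant_only_scalar_recursion_oracle(self, immortal):
        monthly = 1 / 786
        arm = quiet_arm(reop=monthly)
        config = ModelConfig(horizon_years=2.0)
        trace = run_cohort(arm, config, immortal)
        p = 1 - (1 - monthly) ** 3
        cumulative = 1 - (1 - p) ** 8  # scalar recursion over 8 quarters
        assert trace.occupancy[8, S["UNAIDED_EXPLANTED"]] == pytest.approx(
            cumulative, rel=1e-12
        )
        assert cumulative < 0.04

    def test_occupancy_conservation_and_dead_monotone(self, base_inputs):
        osia, baha, config, lt = base_inputs
        for arm in (osia, baha):
            trace = run_cohort(arm, config, lt)
            assert np.all(np.abs(trace.occupancy.sum(axis=1) - 1.0) <= 1e-12)
            dead = trace.occupancy[:, S["DEAD"]]
            assert np.all(np.diff(dead) >= -1e-15)
            assert np.all(trace.occupancy >= -1e-15)

    def test_tunnel_advances_one_state_per_cycle(self, immortal):
        arm = quiet_arm(reop=0.01, split=ReoperationSplit(0.0, 0.0, 1.0))
        config = ModelConfig(horizon_years=3.0)
        trace = run_cohort(arm, config, immortal)
        p = 1 - (1 - 0.01) ** 3
        inflow = trace.occupancy[1, S["TUNNEL_REIMPLANT_Q1"]]
        assert inflow == pytest.approx(p)
        # that inflow reaches AIDED_SECOND exactly four cycles later
        assert trace.occupancy[5, S["AIDED_SECOND"]] >= inflow - 1e-12

    def test_fractional_horizon_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(horizon_years=10.1).n_cycles()


class TestUtilityFor:
    SCHED = UtilitySchedule(0.67, 0.09, 0.09)

    def test_steady_state_gain(self):
        assert utility_for("AIDED_FIRST", 3, self.SCHED) == pytest.approx(0.76)
        assert utility_for("AIDED_FIRST", 99, self.SCHED) == pytest.approx(0.76)

    def test_rehabilitation_ramp(self):
        sched = UtilitySchedule(0.67, 0.06, 0.09)
        assert utility_for("AIDED_FIRST", 1, sched) == 0.67
        assert utility_for("AIDED_FIRST", 2, sched) == pytest.approx(0.73)
        assert utility_for("TUNNEL", 1, sched) == 0.67
        assert utility_for("TUNNEL", 2, sched) == pytest.approx(0.73)
        assert utility_for("TUNNEL", 4, sched) == pytest.approx(0.76)

    def test_explanted_reverts_to_baseline(self):
        assert utility_for("UNAIDED_EXPLANTED", 99, self.SCHED) == 0.67

    def test_dead_is_zero(self):
        assert utility_for("DEAD", 5, self.SCHED) == 0.0

    def test_baha_gain(self):
        sched = UtilitySchedule(0.67, 0.06, 0.06)
        assert utility_for("AIDED_SECOND", 10, sched) == pytest.approx(0.73)


class TestAccrueOutcomes:
    def test_rectangle_rule_exact(self, immortal):
        config = ModelConfig(horizon_years=10.0, discount_annual=0.0)
        out, _ = run_arm(quiet_arm(), config, immortal)
        assert out.qalys_undiscounted == pytest.approx(7.6, abs=1e-12)
        assert out.qalys_discounted == pytest.approx(7.6, abs=1e-12)

    def test_geometric_series_oracle(self, immortal):
        config = ModelConfig(horizon_years=10.0, discount_annual=0.05)
        out, _ = run_arm(quiet_arm(), config, immortal)
        expected = sum(
            0.76 * 0.25 * 1.05 ** (-(i + 0.5) * 0.25) for i in range(40)
        )
        assert out.qalys_discounted == pytest.approx(expected, rel=1e-12)

    def test_initial_cost(self, base_inputs):
        osia, _, config, lt = base_inputs
        out, _ = run_arm(osia, config, lt)
        assert out.cost_breakdown["initial"] == pytest.approx(15125 + 1002 + 5415)

    def test_zero_everything_closed_form_costs(self, immortal):
        config = ModelConfig(horizon_years=10.0, discount_annual=0.0)
        out, _ = run_arm(quiet_arm(), config, immortal)
        # upgrades at years 5 and 10 at full occupancy, nothing else
        assert out.cost_undiscounted == pytest.approx(COSTS.initial + 2 * 7166, abs=1e-9)
        assert out.cost_discounted == pytest.approx(out.cost_undiscounted, abs=1e-9)

    def test_boundary_upgrade_can_be_excluded(self, immortal):
        config = ModelConfig(
            horizon_years=10.0, discount_annual=0.0, include_boundary_upgrade=False
        )
        out, _ = run_arm(quiet_arm(), config, immortal)
        assert out.cost_undiscounted == pytest.approx(COSTS.initial + 7166, abs=1e-9)

    def test_discounted_below_undiscounted(self, base_inputs):
        osia, baha, config, lt = base_inputs
        for arm in (osia, baha):
            out, _ = run_arm(arm, config, lt)
            assert out.cost_discounted < out.cost_undiscounted
            assert out.qalys_discounted < out.qalys_undiscounted

    def test_half_cycle_correction_bracketed_by_rectangles(self):
        lt = make_life_table("constant", q=0.05)
        config = ModelConfig(start_age=50.0, horizon_years=10.0, discount_annual=0.0)
        out, trace = run_arm(quiet_arm(), config, lt)
        u = 0.76
        start = u * trace.occupancy[:-1, : S["DEAD"]].sum(axis=1).sum() * 0.25
        end = u * trace.occupancy[1:, : S["DEAD"]].sum(axis=1).sum() * 0.25
        assert end <= out.qalys_undiscounted <= start

    def test_constant_cost_stream_cancels_in_increment(self, immortal):
        config = ModelConfig(horizon_years=10.0, discount_annual=0.05)
        a = quiet_arm(utilities=UtilitySchedule(0.67, 0.09, 0.09), name="a")
        b = quiet_arm(utilities=UtilitySchedule(0.67, 0.06, 0.06), name="b")
        base = run_model(a, b, config, immortal)
        # identical AE streams in both arms shift totals but not the increment
        a2 = replace(a, ae_rate_monthly=0.01)
        b2 = replace(b, ae_rate_monthly=0.01)
        shifted = run_model(a2, b2, config, immortal)
        assert shifted.incremental_cost == pytest.approx(base.incremental_cost, abs=1e-9)
        assert shifted.icer == pytest.approx(base.icer, rel=1e-12)


class TestICER:
    def _outcomes(self, cost, qaly, arm="x"):
        return ArmOutcomes(
            arm=arm,
            cost_discounted=cost,
            cost_undiscounted=cost,
            qalys_discounted=qaly,
            qalys_undiscounted=qaly,
        )

    def test_published_increment_division(self):
        r = compute_icer(
            self._outcomes(31605.0, 6.09), self._outcomes(31605.0 - 6348.0, 6.09 - 0.2166),
            ModelConfig(),
        )
        assert r.incremental_cost == pytest.approx(6348.0)
        assert r.icer == pytest.approx(29300, abs=20)
        assert r.cost_effective

    def test_identical_arms_undefined(self):
        r = compute_icer(self._outcomes(100.0, 1.0), self._outcomes(100.0, 1.0), ModelConfig())
        assert r.icer is None
        assert r.cost_effective is None

    def test_doubling_costs_doubles_icer(self):
        cfg = ModelConfig()
        r1 = compute_icer(self._outcomes(200.0, 2.0), self._outcomes(100.0, 1.5), cfg)
        r2 = compute_icer(self._outcomes(400.0, 2.0), self._outcomes(200.0, 1.5), cfg)
        assert r2.incremental_cost == pytest.approx(2 * r1.incremental_cost)
        assert r2.icer == pytest.approx(2 * r1.icer)
        assert r2.incremental_qalys == r1.incremental_qalys


class TestLifeTable:
    def test_clamps_outside_range(self):
        lt = LifeTable(np.arange(50, 61), np.full(11, 0.01))
        assert lt.annual_q(30.0) == 0.01
        assert lt.annual_q(90.0) == 0.01

    def test_constant_within_year(self):
        lt = LifeTable(np.arange(0, 3), np.array([0.1, 0.2, 0.3]))
        assert lt.annual_q(1.0) == lt.annual_q(1.75) == 0.2

    def test_validation(self):
        with pytest.raises(ConfigurationError):
            LifeTable(np.array([0, 2]), np.array([0.1, 0.1]))
        with pytest.raises(ConfigurationError):
            LifeTable(np.array([0, 1]), np.array([0.1, 1.1]))

    def test_packaged_fixture_loads(self, base_inputs):
        *_, lt = base_inputs
        assert 0 < lt.annual_q(47.0) < 0.01
        assert lt.annual_q(100.0) > lt.annual_q(50.0)


def test_trace_frame_shape(base_inputs):
    osia, _, config, lt = base_inputs
    _, trace = run_arm(osia, config, lt)
    df = trace_to_frame(trace)
    assert len(df) == 40
    assert set(STATES) <= set(df.columns)
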