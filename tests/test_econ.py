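"""Accrual, discounting and incremental results, checked against closed
forms and an independent nested-loop oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from markovcea import (
    CostSchedule,
    DiscountSchedule,
    StateSpace,
    StructuralError,
    UtilitySchedule,
    accrue,
    compute_icer,
    occupancy_difference,
    simulate_cohort,
)
from markovcea.econ import UNDEFINED_ICER
from markovcea.synthetic import GeneratorConfig, oracle_accrue, random_model
from conftest import constant_trace


@pytest.fixture(scope="module")
def parked():
    """One person parked in a $100/yr, utility-1 state for 2 years."""
    space = StateSpace(("alive", "death"), absorbing=frozenset({"death"}))
    trace = constant_trace(space, 1.0, 2, "alive")
    costs = CostSchedule(space, {"alive": 100.0, "death": 0.0})
    utils = UtilitySchedule(space, {"alive": 1.0, "death": 0.0})
    return trace, costs, utils


class TestAccrue:
    def test_undiscounted_two_years(self, parked):
        trace, costs, utils = parked
        res = accrue(trace, costs, utils, DiscountSchedule(0.0))
        assert res.total_cost == pytest.approx(200.0)
        assert res.total_qaly == pytest.approx(2.0)

    def test_four_percent_first_year_undiscounted(self, parked):
        # origin=1 leaves the first model year undiscounted: 100 + 100/1.04
        trace, costs, utils = parked
        res = accrue(trace, costs, utils, DiscountSchedule(0.04, origin=1))
        assert res.total_cost == pytest.approx(100 + 100 / 1.04)

    def test_four_percent_origin_zero(self, parked):
        trace, costs, utils = parked
        res = accrue(trace, costs, utils, DiscountSchedule(0.04, origin=0))
        assert res.total_cost == pytest.approx(100 / 1.04 + 100 / 1.04**2)

    def test_split_utility_discount(self, parked):
        trace, costs, utils = parked
        res = accrue(
            trace, costs, utils, DiscountSchedule(0.04, origin=0),
            utility_discount=DiscountSchedule(0.0),
        )
        assert res.total_cost == pytest.approx(100 / 1.04 + 100 / 1.04**2)
        assert res.total_qaly == pytest.approx(2.0)

    def test_state_set_mismatch_is_structural(self, parked):
        trace, costs, _ = parked
        other = StateSpace(("x", "death"), absorbing=frozenset({"death"}))
        utils = UtilitySchedule(other, {"x": 1.0, "death": 0.0})
        with pytest.raises(StructuralError):
            accrue(trace, costs, utils, DiscountSchedule(0.0))

    @pytest.mark.parametrize("timing", ["end", "start", "half"])
    def test_matches_loop_oracle(self, timing):
        syn = random_model(GeneratorConfig(seed=404, n_states=4, horizon=10))
        trace = simulate_cohort(syn.model, syn.initial)
        res = accrue(trace, syn.costs, syn.utilities, syn.discount, timing=timing)
        if timing == "half":
            end = oracle_accrue(syn, timing="end")
            start = oracle_accrue(syn, timing="start")
            expected = tuple(0.5 * (a + b) for a, b in zip(end, start))
        else:
            expected = oracle_accrue(syn, timing=timing)
        assert res.total_cost == pytest.approx(expected[0], rel=1e-9)
        assert res.total_qaly == pytest.approx(expected[1], rel=1e-9)

    def test_per_state_costs_sum_to_total(self):
        syn = random_model(GeneratorConfig(seed=77, n_states=5, horizon=12))
        trace = simulate_cohort(syn.model, syn.initial)
        res = accrue(trace, syn.costs, syn.utilities, syn.discount)
        assert sum(res.per_state_cost.values()) == pytest.approx(res.total_cost, rel=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.integers(0, 2**31 - 1),
    st.floats(0.0, 0.2),
    st.floats(0.01, 0.3),
)
def test_totals_non_increasing_in_discount_rate(seed, rate, bump):
    syn = random_model(GeneratorConfig(seed=seed, n_states=4, horizon=8))
    trace = simulate_cohort(syn.model, syn.initial)
    lo = accrue(trace, syn.costs, syn.utilities, DiscountSchedule(rate))
    hi = accrue(trace, syn.costs, syn.utilities, DiscountSchedule(rate + bump))
    assert hi.total_cost <= lo.total_cost + 1e-9 * abs(lo.total_cost)
    assert hi.total_qaly <= lo.total_qaly + 1e-12 * abs(lo.total_qaly)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_accrual_linear_in_cohort_size(seed):
    """Doubling the initial cohort doubles every total exactly."""
    syn = random_model(GeneratorConfig(seed=seed, n_states=4, horizon=8))
    t1 = simulate_cohort(syn.model, syn.initial)
    t2 = simulate_cohort(syn.model, 2.0 * syn.initial)
    r1 = accrue(t1, syn.costs, syn.utilities, syn.discount)
    r2 = accrue(t2, syn.costs, syn.utilities, syn.discount)
    assert r2.total_cost == pytest.approx(2.0 * r1.total_cost, rel=1e-12)
    assert r2.total_qaly == pytest.approx(2.0 * r1.total_qaly, rel=1e-12)


def test_zero_rate_totals_equal_undiscounted_oracle():
    syn = random_model(GeneratorConfig(seed=9, n_states=6, horizon=15, discount_rate=0.0))
    trace = simulate_cohort(syn.model, syn.initial)
    res = accrue(trace, syn.costs, syn.utilities, DiscountSchedule(0.0))
    cost, qaly = oracle_accrue(syn)
    assert res.total_cost == pytest.approx(cost, rel=1e-9)
    assert res.total_qaly == pytest.approx(qaly, rel=1e-9)


class TestComputeIcer:
    def _result(self, cost, qaly, space, horizon=2):
        from markovcea.econ import EconomicResult

        per_state = {s: 0.0 for s in space.states}
        per_state[space.states[0]] = cost
        return EconomicResult(space, cost, qaly, per_state, dict(per_state), horizon)

    def test_simple_ratio(self, two_state_space):
        a = self._result(0.0, 0.0, two_state_space)
        b = self._result(100_000.0, 4.0, two_state_space)
        inc = compute_icer(a, b)
        assert inc.icer == pytest.approx(25_000.0)
        assert inc.status == "defined"

    def test_identical_scenarios_undefined_marker(self, two_state_space):
        a = self._result(5.0, 1.0, two_state_space)
        inc = compute_icer(a, a)
        assert inc.delta_cost == 0.0 and inc.delta_effect == 0.0
        assert inc.icer is None
        assert inc.status == UNDEFINED_ICER

    def test_sign_conventions_preserved(self, two_state_space):
        a = self._result(100.0, 2.0, two_state_space)
        b = self._result(50.0, 1.0, two_state_space)  # cheaper and worse
        inc = compute_icer(a, b)
        assert inc.delta_cost == pytest.approx(-50.0)
        assert inc.delta_effect == pytest.approx(-1.0)
        assert inc.icer == pytest.approx(50.0)

    def test_icer_recomputes_bit_for_bit(self, two_state_space):
        a = self._result(0.0, 0.0, two_state_space)
        b = self._result(2_600_153_130.0, 78_699.0, two_state_space)
        inc = compute_icer(a, b)
        assert inc.icer == inc.delta_cost / inc.delta_effect  # exact float equality

    def test_horizon_mismatch_rejected(self, two_state_space):
        a = self._result(1.0, 1.0, two_state_space, horizon=2)
        b = self._result(2.0, 2.0, two_state_space, horizon=3)
        with pytest.raises(StructuralError):
            compute_icer(a, b)


class TestOccupancyDifference:
    def test_identical_traces_are_zero(self, coin_model):
        t = simulate_cohort(coin_model, {"A": 100.0})
        diff = occupancy_difference(t, t)
        assert (diff == 0).all().all()

    def test_two_state_hand_computation(self, two_state_space, coin_model):
        """0.5^t decay vs no decay: hand-computable differences."""
        import markovcea as mc

        ident = mc.MarkovModel(
            two_state_space, mc.TransitionMatrix(two_state_space, np.eye(2)), horizon=3
        )
        stay = simulate_cohort(ident, {"A": 8.0})
        decay = simulate_cohort(coin_model, {"A": 8.0})
        diff = occupancy_difference(stay, decay)
        # final cycle: 8 * 0.5^3 - 8 = -7 in A
        assert diff.loc["A", "final_cycle"] == pytest.approx(-7.0)
        # person-years over cycles 1..3: (4+2+1) - 24 = -17
        assert diff.loc["A", "person_years"] == pytest.approx(-17.0)
        assert diff.loc["death", "final_cycle"] == pytest.approx(7.0)

    def test_horizon_mismatch_rejected(self, two_state_space, coin_model):
        import markovcea as mc

        short = mc.MarkovModel(two_state_space, coin_model.matrix, horizon=2)
        a = simulate_cohort(coin_model, {"A": 1.0})
        b = simulate_cohort(short, {"A": 1.0})
        with pytest.raises(StructuralError):
            occupancy_difference(a, b)
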