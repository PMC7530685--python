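"""The packaged two-scenario CGM-app study: arm construction, stratum
arithmetic, directionality, and the frozen calibration switches."""

import numpy as np
import pytest

from markovcea import (
    StructuralError,
    StudyPopulation,
    build_arm,
    run_study,
    simulate_cohort,
    validate_matrix,
)
from markovcea.calibrate import sweep
from markovcea.econ import UNDEFINED_ICER
from markovcea.study import (
    APP_ANNUAL_COST_USD,
    DEFAULT_SETTINGS,
    STATES,
    settings_with,
)


class TestBuildArm:
    def test_non_use_matrix_validates(self):
        arm = build_arm("non_use")
        assert validate_matrix(arm.model.matrix).ok

    def test_arms_differ_only_in_onset_utility_and_app_cost(self):
        non = build_arm("non_use")
        app = build_arm("app_use")
        Pn, Pa = non.model.matrix.probs, app.model.matrix.probs
        i = non.model.space.index("insulin_therapy")
        j = non.model.space.index("microalbuminuria")
        # the arm-specific edge: app users develop microalbuminuria at 1.6 %/yr
        assert Pa[i, j] == pytest.approx(0.016)
        assert Pn[i, j] == pytest.approx(0.048)
        # everything else identical up to the row-remainder self-transition
        mask = np.ones_like(Pn, dtype=bool)
        mask[i, j] = mask[i, i] = False
        np.testing.assert_array_equal(Pn[mask], Pa[mask])
        assert non.costs.annual_cost == app.costs.annual_cost
        assert non.app_annual_cost == 0.0
        assert app.app_annual_cost == APP_ANNUAL_COST_USD
        assert app.utilities.annual_utility["insulin_therapy"] == 0.83
        assert non.utilities.annual_utility["insulin_therapy"] == 0.81

    def test_insulin_cost_composition(self):
        arm = build_arm("non_use")
        # a patient with microalbuminuria is still on insulin therapy
        assert arm.costs.annual_cost["microalbuminuria"] == pytest.approx(1892.61 + 4891.76)
        assert arm.costs.annual_cost["insulin_therapy"] == pytest.approx(4891.76)
        plain = build_arm("non_use", settings_with(combine_insulin_cost=False))
        assert plain.costs.annual_cost["microalbuminuria"] == pytest.approx(1892.61)

    def test_overfull_override_rejected_naming_row(self):
        with pytest.raises(StructuralError, match="microalbuminuria"):
            build_arm(
                "non_use",
                edge_overrides={("microalbuminuria", "macroalbuminuria"): 1.5},
            )

    def test_unknown_arm_rejected(self):
        with pytest.raises(StructuralError):
            build_arm("placebo")

    def test_row_repairs_are_logged(self):
        arm = build_arm("non_use")
        assert any("remainder" in line for line in arm.resolution_log)


class TestRunStudy:
    def test_no_users_means_identical_scenarios(self):
        pop = StudyPopulation(app_users=0, uptake_fraction=0.0)
        res = run_study(pop)
        assert res.incremental.delta_cost == pytest.approx(0.0, abs=1e-6)
        assert res.incremental.delta_effect == pytest.approx(0.0, abs=1e-9)
        assert res.incremental.status == UNDEFINED_ICER

    def test_halving_users_halves_deltas_but_not_icer(self, default_study):
        pop = StudyPopulation(app_users=50_000, uptake_fraction=0.073)
        half = run_study(pop)
        assert half.incremental.delta_cost == pytest.approx(
            default_study.incremental.delta_cost / 2, rel=1e-9
        )
        assert half.incremental.delta_effect == pytest.approx(
            default_study.incremental.delta_effect / 2, rel=1e-9
        )
        assert half.incremental.icer == pytest.approx(default_study.incremental.icer, rel=1e-9)

    def test_scenario_b_is_sum_of_its_strata(self, default_study):
        res = default_study
        from markovcea.study import _accrue_arm  # stratum accrual used by run_study

        non = build_arm("non_use")
        app = build_arm("app_use")
        e_non = _accrue_arm(res.trace_b_nonuse, non, res.settings)
        e_app = _accrue_arm(res.trace_b_app, app, res.settings)
        assert res.scenario_b.total_cost == e_non.total_cost + e_app.total_cost
        assert res.scenario_b.total_qaly == e_non.total_qaly + e_app.total_qaly

    def test_cohort_conserved_in_all_traces(self, default_study):
        for trace in (
            default_study.trace_a,
            default_study.trace_b_nonuse,
            default_study.trace_b_app,
        ):
            sums = trace.occupancy.sum(axis=1)
            np.testing.assert_allclose(sums, trace.initial_size, rtol=1e-9)

    def test_app_cost_charged_only_in_configured_states(self, default_study):
        """Removing the app surcharge must reproduce the plain accrual."""
        res = run_study(settings=settings_with())
        app = build_arm("app_use")
        from markovcea import DiscountSchedule, accrue

        plain = accrue(
            res.trace_b_app, app.costs, app.utilities, res.settings.discount,
            utility_discount=res.settings.utility_discount,
            timing=res.settings.accrual_timing,
        )
        surcharge = res.scenario_b.total_cost - (
            plain.total_cost
            + accrue(
                res.trace_b_nonuse, build_arm("non_use").costs,
                build_arm("non_use").utilities, res.settings.discount,
                utility_discount=res.settings.utility_discount,
                timing=res.settings.accrual_timing,
            ).total_cost
        )
        # surcharge equals app cost times discounted insulin-state person-years
        factors = res.settings.discount.factors(np.arange(1, 21))
        ins_py = float(res.trace_b_app.column("insulin_therapy")[:-1] @ factors)
        assert surcharge == pytest.approx(APP_ANNUAL_COST_USD * ins_py, rel=1e-9)

    def test_horizon_mismatch_rejected(self):
        with pytest.raises(StructuralError):
            run_study(horizon=10)

    def test_directionality_of_the_intervention(self):
        """Lowering microalbuminuria onset (all else equal) must reduce
        microalbuminuria, CVD and deaths in the packaged model; without
        the direct macroalbuminuria onset edge the whole downstream
        cascade (ESRD, dialysis included) shrinks."""
        slow = build_arm("non_use", edge_overrides={("insulin_therapy", "microalbuminuria"): 0.016})
        fast = build_arm("non_use")
        t_slow = simulate_cohort(slow.model, {"insulin_therapy": 100_000.0})
        t_fast = simulate_cohort(fast.model, {"insulin_therapy": 100_000.0})
        for state in ("microalbuminuria", "cvd", "death"):
            assert t_slow.column(state)[-1] < t_fast.column(state)[-1]
        # with the direct onset edge removed the chain is pure: every
        # downstream state shrinks
        chain = settings_with(insulin_to_macro=0.0)
        slow = build_arm(
            "non_use", chain,
            edge_overrides={("insulin_therapy", "microalbuminuria"): 0.016},
        )
        fast = build_arm("non_use", chain)
        t_slow = simulate_cohort(slow.model, {"insulin_therapy": 100_000.0})
        t_fast = simulate_cohort(fast.model, {"insulin_therapy": 100_000.0})
        for state in ("microalbuminuria", "macroalbuminuria", "esrd", "dialysis", "cvd", "death"):
            assert t_slow.column(state)[-1] < t_fast.column(state)[-1]

    def test_packaged_count_changes_match_published_signs(self, default_study):
        """The app scenario shifts patients exactly the way the published
        results report: more still on plain insulin therapy, more
        macroalbuminuria (via the direct onset edge), fewer
        microalbuminuria, CVD events and deaths."""
        diff = default_study.incremental.occupancy_diff["final_cycle"]
        assert diff["insulin_therapy"] > 0
        assert diff["macroalbuminuria"] > 0
        assert diff["microalbuminuria"] < 0
        assert diff["cvd"] < 0
        assert diff["death"] < 0
        assert default_study.deaths_averted > 0

    def test_dynamic_uptake_mode(self):
        res = run_study(settings=settings_with(uptake_mode="dynamic"))
        # users accumulate over time instead of starting at 100,000
        app_members = res.trace_b_app.occupancy.sum(axis=1)
        assert app_members[0] == 0.0
        assert np.all(np.diff(app_members) > 0)
        # the two strata together still conserve the eligible cohort
        total = (res.trace_b_nonuse.occupancy + res.trace_b_app.occupancy).sum(axis=1)
        np.testing.assert_allclose(total, 686_000.0, rtol=1e-9)


class TestCalibration:
    def test_defaults_are_the_sweep_winner(self):
        """The packaged switch defaults are the frozen winner of the
        documented exhaustive search against the published headline
        numbers."""
        best = sweep().iloc[0]
        s = DEFAULT_SETTINGS
        assert best["discount_origin"] == s.discount.origin
        assert best["accrual_timing"] == s.accrual_timing
        assert bool(best["combine_insulin_cost"]) == s.combine_insulin_cost
        assert best["insulin_to_macro"] == s.insulin_to_macro
        assert best["app_cost_scope"] == "insulin"
        assert best["utility_discount"] == s.utility_discount.rate
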