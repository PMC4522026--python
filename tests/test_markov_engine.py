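import numpy as np
import pytest

from baricea.markov_engine import (
    HealthState,
    build_transition_row,
    lifetime_event_risk,
    relative_risk,
    run_cohort,
)
from baricea.risk_engine import RiskFactors, build_risk_equations, mortality_path

S = HealthState


@pytest.fixture(scope="module")
def omm_trace(params, base_profile):
    return run_cohort(base_profile, "omm", params)


@pytest.fixture(scope="module")
def surgery_trace(params, base_profile):
    return run_cohort(base_profile, "surgery", params)


class TestConservationAndAbsorption:
    @pytest.mark.parametrize("arm", ["omm", "surgery"])
    def test_rows_sum_to_one(self, params, diabetic_profile, arm):
        trace = run_cohort(diabetic_profile, arm, params)
        sums = trace.occupancy.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_occupancy_nonnegative(self, omm_trace):
        assert omm_trace.occupancy.min() >= 0.0

    def test_death_absorbing_and_monotone(self, surgery_trace):
        dead = surgery_trace.occupancy[:, list(S).index(S.DEAD)]
        assert np.all(np.diff(dead) >= -1e-15)
        assert dead[-1] > 0.999

    def test_cumulative_incidence_nondecreasing(self, omm_trace):
        for ev, flow in omm_trace.inflows.items():
            assert np.all(flow >= -1e-15), ev


class TestLifeTableOracle:
    def test_mortality_only_matches_survival_product(self, mortality_only_params, base_profile):
        """With event hazards off, the engine must reproduce pure
        life-table survival via the closed-form product."""
        trace = run_cohort(base_profile, "omm", mortality_only_params)
        n = trace.n_cycles
        q = mortality_path(
            trace.age[:-1], base_profile.sex, trace.bmi[:-1], False, mortality_only_params
        )
        survival = np.concatenate([[1.0], np.cumprod(1.0 - q)])
        assert np.allclose(trace.alive, survival, atol=1e-9)

    def test_zero_hazards_stay_in_entry_state(self, immortal_params, base_profile):
        trace = run_cohort(base_profile, "omm", immortal_params, horizon_cycles=120)
        col = list(S).index(S.OMM_NO_DIABETES)
        assert np.allclose(trace.occupancy[:, col], 1.0, atol=1e-9)
        for ev in ("angina", "mi_nonfatal", "diabetes"):
            assert lifetime_event_risk(trace, ev) == 0.0


class TestTopology:
    ALLOWED = {
        S.DEAD: {S.DEAD},
        S.INITIAL_SURGERY: {S.POST_SURGERY_DIABETES, S.POST_SURGERY_NO_DIABETES, S.DEAD},
        S.TIA: {S.POST_SURGERY_DIABETES, S.POST_SURGERY_NO_DIABETES, S.OMM_DIABETES,
                S.OMM_NO_DIABETES, S.DEAD},
        S.ACUTE_MI: {S.POST_MI, S.DEAD},
        S.ACUTE_STROKE: {S.POST_STROKE_Y1, S.DEAD},
        S.POST_STROKE_Y1: {S.POST_STROKE_Y1, S.POST_STROKE_Y2PLUS, S.DEAD},
        S.SURGICAL_COMPLICATION: {S.POST_SURGERY_DIABETES, S.POST_SURGERY_NO_DIABETES, S.DEAD},
        S.CONVERSION_SURGERY: {S.POST_SURGERY_DIABETES, S.POST_SURGERY_NO_DIABETES, S.DEAD},
    }
    EVENT_DESTS = {S.ANGINA, S.ACUTE_MI, S.ACUTE_STROKE, S.TIA, S.HEART_FAILURE, S.PAD, S.DEAD}

    @pytest.mark.parametrize("state", list(S))
    def test_rows_sum_to_one_and_respect_edges(self, params, state):
        arm = "surgery"
        rf = RiskFactors(50, "male", 35, 150, True, False)
        row = build_transition_row(state, 24, arm, rf, params)
        assert sum(row.values()) == pytest.approx(1.0, abs=1e-12)
        support = {s for s, p in row.items() if p > 0}
        if state in self.ALLOWED:
            assert support <= self.ALLOWED[state]
        else:
            chronic_allowed = self.EVENT_DESTS | {state}
            if state in (S.POST_SURGERY_DIABETES, S.POST_SURGERY_NO_DIABETES):
                chronic_allowed |= {
                    S.SURGICAL_COMPLICATION, S.CONVERSION_SURGERY,
                    S.POST_SURGERY_DIABETES, S.POST_SURGERY_NO_DIABETES,
                }
            assert support <= chronic_allowed

    def test_dead_is_absorbing(self, params):
        rf = RiskFactors(50, "male", 35, 150, False, False)
        row = build_transition_row(S.DEAD, 10, "omm", rf, params)
        assert row[S.DEAD] == 1.0

    def test_surgical_states_unreachable_in_omm(self, params, omm_trace):
        for st in (S.INITIAL_SURGERY, S.SURGICAL_COMPLICATION, S.CONVERSION_SURGERY,
                   S.POST_SURGERY_DIABETES, S.POST_SURGERY_NO_DIABETES):
            assert omm_trace.occupancy[:, list(S).index(st)].max() == 0.0
        rf = RiskFactors(50, "male", 35, 150, False, False)
        with pytest.raises(ValueError):
            build_transition_row(S.INITIAL_SURGERY, 0, "omm", rf, params)

    def test_no_self_reinfarction_counted(self, params):
        rf = RiskFactors(60, "male", 40, 160, True, True)
        row = build_transition_row(S.POST_MI, 120, "omm", rf, params)
        assert row[S.ACUTE_MI] == 0.0
        row = build_transition_row(S.ANGINA, 120, "omm", rf, params)
        assert row[S.ANGINA] > 0  # residual mass stays put


class TestEventAccounting:
    def test_unknown_event_rejected(self, omm_trace):
        with pytest.raises(KeyError):
            lifetime_event_risk(omm_trace, "appendicitis")

    def test_totals_decompose(self, omm_trace):
        assert lifetime_event_risk(omm_trace, "mi_total") == pytest.approx(
            lifetime_event_risk(omm_trace, "mi_nonfatal")
            + lifetime_event_risk(omm_trace, "mi_fatal")
        )

    def test_relative_risk_definitional(self, surgery_trace, omm_trace):
        for ev in ("angina", "heart_failure", "diabetes"):
            rr = relative_risk(surgery_trace, omm_trace, ev)
            assert rr == pytest.approx(
                lifetime_event_risk(surgery_trace, ev) / lifetime_event_risk(omm_trace, ev)
            )

    def test_identical_traces_give_unit_ratio(self, omm_trace):
        assert relative_risk(omm_trace, omm_trace, "angina") == pytest.approx(1.0)

    def test_zero_denominator_flagged(self, immortal_params, base_profile):
        t = run_cohort(base_profile, "omm", immortal_params, horizon_cycles=24)
        assert np.isnan(relative_risk(t, t, "angina"))


class TestDelayPlan:
    def test_delay_zero_is_bitwise_immediate(self, params, diabetic_profile):
        eqs = build_risk_equations(params)
        a = run_cohort(diabetic_profile, "surgery", params, eqs)
        b = run_cohort(diabetic_profile, "surgery", params, eqs, surgery_at_cycle=0)
        assert np.array_equal(a.occupancy_internal, b.occupancy_internal)
        for k in a.inflows:
            assert np.array_equal(a.inflows[k], b.inflows[k])

    def test_delayed_surgery_charged_once_at_entry(self, params, base_profile):
        t = run_cohort(base_profile, "surgery", params, surgery_at_cycle=36)
        surg = t.inflows["surgery"]
        assert surg[36] > 0.9
        assert surg.sum() == pytest.approx(surg[36])
        # before surgery no complication states are occupied
        comp_col = list(S).index(S.SURGICAL_COMPLICATION)
        assert t.occupancy[:36, comp_col].max() == 0.0
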