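import dataclasses

import numpy as np
import pytest

from conftest import make_params
from baricea.parameters import CVD_EVENTS
from baricea.risk_engine import (
    RiskFactors,
    annual_to_cycle_probability,
    background_mortality,
    build_risk_equations,
    calibrate_risk_equations,
    complication_probability,
    cvd_event_probability,
    diabetes_incidence_probability,
    diabetes_remission_probability,
    remission_relapse_schedule,
)

RF = RiskFactors(age=41, sex="female", bmi=42.8, sbp=140.1, diabetic=False, smoker=False)


class TestAnnualToCycle:
    @pytest.mark.parametrize("p, expected", [(0.0, 0.0), (1.0, 1.0), (0.12, 0.010596)])
    def test_closed_form(self, p, expected):
        assert annual_to_cycle_probability(p) == pytest.approx(expected, abs=1e-5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            annual_to_cycle_probability(1.2)
        with pytest.raises(ValueError):
            annual_to_cycle_probability(-0.1)

    def test_twelve_cycles_recompose_annual(self):
        p = 0.07
        m = annual_to_cycle_probability(p)
        assert 1 - (1 - m) ** 12 == pytest.approx(p, rel=1e-12)


class TestCvdEvents:
    @pytest.mark.parametrize("event", CVD_EVENTS)
    @pytest.mark.parametrize(
        "factor, delta",
        [("age", 10), ("sbp", 20), ("bmi", 5)],
    )
    def test_monotone_in_continuous_factors(self, params, event, factor, delta):
        eqs = build_risk_equations(params)
        worse = dataclasses.replace(RF, **{factor: getattr(RF, factor) + delta})
        assert cvd_event_probability(event, worse, eqs) > cvd_event_probability(event, RF, eqs)

    @pytest.mark.parametrize("event", CVD_EVENTS)
    @pytest.mark.parametrize("flag", ["diabetic", "smoker"])
    def test_monotone_in_binary_factors(self, params, event, flag):
        eqs = build_risk_equations(params)
        worse = dataclasses.replace(RF, **{flag: True})
        assert cvd_event_probability(event, worse, eqs) > cvd_event_probability(event, RF, eqs)

    def test_probabilities_within_unit_interval(self, params):
        eqs = build_risk_equations(params)
        extreme = RiskFactors(age=99, sex="male", bmi=60, sbp=200, diabetic=True, smoker=True)
        for event in CVD_EVENTS:
            assert 0.0 <= cvd_event_probability(event, extreme, eqs) <= 1.0

    def test_unknown_event_rejected(self, params):
        eqs = build_risk_equations(params)
        with pytest.raises(KeyError):
            cvd_event_probability("gout", RF, eqs)


class TestDiabetes:
    def test_incidence_requires_nondiabetic(self, params):
        with pytest.raises(ValueError):
            diabetes_incidence_probability(dataclasses.replace(RF, diabetic=True), params)

    def test_incidence_monotone_in_bmi(self, params):
        lo = diabetes_incidence_probability(dataclasses.replace(RF, bmi=32), params)
        hi = diabetes_incidence_probability(dataclasses.replace(RF, bmi=45), params)
        assert hi > lo > 0

    def test_zero_base_rate_gives_zero(self, params):
        p2 = make_params(params, diabetes__incidence_base_annual=0.0)
        assert diabetes_incidence_probability(RF, p2) == 0.0

    @pytest.mark.parametrize(
        "arm, month, target",
        [("surgery", 24, 0.72), ("surgery", 120, 0.36), ("omm", 24, 0.21), ("omm", 120, 0.13)],
    )
    def test_net_remission_hits_published_anchors(self, params, arm, month, target):
        # forward-simulate an initially diabetic cohort with no other
        # flows (independent oracle for the schedule construction)
        p_rem, p_rel = remission_relapse_schedule(arm, 240, params)
        diabetic, remitted = 1.0, 0.0
        for t in range(month):
            moved = diabetic * p_rem[t]
            back = remitted * p_rel[t]
            diabetic += back - moved
            remitted += moved - back
        assert remitted == pytest.approx(target, abs=0.005)

    def test_zero_anchors_give_zero_schedule(self, params):
        p2 = make_params(
            params,
            remission__surgical={
                2: {"value": 0.0, "psa_dist": None, "range": [0, 0]},
                10: {"value": 0.0, "psa_dist": None, "range": [0, 0]},
            },
        )
        p_rem, p_rel = remission_relapse_schedule("surgery", 240, p2)
        assert not p_rem.any() and not p_rel.any()

    def test_delay_attenuation_reduces_anchors(self, params):
        p_rem, _ = remission_relapse_schedule("surgery", 60, params)
        p_rem_d, _ = remission_relapse_schedule("surgery", 60, params, delay_years=3)
        diabetic = np.cumprod(1 - p_rem[:24])[-1]
        diabetic_d = np.cumprod(1 - p_rem_d[:24])[-1]
        assert 1 - diabetic_d == pytest.approx((1 - 0.045 * 3) * 0.72, abs=0.01)
        assert diabetic_d > diabetic

    def test_negative_time_rejected(self, params):
        with pytest.raises(ValueError):
            diabetes_remission_probability("surgery", -1.0, params)


class TestComplications:
    def test_unknown_complication_rejected(self, params):
        with pytest.raises(KeyError):
            complication_probability("appendectomy", 6, params)

    def test_short_term_window(self, params):
        p_short = complication_probability("leakage_abscess", 0.5, params)
        assert p_short == params.raw["complications"]["types"]["leakage_abscess"]["short_term_prob"]
        # outside both windows: zero
        assert complication_probability("leakage_abscess", 26 * 12, params) == 0.0

    def test_long_term_window(self, params):
        p = complication_probability("skin_surgery", 36, params)
        assert p == pytest.approx(annual_to_cycle_probability(0.010))
        assert complication_probability("skin_surgery", 13, params) == 0.0

    def test_zero_config_gives_zero(self, mortality_only_params):
        for name in ("cholecystectomy", "skin_surgery"):
            assert complication_probability(name, 6, mortality_only_params) == 0.0

    def test_probability_budget_validated_at_load(self, params):
        import copy

        raw = copy.deepcopy(params.raw)
        for entry in raw["complications"]["types"].values():
            entry["short_term_prob"] = 0.2
        from baricea.parameters import ConfigError, load_parameter_set

        with pytest.raises(ConfigError):
            load_parameter_set(raw)


class TestMortality:
    def test_terminal_age_absorbs(self, params):
        assert background_mortality(params.max_age, "male", params) == 1.0

    def test_monotone_in_age(self, params):
        for sex in ("male", "female"):
            assert background_mortality(70, sex, params) > background_mortality(40, sex, params)

    def test_male_excess(self, params):
        for age in (40, 60, 80):
            assert background_mortality(age, "male", params) >= background_mortality(
                age, "female", params
            )


class TestCalibration:
    def test_iterations_reduce_target_error(self, params):
        # perturb the shipped (calibrated) rates and check the
        # calibration loop pulls the model back toward the targets
        rates = {
            k: 2.0 * v for k, v in params.raw["risk_equations"]["base_annual_rates"].items()
        }
        p2 = make_params(params, risk_equations__base_annual_rates=rates)
        _, report = calibrate_risk_equations(p2, n_iter=3)
        def err(row):
            return abs(row["model_angina"] - row["target_angina"]) + abs(
                row["model_heart_failure"] - row["target_heart_failure"]
            )
        assert err(report[-1]) < 0.2 * err(report[0])
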