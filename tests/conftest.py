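import copy

import pytest

from baricea.parameters import PatientProfile, load_parameter_set


@pytest.fixture(scope="session")
def params():
    """Shipped default (calibrated) parameter set."""
    return load_parameter_set()


@pytest.fixture(scope="session")
def base_profile():
    """Cohort-mean non-diabetic non-smoking female."""
    return PatientProfile(age=41.0, sex="female", bmi=42.8, sbp=140.1, diabetic=False, smoker=False)


@pytest.fixture(scope="session")
def diabetic_profile():
    return PatientProfile(age=41.0, sex="male", bmi=42.8, sbp=140.1, diabetic=True, smoker=False)


def make_params(params, **section_updates):
    """Deep-copied raw config with section dictionaries merged in."""
    raw = copy.deepcopy(params.raw)
    for dotted, value in section_updates.items():
        node = raw
        keys = dotted.split("__")
        for k in keys[:-1]:
            node = node[k]
        node[keys[-1]] = value
    return load_parameter_set(raw)


@pytest.fixture(scope="session")
def mortality_only_params(params):
    """Background mortality is the only active hazard."""
    return make_params(
        params,
        risk_equations__base_annual_rates={
            k: 0.0 for k in params.raw["risk_equations"]["base_annual_rates"]
        },
        diabetes__incidence_base_annual=0.0,
        complications__types={
            k: dict(v, short_term_prob=0.0, annual_rate=0.0)
            for k, v in params.raw["complications"]["types"].items()
        },
        complications__conversion_surgery=dict(
            params.raw["complications"]["conversion_surgery"], short_term_prob=0.0, annual_rate=0.0
        ),
    )


@pytest.fixture(scope="session")
def immortal_params(mortality_only_params):
    """No hazards at all: negligible mortality on top of zero event rates."""
    lt = copy.deepcopy(mortality_only_params.raw["mortality"]["life_table"])
    lt["male"] = [1e-300] * len(lt["ages"])
    lt["female"] = [1e-300] * len(lt["ages"])
    return make_params(
        mortality_only_params,
        mortality__life_table=lt,
        mortality__bmi_log_hr_per_unit=0.0,
        mortality__diabetes_hr=1.0,
    )
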