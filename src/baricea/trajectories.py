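"""BMI and systolic-blood-pressure time paths by treatment arm.

Surgical BMI reductions at years 1 and 2 come from registry observations
(by procedure and sex); years 3-15 extrapolate the 2-year reduction with
a configured partial-regain shape, and the year-15 level is held stable
for the remainder of life.  The medical-management arm follows a
configured control-arm curve (default: no change).  SBP is coupled to
BMI through a configured mmHg-per-unit slope.

All curves are cohort-mean paths; individual weight variability is not
modelled.
"""

from __future__ import annotations

import numpy as np

from .parameters import PROCEDURES, SEXES, ParameterSet, PatientProfile

__all__ = [
    "surgical_bmi_delta",
    "omm_bmi_delta",
    "mixed_procedure_delta",
    "annual_delta_curve",
    "bmi_at_cycle",
    "bmi_path",
    "sbp_path",
]

_STABLE_AFTER_YEAR = 15


def surgical_bmi_delta(procedure: str, sex: str, year: int, params: ParameterSet) -> float:
    """BMI reduction (kg/m^2, positive = loss) at end of ``year`` after surgery."""
    if procedure not in PROCEDURES:
        raise KeyError(f"unknown procedure {procedure!r}")
    if sex not in SEXES:
        raise KeyError(f"unknown sex {sex!r}")
    if year < 1:
        raise ValueError(f"year must be >= 1, got {year}")
    year = min(year, _STABLE_AFTER_YEAR)
    if year in (1, 2):
        return params.bmi_delta(procedure, sex, year)
    mult = params.raw["trajectory"]["regain_multiplier_by_year"]
    return params.bmi_delta(procedure, sex, 2) * float(mult[year])


def omm_bmi_delta(sex: str, year: int, params: ParameterSet) -> float:
    """BMI reduction under medical management (default curve: zero)."""
    if year < 1:
        raise ValueError(f"year must be >= 1, got {year}")
    year = min(year, _STABLE_AFTER_YEAR)
    curve = params.raw["trajectory"]["omm_delta_by_year"]
    years = sorted(curve)
    # piecewise-linear between configured anchors, flat outside
    if year <= years[0]:
        return float(curve[years[0]])
    if year >= years[-1]:
        return float(curve[years[-1]])
    return float(np.interp(year, years, [curve[y] for y in years]))


def mixed_procedure_delta(
    mix: dict[str, float], sex: str, year: int, params: ParameterSet
) -> float:
    """Procedure-mix-weighted BMI reduction."""
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"procedure mix must sum to 1, got {total}")
    return sum(
        w * surgical_bmi_delta(proc, sex, year, params) for proc, w in mix.items() if w
    )


def annual_delta_curve(
    arm: str,
    sex: str,
    params: ParameterSet,
    mix: dict[str, float] | None = None,
    n_years: int = 80,
) -> np.ndarray:
    """Yearly BMI-reduction anchors, index 0 = baseline (delta 0)."""
    if arm == "omm":
        deltas = [omm_bmi_delta(sex, y, params) for y in range(1, n_years + 1)]
    elif arm == "surgery":
        mix = params.procedure_mix if mix is None else mix
        deltas = [mixed_procedure_delta(mix, sex, y, params) for y in range(1, n_years + 1)]
    else:
        raise ValueError(f"arm must be 'surgery' or 'omm', got {arm!r}")
    return np.array([0.0] + deltas)


def bmi_at_cycle(
    profile: PatientProfile,
    arm: str,
    cycle: int,
    params: ParameterSet,
    mix: dict[str, float] | None = None,
) -> float:
    """BMI at a monthly cycle: linear interpolation of the annual curve."""
    if cycle < 0:
        raise ValueError(f"cycle must be >= 0, got {cycle}")
    curve = annual_delta_curve(arm, profile.sex, params, mix=mix)
    return float(
        _apply_curve(profile.bmi, curve, np.array([cycle]), params.bmi_floor)[0]
    )


def _apply_curve(
    baseline: float, curve: np.ndarray, cycles: np.ndarray, floor: float
) -> np.ndarray:
    years = np.arange(len(curve))
    delta = np.interp(cycles / 12.0, years, curve)
    return np.maximum(baseline - delta, floor)


def bmi_path(
    profile: PatientProfile,
    arm: str,
    n_cycles: int,
    params: ParameterSet,
    mix: dict[str, float] | None = None,
    surgery_at_cycle: int | None = None,
) -> np.ndarray:
    """Monthly BMI path over ``n_cycles`` cycles (length ``n_cycles + 1``).

    ``surgery_at_cycle`` supports waiting-list plans: the path follows
    the medical-management curve until that cycle, then the surgical
    curve re-anchored at the BMI reached at surgery.
    """
    cycles = np.arange(n_cycles + 1)
    if arm == "omm":
        curve = annual_delta_curve("omm", profile.sex, params)
        return _apply_curve(profile.bmi, curve, cycles, params.bmi_floor)
    t0 = 0 if surgery_at_cycle is None else int(surgery_at_cycle)
    omm_curve = annual_delta_curve("omm", profile.sex, params)
    pre = _apply_curve(profile.bmi, omm_curve, cycles[: t0 + 1], params.bmi_floor)
    surg_curve = annual_delta_curve("surgery", profile.sex, params, mix=mix)
    post = _apply_curve(float(pre[-1]), surg_curve, cycles[: n_cycles - t0 + 1], params.bmi_floor)
    return np.concatenate([pre[:-1], post])


def sbp_path(
    profile: PatientProfile,
    bmi: np.ndarray,
    params: ParameterSet,
) -> np.ndarray:
    """SBP path coupled to the BMI path, floored at the configured minimum."""
    k = float(params.raw["trajectory"]["sbp_per_bmi_unit"])
    sbp = profile.sbp - k * (profile.bmi - bmi)
    return np.maximum(sbp, params.sbp_floor)
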