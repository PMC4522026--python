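"""Named analyses: base case, subgroup grid, waiting-list delay,
procedure mix and population extrapolation."""

from __future__ import annotations

from .economics import (
    ArmResult,
    ComparisonResult,
    average_arm_results,
    compare,
    evaluate_arm,
)
from .markov_engine import run_cohort
from .parameters import ParameterSet, PatientProfile
from .risk_engine import RiskEquationSet, build_risk_equations
from .synthetic_cohort import (
    generate_cohort,
    subgroup_grid_profiles,
    weighted_mean_profiles,
)

__all__ = [
    "evaluate_profile",
    "run_base_case",
    "run_deterministic_base",
    "run_delay_scenario",
    "run_subgroup_grid",
    "run_procedure_mix",
    "extrapolate_to_population",
]


def evaluate_profile(
    profile: PatientProfile,
    params: ParameterSet,
    eqs: RiskEquationSet | None = None,
    mix: dict[str, float] | None = None,
    surgery_at_cycle: int | None = None,
) -> tuple[ArmResult, ArmResult]:
    """(surgery, omm) arm results for one profile."""
    if eqs is None:
        eqs = build_risk_equations(params)
    t_s = run_cohort(
        profile, "surgery", params, eqs, mix=mix, surgery_at_cycle=surgery_at_cycle
    )
    t_o = run_cohort(profile, "omm", params, eqs)
    return evaluate_arm(t_s, params), evaluate_arm(t_o, params)


def run_base_case(
    params: ParameterSet,
    eqs: RiskEquationSet | None = None,
    n_profiles: int | None = None,
    seed: int = 1,
) -> ComparisonResult:
    """Multiple-cohort base case: average over sampled candidate profiles."""
    if eqs is None:
        eqs = build_risk_equations(params)
    if n_profiles is None:
        n_profiles = int(params.raw["scenarios"]["base_case_n_profiles"])
    cohort = generate_cohort(n_profiles, params, seed)
    surg, omm = [], []
    for p in cohort:
        s, o = evaluate_profile(p, params, eqs)
        surg.append(s)
        omm.append(o)
    return compare(
        average_arm_results(surg), average_arm_results(omm), params.wtp_threshold
    )


def run_deterministic_base(
    params: ParameterSet,
    eqs: RiskEquationSet | None = None,
    mix: dict[str, float] | None = None,
) -> ComparisonResult:
    """Base case on the deterministic mean-characteristic cohort.

    Used where reproducibility without Monte-Carlo noise matters
    (tornado analysis, procedure-mix deltas, time-to-cost-effectiveness).
    """
    if eqs is None:
        eqs = build_risk_equations(params)
    profiles = weighted_mean_profiles(params)
    surg, omm, w = [], [], []
    for p in profiles:
        s, o = evaluate_profile(p, params, eqs, mix=mix)
        surg.append(s)
        omm.append(o)
        w.append(p.weight)
    return compare(
        average_arm_results(surg, w), average_arm_results(omm, w), params.wtp_threshold
    )


def run_delay_scenario(
    profile: PatientProfile,
    params: ParameterSet,
    eqs: RiskEquationSet | None = None,
    delay_years: float | None = None,
) -> dict[str, float]:
    """Deltas (delayed minus immediate surgery) of cost, LY and QALYs.

    The delayed patient follows medical management for ``delay_years``
    (BMI per the control curve, diabetes may onset or remit on the
    medical schedule), then undergoes surgery with the risk factors
    reached at that point.
    """
    if eqs is None:
        eqs = build_risk_equations(params)
    if delay_years is None:
        delay_years = float(params.raw["scenarios"]["delay_years"])
    if delay_years < 0:
        raise ValueError("delay_years must be >= 0")
    delay_cycles = int(round(delay_years * 12))
    immediate = evaluate_arm(run_cohort(profile, "surgery", params, eqs), params)
    delayed = evaluate_arm(
        run_cohort(profile, "surgery", params, eqs, surgery_at_cycle=delay_cycles),
        params,
    )
    return {
        "delta_cost": delayed.total_cost - immediate.total_cost,
        "delta_ly": delayed.life_years - immediate.life_years,
        "delta_qaly": delayed.qalys - immediate.qalys,
    }


def run_subgroup_grid(
    params: ParameterSet, eqs: RiskEquationSet | None = None
) -> dict[tuple[str, str, bool], ComparisonResult]:
    """Comparisons for the 16 fixed subgroup cohorts."""
    if eqs is None:
        eqs = build_risk_equations(params)
    out = {}
    for key, profile in subgroup_grid_profiles(params).items():
        s, o = evaluate_profile(profile, params, eqs)
        out[key] = compare(s, o, params.wtp_threshold)
    return out


def run_procedure_mix(
    mix_a: dict[str, float],
    mix_b: dict[str, float],
    params: ParameterSet,
    eqs: RiskEquationSet | None = None,
) -> dict[str, float]:
    """Per-patient loss/gain of running mix_b instead of mix_a.

    Returned deltas are (mix_b surgery arm) minus (mix_a surgery arm):
    a negative ``delta_qaly`` means mix_b forgoes health benefit.
    """
    if eqs is None:
        eqs = build_risk_equations(params)
    profiles = weighted_mean_profiles(params)
    w = [p.weight for p in profiles]
    res = {}
    for name, mix in (("a", mix_a), ("b", mix_b)):
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mix_{name} must sum to 1, got {total}")
        arms = [
            evaluate_arm(run_cohort(p, "surgery", params, eqs, mix=mix), params)
            for p in profiles
        ]
        res[name] = average_arm_results(arms, w)
    return {
        "delta_cost": res["b"].total_cost - res["a"].total_cost,
        "delta_qaly": res["b"].qalys - res["a"].qalys,
        "delta_ly": res["b"].life_years - res["a"].life_years,
    }


def extrapolate_to_population(
    comparison: ComparisonResult, n_patients: int
) -> dict[str, float]:
    """Scale per-patient discounted deltas to a treated population."""
    if n_patients < 0:
        raise ValueError("n_patients must be >= 0")
    return {
        "person_years": comparison.delta_ly * n_patients,
        "qaly_person_years": comparison.delta_qaly * n_patients,
        "total_savings": -comparison.delta_cost * n_patients,
    }
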