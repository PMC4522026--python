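"""Transition hazards: cardiovascular events, diabetes, complications, death.

The cardiovascular machinery follows the risk-factor-driven design of
decision models in this area: a patient's current age, sex, SBP, BMI,
diabetes and smoking status enter a Framingham-type log-linear hazard
shared across the six event types (angina, myocardial infarction,
stroke, transient ischaemic attack, heart failure, peripheral arterial
disease), each anchored by a per-event baseline annual rate.  The
baseline rates are calibrated once — by :func:`calibrate_risk_equations`
— so that the medical-management arm reproduces the configured lifetime
risk targets; the shipped configuration stores the calibrated values.

Diabetes dynamics combine BMI-dependent incidence with a net-remission
schedule anchored at the published 2- and 10-year remitted proportions
for each arm (remission and relapse hazards are derived from the net
curve, since only net proportions are observed).

Implementations are provided both as scalar functions (the documented
operation contracts) and as vectorized per-cycle arrays consumed by the
Markov engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .parameters import CVD_EVENTS, ParameterSet, PatientProfile

__all__ = [
    "RiskFactors",
    "RiskEquationSet",
    "FraminghamLikeEquations",
    "build_risk_equations",
    "RISK_EQUATION_REGISTRY",
    "annual_to_cycle_probability",
    "cvd_event_probability",
    "diabetes_incidence_probability",
    "diabetes_remission_probability",
    "remission_relapse_schedule",
    "complication_probability",
    "background_mortality",
    "calibrate_risk_equations",
]

COMPLICATIONS = (
    "cholecystectomy",
    "hernia_repair",
    "leakage_abscess",
    "gastric_stricture",
    "gastric_ulcer",
    "skin_surgery",
)


@dataclass(frozen=True)
class RiskFactors:
    """Current risk-factor vector; age may exceed 65 as the cohort ages."""

    age: float
    sex: str
    bmi: float
    sbp: float
    diabetic: bool
    smoker: bool

    @classmethod
    def from_profile(cls, p: PatientProfile) -> "RiskFactors":
        return cls(p.age, p.sex, p.bmi, p.sbp, p.diabetic, p.smoker)


def annual_to_cycle_probability(p_annual: float | np.ndarray) -> float | np.ndarray:
    """Convert an annual probability to a monthly one: 1 - (1-p)^(1/12)."""
    p = np.asarray(p_annual, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("annual probability outside [0, 1]")
    out = 1.0 - (1.0 - p) ** (1.0 / 12.0)
    return float(out) if np.isscalar(p_annual) or p.ndim == 0 else out


class RiskEquationSet:
    """Contract for pluggable per-event annual-probability equations."""

    events: tuple[str, ...] = CVD_EVENTS

    def annual_probability(self, event: str, rf: RiskFactors) -> float:
        raise NotImplementedError

    def annual_probability_path(
        self,
        event: str,
        age: np.ndarray,
        sex: str,
        bmi: np.ndarray,
        sbp: np.ndarray,
        diabetic: bool,
        smoker: bool,
    ) -> np.ndarray:
        raise NotImplementedError

    def fatal_fraction(self, event: str) -> float:
        return 0.0


@dataclass(frozen=True)
class FraminghamLikeEquations(RiskEquationSet):
    """Shared log-linear hazard with per-event baseline annual rates.

    annual rate(event) = base[event] * exp(b_age*(age-ref) + b_male*male
    + b_sbp*(sbp-ref) + b_bmi*(bmi-ref) + b_dm*dm + b_smoke*smoke),
    converted to a probability with 1 - exp(-rate) and capped at 1.
    """

    coefficients: Mapping[str, float]
    reference: Mapping[str, float]
    base_annual_rates: Mapping[str, float]
    event_fatal_fractions: Mapping[str, float]

    def _log_rr(
        self, age: np.ndarray, sex: str, bmi: np.ndarray, sbp: np.ndarray,
        diabetic: bool, smoker: bool,
    ) -> np.ndarray:
        c, ref = self.coefficients, self.reference
        lp = (
            c["age"] * (age - ref["age"])
            + c["sbp"] * (sbp - ref["sbp"])
            + c["bmi"] * (bmi - ref["bmi"])
        )
        if sex == "male":
            lp = lp + c["male"]
        if diabetic:
            lp = lp + c["diabetes"]
        if smoker:
            lp = lp + c["smoking"]
        return lp

    def annual_probability(self, event: str, rf: RiskFactors) -> float:
        return float(
            self.annual_probability_path(
                event,
                np.array([rf.age]),
                rf.sex,
                np.array([rf.bmi]),
                np.array([rf.sbp]),
                rf.diabetic,
                rf.smoker,
            )[0]
        )

    def annual_probability_path(
        self, event, age, sex, bmi, sbp, diabetic, smoker
    ) -> np.ndarray:
        if event not in self.base_annual_rates:
            raise KeyError(f"unknown event {event!r}")
        rate = self.base_annual_rates[event] * np.exp(
            self._log_rr(age, sex, bmi, sbp, diabetic, smoker)
        )
        return 1.0 - np.exp(-rate)

    def fatal_fraction(self, event: str) -> float:
        return float(self.event_fatal_fractions.get(event, 0.0))

    def with_base_rates(self, rates: Mapping[str, float]) -> "FraminghamLikeEquations":
        return FraminghamLikeEquations(
            coefficients=dict(self.coefficients),
            reference=dict(self.reference),
            base_annual_rates=dict(rates),
            event_fatal_fractions=dict(self.event_fatal_fractions),
        )


def _build_framingham(params: ParameterSet) -> FraminghamLikeEquations:
    block = params.raw["risk_equations"]
    return FraminghamLikeEquations(
        coefficients={k: float(v) for k, v in block["coefficients"].items()},
        reference={k: float(v) for k, v in block["reference"].items()},
        base_annual_rates={k: float(v) for k, v in block["base_annual_rates"].items()},
        event_fatal_fractions={
            k: float(v) for k, v in block["event_fatal_fractions"].items()
        },
    )


RISK_EQUATION_REGISTRY = {"framingham_default": _build_framingham}


def build_risk_equations(params: ParameterSet) -> RiskEquationSet:
    """Instantiate the risk-equation plug-in named in the configuration."""
    name = str(params.raw["risk_equations"]["name"])
    try:
        factory = RISK_EQUATION_REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown risk-equation plug-in {name!r}") from None
    return factory(params)


def cvd_event_probability(event: str, rf: RiskFactors, eqs: RiskEquationSet) -> float:
    """Per-cycle (monthly) probability of ``event`` for the given factors."""
    if event not in eqs.events:
        raise KeyError(f"unknown event {event!r}")
    return float(annual_to_cycle_probability(eqs.annual_probability(event, rf)))


# ---------------------------------------------------------------------------
# Diabetes


def _incidence_annual(bmi: np.ndarray, params: ParameterSet) -> np.ndarray:
    d = params.raw["diabetes"]
    rate = float(d["incidence_base_annual"]) * np.exp(
        float(d["incidence_bmi_log_slope"]) * (bmi - float(d["incidence_reference_bmi"]))
    )
    return 1.0 - np.exp(-rate)


def diabetes_incidence_probability(rf: RiskFactors, params: ParameterSet) -> float:
    """Per-cycle probability of diabetes onset (non-diabetics only)."""
    if rf.diabetic:
        raise ValueError("incidence is defined only for non-diabetic patients")
    return float(annual_to_cycle_probability(_incidence_annual(np.array(rf.bmi), params)))


def _net_remission_curve(r2: float, r10: float, n_months: int) -> np.ndarray:
    """Net remitted proportion by month since arm entry.

    Linear ramp 0 -> r2 over months 0..24, then log-linear bridge to the
    10-year anchor, constant afterwards.  Handles both net relapse
    (r10 < r2, the observed pattern) and net further remission.
    """
    m = np.arange(n_months + 1, dtype=float)
    curve = np.empty_like(m)
    ramp = np.minimum(m, 24.0) / 24.0
    curve = r2 * ramp
    after = m > 24
    if r2 <= 0:
        curve[after] = r10 * np.minimum((m[after] - 24) / 96.0, 1.0)
    else:
        frac = np.minimum((m[after] - 24) / 96.0, 1.0)
        if r10 <= 0:
            curve[after] = r2 * (1.0 - frac)
        else:
            curve[after] = r2 * (r10 / r2) ** frac
    return curve


def remission_relapse_schedule(
    arm: str, n_months: int, params: ParameterSet, delay_years: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Monthly remission and relapse probabilities realizing the net curve.

    Returns ``(p_remission, p_relapse)`` arrays of length ``n_months``;
    ``p_remission[t]`` applies to currently diabetic mass during month
    t -> t+1, ``p_relapse[t]`` to currently remitted mass.

    ``delay_years`` attenuates the surgical anchors for waiting-list
    plans: remission odds after bariatric surgery decline with diabetes
    duration, so each year of delayed surgery scales the net-remission
    targets down by the configured relative factor.
    """
    key = {"surgery": "surgical", "surgical": "surgical", "omm": "omm"}.get(arm)
    if key is None:
        raise KeyError(f"unknown arm {arm!r}")
    r2 = params.remission_anchor(key, 2)
    r10 = params.remission_anchor(key, 10)
    if delay_years > 0 and key == "surgical":
        atten = float(
            params.raw["remission"].get("delay_attenuation_per_year", 0.0)
        )
        factor = max(0.0, 1.0 - atten * delay_years)
        r2 *= factor
        r10 *= factor
    curve = _net_remission_curve(r2, r10, n_months)
    p_rem = np.zeros(n_months)
    p_rel = np.zeros(n_months)
    dR = np.diff(curve)
    rising = dR > 0
    denom_rem = 1.0 - curve[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        p_rem[rising] = dR[rising] / denom_rem[rising]
        falling = dR < 0
        p_rel[falling] = -dR[falling] / curve[:-1][falling]
    return np.clip(p_rem, 0.0, 1.0), np.clip(p_rel, 0.0, 1.0)


def diabetes_remission_probability(
    arm: str, years_since_entry: float, params: ParameterSet
) -> float:
    """Per-cycle net remission probability at a given time since entry.

    Negative values are never returned; months of net relapse yield 0
    (the relapse flow is carried by the paired relapse schedule).
    """
    if years_since_entry < 0:
        raise ValueError(f"years_since_entry must be >= 0, got {years_since_entry}")
    month = int(round(years_since_entry * 12))
    p_rem, _ = remission_relapse_schedule(arm, month + 1, params)
    return float(p_rem[month])


# ---------------------------------------------------------------------------
# Surgical complications


def complication_probability(
    complication: str, months_since_surgery: float, params: ParameterSet
) -> float:
    """Per-cycle probability of one complication type (piecewise-constant).

    The short-term probability applies once within the first
    post-operative month; afterwards the long-term annual rate applies
    inside its configured year window.
    """
    if months_since_surgery < 0:
        raise ValueError("months_since_surgery must be >= 0")
    if complication == "conversion_surgery":
        entry = params.raw["complications"]["conversion_surgery"]
    else:
        try:
            entry = params.raw["complications"]["types"][complication]
        except KeyError:
            raise KeyError(f"unknown complication {complication!r}") from None
    if months_since_surgery <= 1:
        return float(entry["short_term_prob"])
    y0, y1 = entry["window_years"]
    year = months_since_surgery / 12.0
    if y0 <= year <= y1:
        return float(annual_to_cycle_probability(float(entry["annual_rate"])))
    return 0.0


def complication_schedules(
    n_months: int, params: ParameterSet, surgery_at: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aggregate per-cycle complication probability, expected cost per
    complication entry, and conversion-surgery probability, as arrays
    indexed by model cycle (``surgery_at`` shifts the clock)."""
    p_total = np.zeros(n_months)
    cost_weighted = np.zeros(n_months)
    p_conv = np.zeros(n_months)
    months = np.arange(n_months, dtype=float) - surgery_at
    types = params.raw["complications"]["types"]
    for name in COMPLICATIONS:
        entry = types[name]
        p = np.zeros(n_months)
        short = (months >= 0) & (months < 1)
        p[short] = float(entry["short_term_prob"])
        y = months / 12.0
        y0, y1 = entry["window_years"]
        longterm = (months >= 1) & (y >= y0) & (y <= y1)
        p[longterm] = annual_to_cycle_probability(float(entry["annual_rate"]))
        p_total += p
        cost_weighted += p * float(entry["cost_eur"])
    conv = params.raw["complications"]["conversion_surgery"]
    y = months / 12.0
    y0, y1 = conv["window_years"]
    mask = (months >= 1) & (y >= y0) & (y <= y1)
    p_conv[mask] = annual_to_cycle_probability(float(conv["annual_rate"]))
    with np.errstate(invalid="ignore"):
        cost_per_entry = np.where(p_total > 0, cost_weighted / np.maximum(p_total, 1e-300), 0.0)
    return p_total, cost_per_entry, p_conv


# ---------------------------------------------------------------------------
# Mortality


def _life_table_annual_q(age: np.ndarray, sex: str, params: ParameterSet) -> np.ndarray:
    lt = params.raw["mortality"]["life_table"]
    ages = np.asarray(lt["ages"], dtype=float)
    q = np.asarray(lt[sex], dtype=float)
    # log-linear interpolation between anchor ages; terminal value at max age
    logq = np.interp(np.clip(age, ages[0], ages[-1]), ages, np.log(q))
    out = np.exp(logq)
    out[age >= ages[-1]] = q[-1]
    return out


def background_mortality(age: float, sex: str, params: ParameterSet) -> float:
    """Per-cycle all-cause death probability from the bundled life table."""
    if age < 0:
        raise ValueError("age must be >= 0")
    if age >= float(params.max_age):
        return 1.0
    q = float(_life_table_annual_q(np.array([age], dtype=float), sex, params)[0])
    return float(annual_to_cycle_probability(q))


def mortality_path(
    age: np.ndarray,
    sex: str,
    bmi: np.ndarray,
    diabetic: bool,
    params: ParameterSet,
) -> np.ndarray:
    """Monthly death probability path with BMI and diabetes hazard ratios.

    Hazard ratios act on the annual hazard scale (proportional hazards),
    so q_eff = 1 - (1-q)^HR before the monthly conversion.
    """
    m = params.raw["mortality"]
    q = _life_table_annual_q(age, sex, params)
    hr = np.exp(float(m["bmi_log_hr_per_unit"]) * (bmi - float(m["bmi_reference"])))
    if diabetic:
        hr = hr * float(m["diabetes_hr"])
    q_eff = 1.0 - (1.0 - q) ** hr
    out = annual_to_cycle_probability(np.clip(q_eff, 0.0, 1.0))
    out = np.asarray(out)
    out[age >= float(params.max_age)] = 1.0
    return out


# ---------------------------------------------------------------------------
# Calibration


def calibrate_risk_equations(
    params: ParameterSet,
    n_iter: int = 6,
    targets: Mapping[str, float] | None = None,
) -> tuple[ParameterSet, list[dict[str, float]]]:
    """One-time calibration of baseline event rates and diabetes incidence.

    Scales each event's baseline annual rate (and the diabetes incidence
    base rate) multiplicatively until the medical-management arm of the
    deterministic mean-characteristic cohort reproduces the configured
    lifetime-risk targets.  Returns the updated parameter set and a
    report (one row per iteration) suitable for CSV export.
    """
    from .markov_engine import lifetime_event_risk, run_cohort
    from .synthetic_cohort import weighted_mean_profiles

    if targets is None:
        targets = {
            k: float(v)
            for k, v in params.raw["calibration"]["omm_lifetime_risk_targets"].items()
        }

    target_events = {
        "angina": "angina",
        "mi_total": "mi_total",
        "stroke_total": "stroke_total",
        "tia": "tia",
        "heart_failure": "heart_failure",
        "pad": "pad",
        "diabetes": "diabetes",
    }
    rate_key = {
        "angina": "angina",
        "mi_total": "mi",
        "stroke_total": "stroke",
        "tia": "tia",
        "heart_failure": "heart_failure",
        "pad": "pad",
    }

    surg_target = params.raw["calibration"].get("surgical_arm_targets", {})
    dm_surg_target = float(surg_target.get("diabetes", 0.0)) or None

    report: list[dict[str, float]] = []
    current = params
    for it in range(n_iter):
        profiles = weighted_mean_profiles(current)
        risks = {k: 0.0 for k in target_events}
        dm_surg = 0.0
        for p in profiles:
            trace = run_cohort(p, "omm", current)
            for tname, ev in target_events.items():
                risks[tname] += p.weight * lifetime_event_risk(trace, ev)
            if dm_surg_target is not None:
                trace_s = run_cohort(p, "surgery", current)
                dm_surg += p.weight * lifetime_event_risk(trace_s, "diabetes")
        row = {"iteration": float(it)}
        updates: dict[tuple, float] = {}
        for tname, model_val in risks.items():
            target = targets[tname]
            row[f"model_{tname}"] = model_val
            row[f"target_{tname}"] = target
            factor = target / model_val if model_val > 0 else 1.0
            factor = float(np.clip(factor, 0.1, 10.0))
            if tname == "diabetes":
                old = float(current.raw["diabetes"]["incidence_base_annual"])
                updates[("diabetes", "incidence_base_annual")] = old * factor
            else:
                rk = rate_key[tname]
                old = float(current.raw["risk_equations"]["base_annual_rates"][rk])
                updates[("risk_equations", "base_annual_rates", rk)] = old * factor
        if dm_surg_target is not None and risks["diabetes"] > 0 and dm_surg > 0:
            # fit the incidence BMI gradient to the surgical-arm target:
            # the arm ratio scales roughly as exp(slope * dBMI)
            row["model_surgical_diabetes"] = dm_surg
            row["target_surgical_diabetes"] = dm_surg_target
            rr_model = dm_surg / risks["diabetes"]
            rr_target = dm_surg_target / targets["diabetes"]
            if 0 < rr_model < 1 and 0 < rr_target < 1:
                slope = float(current.raw["diabetes"]["incidence_bmi_log_slope"])
                adj = float(np.clip(np.log(rr_target) / np.log(rr_model), 0.5, 2.0))
                updates[("diabetes", "incidence_bmi_log_slope")] = slope * adj
        report.append(row)
        current = current.with_raw_updates(updates)
    return current, report
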