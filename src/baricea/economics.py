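"""Discounted costs, life-years, QALYs, ICERs and dominance.

Costs and outcomes beyond the first year are discounted at the
configured annual rate (Swedish convention: the first model year is
undiscounted, year Y carries the factor (1+r)^-(Y-1)).  Annual state
costs are accrued monthly; one-off tariffs (surgery, acute myocardial
infarction, acute stroke, transient ischaemic attack, complications,
conversion surgery) are charged on entry to their state.

The diabetes treatment cost follows the diabetic attribute of the
cohort, so diabetic patients continue to accrue diabetes care while
occupying a cardiovascular event state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov_engine import (
    CohortTrace,
    _I_ANGINA,
    _I_BASE_DM,
    _I_BASE_NODM,
    _I_DEAD,
    _I_HF,
    _I_PAD,
    _I_PMI,
    _I_PS2,
    _I_SURG,
    _I_TUN0,
)
from .parameters import ParameterSet
from .risk_engine import complication_schedules

__all__ = [
    "ArmResult",
    "ComparisonResult",
    "discount_factor",
    "evaluate_arm",
    "compare",
    "average_arm_results",
    "time_to_cost_effectiveness",
]


@dataclass(frozen=True)
class ArmResult:
    """Discounted (and undiscounted) totals for one strategy."""

    total_cost: float
    life_years: float
    qalys: float
    total_cost_undiscounted: float
    life_years_undiscounted: float
    qalys_undiscounted: float
    event_risks: dict[str, float]
    # per-cycle discounted accruals, for truncated-horizon analyses
    cost_by_cycle: np.ndarray | None = None
    qaly_by_cycle: np.ndarray | None = None
    ly_by_cycle: np.ndarray | None = None


@dataclass(frozen=True)
class ComparisonResult:
    """Incremental results of surgery versus medical management."""

    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer: float | None  # EUR/QALY; None when labelled
    label: str  # "icer", "dominant", "dominated", "undefined"
    cost_effective: bool
    surgery: ArmResult | None = None
    omm: ArmResult | None = None


def discount_factor(time_years: float | np.ndarray, rate: float) -> float | np.ndarray:
    """Discount factor: 1 within the first year, (1+r)^-(Y-1) in year Y."""
    t = np.asarray(time_years, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    years = np.maximum(np.ceil(t), 1.0)  # year index Y >= 1; t=2.0 is year 2
    out = (1.0 + rate) ** (-(years - 1.0))
    return float(out) if np.isscalar(time_years) else out


def _cycle_discount_factors(n_cycles: int, rate: float) -> np.ndarray:
    # cycle t covers (t, t+1] months; its year index is floor(t/12) + 1
    years = np.arange(n_cycles) // 12
    return (1.0 + rate) ** (-years.astype(float))


def evaluate_arm(trace: CohortTrace, params: ParameterSet) -> ArmResult:
    """Accumulate discounted cost, life-years and QALYs from a trace."""
    n = trace.n_cycles
    occ = trace.occupancy_internal  # (n+1, 26, 3)
    costs = params.costs
    util = params.utilities
    df = _cycle_discount_factors(n, params.discount_rate)

    # state-occupancy snapshot at the END of each cycle (membership
    # counted at cycle end; no half-cycle correction)
    end = occ[1:]  # (n, 26, 3)
    alive = 1.0 - end[:, _I_DEAD, :].sum(axis=1)

    # --- annual state costs, accrued monthly ---------------------------
    annual_state_cost = np.zeros(26)
    annual_state_cost[_I_ANGINA] = costs.eur("annual", "angina")
    annual_state_cost[_I_PMI] = costs.eur("annual", "post_mi")
    annual_state_cost[_I_TUN0 : _I_TUN0 + 12] = costs.eur("annual", "post_stroke_y1")
    annual_state_cost[_I_PS2] = costs.eur("annual", "post_stroke_y2plus")
    annual_state_cost[_I_HF] = costs.eur("annual", "heart_failure")
    annual_state_cost[_I_PAD] = costs.eur("annual", "pad")
    occ_states = end.sum(axis=2)  # (n, 26)
    cost_cycle = occ_states @ (annual_state_cost / 12.0)

    # management / follow-up care applies while in the living base
    # states: medical-management cost for life in the OMM arm (and
    # during a surgical wait), post-surgical follow-up for a configured
    # number of years after the operation
    base_mass = occ_states[:, _I_BASE_DM] + occ_states[:, _I_BASE_NODM]
    months = np.arange(n, dtype=float)
    t0_cost = trace.surgery_at_cycle or 0
    omm_mgmt = costs.eur("annual", "omm_management")
    followup = costs.eur("annual", "surgical_followup")
    fu_years = float(
        params.raw["costs"]["annual"]["surgical_followup"].get("window_years", np.inf)
    )
    if trace.arm == "omm":
        mgmt_annual = np.full(n, omm_mgmt)
    else:
        since_surgery = months - t0_cost
        mgmt_annual = np.where(
            since_surgery < 0,
            omm_mgmt,
            np.where(since_surgery < fu_years * 12.0, followup, 0.0),
        )
    cost_cycle = cost_cycle + base_mass * mgmt_annual / 12.0
    # diabetes care follows the diabetic attribute through every state
    diabetic_mass = end[:, :_I_DEAD, 1].sum(axis=1)
    cost_cycle = cost_cycle + diabetic_mass * (costs.eur("annual", "diabetes") / 12.0)

    # --- one-off costs on event inflows --------------------------------
    inf = trace.inflows
    p_surg_comp = float(params.raw["complications"]["surgery_complication_prob"])
    surgery_unit = costs.eur("one_off", "surgery_no_complication") * (1 - p_surg_comp) + costs.eur(
        "one_off", "surgery_with_complication"
    ) * p_surg_comp
    t0 = trace.surgery_at_cycle or 0
    _, ccomp, _ = complication_schedules(n, params, surgery_at=t0 if trace.arm != "omm" else 0)
    oneoff_cycle = (
        inf["surgery"][1:] * surgery_unit
        + inf["tia"][1:] * costs.eur("one_off", "tia")
        + inf["mi_nonfatal"][1:] * costs.eur("one_off", "acute_mi")
        + inf["stroke_nonfatal"][1:] * costs.eur("one_off", "acute_stroke")
        + inf["conversion"][1:] * costs.eur("one_off", "conversion_surgery")
        + inf["complication"][1:] * ccomp[: n]
    )
    # surgery charged at entry (inflow recorded at the entry cycle index)
    oneoff_cycle = oneoff_cycle + np.concatenate([[inf["surgery"][0] * surgery_unit], np.zeros(n - 1)])
    cost_cycle = cost_cycle + oneoff_cycle

    # --- utilities ------------------------------------------------------
    state_mult = np.ones(26)
    name_by_idx = {
        _I_SURG: "initial_surgery",
        _I_ANGINA: "angina",
        4: "acute_mi",
        _I_PMI: "post_mi",
        6: "acute_stroke",
        _I_PS2: "post_stroke_y2plus",
        20: "tia",
        _I_HF: "heart_failure",
        _I_PAD: "pad",
        23: "surgical_complication",
        24: "conversion_surgery",
    }
    for idx in range(_I_TUN0, _I_TUN0 + 12):
        name_by_idx[idx] = "post_stroke_y1"
    for idx, name in name_by_idx.items():
        state_mult[idx] = util.state_multipliers.get(name, 1.0)
    state_mult[_I_DEAD] = 0.0

    bmi_end = trace.bmi[1:]
    u_nodm = util.baseline_array(bmi_end, diabetic=False)  # (n,)
    u_dm = util.baseline_array(bmi_end, diabetic=True)
    # mass x state multiplier, split by diabetic attribute
    nondm_mass = end[:, :, 0] + end[:, :, 2]
    qaly_cycle = (
        (nondm_mass @ state_mult) * u_nodm + (end[:, :, 1] @ state_mult) * u_dm
    ) / 12.0
    ly_cycle = alive / 12.0

    return ArmResult(
        total_cost=float(cost_cycle @ df),
        life_years=float(ly_cycle @ df),
        qalys=float(qaly_cycle @ df),
        total_cost_undiscounted=float(cost_cycle.sum()),
        life_years_undiscounted=float(ly_cycle.sum()),
        qalys_undiscounted=float(qaly_cycle.sum()),
        event_risks={k: float(v[: n + 1].sum()) for k, v in inf.items()},
        cost_by_cycle=cost_cycle * df,
        qaly_by_cycle=qaly_cycle * df,
        ly_by_cycle=ly_cycle * df,
    )


def average_arm_results(results: list[ArmResult], weights: list[float] | None = None) -> ArmResult:
    """Weighted average of arm results across a cohort of profiles."""
    if not results:
        raise ValueError("no results to average")
    w = np.ones(len(results)) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()

    def avg(attr: str) -> float:
        return float(sum(wi * getattr(r, attr) for wi, r in zip(w, results)))

    def avg_cycles(attr: str) -> np.ndarray | None:
        arrays = [getattr(r, attr) for r in results]
        if any(a is None for a in arrays):
            return None
        n = max(len(a) for a in arrays)
        out = np.zeros(n)
        for wi, a in zip(w, arrays):
            out[: len(a)] += wi * a
        return out

    keys = set()
    for r in results:
        keys.update(r.event_risks)
    risks = {
        k: float(sum(wi * r.event_risks.get(k, 0.0) for wi, r in zip(w, results)))
        for k in keys
    }
    return ArmResult(
        total_cost=avg("total_cost"),
        life_years=avg("life_years"),
        qalys=avg("qalys"),
        total_cost_undiscounted=avg("total_cost_undiscounted"),
        life_years_undiscounted=avg("life_years_undiscounted"),
        qalys_undiscounted=avg("qalys_undiscounted"),
        event_risks=risks,
        cost_by_cycle=avg_cycles("cost_by_cycle"),
        qaly_by_cycle=avg_cycles("qaly_by_cycle"),
        ly_by_cycle=avg_cycles("ly_by_cycle"),
    )


def compare(surgery: ArmResult, omm: ArmResult, threshold: float) -> ComparisonResult:
    """Incremental comparison with dominance labelling."""
    d_cost = surgery.total_cost - omm.total_cost
    d_ly = surgery.life_years - omm.life_years
    d_qaly = surgery.qalys - omm.qalys
    if d_cost < 0 and d_qaly > 0:
        label, icer, ce = "dominant", None, True
    elif d_cost > 0 and d_qaly < 0:
        label, icer, ce = "dominated", None, False
    elif d_qaly == 0:
        label, icer = "undefined", None
        ce = d_cost < 0
    else:
        icer = d_cost / d_qaly
        label = "icer"
        ce = (icer <= threshold) if d_qaly > 0 else (icer >= threshold)
    return ComparisonResult(
        delta_cost=d_cost,
        delta_ly=d_ly,
        delta_qaly=d_qaly,
        icer=icer,
        label=label,
        cost_effective=ce,
        surgery=surgery,
        omm=omm,
    )


def time_to_cost_effectiveness(
    surgery: ArmResult,
    omm: ArmResult,
    threshold: float,
    max_years: int | None = None,
) -> dict[str, object]:
    """First analysis year at which surgery is cost-effective / cost saving.

    Evaluates the comparison on horizons truncated at whole years, using
    the per-cycle discounted accruals of the lifetime run.  Returns a
    mapping with ``first_ce_year``, ``first_cost_saving_year`` and the
    year-2 ICER (``None`` entries flag "never").
    """
    for r in (surgery, omm):
        if r.cost_by_cycle is None:
            raise ValueError("arm results lack per-cycle accruals")
    n = min(len(surgery.cost_by_cycle), len(omm.cost_by_cycle))
    d_cost = np.cumsum(surgery.cost_by_cycle[:n] - omm.cost_by_cycle[:n])
    d_qaly = np.cumsum(surgery.qaly_by_cycle[:n] - omm.qaly_by_cycle[:n])
    years = range(1, (n // 12 if max_years is None else min(max_years, n // 12)) + 1)
    first_ce = None
    first_saving = None
    icer_by_year: dict[int, float | None] = {}
    for y in years:
        i = y * 12 - 1
        dc, dq = float(d_cost[i]), float(d_qaly[i])
        icer = dc / dq if dq > 0 else None
        icer_by_year[y] = icer
        ce = (dc < 0 and dq > 0) or (icer is not None and icer <= threshold)
        if first_ce is None and ce:
            first_ce = y
        if first_saving is None and dc < 0:
            first_saving = y
    return {
        "first_ce_year": first_ce,
        "first_cost_saving_year": first_saving,
        "icer_by_year": icer_by_year,
    }
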