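"""Monthly-cycle cohort state-transition engine.

The model propagates cohort fractions through 17 health states: entry
surgery, post-surgery / medical-management living states split by
diabetes status, six cardiovascular event pathways (angina, acute and
post myocardial infarction, acute stroke, a 12-month post-stroke tunnel
followed by a chronic post-stroke state, transient ischaemic attack,
heart failure, peripheral arterial disease), surgical complication and
conversion-surgery states, and an absorbing dead state.

Internally the post-stroke year-1 tunnel is expanded into 12 monthly
slots, and every state carries a three-way diabetes attribute (never
diabetic / diabetic / in remission) so that incidence, net remission and
relapse can be tracked through event states without enlarging the
public state space.

Transition hazards come from the risk engine and are re-evaluated every
cycle from the cohort-mean risk-factor path (age, BMI, SBP).  Competing
risks within a cycle are resolved by evaluating death first and scaling
the remaining exits proportionally if they would exceed the surviving
mass; with monthly probabilities this correction is second-order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .parameters import ParameterSet, PatientProfile
from .risk_engine import (
    RiskEquationSet,
    RiskFactors,
    annual_to_cycle_probability,
    build_risk_equations,
    complication_schedules,
    mortality_path,
    remission_relapse_schedule,
    _incidence_annual,
)
from .trajectories import bmi_path, sbp_path

__all__ = [
    "HealthState",
    "CohortTrace",
    "run_cohort",
    "build_transition_row",
    "lifetime_event_risk",
    "relative_risk",
    "EVENT_KEYS",
]


class HealthState(str, Enum):
    INITIAL_SURGERY = "initial_surgery"
    POST_SURGERY_DIABETES = "post_surgery_diabetes"
    POST_SURGERY_NO_DIABETES = "post_surgery_no_diabetes"
    OMM_DIABETES = "omm_diabetes"
    OMM_NO_DIABETES = "omm_no_diabetes"
    ANGINA = "angina"
    ACUTE_MI = "acute_mi"
    POST_MI = "post_mi"
    ACUTE_STROKE = "acute_stroke"
    POST_STROKE_Y1 = "post_stroke_y1"
    POST_STROKE_Y2PLUS = "post_stroke_y2plus"
    TIA = "tia"
    HEART_FAILURE = "heart_failure"
    PAD = "pad"
    SURGICAL_COMPLICATION = "surgical_complication"
    CONVERSION_SURGERY = "conversion_surgery"
    DEAD = "dead"


# internal compact state indices
_I_SURG = 0
_I_BASE_DM = 1
_I_BASE_NODM = 2
_I_ANGINA = 3
_I_AMI = 4
_I_PMI = 5
_I_ASTROKE = 6
_I_TUN0 = 7  # 12 tunnel slots: 7..18
_I_PS2 = 19
_I_TIA = 20
_I_HF = 21
_I_PAD = 22
_I_COMP = 23
_I_CONV = 24
_I_DEAD = 25
_N_INTERNAL = 26

_CHRONIC = (_I_BASE_DM, _I_BASE_NODM, _I_ANGINA, _I_PMI, _I_PS2, _I_HF, _I_PAD)
# chronic state whose own event is not re-counted from within it
_OWN_EVENT = {_I_ANGINA: "angina", _I_PMI: "mi", _I_PS2: "stroke", _I_HF: "heart_failure", _I_PAD: "pad"}

EVENT_KEYS = (
    "angina",
    "mi_nonfatal",
    "mi_fatal",
    "mi_total",
    "stroke_nonfatal",
    "stroke_fatal",
    "stroke_total",
    "tia",
    "heart_failure",
    "pad",
    "diabetes",
    "complication",
    "conversion",
)


@dataclass
class CohortTrace:
    """Occupancy trace and cumulative event inflows for one strategy."""

    profile: PatientProfile
    arm: str
    n_cycles: int
    occupancy_internal: np.ndarray  # (n_cycles+1, 26, 3)
    inflows: dict[str, np.ndarray]  # each (n_cycles,)
    bmi: np.ndarray  # (n_cycles+1,)
    sbp: np.ndarray
    age: np.ndarray
    surgery_at_cycle: int | None = None

    @property
    def occupancy(self) -> np.ndarray:
        """Public (n_cycles+1, 17) occupancy matrix; rows sum to 1."""
        occ3 = self.occupancy_internal.sum(axis=2)
        out = np.zeros((self.n_cycles + 1, len(HealthState)))
        order = list(HealthState)
        col = {s: i for i, s in enumerate(order)}
        surgical = self.arm != "omm"
        out[:, col[HealthState.INITIAL_SURGERY]] = occ3[:, _I_SURG]
        dm_state = (
            HealthState.POST_SURGERY_DIABETES if surgical else HealthState.OMM_DIABETES
        )
        nodm_state = (
            HealthState.POST_SURGERY_NO_DIABETES
            if surgical
            else HealthState.OMM_NO_DIABETES
        )
        out[:, col[dm_state]] = occ3[:, _I_BASE_DM]
        out[:, col[nodm_state]] = occ3[:, _I_BASE_NODM]
        out[:, col[HealthState.ANGINA]] = occ3[:, _I_ANGINA]
        out[:, col[HealthState.ACUTE_MI]] = occ3[:, _I_AMI]
        out[:, col[HealthState.POST_MI]] = occ3[:, _I_PMI]
        out[:, col[HealthState.ACUTE_STROKE]] = occ3[:, _I_ASTROKE]
        out[:, col[HealthState.POST_STROKE_Y1]] = occ3[:, _I_TUN0 : _I_TUN0 + 12].sum(axis=1)
        out[:, col[HealthState.POST_STROKE_Y2PLUS]] = occ3[:, _I_PS2]
        out[:, col[HealthState.TIA]] = occ3[:, _I_TIA]
        out[:, col[HealthState.HEART_FAILURE]] = occ3[:, _I_HF]
        out[:, col[HealthState.PAD]] = occ3[:, _I_PAD]
        out[:, col[HealthState.SURGICAL_COMPLICATION]] = occ3[:, _I_COMP]
        out[:, col[HealthState.CONVERSION_SURGERY]] = occ3[:, _I_CONV]
        out[:, col[HealthState.DEAD]] = occ3[:, _I_DEAD]
        return out

    @property
    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy_internal[:, _I_DEAD, :].sum(axis=1)

    @property
    def diabetic_fraction(self) -> np.ndarray:
        """Fraction of the entering cohort currently diabetic, per cycle."""
        return self.occupancy_internal[:, :_I_DEAD, 1].sum(axis=1)


def _hazard_arrays(
    profile: PatientProfile,
    arm: str,
    n_cycles: int,
    params: ParameterSet,
    eqs: RiskEquationSet,
    mix: dict[str, float] | None,
    surgery_at_cycle: int | None,
):
    """Precompute every per-cycle probability used by the cycle loop."""
    bmi = bmi_path(profile, arm, n_cycles, params, mix=mix, surgery_at_cycle=surgery_at_cycle)
    sbp = sbp_path(profile, bmi, params)
    age = profile.age + np.arange(n_cycles + 1) / 12.0
    b, s, a = bmi[:-1], sbp[:-1], age[:-1]

    pe = {}  # (event, diabetic_flag) -> (n_cycles,)
    for ev in eqs.events:
        for dm in (False, True):
            annual = eqs.annual_probability_path(ev, a, profile.sex, b, s, dm, profile.smoker)
            pe[(ev, dm)] = np.asarray(annual_to_cycle_probability(np.clip(annual, 0.0, 1.0)))

    pdead = {
        dm: mortality_path(a, profile.sex, b, dm, params) for dm in (False, True)
    }
    pinc = np.asarray(annual_to_cycle_probability(_incidence_annual(b, params)))

    t0 = surgery_at_cycle if surgery_at_cycle is not None else 0
    if arm == "omm":
        prem, prel = remission_relapse_schedule("omm", n_cycles, params)
        pcomp = np.zeros(n_cycles)
        ccomp = np.zeros(n_cycles)
        pconv = np.zeros(n_cycles)
    else:
        prem_s, prel_s = remission_relapse_schedule(
            "surgery", n_cycles, params, delay_years=t0 / 12.0
        )
        if t0 > 0:
            prem_o, prel_o = remission_relapse_schedule("omm", n_cycles, params)
            prem = np.concatenate([prem_o[:t0], prem_s[: n_cycles - t0]])
            prel = np.concatenate([prel_o[:t0], prel_s[: n_cycles - t0]])
        else:
            prem, prel = prem_s, prel_s
        pcomp, ccomp, pconv = complication_schedules(n_cycles, params, surgery_at=t0)
    return bmi, sbp, age, pe, pdead, pinc, prem, prel, pcomp, ccomp, pconv


def run_cohort(
    profile: PatientProfile,
    arm: str,
    params: ParameterSet,
    eqs: RiskEquationSet | None = None,
    horizon_cycles: int | None = None,
    mix: dict[str, float] | None = None,
    surgery_at_cycle: int | None = None,
) -> CohortTrace:
    """Run the cohort model for one profile and strategy.

    ``arm`` is ``"surgery"`` or ``"omm"``.  ``surgery_at_cycle`` delays
    entry into the surgical pathway (waiting-list plan): until that
    cycle the cohort follows medical-management dynamics, then alive
    mass in the living states undergoes surgery with its then-current
    risk factors.
    """
    if arm not in ("surgery", "omm"):
        raise ValueError(f"arm must be 'surgery' or 'omm', got {arm!r}")
    if eqs is None:
        eqs = build_risk_equations(params)
    n_cycles = (
        int(round((params.max_age - profile.age) * 12))
        if horizon_cycles is None
        else int(horizon_cycles)
    )
    t0 = 0 if arm == "omm" else int(surgery_at_cycle or 0)

    bmi, sbp, age, pe, pdead, pinc, prem, prel, pcomp, ccomp, pconv = _hazard_arrays(
        profile, arm, n_cycles, params, eqs, mix, surgery_at_cycle
    )
    f_mi = eqs.fatal_fraction("mi")
    f_stroke = eqs.fatal_fraction("stroke")

    occ = np.zeros((n_cycles + 1, _N_INTERNAL, 3))
    flag0 = 1 if profile.diabetic else 0
    inflow_names = (
        "angina", "mi_nonfatal", "mi_fatal", "stroke_nonfatal", "stroke_fatal",
        "tia", "heart_failure", "pad", "diabetes", "complication", "conversion",
        "surgery",
    )
    inflows = {k: np.zeros(n_cycles + 1) for k in inflow_names}

    if arm == "surgery" and t0 == 0:
        occ[0, _I_SURG, flag0] = 1.0
        inflows["surgery"][0] = 1.0
    else:
        occ[0, _I_BASE_DM if flag0 == 1 else _I_BASE_NODM, flag0] = 1.0

    # scalar per-cycle hazard columns (plain lists keep the cycle loop
    # in float arithmetic; the small-array numpy form is ~10x slower)
    peL = {
        ev: (pe[(ev, False)].tolist(), pe[(ev, True)].tolist()) for ev in eqs.events
    }
    pdead0, pdead1 = pdead[False].tolist(), pdead[True].tolist()
    pincL, premL, prelL = pinc.tolist(), prem.tolist(), prel.tolist()
    pcompL, pconvL = pcomp.tolist(), pconv.tolist()

    # occupancy as nested python lists cur[state][flag]
    cur = [[float(occ[0, s, d]) for d in range(3)] for s in range(_N_INTERNAL)]
    ev_dest = {"angina": _I_ANGINA, "heart_failure": _I_HF, "pad": _I_PAD, "tia": _I_TIA}
    own_by_state = {s: _OWN_EVENT.get(s) for s in _CHRONIC}
    events = list(eqs.events)

    for t in range(n_cycles):
        new = [[0.0, 0.0, 0.0] for _ in range(_N_INTERNAL)]
        new[_I_DEAD][0] = cur[_I_DEAD][0] + cur[_I_DEAD][1] + cur[_I_DEAD][2]

        pi, pr, pl = pincL[t], premL[t], prelL[t]
        q = (pdead0[t], pdead1[t], pdead0[t])
        pevt = {ev: (peL[ev][0][t], peL[ev][1][t], peL[ev][0][t]) for ev in events}
        evsum = (
            sum(pevt[ev][0] for ev in events),
            sum(pevt[ev][1] for ev in events),
            sum(pevt[ev][2] for ev in events),
        )
        pc_pv = pcompL[t] + pconvL[t]
        dead_flow = 0.0
        inc_flow = 0.0
        ev_flow = {ev: [0.0, 0.0, 0.0] for ev in events}
        comp_flow = [0.0, 0.0, 0.0]
        conv_flow = [0.0, 0.0, 0.0]
        stay_base = [0.0, 0.0, 0.0]

        def mix_into(dest_row: list, m0: float, m1: float, m2: float) -> None:
            dest_row[0] += m0 * (1.0 - pi)
            dest_row[1] += m0 * pi + m1 * (1.0 - pr) + m2 * pl
            dest_row[2] += m1 * pr + m2 * (1.0 - pl)

        # --- chronic states: death first, then events / complications ----
        for s in _CHRONIC:
            row = cur[s]
            if row[0] == 0.0 and row[1] == 0.0 and row[2] == 0.0:
                continue
            own_ev = own_by_state[s]
            is_base = s == _I_BASE_DM or s == _I_BASE_NODM
            stay = [0.0, 0.0, 0.0]
            for d in range(3):
                m = row[d]
                if m == 0.0:
                    continue
                qd = q[d]
                exit_nd = evsum[d] + (pc_pv if is_base else 0.0)
                if own_ev is not None:
                    exit_nd -= pevt[own_ev][d]
                surv = 1.0 - qd
                scale = surv / exit_nd if exit_nd > surv and exit_nd > 0.0 else 1.0
                dead_flow += m * qd
                for ev in events:
                    if ev == own_ev:
                        continue
                    p = pevt[ev][d] * scale
                    if p:
                        ev_flow[ev][d] += m * p
                if is_base and pc_pv:
                    comp_flow[d] += m * pcompL[t] * scale
                    conv_flow[d] += m * pconvL[t] * scale
                stay[d] = m * (surv - exit_nd * scale)
            if is_base:
                stay_base[0] += stay[0]
                stay_base[1] += stay[1]
                stay_base[2] += stay[2]
            else:
                inc_flow += stay[0] * pi
                mix_into(new[s], stay[0], stay[1], stay[2])

        inc_flow += stay_base[0] * pi
        mix_into_base = [0.0, 0.0, 0.0]
        mix_into(mix_into_base, stay_base[0], stay_base[1], stay_base[2])

        # --- event inflows ------------------------------------------------
        for ev in events:
            f0, f1, f2 = ev_flow[ev]
            total = f0 + f1 + f2
            if total == 0.0:
                continue
            if ev == "mi":
                keep = 1.0 - f_mi
                for d, f in enumerate((f0, f1, f2)):
                    new[_I_AMI][d] += f * keep
                dead_flow += total * f_mi
                inflows["mi_nonfatal"][t + 1] += total * keep
                inflows["mi_fatal"][t + 1] += total * f_mi
            elif ev == "stroke":
                keep = 1.0 - f_stroke
                for d, f in enumerate((f0, f1, f2)):
                    new[_I_ASTROKE][d] += f * keep
                dead_flow += total * f_stroke
                inflows["stroke_nonfatal"][t + 1] += total * keep
                inflows["stroke_fatal"][t + 1] += total * f_stroke
            else:
                dest = ev_dest[ev]
                new[dest][0] += f0
                new[dest][1] += f1
                new[dest][2] += f2
                inflows[ev][t + 1] += total
        ctot = comp_flow[0] + comp_flow[1] + comp_flow[2]
        vtot = conv_flow[0] + conv_flow[1] + conv_flow[2]
        if ctot:
            for d in range(3):
                new[_I_COMP][d] += comp_flow[d]
            inflows["complication"][t + 1] += ctot
        if vtot:
            for d in range(3):
                new[_I_CONV][d] += conv_flow[d]
            inflows["conversion"][t + 1] += vtot

        # --- tunnel slots: death, flag mixing, advance --------------------
        for k in range(11, -1, -1):
            row = cur[_I_TUN0 + k]
            if row[0] == 0.0 and row[1] == 0.0 and row[2] == 0.0:
                continue
            s0, s1, s2 = row[0] * (1.0 - q[0]), row[1] * (1.0 - q[1]), row[2] * (1.0 - q[2])
            dead_flow += row[0] * q[0] + row[1] * q[1] + row[2] * q[2]
            inc_flow += s0 * pi
            dest = _I_PS2 if k == 11 else _I_TUN0 + k + 1
            mix_into(new[dest], s0, s1, s2)

        # --- one-cycle states ---------------------------------------------
        for s, dest in (
            (_I_SURG, None),
            (_I_TIA, None),
            (_I_COMP, None),
            (_I_CONV, None),
            (_I_AMI, _I_PMI),
            (_I_ASTROKE, _I_TUN0),
        ):
            row = cur[s]
            if row[0] == 0.0 and row[1] == 0.0 and row[2] == 0.0:
                continue
            s0, s1, s2 = row[0] * (1.0 - q[0]), row[1] * (1.0 - q[1]), row[2] * (1.0 - q[2])
            dead_flow += row[0] * q[0] + row[1] * q[1] + row[2] * q[2]
            inc_flow += s0 * pi
            if dest is None:
                mix_into(mix_into_base, s0, s1, s2)
            else:
                mix_into(new[dest], s0, s1, s2)

        new[_I_BASE_NODM][0] += mix_into_base[0]
        new[_I_BASE_DM][1] += mix_into_base[1]
        new[_I_BASE_NODM][2] += mix_into_base[2]
        new[_I_DEAD][0] += dead_flow
        inflows["diabetes"][t + 1] = inc_flow

        # --- delayed surgery: alive base mass enters surgery -------------
        if arm == "surgery" and t0 > 0 and t + 1 == t0:
            moved = [
                new[_I_BASE_DM][d] + new[_I_BASE_NODM][d] for d in range(3)
            ]
            inflows["surgery"][t + 1] = moved[0] + moved[1] + moved[2]
            new[_I_BASE_DM] = [0.0, 0.0, 0.0]
            new[_I_BASE_NODM] = [0.0, 0.0, 0.0]
            for d in range(3):
                new[_I_SURG][d] += moved[d]

        cur = new
        occ[t + 1] = new

    return CohortTrace(
        profile=profile,
        arm=arm,
        n_cycles=n_cycles,
        occupancy_internal=occ,
        inflows=inflows,
        bmi=bmi,
        sbp=sbp,
        age=age,
        surgery_at_cycle=surgery_at_cycle if arm == "surgery" else None,
    )


def lifetime_event_risk(trace: CohortTrace, event: str) -> float:
    """Expected lifetime incidence of ``event`` per entering patient.

    Computed as the cumulative inflow into the event; for rare repeat
    sequences this slightly exceeds the ever-affected fraction, which is
    the standard cohort-model approximation.
    """
    if event == "mi_total":
        return lifetime_event_risk(trace, "mi_nonfatal") + lifetime_event_risk(trace, "mi_fatal")
    if event == "stroke_total":
        return lifetime_event_risk(trace, "stroke_nonfatal") + lifetime_event_risk(
            trace, "stroke_fatal"
        )
    if event not in trace.inflows:
        raise KeyError(f"unknown event {event!r}")
    return float(trace.inflows[event].sum())


def relative_risk(trace_surgery: CohortTrace, trace_omm: CohortTrace, event: str) -> float:
    """Lifetime risk ratio, surgical over medical management."""
    denom = lifetime_event_risk(trace_omm, event)
    if denom == 0:
        return float("nan")
    return lifetime_event_risk(trace_surgery, event) / denom


def build_transition_row(
    state: HealthState,
    cycle: int,
    arm: str,
    rf: RiskFactors,
    params: ParameterSet,
    eqs: RiskEquationSet | None = None,
    months_since_surgery: float | None = None,
) -> dict[HealthState, float]:
    """One transition row of the public state space; sums to 1.

    This is the readable per-state contract used for topology and
    conservation tests; the engine itself propagates the equivalent
    vectorized form.
    """
    if eqs is None:
        eqs = build_risk_equations(params)
    surgical = arm != "omm"
    row = {s: 0.0 for s in HealthState}
    if state == HealthState.DEAD:
        row[HealthState.DEAD] = 1.0
        return row
    if not surgical and state in (
        HealthState.INITIAL_SURGERY,
        HealthState.SURGICAL_COMPLICATION,
        HealthState.CONVERSION_SURGERY,
        HealthState.POST_SURGERY_DIABETES,
        HealthState.POST_SURGERY_NO_DIABETES,
    ):
        raise ValueError(f"state {state.value} unreachable in the OMM arm")

    q = mortality_path(
        np.array([rf.age]), rf.sex, np.array([rf.bmi]), rf.diabetic, params
    )[0]
    base_dm = HealthState.POST_SURGERY_DIABETES if surgical else HealthState.OMM_DIABETES
    base_nodm = (
        HealthState.POST_SURGERY_NO_DIABETES if surgical else HealthState.OMM_NO_DIABETES
    )
    base = base_dm if rf.diabetic else base_nodm
    row[HealthState.DEAD] = float(q)
    surv = 1.0 - float(q)

    one_cycle_dest = {
        HealthState.INITIAL_SURGERY: base,
        HealthState.TIA: base,
        HealthState.SURGICAL_COMPLICATION: base,
        HealthState.CONVERSION_SURGERY: base,
        HealthState.ACUTE_MI: HealthState.POST_MI,
        HealthState.ACUTE_STROKE: HealthState.POST_STROKE_Y1,
    }
    if state in one_cycle_dest:
        row[one_cycle_dest[state]] = surv
        return row
    if state == HealthState.POST_STROKE_Y1:
        # within-tunnel months remain in the public tunnel state
        row[HealthState.POST_STROKE_Y1] = surv
        return row

    own = {
        HealthState.ANGINA: "angina",
        HealthState.POST_MI: "mi",
        HealthState.POST_STROKE_Y2PLUS: "stroke",
        HealthState.HEART_FAILURE: "heart_failure",
        HealthState.PAD: "pad",
    }.get(state)
    dest = {
        "angina": HealthState.ANGINA,
        "heart_failure": HealthState.HEART_FAILURE,
        "pad": HealthState.PAD,
        "tia": HealthState.TIA,
    }
    exits = 0.0
    for ev in eqs.events:
        if ev == own:
            continue
        p = float(
            annual_to_cycle_probability(eqs.annual_probability(ev, rf))
        )
        if ev == "mi":
            f = eqs.fatal_fraction("mi")
            row[HealthState.ACUTE_MI] += surv * p * (1 - f)
            row[HealthState.DEAD] += surv * p * f
        elif ev == "stroke":
            f = eqs.fatal_fraction("stroke")
            row[HealthState.ACUTE_STROKE] += surv * p * (1 - f)
            row[HealthState.DEAD] += surv * p * f
        else:
            row[dest[ev]] += surv * p
        exits += p
    if surgical and state in (base_dm, base_nodm):
        ms = cycle if months_since_surgery is None else months_since_surgery
        pcomp, _, pconv = complication_schedules(int(ms) + 1, params)
        row[HealthState.SURGICAL_COMPLICATION] = surv * float(pcomp[int(ms)])
        row[HealthState.CONVERSION_SURGERY] = surv * float(pconv[int(ms)])
        exits += float(pcomp[int(ms)]) + float(pconv[int(ms)])
    if exits > 1.0:
        raise ValueError(
            f"exit probability {exits:.3f} > 1 from {state.value} at cycle {cycle}"
        )
    # diabetes incidence / remission move between the base states
    if state in (base_dm, base_nodm):
        if rf.diabetic:
            p_flip = diabetes_remission_for_row(arm, cycle, params)
            row[base_nodm] += surv * (1 - exits) * p_flip
            row[base_dm] += surv * (1 - exits) * (1 - p_flip)
        else:
            from .risk_engine import diabetes_incidence_probability

            p_flip = diabetes_incidence_probability(rf, params)
            row[base_dm] += surv * (1 - exits) * p_flip
            row[base_nodm] += surv * (1 - exits) * (1 - p_flip)
    else:
        row[state] += surv * (1 - exits)
    return row


def diabetes_remission_for_row(arm: str, cycle: int, params: ParameterSet) -> float:
    sched_arm = "surgery" if arm != "omm" else "omm"
    p_rem, _ = remission_relapse_schedule(sched_arm, cycle + 1, params)
    return float(p_rem[cycle])
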