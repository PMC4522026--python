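"""One-way deterministic sensitivity analysis and probabilistic
sensitivity analysis (PSA).

The tornado analysis re-runs the deterministic base-case pipeline with
one parameter at a time set to the bounds of its declared range (costs
default to +/-50%), holding everything else at base-case values.

The PSA draws, per simulation, one parameter set from the declared
uncertainty distributions and (by default) one patient profile from the
baseline-characteristic distributions, runs both strategies, and
records the incremental cost and QALYs.  Parameters are sampled
independently; no correlation structure is imposed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .economics import compare, evaluate_arm
from .markov_engine import run_cohort
from .parameters import (
    DistributionSpec,
    ParameterSet,
    PatientProfile,
    child_rng,
    distribution_mean,
    sample,
)
from .risk_engine import build_risk_equations
from .scenarios import run_deterministic_base
from .synthetic_cohort import weighted_mean_profiles

__all__ = [
    "TornadoEntry",
    "PsaResult",
    "dsa_parameter_registry",
    "one_way_dsa",
    "run_psa",
    "ce_plane_export",
    "degenerate_psa_params",
]


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    delta_cost_low: float
    delta_cost_high: float
    delta_qaly_low: float
    delta_qaly_high: float

    @property
    def cost_swing(self) -> float:
        return abs(self.delta_cost_high - self.delta_cost_low)

    @property
    def crosses_cost_saving(self) -> bool:
        """True if the incremental cost changes sign across the range."""
        return (self.delta_cost_low >= 0) != (self.delta_cost_high >= 0)


@dataclass
class PsaResult:
    n_sims: int
    seed: int
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    delta_ly: np.ndarray
    diabetic_at_entry: np.ndarray  # bool per draw
    threshold: float

    @property
    def fraction_cost_saving(self) -> float:
        return float(np.mean(self.delta_cost < 0))

    @property
    def fraction_cost_effective_not_saving(self) -> float:
        with np.errstate(divide="ignore", invalid="ignore"):
            icer = np.where(self.delta_qaly > 0, self.delta_cost / self.delta_qaly, np.inf)
        ce = (self.delta_cost >= 0) & (self.delta_qaly > 0) & (icer <= self.threshold)
        return float(np.mean(ce))

    @property
    def fraction_positive_qaly(self) -> float:
        return float(np.mean(self.delta_qaly > 0))


# ---------------------------------------------------------------------------
# Deterministic one-way analysis


def dsa_parameter_registry(params: ParameterSet) -> dict[str, tuple[tuple, float, float]]:
    """Parameter name -> (raw path, low, high) for the tornado analysis.

    Ranges come from the declared ``range`` entries of the
    configuration; cost items without one default to +/-50% of the
    point value.  The SBP entry varies the gamma scale so the implied
    mean spans the declared SBP range.
    """
    raw = params.raw
    reg: dict[str, tuple[tuple, float, float]] = {}
    age = raw["cohort"]["age"]
    reg["start_age"] = (("cohort", "age", "param_a"), float(age["lower_bound"]), float(age["upper_bound"]))
    bmi = raw["cohort"]["bmi"]
    reg["baseline_bmi"] = (("cohort", "bmi", "param_a"), float(bmi["lower_bound"]), float(bmi["upper_bound"]))
    sbp = raw["cohort"]["sbp"]
    shape = float(sbp["param_a"])
    reg["baseline_sbp"] = (
        ("cohort", "sbp", "param_b"),
        float(sbp["lower_bound"]) / shape,
        float(sbp["upper_bound"]) / shape,
    )
    for sex in ("male", "female"):
        for year in (1, 2):
            entry = raw["bmi_deltas"]["GBP"][sex][year]
            lo, hi = entry["range"]
            reg[f"bmi_delta_GBP_{sex}_y{year}"] = (
                ("bmi_deltas", "GBP", sex, year, "value"),
                float(lo),
                float(hi),
            )
    for arm in ("surgical", "omm"):
        for year in (2, 10):
            entry = raw["remission"][arm][year]
            lo, hi = entry["range"]
            reg[f"remission_{arm}_y{year}"] = (
                ("remission", arm, year, "value"),
                float(lo),
                float(hi),
            )
    for kind in ("one_off", "annual"):
        for name, entry in raw["costs"][kind].items():
            point = float(entry["eur"])
            if "range" in entry:
                lo, hi = (float(x) for x in entry["range"])
            else:
                lo, hi = 0.5 * point, 1.5 * point
            reg[f"cost_{name}"] = (("costs", kind, name, "eur"), lo, hi)
    return reg


def one_way_dsa(
    params: ParameterSet,
    parameter_list: list[str] | None = None,
) -> list[TornadoEntry]:
    """Tornado analysis over the registered parameters, sorted by swing."""
    registry = dsa_parameter_registry(params)
    if parameter_list is None:
        parameter_list = list(registry)
    entries = []
    for name in parameter_list:
        if name not in registry:
            raise KeyError(f"parameter {name!r} has no declared range")
        path, lo, hi = registry[name]
        results = {}
        for bound, value in (("low", lo), ("high", hi)):
            p2 = params.with_raw_updates({path: value})
            results[bound] = run_deterministic_base(p2)
        entries.append(
            TornadoEntry(
                parameter=name,
                low=lo,
                high=hi,
                delta_cost_low=results["low"].delta_cost,
                delta_cost_high=results["high"].delta_cost,
                delta_qaly_low=results["low"].delta_qaly,
                delta_qaly_high=results["high"].delta_qaly,
            )
        )
    entries.sort(key=lambda e: e.cost_swing, reverse=True)
    return entries


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


def _psa_parameter_draws(params: ParameterSet, rng: np.random.Generator) -> dict[tuple, float]:
    """Draw one set of parameter overrides from the PSA distributions."""
    raw = params.raw
    rate = params.sek_to_eur_rate
    updates: dict[tuple, float] = {}
    for proc in raw["bmi_deltas"]:
        for sex in raw["bmi_deltas"][proc]:
            for year, entry in raw["bmi_deltas"][proc][sex].items():
                spec = DistributionSpec(
                    "normal", float(entry["value"]), float(entry["sd"]), lower_bound=0.1
                )
                updates[("bmi_deltas", proc, sex, year, "value")] = float(sample(spec, rng))
    for arm in ("surgical", "omm"):
        for year in (2, 10):
            entry = raw["remission"][arm][year]
            spec = DistributionSpec.from_dict(entry["psa_dist"])
            updates[("remission", arm, year, "value")] = float(sample(spec, rng))
    for kind in ("one_off", "annual"):
        for name, entry in raw["costs"][kind].items():
            dist = entry.get("psa_dist")
            if not dist:
                continue
            spec = DistributionSpec.from_dict(dist)
            value = float(sample(spec, rng))
            if entry.get("dist_currency", "EUR") == "SEK":
                value *= rate
            updates[("costs", kind, name, "eur")] = value
    return updates


def _psa_patient_draw(params: ParameterSet, rng: np.random.Generator) -> PatientProfile:
    raw = params.raw["cohort"]
    props = {}
    for name in ("male", "diabetic", "smoker"):
        dist = raw[name].get("psa_dist")
        p = (
            float(sample(DistributionSpec.from_dict(dist), rng))
            if dist
            else float(raw[name]["proportion"])
        )
        props[name] = rng.random() < p
    age = float(sample(DistributionSpec.from_dict(raw["age"]), rng))
    bmi = float(sample(DistributionSpec.from_dict(raw["bmi"]), rng))
    sbp = float(sample(DistributionSpec.from_dict(raw["sbp"]), rng))
    return PatientProfile(
        age=age,
        sex="male" if props["male"] else "female",
        bmi=bmi,
        sbp=sbp,
        diabetic=props["diabetic"],
        smoker=props["smoker"],
    )


def run_psa(
    params: ParameterSet,
    n_sims: int | None = None,
    seed: int = 7,
    sampling_level: str | None = None,
) -> PsaResult:
    """Monte-Carlo PSA over parameters (and, by default, patients)."""
    if n_sims is None:
        n_sims = int(params.raw["psa"]["n_default"])
    if sampling_level is None:
        sampling_level = str(params.raw["psa"]["sampling_level"])
    if sampling_level not in ("patient_and_parameters", "parameters_only"):
        raise ValueError(f"unknown sampling_level {sampling_level!r}")
    rng = child_rng(seed, "psa")
    d_cost = np.empty(n_sims)
    d_qaly = np.empty(n_sims)
    d_ly = np.empty(n_sims)
    diabetic = np.zeros(n_sims, dtype=bool)
    for i in range(n_sims):
        updates = _psa_parameter_draws(params, rng)
        p_i = params.with_raw_updates(updates)
        eqs = build_risk_equations(p_i)
        if sampling_level == "patient_and_parameters":
            patient = _psa_patient_draw(p_i, rng)
            s = evaluate_arm(run_cohort(patient, "surgery", p_i, eqs), p_i)
            o = evaluate_arm(run_cohort(patient, "omm", p_i, eqs), p_i)
            diabetic[i] = patient.diabetic
            d_cost[i] = s.total_cost - o.total_cost
            d_qaly[i] = s.qalys - o.qalys
            d_ly[i] = s.life_years - o.life_years
        else:
            cmp_i = run_deterministic_base(p_i, eqs)
            diabetic[i] = False
            d_cost[i] = cmp_i.delta_cost
            d_qaly[i] = cmp_i.delta_qaly
            d_ly[i] = cmp_i.delta_ly
    return PsaResult(
        n_sims=n_sims,
        seed=seed,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        delta_ly=d_ly,
        diabetic_at_entry=diabetic,
        threshold=params.wtp_threshold,
    )


def ce_plane_export(psa: PsaResult) -> list[dict[str, float | bool]]:
    """Cost-effectiveness-plane rows: one per simulated patient."""
    return [
        {
            "delta_qaly": float(psa.delta_qaly[i]),
            "delta_cost": float(psa.delta_cost[i]),
            "diabetic_at_entry": bool(psa.diabetic_at_entry[i]),
        }
        for i in range(psa.n_sims)
    ]


def degenerate_psa_params(params: ParameterSet) -> ParameterSet:
    """Copy of ``params`` with every PSA distribution collapsed to a point.

    With all distributions degenerate, each PSA draw reproduces the
    base-case parameter set exactly (oracle for the PSA plumbing).
    """
    raw = copy.deepcopy(params.raw)
    for proc in raw["bmi_deltas"]:
        for sex in raw["bmi_deltas"][proc]:
            for entry in raw["bmi_deltas"][proc][sex].values():
                entry["sd"] = 0.0
    for arm in ("surgical", "omm"):
        for year in (2, 10):
            entry = raw["remission"][arm][year]
            v = float(entry["value"])
            entry["psa_dist"] = {"family": "uniform", "param_a": v, "param_b": v}
    rate = float(raw["currency"]["sek_to_eur"])
    for kind in ("one_off", "annual"):
        for entry in raw["costs"][kind].values():
            if entry.get("psa_dist"):
                v = float(entry["eur"])
                if entry.get("dist_currency", "EUR") == "SEK":
                    v = v / rate
                entry["psa_dist"] = {"family": "uniform", "param_a": v, "param_b": v}
    for name in ("male", "diabetic", "smoker"):
        entry = raw["cohort"][name]
        if entry.get("psa_dist"):
            p = float(entry["proportion"])
            entry["psa_dist"] = {"family": "uniform", "param_a": p, "param_b": p}
    from .parameters import load_parameter_set

    return load_parameter_set(raw)
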