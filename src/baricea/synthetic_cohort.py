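"""Synthetic surgical-candidate cohorts.

Generates patient profiles with the marginal structure of the Swedish
surgical-candidate population (registry 2011 intake): age ~ N(41, 5) on
[25, 65], 24% male, BMI ~ N(42.8, 5.8) on [30, 60], 18.39% diabetic,
SBP ~ Gamma(shape 55.53, scale 2.52) on [125, 200], 14.3% smokers.
Characteristics are sampled independently; the joint correlation
structure of the real population is not emulated.

Also provides the 16 fixed subgroup cohorts (sex x BMI class x diabetes)
of 41-year-old non-smokers used for subgroup and waiting-list analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .parameters import (
    ParameterSet,
    PatientProfile,
    child_rng,
    distribution_mean,
    sample,
)

__all__ = [
    "Cohort",
    "generate_cohort",
    "fixed_subgroup_profile",
    "subgroup_grid_profiles",
    "weighted_mean_profiles",
    "cohort_summary",
    "BMI_CLASSES",
]

BMI_CLASSES = ("moderate", "severe", "morbid", "super")


@dataclass(frozen=True)
class Cohort:
    """Ordered collection of patient profiles with provenance metadata."""

    members: tuple[PatientProfile, ...]
    label: str = ""
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[PatientProfile]:
        return iter(self.members)


def generate_cohort(n: int, params: ParameterSet, seed: int, label: str = "multiple") -> Cohort:
    """Draw ``n`` independent patient profiles; deterministic under ``seed``."""
    if n < 0:
        raise ValueError(f"cohort size must be >= 0, got {n}")
    rng = child_rng(seed, "cohort")
    if n == 0:
        return Cohort(members=(), label=label, seed=seed)

    age = sample(params.cohort_spec("age"), rng, size=n)
    bmi = sample(params.cohort_spec("bmi"), rng, size=n)
    sbp = sample(params.cohort_spec("sbp"), rng, size=n)
    male = rng.random(n) < params.cohort_proportion("male")
    diabetic = rng.random(n) < params.cohort_proportion("diabetic")
    smoker = rng.random(n) < params.cohort_proportion("smoker")

    members = tuple(
        PatientProfile(
            age=float(age[i]),
            sex="male" if male[i] else "female",
            bmi=float(bmi[i]),
            sbp=float(sbp[i]),
            diabetic=bool(diabetic[i]),
            smoker=bool(smoker[i]),
        )
        for i in range(n)
    )
    return Cohort(members=members, label=label, seed=seed)


def fixed_subgroup_profile(
    sex: str,
    bmi_class: str,
    diabetic: bool,
    params: ParameterSet,
) -> PatientProfile:
    """Deterministic subgroup profile: 41-year-old non-smoker.

    BMI is the configured representative value of the class (midpoints
    32 / 37 / 45; 55 for the super-obese class); SBP is fixed at the
    cohort mean so the subgrids isolate BMI and diabetes effects.
    """
    if bmi_class not in BMI_CLASSES:
        raise ValueError(f"bmi_class must be one of {BMI_CLASSES}, got {bmi_class!r}")
    sub = params.raw["subgroups"]
    return PatientProfile(
        age=float(sub["age"]),
        sex=sex,
        bmi=float(sub["bmi_class_values"][bmi_class]),
        sbp=float(sub["sbp"]),
        diabetic=bool(diabetic),
        smoker=False,
    )


def subgroup_grid_profiles(params: ParameterSet) -> dict[tuple[str, str, bool], PatientProfile]:
    """All 16 fixed subgroup profiles keyed by (sex, bmi_class, diabetic)."""
    return {
        (sex, cls, dm): fixed_subgroup_profile(sex, cls, dm, params)
        for sex in ("male", "female")
        for cls in BMI_CLASSES
        for dm in (False, True)
    }


def weighted_mean_profiles(params: ParameterSet) -> tuple[PatientProfile, ...]:
    """Deterministic mean-characteristic cohort for fast pipelines.

    Eight profiles at the cohort-mean age/BMI/SBP covering the binary
    axes sex x diabetes x smoking, weighted by the configured
    proportions.  Used where a deterministic stand-in for the sampled
    multiple cohort is preferable (calibration, tornado analysis).
    """
    p_male = params.cohort_proportion("male")
    p_dm = params.cohort_proportion("diabetic")
    p_smoke = params.cohort_proportion("smoker")
    age = distribution_mean(params.cohort_spec("age"))
    bmi = distribution_mean(params.cohort_spec("bmi"))
    sbp = distribution_mean(params.cohort_spec("sbp"))
    out = []
    for male in (True, False):
        for dm in (True, False):
            for smoke in (True, False):
                w = (
                    (p_male if male else 1 - p_male)
                    * (p_dm if dm else 1 - p_dm)
                    * (p_smoke if smoke else 1 - p_smoke)
                )
                out.append(
                    PatientProfile(
                        age=age,
                        sex="male" if male else "female",
                        bmi=bmi,
                        sbp=sbp,
                        diabetic=dm,
                        smoker=smoke,
                        weight=w,
                    )
                )
    return tuple(out)


def cohort_summary(cohort: Cohort) -> dict[str, dict[str, float]]:
    """Per-characteristic summary statistics (mean/SD or proportion)."""
    if len(cohort) == 0:
        return {}
    age = np.array([m.age for m in cohort])
    bmi = np.array([m.bmi for m in cohort])
    sbp = np.array([m.sbp for m in cohort])
    out: dict[str, dict[str, float]] = {}
    for name, arr in (("age", age), ("bmi", bmi), ("sbp", sbp)):
        out[name] = {"mean": float(arr.mean()), "sd": float(arr.std(ddof=0))}
    for name, pred in (
        ("male", lambda m: m.sex == "male"),
        ("diabetic", lambda m: m.diabetic),
        ("smoker", lambda m: m.smoker),
    ):
        out[name] = {"proportion": float(np.mean([pred(m) for m in cohort]))}
    return out
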