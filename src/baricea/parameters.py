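"""Model inputs: typed parameter records, distributions, and configuration I/O.

All quantitative inputs of the model — baseline cohort distributions,
procedure-specific BMI reductions, diabetes remission anchors, unit costs
(with their probabilistic-sensitivity-analysis distributions), utilities,
risk-equation coefficients and the abridged life table — live in a single
structured YAML document.  A fully populated default configuration is
shipped as package data; :func:`load_parameter_set` validates a document
against the schema and returns an immutable :class:`ParameterSet`.

Costs whose uncertainty distribution is declared in Swedish krona carry
``dist_currency: SEK`` and are converted to euro with the configured
purchasing-power rate (default 1 SEK = 0.089 EUR).
"""

from __future__ import annotations

import copy
import importlib.resources
import io
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "DistributionSpec",
    "PatientProfile",
    "CostSet",
    "UtilitySet",
    "ParameterSet",
    "ConfigError",
    "distribution_mean",
    "sample",
    "default_config_dict",
    "load_parameter_set",
    "dump_parameter_set",
    "child_rng",
]

PROCEDURES = ("GBP", "SG", "GB")
SEXES = ("male", "female")

# Events driven by the cardiovascular risk equations.
CVD_EVENTS = ("angina", "mi", "stroke", "tia", "heart_failure", "pad")

DISTRIBUTION_FAMILIES = ("normal", "beta", "gamma", "uniform", "log_normal")


class ConfigError(ValueError):
    """Raised when a configuration document violates the schema."""


class UnknownDistributionError(ConfigError):
    """Raised for a distribution family outside the supported set."""


class TruncationError(ValueError):
    """Raised when a truncation region has vanishing probability mass."""


# ---------------------------------------------------------------------------
# Distributions


@dataclass(frozen=True)
class DistributionSpec:
    """Parametric distribution used for PSA draws and cohort sampling.

    ``param_a``/``param_b`` follow the field's conventional
    parameterization per family:

    ====== =========================== ======================
    family param_a                     param_b
    ====== =========================== ======================
    normal mean                        standard deviation
    beta   alpha                       beta
    gamma  shape (alpha)               scale (lambda; mean = shape*scale)
    uniform lower                      upper
    log_normal mean of log             SD of log
    ====== =========================== ======================

    Optional bounds truncate the distribution by resampling.
    """

    family: str
    param_a: float
    param_b: float
    lower_bound: float | None = None
    upper_bound: float | None = None

    def __post_init__(self) -> None:
        if self.family not in DISTRIBUTION_FAMILIES:
            raise UnknownDistributionError(
                f"unknown distribution family {self.family!r}"
            )
        a, b = self.param_a, self.param_b
        if self.family == "beta" and (a <= 0 or b <= 0):
            raise ConfigError(f"beta requires alpha,beta > 0, got ({a}, {b})")
        if self.family == "gamma" and (a <= 0 or b <= 0):
            raise ConfigError(f"gamma requires shape,scale > 0, got ({a}, {b})")
        if self.family == "normal" and b < 0:
            raise ConfigError(f"normal requires SD >= 0, got {b}")
        if self.family == "log_normal" and b < 0:
            raise ConfigError(f"log_normal requires sigma >= 0, got {b}")
        if self.family == "uniform" and b < a:
            raise ConfigError(f"uniform requires a <= b, got ({a}, {b})")
        if (
            self.lower_bound is not None
            and self.upper_bound is not None
            and not self.lower_bound < self.upper_bound
        ):
            raise ConfigError(
                f"bounds must satisfy lower < upper, got "
                f"({self.lower_bound}, {self.upper_bound})"
            )

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "family": self.family,
            "param_a": self.param_a,
            "param_b": self.param_b,
        }
        if self.lower_bound is not None:
            d["lower_bound"] = self.lower_bound
        if self.upper_bound is not None:
            d["upper_bound"] = self.upper_bound
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DistributionSpec":
        try:
            return cls(
                family=str(d["family"]),
                param_a=float(d["param_a"]),
                param_b=float(d["param_b"]),
                lower_bound=(
                    float(d["lower_bound"]) if d.get("lower_bound") is not None else None
                ),
                upper_bound=(
                    float(d["upper_bound"]) if d.get("upper_bound") is not None else None
                ),
            )
        except KeyError as exc:  # pragma: no cover - defensive
            raise ConfigError(f"distribution spec missing key {exc}") from exc


def distribution_mean(spec: DistributionSpec) -> float:
    """Analytic mean of ``spec`` (ignoring truncation bounds)."""
    a, b = spec.param_a, spec.param_b
    if spec.family == "normal":
        return a
    if spec.family == "beta":
        return a / (a + b)
    if spec.family == "gamma":
        return a * b
    if spec.family == "uniform":
        return 0.5 * (a + b)
    if spec.family == "log_normal":
        return math.exp(a + 0.5 * b * b)
    raise UnknownDistributionError(spec.family)  # pragma: no cover


def sample(
    spec: DistributionSpec,
    rng: np.random.Generator,
    size: int | None = None,
) -> float | np.ndarray:
    """Draw from ``spec``; truncation bounds are honoured by resampling.

    Identical generator state yields identical draws.  A truncation region
    that repeatedly rejects (probability mass below ~1e-6) raises
    :class:`TruncationError`.
    """
    n = 1 if size is None else int(size)

    def draw(k: int) -> np.ndarray:
        if spec.family == "normal":
            return rng.normal(spec.param_a, spec.param_b, size=k)
        if spec.family == "beta":
            return rng.beta(spec.param_a, spec.param_b, size=k)
        if spec.family == "gamma":
            return rng.gamma(spec.param_a, spec.param_b, size=k)
        if spec.family == "uniform":
            return rng.uniform(spec.param_a, spec.param_b, size=k)
        if spec.family == "log_normal":
            return rng.lognormal(spec.param_a, spec.param_b, size=k)
        raise UnknownDistributionError(spec.family)  # pragma: no cover

    lo = -math.inf if spec.lower_bound is None else spec.lower_bound
    hi = math.inf if spec.upper_bound is None else spec.upper_bound

    out = draw(n)
    if spec.lower_bound is not None or spec.upper_bound is not None:
        bad = (out < lo) | (out > hi)
        attempts = 0
        while bad.any():
            attempts += 1
            if attempts > 200:
                raise TruncationError(
                    f"truncation region [{lo}, {hi}] has negligible mass "
                    f"for {spec.family}({spec.param_a}, {spec.param_b})"
                )
            out[bad] = draw(int(bad.sum()))
            bad = (out < lo) | (out > hi)
    if size is None:
        return float(out[0])
    return out


def child_rng(master_seed: int, *keys: str | int) -> np.random.Generator:
    """Named child random stream derived from a single master seed.

    Every source of randomness in the package takes its generator from
    here, so adding one stage never perturbs another stage's draws.
    """
    import zlib

    entropy = [int(master_seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, int):
            entropy.append(k & 0x7FFFFFFF)
        else:
            entropy.append(zlib.crc32(str(k).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Typed records


@dataclass(frozen=True)
class PatientProfile:
    """Baseline risk factors of one (cohort-average) patient."""

    age: float
    sex: str
    bmi: float
    sbp: float
    diabetic: bool
    smoker: bool
    weight: float = 1.0  # mixing weight when used in a weighted cohort

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not 25 <= self.age <= 65:
            raise ValueError(f"entry age {self.age} outside [25, 65]")
        if not 30 <= self.bmi <= 60:
            raise ValueError(f"entry BMI {self.bmi} outside [30, 60]")
        if not 125 <= self.sbp <= 200:
            raise ValueError(f"entry SBP {self.sbp} outside [125, 200]")


@dataclass(frozen=True)
class CostItem:
    """One unit cost: euro point value plus optional PSA distribution."""

    point_value: float  # EUR
    psa_dist: DistributionSpec | None = None
    dist_currency: str = "EUR"  # currency the PSA distribution is declared in

    def __post_init__(self) -> None:
        if self.point_value < 0:
            raise ConfigError(f"cost point value must be >= 0, got {self.point_value}")
        if self.dist_currency not in ("EUR", "SEK"):
            raise ConfigError(f"dist_currency must be EUR or SEK, got {self.dist_currency}")


@dataclass(frozen=True)
class CostSet:
    """Unit costs: one-off event tariffs and annual state costs (EUR)."""

    one_off: dict[str, CostItem]
    annual: dict[str, CostItem]

    def eur(self, kind: str, name: str) -> float:
        table = self.one_off if kind == "one_off" else self.annual
        return table[name].point_value

    def items(self) -> Iterable[tuple[str, str, CostItem]]:
        for name, item in self.one_off.items():
            yield "one_off", name, item
        for name, item in self.annual.items():
            yield "annual", name, item


@dataclass(frozen=True)
class UtilitySet:
    """EQ-5D-style utilities: BMI-dependent baseline x diabetes, state decrements.

    ``baseline_knots`` is a table of (BMI, utility) points interpolated
    piecewise-linearly (flat beyond the outer knots), reflecting the
    graded decline of health-related quality of life with BMI.
    Event-state decrements are multiplicative by default.
    """

    baseline_knots: tuple[tuple[float, float], ...]  # (bmi, utility)
    diabetes_multiplier: float
    state_multipliers: dict[str, float]
    decrement_mode: str = "multiplicative"

    def __post_init__(self) -> None:
        for x, u in self.baseline_knots:
            if not 0.0 <= u <= 1.0:
                raise ConfigError(f"utility {u} at BMI {x} outside [0, 1]")
        if not 0.0 <= self.diabetes_multiplier <= 1.0:
            raise ConfigError("diabetes utility multiplier outside [0, 1]")
        for s, m in self.state_multipliers.items():
            if not 0.0 <= m <= 1.0:
                raise ConfigError(f"state multiplier for {s} outside [0, 1]")
        if self.decrement_mode not in ("multiplicative", "additive"):
            raise ConfigError(f"unknown decrement_mode {self.decrement_mode!r}")

    def baseline(self, bmi: float, diabetic: bool) -> float:
        return float(self.baseline_array(np.array([bmi]), diabetic)[0])

    def baseline_array(self, bmi: np.ndarray, diabetic: bool) -> np.ndarray:
        xs = np.array([x for x, _ in self.baseline_knots])
        us = np.array([u for _, u in self.baseline_knots])
        u = np.interp(bmi, xs, us)
        if diabetic:
            u = u * self.diabetes_multiplier
        return u


@dataclass(frozen=True)
class ParameterSet:
    """Fully validated model input set.

    The raw (already validated) configuration mapping is retained in
    ``raw`` so sensitivity analyses can perturb single keys and re-load.
    """

    raw: dict[str, Any] = field(repr=False)
    sek_to_eur_rate: float = 0.089
    discount_rate: float = 0.03
    wtp_threshold: float = 35526.0
    cycle_length_months: int = 1
    max_age: float = 100.0
    bmi_floor: float = 18.5
    sbp_floor: float = 110.0
    procedure_mix: dict[str, float] = field(default_factory=dict)
    costs: CostSet | None = None
    utilities: UtilitySet | None = None

    # -- convenience accessors into the raw document ---------------------

    def cohort_spec(self, name: str) -> DistributionSpec:
        return DistributionSpec.from_dict(self.raw["cohort"][name])

    def cohort_proportion(self, name: str) -> float:
        return float(self.raw["cohort"][name]["proportion"])

    def bmi_delta(self, procedure: str, sex: str, year: int) -> float:
        if procedure not in PROCEDURES:
            raise KeyError(f"unknown procedure {procedure!r}")
        if sex not in SEXES:
            raise KeyError(f"unknown sex {sex!r}")
        return float(self.raw["bmi_deltas"][procedure][sex][year]["value"])

    def bmi_delta_sd(self, procedure: str, sex: str, year: int) -> float:
        return float(self.raw["bmi_deltas"][procedure][sex][year]["sd"])

    def remission_anchor(self, arm: str, year: int) -> float:
        return float(self.raw["remission"][arm][year]["value"])

    def with_raw_updates(self, updates: Mapping[tuple, Any]) -> "ParameterSet":
        """Return a new ParameterSet with dotted-path overrides applied.

        ``updates`` maps key tuples (paths into the raw mapping) to values.
        """
        raw = copy.deepcopy(self.raw)
        for path, value in updates.items():
            node = raw
            for k in path[:-1]:
                node = node[k]
            if path[-1] not in node:
                raise KeyError(f"unknown parameter path {path}")
            node[path[-1]] = value
        return _build_parameter_set(raw)


def sek_to_eur(amount_sek: float, rate: float = 0.089) -> float:
    """Convert Swedish krona to euro at the configured rate."""
    if not math.isfinite(amount_sek):
        raise ValueError(f"amount must be finite, got {amount_sek}")
    return amount_sek * rate


# ---------------------------------------------------------------------------
# Configuration loading


def default_config_dict() -> dict[str, Any]:
    """The shipped default configuration as a plain mapping."""
    text = (
        importlib.resources.files("baricea")
        .joinpath("data/default_config.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


_REQUIRED_TOP_KEYS = (
    "schema_version",
    "currency",
    "economics",
    "model",
    "cohort",
    "procedure_mix",
    "bmi_deltas",
    "trajectory",
    "remission",
    "costs",
    "utilities",
    "risk_equations",
    "diabetes",
    "mortality",
    "complications",
    "subgroups",
    "calibration",
    "psa",
)


def _parse_costs(doc: Mapping[str, Any]) -> CostSet:
    def parse_table(table: Mapping[str, Any]) -> dict[str, CostItem]:
        out = {}
        for name, entry in table.items():
            dist = entry.get("psa_dist")
            out[name] = CostItem(
                point_value=float(entry["eur"]),
                psa_dist=DistributionSpec.from_dict(dist) if dist else None,
                dist_currency=str(entry.get("dist_currency", "EUR")),
            )
        return out

    return CostSet(
        one_off=parse_table(doc["one_off"]),
        annual=parse_table(doc["annual"]),
    )


def _parse_utilities(doc: Mapping[str, Any]) -> UtilitySet:
    knots = tuple(
        (float(b["bmi"]), float(b["utility"])) for b in doc["baseline_by_bmi"]
    )
    if list(knots) != sorted(knots, key=lambda t: t[0]):
        raise ConfigError("utilities.baseline_by_bmi knots must be sorted by bmi")
    return UtilitySet(
        baseline_knots=knots,
        diabetes_multiplier=float(doc["diabetes_multiplier"]),
        state_multipliers={str(k): float(v) for k, v in doc["state_multipliers"].items()},
        decrement_mode=str(doc.get("decrement_mode", "multiplicative")),
    )


def _build_parameter_set(raw: dict[str, Any]) -> ParameterSet:
    missing = [k for k in _REQUIRED_TOP_KEYS if k not in raw]
    if missing:
        raise ConfigError(f"configuration missing required keys: {missing}")

    mix = {str(k): float(v) for k, v in raw["procedure_mix"].items()}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ConfigError(
            f"procedure_mix proportions must sum to 1, got {sum(mix.values())}"
        )
    for p in mix:
        if p not in PROCEDURES:
            raise ConfigError(f"unknown procedure in mix: {p!r}")

    econ = raw["economics"]
    model = raw["model"]
    if int(model["cycle_length_months"]) != 1:
        raise ConfigError("cycle_length_months must be 1")
    discount = float(econ["discount_rate"])
    if discount < 0:
        raise ConfigError("discount_rate must be >= 0")

    # Validate distribution specs in the cohort block.
    for name, entry in raw["cohort"].items():
        if "family" in entry:
            DistributionSpec.from_dict(entry)
        elif "proportion" in entry:
            p = float(entry["proportion"])
            if not 0 <= p <= 1:
                raise ConfigError(f"cohort.{name}.proportion outside [0, 1]")
            if entry.get("psa_dist"):
                DistributionSpec.from_dict(entry["psa_dist"])
        else:
            raise ConfigError(f"cohort.{name} needs 'family' or 'proportion'")

    # BMI-delta table must cover all procedures, sexes, years 1 and 2.
    for proc in PROCEDURES:
        for sex in SEXES:
            for year in (1, 2):
                try:
                    raw["bmi_deltas"][proc][sex][year]["value"]
                except (KeyError, TypeError) as exc:
                    raise ConfigError(
                        f"bmi_deltas missing entry ({proc}, {sex}, year {year})"
                    ) from exc

    for arm in ("surgical", "omm"):
        for year in (2, 10):
            if year not in raw["remission"][arm]:
                raise ConfigError(f"remission.{arm} missing year-{year} anchor")

    costs = _parse_costs(raw["costs"])
    utilities = _parse_utilities(raw["utilities"])

    # Complication probabilities must leave room in every monthly row.
    comp = raw["complications"]
    short_total = sum(float(c["short_term_prob"]) for c in comp["types"].values())
    if short_total >= 1.0:
        raise ConfigError("short-term complication probabilities sum to >= 1")

    return ParameterSet(
        raw=raw,
        sek_to_eur_rate=float(raw["currency"]["sek_to_eur"]),
        discount_rate=discount,
        wtp_threshold=float(econ["wtp_threshold_eur_per_qaly"]),
        cycle_length_months=int(model["cycle_length_months"]),
        max_age=float(model["max_age"]),
        bmi_floor=float(model["bmi_floor"]),
        sbp_floor=float(model["sbp_floor"]),
        procedure_mix=mix,
        costs=costs,
        utilities=utilities,
    )


def load_parameter_set(source: str | Mapping[str, Any] | io.TextIOBase | None = None) -> ParameterSet:
    """Load and validate a parameter configuration.

    ``source`` may be a path to a YAML file, an already-parsed mapping, an
    open text stream, or ``None`` for the shipped default configuration.
    """
    if source is None:
        raw = default_config_dict()
    elif isinstance(source, Mapping):
        raw = copy.deepcopy(dict(source))
    elif isinstance(source, io.TextIOBase):
        raw = yaml.safe_load(source)
    else:
        with open(source, "r") as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("configuration document must be a mapping")
    return _build_parameter_set(raw)


def dump_parameter_set(params: ParameterSet, path: str | None = None) -> str:
    """Serialize a ParameterSet back to YAML; round-trips losslessly."""
    text = yaml.safe_dump(params.raw, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
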