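"""Model inputs: domain types, probability conversion, PSA distribution fitting,
and country-setting config I/O.

All probabilities are *monthly* transition probabilities, all costs are 2020
US$, utilities are on the annual 0-1 scale.  A :class:`CountrySetting` bundles
the two treatment arms (intervention first, comparator second) with the shared
economic inputs and the willingness-to-pay thresholds used to classify
cost-effectiveness (1x and 3x GDP per capita).
"""

from __future__ import annotations

import copy
import dataclasses
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator

import yaml

__all__ = [
    "ArmParameters",
    "EconomicInputs",
    "ModelSettings",
    "ParameterDistribution",
    "CountrySetting",
    "proportion_to_monthly_prob",
    "monthly_prob_to_proportion",
    "fit_beta",
    "fit_gamma",
    "load_setting",
    "load_config",
    "save_setting",
    "setting_to_csv",
    "taiwan_base",
    "taiwan_distributions",
    "taiwan_settings",
    "get_param",
    "set_param",
    "parameter_paths",
]

SCHEMA = "empacea-setting/1"


class ConfigError(ValueError):
    """Raised when a config file or parameter set violates the schema."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArmParameters:
    """Per-arm monthly transition probabilities and drug acquisition cost."""

    name: str
    p_hhf: float
    p_cvd: float
    p_ncd: float
    drug_cost: float

    def validate(self) -> None:
        for key in ("p_hhf", "p_cvd", "p_ncd"):
            v = getattr(self, key)
            if not (0.0 <= v < 1.0):
                raise ConfigError(f"{self.name}.{key} must be in [0, 1), got {v}")
        if self.p_cvd + self.p_ncd >= 1.0:
            raise ConfigError(
                f"{self.name}: p_cvd + p_ncd must be < 1, got {self.p_cvd + self.p_ncd}"
            )
        if self.drug_cost < 0:
            raise ConfigError(f"{self.name}.drug_cost must be >= 0, got {self.drug_cost}")


@dataclass(frozen=True)
class EconomicInputs:
    """Utilities, disutilities, costs and the annual discount rate.

    ``u_stable`` is the annual utility of stable heart failure;
    ``u_age_decrement`` is the utility lost per additional year of age;
    ``u_hhf_decrement`` applies for the single month of a hospitalization.
    ``cost_stable`` accrues monthly while alive; ``cost_hhf`` is one-off per
    hospitalization; the pre-death costs are one-off in the cycle of death.
    """

    u_stable: float
    u_age_decrement: float
    u_hhf_decrement: float
    cost_stable: float
    cost_hhf: float
    cost_pre_cvd: float
    cost_pre_ncd: float
    discount_rate_annual: float

    def validate(self) -> None:
        if not (0.0 <= self.u_stable <= 1.0):
            raise ConfigError(f"u_stable must be in [0, 1], got {self.u_stable}")
        if self.u_age_decrement > 0:
            raise ConfigError(f"u_age_decrement must be <= 0, got {self.u_age_decrement}")
        if self.u_hhf_decrement > 0:
            raise ConfigError(f"u_hhf_decrement must be <= 0, got {self.u_hhf_decrement}")
        if self.u_stable + self.u_hhf_decrement < 0:
            raise ConfigError("u_stable + u_hhf_decrement must be >= 0")
        for key in ("cost_stable", "cost_hhf", "cost_pre_cvd", "cost_pre_ncd"):
            if getattr(self, key) < 0:
                raise ConfigError(f"{key} must be >= 0, got {getattr(self, key)}")
        if self.discount_rate_annual < 0:
            raise ConfigError(
                f"discount_rate_annual must be >= 0, got {self.discount_rate_annual}"
            )


@dataclass(frozen=True)
class ModelSettings:
    """Simulation and accounting conventions.

    ``occupancy_counting`` selects how state membership is credited per cycle:
    ``"boundary"`` credits the alive fraction at both cycle boundaries (two
    month-equivalents per cycle), which is the convention the published Taiwan
    analysis used; ``"single"`` is the textbook once-per-cycle accounting.
    ``age_decrement_basis`` applies the utility age decrement to credited time
    (advancing at the occupancy-counting rate) or to calendar time.
    ``first_cycle_event_free`` suppresses all events in cycle 1 when set.
    """

    start_age: float = 67.0
    cycle_length_months: int = 1
    horizon_cycles: int = 180
    half_cycle_correction: bool = False
    first_cycle_event_free: bool = False
    occupancy_counting: str = "boundary"
    age_decrement_basis: str = "credited"
    discount_mode: str = "monthly_compound"

    def validate(self) -> None:
        if self.horizon_cycles < 1:
            raise ConfigError(f"horizon_cycles must be >= 1, got {self.horizon_cycles}")
        if self.start_age <= 0:
            raise ConfigError(f"start_age must be > 0, got {self.start_age}")
        if self.cycle_length_months != 1:
            raise ConfigError("cycle_length_months is fixed at 1")
        if self.occupancy_counting not in ("boundary", "single"):
            raise ConfigError(f"unknown occupancy_counting {self.occupancy_counting!r}")
        if self.age_decrement_basis not in ("credited", "calendar"):
            raise ConfigError(f"unknown age_decrement_basis {self.age_decrement_basis!r}")
        if self.discount_mode not in ("monthly_compound", "annual_step"):
            raise ConfigError(f"unknown discount_mode {self.discount_mode!r}")

    @property
    def occupancy_weight(self) -> float:
        return 2.0 if self.occupancy_counting == "boundary" else 1.0


@dataclass(frozen=True)
class ParameterDistribution:
    """Second-order uncertainty for one input (PSA sampling).

    ``family`` is ``"beta"`` (probabilities and utilities, method-of-moments),
    ``"gamma"`` (costs), or ``"fixed"``.  ``mean`` and ``se`` are on the
    parameter's native scale; for negative utility decrements the magnitude is
    sampled and negated.
    """

    family: str
    mean: float
    se: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise ConfigError(f"unknown distribution family {self.family!r}")
        if self.se < 0:
            raise ConfigError(f"se must be >= 0, got {self.se}")
        if self.family == "beta":
            m = abs(self.mean)
            if not (0.0 < m < 1.0):
                raise ConfigError(f"beta mean magnitude must be in (0, 1), got {self.mean}")
            if self.se > 0:
                try:
                    fit_beta(m, self.se)  # fail at setup, not draw time
                except ValueError as exc:
                    raise ConfigError(str(exc)) from None
        if self.family == "gamma" and abs(self.mean) <= 0:
            raise ConfigError(f"gamma mean must be > 0, got {self.mean}")


@dataclass(frozen=True)
class CountrySetting:
    """A complete country parameter set: two arms, economics, WTP thresholds."""

    label: str
    arms: tuple[ArmParameters, ArmParameters]
    econ: EconomicInputs
    wtp_1x: float
    wtp_3x: float

    def validate(self) -> None:
        if len(self.arms) != 2:
            raise ConfigError(f"exactly two arms required, got {len(self.arms)}")
        for arm in self.arms:
            arm.validate()
        if self.arms[0].name == self.arms[1].name:
            raise ConfigError("arm names must be distinct")
        self.econ.validate()
        if not (0 <= self.wtp_1x <= self.wtp_3x):
            raise ConfigError("require 0 <= wtp_1x <= wtp_3x")

    @property
    def intervention(self) -> ArmParameters:
        return self.arms[0]

    @property
    def comparator(self) -> ArmParameters:
        return self.arms[1]


# ---------------------------------------------------------------------------
# Probability conversion
# ---------------------------------------------------------------------------


def proportion_to_monthly_prob(p_followup: float, followup_months: int) -> float:
    """Convert a cumulative event proportion over a follow-up window into the
    constant monthly probability with the same cumulative risk.

    Assumes a constant per-month hazard, so
    ``p_month = 1 - (1 - p_followup)**(1 / followup_months)``.
    """
    if not (0.0 <= p_followup < 1.0):
        raise ValueError(f"p_followup must be in [0, 1), got {p_followup}")
    if followup_months < 1:
        raise ValueError(f"followup_months must be >= 1, got {followup_months}")
    return 1.0 - (1.0 - p_followup) ** (1.0 / followup_months)


def monthly_prob_to_proportion(p_month: float, followup_months: int) -> float:
    """Inverse of :func:`proportion_to_monthly_prob`."""
    if not (0.0 <= p_month < 1.0):
        raise ValueError(f"p_month must be in [0, 1), got {p_month}")
    if followup_months < 1:
        raise ValueError(f"followup_months must be >= 1, got {followup_months}")
    return 1.0 - (1.0 - p_month) ** followup_months


# ---------------------------------------------------------------------------
# Distribution fitting (method of moments)
# ---------------------------------------------------------------------------


def fit_beta(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta shapes (a, b) with the given mean and SE."""
    if not (0.0 < mean < 1.0):
        raise ValueError(f"beta mean must be in (0, 1), got {mean}")
    var = se * se
    if not (0.0 < var < mean * (1.0 - mean)):
        raise ValueError(
            f"beta moments infeasible: need 0 < se^2 < mean*(1-mean), "
            f"got se^2={var}, bound={mean * (1.0 - mean)}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_gamma(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments gamma (shape, scale) with the given mean and SE."""
    if mean <= 0:
        raise ValueError(f"gamma mean must be > 0, got {mean}")
    if se <= 0:
        raise ValueError(f"gamma se must be > 0, got {se}")
    shape = (mean / se) ** 2
    scale = se * se / mean
    return shape, scale


# ---------------------------------------------------------------------------
# Parameter paths (used by scenarios, tornado and PSA)
# ---------------------------------------------------------------------------

_ECON_FIELDS = tuple(f.name for f in dataclasses.fields(EconomicInputs))
_ARM_NUMERIC = ("p_hhf", "p_cvd", "p_ncd", "drug_cost")


def parameter_paths(setting: CountrySetting) -> list[str]:
    """Dotted paths of every numeric input of a setting, arms first."""
    paths = [f"arms.{arm.name}.{f}" for arm in setting.arms for f in _ARM_NUMERIC]
    paths += [f"econ.{f}" for f in _ECON_FIELDS]
    return paths


def get_param(setting: CountrySetting, path: str) -> float:
    parts = path.split(".")
    if parts[0] == "arms" and len(parts) == 3:
        for arm in setting.arms:
            if arm.name == parts[1]:
                if parts[2] not in _ARM_NUMERIC:
                    raise KeyError(f"unknown arm field {parts[2]!r} in {path!r}")
                return getattr(arm, parts[2])
        raise KeyError(f"unknown arm {parts[1]!r} in {path!r}")
    if parts[0] == "econ" and len(parts) == 2:
        if parts[1] not in _ECON_FIELDS:
            raise KeyError(f"unknown econ field {parts[1]!r} in {path!r}")
        return getattr(setting.econ, parts[1])
    raise KeyError(f"unknown parameter path {path!r}")


def set_param(setting: CountrySetting, path: str, value: float) -> CountrySetting:
    """Return a new setting with one parameter replaced (pure update)."""
    get_param(setting, path)  # validates the path
    parts = path.split(".")
    if parts[0] == "arms":
        arms = tuple(
            replace(arm, **{parts[2]: value}) if arm.name == parts[1] else arm
            for arm in setting.arms
        )
        new = replace(setting, arms=arms)  # type: ignore[arg-type]
    else:
        new = replace(setting, econ=replace(setting.econ, **{parts[1]: value}))
    new.validate()
    return new


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

_SETTINGS_FIELDS = {f.name for f in dataclasses.fields(ModelSettings)}


def _leaf(node, key: str) -> tuple[float, float | None]:
    """A numeric leaf is either a scalar or a {mean, se} mapping."""
    if isinstance(node, dict):
        unknown = set(node) - {"mean", "se"}
        if unknown:
            raise ConfigError(f"{key}: unknown keys {sorted(unknown)}")
        if "mean" not in node:
            raise ConfigError(f"{key}: mapping leaf requires 'mean'")
        return float(node["mean"]), (float(node["se"]) if "se" in node else None)
    if isinstance(node, bool) or not isinstance(node, (int, float)):
        raise ConfigError(f"{key}: expected a number, got {node!r}")
    return float(node), None


def _parse(doc: dict):
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    required = {"schema", "label", "arms", "econ", "wtp_1x", "wtp_3x"}
    unknown = set(doc) - required - {"settings"}
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
    missing = required - set(doc)
    if missing:
        raise ConfigError(f"missing required keys {sorted(missing)}")
    if doc["schema"] != SCHEMA:
        raise ConfigError(f"schema: expected {SCHEMA!r}, got {doc['schema']!r}")

    ses: dict[str, float] = {}
    arms = []
    if not isinstance(doc["arms"], list) or len(doc["arms"]) != 2:
        raise ConfigError("arms: exactly two arms required (intervention, comparator)")
    for raw in doc["arms"]:
        if "name" not in raw:
            raise ConfigError("arms: each arm requires 'name'")
        name = str(raw["name"])
        unknown = set(raw) - {"name", *_ARM_NUMERIC}
        if unknown:
            raise ConfigError(f"arms.{name}: unknown keys {sorted(unknown)}")
        vals = {}
        for f in _ARM_NUMERIC:
            if f not in raw:
                raise ConfigError(f"arms.{name}.{f}: missing")
            vals[f], se = _leaf(raw[f], f"arms.{name}.{f}")
            if se is not None:
                ses[f"arms.{name}.{f}"] = se
        arms.append(ArmParameters(name=name, **vals))

    raw = doc["econ"]
    unknown = set(raw) - set(_ECON_FIELDS)
    if unknown:
        raise ConfigError(f"econ: unknown keys {sorted(unknown)}")
    vals = {}
    for f in _ECON_FIELDS:
        if f not in raw:
            raise ConfigError(f"econ.{f}: missing")
        vals[f], se = _leaf(raw[f], f"econ.{f}")
        if se is not None:
            ses[f"econ.{f}"] = se
    econ = EconomicInputs(**vals)

    wtp_1x, _ = _leaf(doc["wtp_1x"], "wtp_1x")
    wtp_3x, _ = _leaf(doc["wtp_3x"], "wtp_3x")
    setting = CountrySetting(
        label=str(doc["label"]), arms=tuple(arms), econ=econ, wtp_1x=wtp_1x, wtp_3x=wtp_3x
    )
    setting.validate()

    settings = ModelSettings()
    if "settings" in doc:
        raw = doc["settings"]
        unknown = set(raw) - _SETTINGS_FIELDS
        if unknown:
            raise ConfigError(f"settings: unknown keys {sorted(unknown)}")
        settings = ModelSettings(**raw)
    settings.validate()

    distributions = _distributions_from_ses(setting, ses)
    return setting, distributions, settings


def _distributions_from_ses(
    setting: CountrySetting, ses: dict[str, float]
) -> dict[str, ParameterDistribution]:
    """Assign the conventional family per parameter class: beta for
    probabilities and utilities (magnitude for decrements), gamma for costs."""
    out: dict[str, ParameterDistribution] = {}
    for path, se in ses.items():
        mean = get_param(setting, path)
        leaf_name = path.split(".")[-1]
        if leaf_name.startswith("p_") or leaf_name.startswith("u_"):
            family = "beta"
        else:
            family = "gamma"
        if se == 0 or mean == 0:
            family = "fixed"
        out[path] = ParameterDistribution(family=family, mean=mean, se=se)
    return out


def load_config(path) -> tuple[CountrySetting, dict[str, ParameterDistribution], ModelSettings]:
    """Read a config file; returns (setting, PSA distributions, run settings)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _parse(doc)


def load_setting(path) -> CountrySetting:
    """Read and validate a country setting from a config file."""
    return load_config(path)[0]


def save_setting(
    path,
    setting: CountrySetting,
    distributions: dict[str, ParameterDistribution] | None = None,
    settings: ModelSettings | None = None,
) -> None:
    """Write a setting (with optional SEs and run settings) as a config file."""
    setting.validate()
    distributions = distributions or {}

    def leaf(path_key: str, value: float):
        dist = distributions.get(path_key)
        if dist is not None and dist.se:
            return {"mean": value, "se": dist.se}
        return value

    doc: dict = {
        "schema": SCHEMA,
        "label": setting.label,
        "wtp_1x": setting.wtp_1x,
        "wtp_3x": setting.wtp_3x,
        "arms": [
            {
                "name": arm.name,
                **{f: leaf(f"arms.{arm.name}.{f}", getattr(arm, f)) for f in _ARM_NUMERIC},
            }
            for arm in setting.arms
        ],
        "econ": {f: leaf(f"econ.{f}", getattr(setting.econ, f)) for f in _ECON_FIELDS},
    }
    if settings is not None:
        settings.validate()
        doc["settings"] = dataclasses.asdict(settings)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def setting_to_csv(setting: CountrySetting) -> str:
    """Flat CSV (parameter,value) export of a setting, for audit."""
    buf = io.StringIO()
    buf.write("parameter,value\n")
    buf.write(f"label,{setting.label}\n")
    for path in parameter_paths(setting):
        buf.write(f"{path},{get_param(setting, path)!r}\n")
    buf.write(f"wtp_1x,{setting.wtp_1x!r}\n")
    buf.write(f"wtp_3x,{setting.wtp_3x!r}\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Bundled Taiwan base case
# ---------------------------------------------------------------------------


def _bundled():
    ref = resources.files("empacea").joinpath("data/taiwan_base.yaml")
    with resources.as_file(ref) as p:
        return load_config(p)


def taiwan_base() -> CountrySetting:
    """The bundled Taiwan base-case setting."""
    return _bundled()[0]


def taiwan_distributions() -> dict[str, ParameterDistribution]:
    """PSA distributions for the bundled Taiwan setting."""
    return _bundled()[1]


def taiwan_settings() -> ModelSettings:
    """Run settings of the bundled Taiwan base case (15 y, 3%/y discount is in econ)."""
    return _bundled()[2]
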