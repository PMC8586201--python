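"""One-way (tornado) sensitivity analysis, scenario runner, adverse-event
extension and the threshold drug-price solver.

Scenarios are pure: overrides are applied to a copy of the setting; the base
setting is never mutated.  Override keys are dotted parameter paths
(``arms.<name>.<field>``, ``econ.<field>``, ``settings.<field>``); the special
value ``"=comparator"`` copies the comparator arm's value into the
intervention arm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from scipy.optimize import brentq

from . import economics, engine
from .parameters import (
    ConfigError,
    CountrySetting,
    ModelSettings,
    get_param,
    parameter_paths,
    set_param,
)

__all__ = [
    "ScenarioSpec",
    "AdverseEventSpec",
    "TornadoEntry",
    "one_way_sa",
    "run_scenario",
    "run_with_adverse_events",
    "threshold_drug_price",
    "scenario_suite",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AdverseEventSpec:
    """A generic adverse event added as an expected-value stream.

    ``probs`` maps arm name to monthly event probability; ``cost`` is per
    event (US$); ``utility_decrement`` (annual scale, <= 0) applies for the
    event month.
    """

    label: str
    probs: dict[str, float]
    cost: float
    utility_decrement: float

    def __post_init__(self) -> None:
        for name, p in self.probs.items():
            if not (0.0 <= p < 1.0):
                raise ConfigError(f"adverse event {self.label}: prob for {name} not in [0,1)")
        if self.cost < 0:
            raise ConfigError(f"adverse event {self.label}: cost must be >= 0")
        if self.utility_decrement > 0:
            raise ConfigError(f"adverse event {self.label}: decrement must be <= 0")

    def prob_for(self, arm_name: str) -> float:
        return self.probs.get(arm_name, 0.0)


@dataclass(frozen=True)
class ScenarioSpec:
    """Named parameter overrides, optionally with adverse events."""

    label: str
    overrides: dict = field(default_factory=dict)
    adverse_events: tuple = ()


@dataclass(frozen=True)
class TornadoEntry:
    """One tornado bar: the cost-effectiveness ratio at the low and high
    parameter inputs.

    Values are *signed* incremental-cost/incremental-QALY ratios: if a
    perturbation flips the intervention to dominated (more costly, fewer
    QALYs) the ratio is negative, keeping the bar — and the influence
    ranking — well defined.
    """

    parameter: str
    icer_low: float
    icer_high: float

    @property
    def width(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _run(setting: CountrySetting, settings: ModelSettings, adverse_events=()):
    totals = []
    for arm in setting.arms:
        tr = engine.run_cohort(arm, settings)
        totals.append(
            economics.accumulate(tr, arm, setting.econ, settings, adverse_events=adverse_events)
        )
    return economics.compare(totals[0], totals[1])


def _perturb(setting: CountrySetting, path: str, value: float) -> CountrySetting:
    """Set a parameter, clamping to its valid boundary if the perturbation
    leaves the admissible range (logged)."""
    leaf = path.split(".")[-1]
    clamped = value
    if leaf.startswith("p_"):
        clamped = min(max(value, 0.0), 1.0 - 1e-12)
    elif leaf == "u_stable":
        clamped = min(max(value, 0.0), 1.0)
    elif leaf.startswith("u_"):
        clamped = min(value, 0.0)
    elif leaf.startswith("cost_") or leaf == "drug_cost":
        clamped = max(value, 0.0)
    if clamped != value:
        logger.info("tornado: clamped %s from %g to %g", path, value, clamped)
    return set_param(setting, path, clamped)


def one_way_sa(
    setting: CountrySetting,
    relative_range: float = 0.10,
    settings: ModelSettings | None = None,
) -> list[TornadoEntry]:
    """ICER at mean*(1 +/- relative_range) for every input parameter, holding
    the others at base; entries sorted by descending range width."""
    if not (0.0 <= relative_range < 1.0):
        raise ValueError(f"relative_range must be in [0, 1), got {relative_range}")
    settings = settings if settings is not None else ModelSettings()
    entries = []
    for path in parameter_paths(setting):
        mean = get_param(setting, path)
        icers = []
        for mult in (1.0 - relative_range, 1.0 + relative_range):
            res = _run(_perturb(setting, path, mean * mult), settings)
            icers.append(res.d_cost / res.d_qaly if res.d_qaly != 0 else float("inf"))
        entries.append(TornadoEntry(parameter=path, icer_low=icers[0], icer_high=icers[1]))
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries


def _apply_overrides(
    setting: CountrySetting, settings: ModelSettings, overrides: dict
) -> tuple[CountrySetting, ModelSettings]:
    new_setting = setting
    new_settings = settings
    for key, value in overrides.items():
        parts = key.split(".")
        if parts[0] == "settings":
            if len(parts) != 2 or not hasattr(settings, parts[1]):
                raise KeyError(f"unknown settings override {key!r}")
            new_settings = replace(new_settings, **{parts[1]: value})
        elif value == "=comparator":
            comp_path = f"arms.{setting.comparator.name}.{parts[2]}"
            if parts[0] != "arms" or parts[1] != setting.intervention.name:
                raise KeyError(f"'=comparator' only applies to intervention-arm paths: {key!r}")
            new_setting = set_param(new_setting, key, get_param(new_setting, comp_path))
        else:
            new_setting = set_param(new_setting, key, float(value))
    new_settings.validate()
    return new_setting, new_settings


def run_scenario(
    setting: CountrySetting,
    spec: ScenarioSpec,
    settings: ModelSettings | None = None,
) -> economics.EconResult:
    """Apply a scenario's overrides and rerun both arms."""
    settings = settings if settings is not None else ModelSettings()
    new_setting, new_settings = _apply_overrides(setting, settings, spec.overrides)
    return _run(new_setting, new_settings, adverse_events=spec.adverse_events)


def run_with_adverse_events(
    setting: CountrySetting,
    events,
    settings: ModelSettings | None = None,
) -> economics.EconResult:
    """Base-case model plus expected-value adverse-event cost/disutility streams."""
    settings = settings if settings is not None else ModelSettings()
    return _run(setting, settings, adverse_events=tuple(events))


def threshold_drug_price(
    setting: CountrySetting,
    wtp: float,
    settings: ModelSettings | None = None,
    tol: float = 0.01,
) -> float:
    """Monthly intervention drug price at which the ICER equals ``wtp``.

    The ICER is affine and strictly increasing in the intervention drug price
    (incremental QALYs are unaffected), so the root is found by bracketed
    root-finding on NMB over [0, 10x base price].
    """
    if wtp <= 0:
        raise ValueError(f"wtp must be > 0, got {wtp}")
    settings = settings if settings is not None else ModelSettings()
    base = _run(setting, settings)
    if base.d_qaly <= 0:
        raise ValueError("threshold price undefined: incremental QALYs not positive at base")
    path = f"arms.{setting.intervention.name}.drug_cost"
    base_price = max(get_param(setting, path), 1.0)

    def f(price: float) -> float:
        res = _run(set_param(setting, path, price), settings)
        return res.d_cost - wtp * res.d_qaly  # zero where ICER == wtp

    lo, hi = 0.0, 10.0 * base_price
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise ValueError(
            f"no threshold price in [0, {hi:g}]: ICER exceeds WTP even at zero price"
            if flo > 0
            else f"no threshold price in [0, {hi:g}]: ICER below WTP everywhere"
        )
    return float(brentq(f, lo, hi, xtol=tol))


def scenario_suite(setting: CountrySetting) -> dict[str, ScenarioSpec]:
    """Bundled scenario suite for the Taiwan analysis (one spec per scenario
    row: equal risks, half costs, alternative horizons and discount rates)."""
    iv = setting.intervention.name
    half_drug = setting.intervention.drug_cost / 2.0
    half_hhf = setting.econ.cost_hhf / 2.0
    return {
        "equal_cv_mortality": ScenarioSpec(
            "Risk of cardiovascular mortality of intervention equal to comparator",
            {f"arms.{iv}.p_cvd": "=comparator"},
        ),
        "equal_non_cv_death": ScenarioSpec(
            "Risk of non-cardiovascular death of intervention equal to comparator",
            {f"arms.{iv}.p_ncd": "=comparator"},
        ),
        "equal_hhf": ScenarioSpec(
            "Risk of HHF of intervention equal to comparator",
            {f"arms.{iv}.p_hhf": "=comparator"},
        ),
        "half_drug_cost": ScenarioSpec(
            "Half the monthly drug cost", {f"arms.{iv}.drug_cost": half_drug}
        ),
        "half_hhf_cost": ScenarioSpec(
            "Half the cost of HHF treatment", {"econ.cost_hhf": half_hhf}
        ),
        "horizon_16_months": ScenarioSpec(
            "Time horizon 16 months", {"settings.horizon_cycles": 16}
        ),
        "horizon_30_years": ScenarioSpec(
            "Time horizon 30 years", {"settings.horizon_cycles": 360}
        ),
        "discount_0": ScenarioSpec(
            "Discount rate 0%", {"econ.discount_rate_annual": 0.0}
        ),
        "discount_10": ScenarioSpec(
            "Discount rate 10%", {"econ.discount_rate_annual": 0.10}
        ),
    }
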