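"""Discounted cost, life-year and QALY accounting, and incremental results.

Per cycle, costs are::

    occupancy * (drug_cost + cost_stable)
    + hhf * cost_hhf + cvd * cost_pre_cvd + ncd * cost_pre_ncd

where ``occupancy`` is the credited alive person-months for the cycle (see
``ModelSettings.occupancy_counting``) and event terms are credited once per
event.  QALYs accrue as ``occupancy * u(age) / 12`` plus the one-month
hospitalization disutility ``hhf * u_hhf_decrement / 12``; life-years as
``occupancy / 12``.  Everything is multiplied by the cycle's discount factor,
anchored so cycle 1 is undiscounted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .engine import CohortTrace
from .parameters import ArmParameters, EconomicInputs, ModelSettings

__all__ = [
    "ArmTotals",
    "EconResult",
    "discount_factor",
    "discount_factors",
    "accumulate",
    "compare",
    "net_monetary_benefit",
]

logger = logging.getLogger(__name__)

#: |incremental QALYs| below this is reported as "undefined" rather than an ICER
QALY_TOL = 1e-9


@dataclass(frozen=True)
class ArmTotals:
    """Discounted totals for one arm over the horizon."""

    arm_name: str
    cost: float
    qaly: float
    life_years: float


@dataclass(frozen=True)
class EconResult:
    """Incremental comparison of intervention (first) vs comparator (second).

    ``icer_per_qaly``/``icer_per_ly`` are finite numbers when the respective
    incremental denominator is positive and incremental cost is positive;
    otherwise ``label`` carries the dominance classification and the ICER
    fields are ``nan``.
    """

    intervention: ArmTotals
    comparator: ArmTotals
    d_cost: float
    d_qaly: float
    d_ly: float
    icer_per_qaly: float
    icer_per_ly: float
    label: str

    def summary_row(self) -> dict:
        return {
            "cost_intervention": self.intervention.cost,
            "cost_comparator": self.comparator.cost,
            "d_cost": self.d_cost,
            "qaly_intervention": self.intervention.qaly,
            "qaly_comparator": self.comparator.qaly,
            "d_qaly": self.d_qaly,
            "ly_intervention": self.intervention.life_years,
            "ly_comparator": self.comparator.life_years,
            "d_ly": self.d_ly,
            "icer_per_qaly": self.icer_per_qaly,
            "icer_per_ly": self.icer_per_ly,
            "label": self.label,
        }


def discount_factor(cycle: int, annual_rate: float) -> float:
    """Discount multiplier for a 1-month cycle; cycle 1 is undiscounted."""
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    if annual_rate < 0:
        raise ValueError(f"annual_rate must be >= 0, got {annual_rate}")
    return float((1.0 + annual_rate) ** (-(cycle - 1) / 12.0))


def discount_factors(
    cycles: np.ndarray, annual_rate: float, mode: str = "monthly_compound"
) -> np.ndarray:
    """Vector of discount multipliers; ``annual_step`` discounts by whole
    elapsed years instead of compounding monthly."""
    if mode == "monthly_compound":
        return (1.0 + annual_rate) ** (-(cycles - 1) / 12.0)
    if mode == "annual_step":
        return (1.0 + annual_rate) ** (-((cycles - 1) // 12).astype(float))
    raise ValueError(f"unknown discount mode {mode!r}")


def _occupancy(trace: CohortTrace, settings: ModelSettings) -> np.ndarray:
    """Credited alive person-months per cycle."""
    base = trace.alive
    if settings.half_cycle_correction:
        base = 0.5 * (trace.alive + trace.alive_end)
    return settings.occupancy_weight * base


def accumulate(
    trace: CohortTrace,
    arm: ArmParameters,
    econ: EconomicInputs,
    settings: ModelSettings,
    adverse_events=(),
) -> ArmTotals:
    """Discounted cost/QALY/LY totals for one arm's trace.

    ``adverse_events`` is an optional sequence of
    :class:`~empacea.sensitivity.AdverseEventSpec`; each contributes an
    expected per-cycle cost ``alive * p * cost`` and disutility
    ``alive * p * decrement / 12`` for this arm.
    """
    econ.validate()
    settings.validate()
    disc = discount_factors(trace.cycle, econ.discount_rate_annual, settings.discount_mode)
    occ = _occupancy(trace, settings)

    # elapsed years driving the age decrement: credited time advances at the
    # occupancy-counting rate, calendar time at one month per cycle
    if settings.age_decrement_basis == "credited":
        elapsed = settings.occupancy_weight * (trace.cycle - 1) / 12.0
    else:
        elapsed = (trace.cycle - 1) / 12.0
    u = econ.u_stable + econ.u_age_decrement * elapsed
    if np.any(u < 0):
        logger.warning(
            "age decrement drives utility below 0 at age >= %.1f; clamping",
            float(trace.age[np.argmax(u < 0)]),
        )
        u = np.clip(u, 0.0, None)

    cost = (
        occ * (arm.drug_cost + econ.cost_stable)
        + trace.hhf * econ.cost_hhf
        + trace.cvd * econ.cost_pre_cvd
        + trace.ncd * econ.cost_pre_ncd
    )
    qaly = (occ * u + trace.hhf * econ.u_hhf_decrement) / 12.0
    ly = occ / 12.0

    for ev in adverse_events:
        p = ev.prob_for(arm.name)
        cost = cost + trace.alive * p * ev.cost
        qaly = qaly + trace.alive * p * ev.utility_decrement / 12.0

    return ArmTotals(
        arm_name=arm.name,
        cost=float(np.sum(cost * disc)),
        qaly=float(np.sum(qaly * disc)),
        life_years=float(np.sum(ly * disc)),
    )


def compare(intervention: ArmTotals, comparator: ArmTotals) -> EconResult:
    """Incremental result: intervention minus comparator."""
    d_cost = intervention.cost - comparator.cost
    d_qaly = intervention.qaly - comparator.qaly
    d_ly = intervention.life_years - comparator.life_years

    if abs(d_qaly) < QALY_TOL:
        label = "undefined"
        icer_q = float("nan")
    elif d_cost < 0 and d_qaly > 0:
        label = "dominant"
        icer_q = float("nan")
    elif d_cost > 0 and d_qaly < 0:
        label = "dominated"
        icer_q = float("nan")
    else:
        label = "icer"
        icer_q = d_cost / d_qaly
    icer_ly = d_cost / d_ly if abs(d_ly) > QALY_TOL and label == "icer" else float("nan")

    return EconResult(
        intervention=intervention,
        comparator=comparator,
        d_cost=d_cost,
        d_qaly=d_qaly,
        d_ly=d_ly,
        icer_per_qaly=icer_q,
        icer_per_ly=icer_ly,
        label=label,
    )


def net_monetary_benefit(result: EconResult, wtp: float) -> float:
    """NMB = dQALY * WTP - dCost; positive iff cost-effective at ``wtp``."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp}")
    return result.d_qaly * wtp - result.d_cost
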