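"""Synthetic two-arm trial generator and fixture fabrication.

The generator emulates the statistical structure the cohort model assumes: a
two-arm trial followed for a fixed number of months in which each patient's
hospitalization, cardiovascular-death and non-cardiovascular-death processes
are independent constant-hazard monthly Bernoulli sequences.  Event processes
are deliberately *not* censored by death, so the per-arm proportion of
patients with at least one event over ``followup`` months has expectation
exactly ``1 - (1 - p)**followup`` and the proportion-to-monthly-probability
conversion is exactly self-consistent.  (A real trial censors follow-up at
death; see the methods note for what this simplification implies.)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .parameters import (
    ArmParameters,
    CountrySetting,
    proportion_to_monthly_prob,
    taiwan_base,
)

__all__ = [
    "TrialSimConfig",
    "ArmSummary",
    "TrialSummary",
    "simulate_trial",
    "derive_arm_parameters",
    "fabricate_country",
]

_EVENTS = ("hhf", "cv_death", "non_cv_death")


@dataclass(frozen=True)
class TrialSimConfig:
    """True monthly event probabilities per arm, trial size and follow-up."""

    n_per_arm: int
    followup_months: int
    arms: dict  # name -> {"hhf": p, "cv_death": p, "non_cv_death": p}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError(f"n_per_arm must be >= 1, got {self.n_per_arm}")
        if self.followup_months < 1:
            raise ValueError(f"followup_months must be >= 1, got {self.followup_months}")
        for name, probs in self.arms.items():
            unknown = set(probs) - set(_EVENTS)
            if unknown:
                raise ValueError(f"arm {name}: unknown events {sorted(unknown)}")
            for ev, p in probs.items():
                if not (0.0 <= p < 1.0):
                    raise ValueError(f"arm {name}.{ev}: probability not in [0, 1)")


@dataclass(frozen=True)
class ArmSummary:
    """Counts and proportions of patients with >= 1 event over follow-up."""

    name: str
    n: int
    counts: dict
    proportions: dict


@dataclass(frozen=True)
class TrialSummary:
    followup_months: int
    arms: dict  # name -> ArmSummary

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arm in self.arms.values():
            for ev in _EVENTS:
                rows.append(
                    {
                        "arm": arm.name,
                        "event": ev,
                        "n": arm.n,
                        "count": arm.counts[ev],
                        "proportion": arm.proportions[ev],
                    }
                )
        return pd.DataFrame(rows)


def simulate_trial(config: TrialSimConfig) -> TrialSummary:
    """Simulate the trial and summarize first-event proportions per arm.

    A patient registers an event if any of their ``followup_months``
    independent Bernoulli trials at the true monthly probability fires;
    equivalently the first-event month is geometric and the indicator is
    ``first <= followup``.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    arms = {}
    for name in sorted(config.arms):
        probs = config.arms[name]
        counts = {}
        proportions = {}
        for ev in _EVENTS:
            p = probs.get(ev, 0.0)
            if p == 0.0:
                count = 0
            else:
                # geometric first-success month; support {1, 2, ...}
                first = rng.geometric(p, size=config.n_per_arm)
                count = int(np.sum(first <= config.followup_months))
            counts[ev] = count
            proportions[ev] = count / config.n_per_arm
        arms[name] = ArmSummary(
            name=name, n=config.n_per_arm, counts=counts, proportions=proportions
        )
    return TrialSummary(followup_months=config.followup_months, arms=arms)


def derive_arm_parameters(
    summary: ArmSummary, followup_months: int, drug_cost: float = 0.0
) -> ArmParameters:
    """Convert an arm's event proportions into monthly transition probabilities."""
    for ev in _EVENTS:
        if summary.proportions[ev] >= 1.0:
            raise ValueError(f"{summary.name}.{ev}: proportion 1 implies infinite hazard")
    return ArmParameters(
        name=summary.name,
        p_hhf=proportion_to_monthly_prob(summary.proportions["hhf"], followup_months),
        p_cvd=proportion_to_monthly_prob(summary.proportions["cv_death"], followup_months),
        p_ncd=proportion_to_monthly_prob(summary.proportions["non_cv_death"], followup_months),
        drug_cost=drug_cost,
    )


def fabricate_country(
    seed: int, cost_scale: float = 1.0, utility_jitter: float = 0.0
) -> CountrySetting:
    """A plausible synthetic country setting for multi-country runner tests.

    Starts from the Taiwan template, scales every cost and WTP threshold by
    ``cost_scale`` and jitters ``u_stable`` by up to ``+/- utility_jitter``
    (kept inside (|u_hhf_decrement|, 1)).  ``cost_scale=1, utility_jitter=0``
    reproduces the template exactly (apart from the label).
    """
    if cost_scale <= 0:
        raise ValueError(f"cost_scale must be > 0, got {cost_scale}")
    rng = np.random.default_rng(seed)
    base = taiwan_base()
    econ = base.econ
    u = econ.u_stable
    if utility_jitter:
        lo = max(-econ.u_hhf_decrement + 1e-6, u - utility_jitter)
        hi = min(1.0, u + utility_jitter)
        u = float(rng.uniform(lo, hi))
    econ = replace(
        econ,
        u_stable=u,
        cost_stable=econ.cost_stable * cost_scale,
        cost_hhf=econ.cost_hhf * cost_scale,
        cost_pre_cvd=econ.cost_pre_cvd * cost_scale,
        cost_pre_ncd=econ.cost_pre_ncd * cost_scale,
    )
    arms = tuple(replace(arm, drug_cost=arm.drug_cost * cost_scale) for arm in base.arms)
    setting = CountrySetting(
        label=f"synthetic-{seed}",
        arms=arms,  # type: ignore[arg-type]
        econ=econ,
        wtp_1x=base.wtp_1x * cost_scale,
        wtp_3x=base.wtp_3x * cost_scale,
    )
    setting.validate()
    return setting
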