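"""Monthly-cycle cohort simulation for one treatment arm.

The cohort starts fully in stable heart failure.  Each cycle, the alive
fraction may be hospitalized for heart failure (a transient within-cycle
event: survivors return to stable HF), die of a cardiovascular cause, or die
of a non-cardiovascular cause.  Transition probabilities are constant over
time; within a cycle the events are treated as independent, so hospitalization
and death may co-occur.  Deaths are removed from the alive fraction at the end
of the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ArmParameters, ModelSettings

__all__ = ["CohortTrace", "run_cohort", "expected_events"]


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy and event incidence for one arm.

    Arrays are aligned on cycle index 1..horizon.  ``alive`` is the fraction
    alive at cycle start; ``hhf``/``cvd``/``ncd`` are the fractions
    experiencing each event during the cycle; ``cum_dead_cv``/``cum_dead_ncv``
    are cumulative by end of cycle.  ``age`` is calendar cohort age at cycle
    start in years.
    """

    arm_name: str
    cycle: np.ndarray
    age: np.ndarray
    alive: np.ndarray
    hhf: np.ndarray
    cvd: np.ndarray
    ncd: np.ndarray
    cum_dead_cv: np.ndarray
    cum_dead_ncv: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.cycle)

    @property
    def alive_end(self) -> np.ndarray:
        """Fraction alive at the end of each cycle."""
        return self.alive - self.cvd - self.ncd

    @property
    def final_mortality(self) -> float:
        """Cumulative all-cause mortality at the end of the horizon."""
        return float(self.cum_dead_cv[-1] + self.cum_dead_ncv[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": self.cycle,
                "age": self.age,
                "alive": self.alive,
                "hhf_frac": self.hhf,
                "cvd_frac": self.cvd,
                "ncd_frac": self.ncd,
                "cum_dead_cv": self.cum_dead_cv,
                "cum_dead_ncv": self.cum_dead_ncv,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_cohort(arm: ArmParameters, settings: ModelSettings) -> CohortTrace:
    """Run the cohort for ``settings.horizon_cycles`` monthly cycles."""
    arm.validate()
    settings.validate()
    n = settings.horizon_cycles

    alive = np.empty(n)
    hhf = np.empty(n)
    cvd = np.empty(n)
    ncd = np.empty(n)

    a = 1.0
    for t in range(n):
        alive[t] = a
        if t == 0 and settings.first_cycle_event_free:
            hhf[t] = cvd[t] = ncd[t] = 0.0
        else:
            hhf[t] = a * arm.p_hhf
            cvd[t] = a * arm.p_cvd
            ncd[t] = a * arm.p_ncd
        a -= cvd[t] + ncd[t]

    cycle = np.arange(1, n + 1)
    age = settings.start_age + (cycle - 1) / 12.0
    return CohortTrace(
        arm_name=arm.name,
        cycle=cycle,
        age=age,
        alive=alive,
        hhf=hhf,
        cvd=cvd,
        ncd=ncd,
        cum_dead_cv=np.cumsum(cvd),
        cum_dead_ncv=np.cumsum(ncd),
    )


def expected_events(trace: CohortTrace, per: float = 1.0) -> dict[str, float]:
    """Expected event counts over the horizon for a cohort of size ``per``."""
    return {
        "hhf": float(trace.hhf.sum() * per),
        "cv_death": float(trace.cvd.sum() * per),
        "non_cv_death": float(trace.ncd.sum() * per),
    }
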