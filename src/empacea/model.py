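"""Model/Results facade tying the cohort engine and economics together.

``MarkovCEA`` is constructed from a :class:`~empacea.parameters.CountrySetting`
(plus optional run settings); ``fit()`` runs both arms and returns a
:class:`CEAResults` carrying traces, discounted totals, increments and ICERs,
with ``summary()`` for a human-readable table.  Sensitivity analyses, PSA and
the threshold-price solver hang off the model object.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from . import economics, engine
from .parameters import (
    CountrySetting,
    ModelSettings,
    ParameterDistribution,
    load_config,
)

__all__ = ["MarkovCEA", "CEAResults"]


class MarkovCEA:
    """Two-arm Markov cohort cost-effectiveness model.

    Parameters
    ----------
    setting : CountrySetting
        Arms (intervention first), economics and WTP thresholds.
    settings : ModelSettings, optional
        Simulation/accounting conventions; defaults reproduce the published
        Taiwan analysis (180 monthly cycles, boundary occupancy counting).
    distributions : dict, optional
        PSA distributions keyed by parameter path; required for ``psa()``.
    """

    def __init__(
        self,
        setting: CountrySetting,
        settings: ModelSettings | None = None,
        distributions: dict[str, ParameterDistribution] | None = None,
    ):
        setting.validate()
        self.setting = setting
        self.settings = settings if settings is not None else ModelSettings()
        self.settings.validate()
        self.distributions = distributions or {}

    @classmethod
    def from_config(cls, path) -> "MarkovCEA":
        setting, distributions, settings = load_config(path)
        return cls(setting, settings=settings, distributions=distributions)

    def fit(self, adverse_events=()) -> "CEAResults":
        """Run both arms and compute the incremental comparison."""
        traces = {}
        totals = []
        for arm in self.setting.arms:
            tr = engine.run_cohort(arm, self.settings)
            traces[arm.name] = tr
            totals.append(
                economics.accumulate(
                    tr, arm, self.setting.econ, self.settings, adverse_events=adverse_events
                )
            )
        econ = economics.compare(totals[0], totals[1])
        return CEAResults(model=self, econ=econ, traces=traces)

    # -- analyses delegating to the sensitivity / psa modules ---------------

    def tornado(self, relative_range: float = 0.10):
        from .sensitivity import one_way_sa

        return one_way_sa(self.setting, relative_range, settings=self.settings)

    def scenario(self, spec):
        from .sensitivity import run_scenario

        return run_scenario(self.setting, spec, settings=self.settings)

    def threshold_price(self, wtp: float) -> float:
        from .sensitivity import threshold_drug_price

        return threshold_drug_price(self.setting, wtp, settings=self.settings)

    def psa(self, n: int = 1000, seed: int = 0, wtp_grid=None, n_subjects="default",
            couple_arms: bool = True):
        from .psa import DEFAULT_N_SUBJECTS, run_psa

        if n_subjects == "default":
            n_subjects = DEFAULT_N_SUBJECTS
        return run_psa(
            self.setting,
            n=n,
            seed=seed,
            distributions=self.distributions or None,
            settings=self.settings,
            wtp_grid=wtp_grid,
            n_subjects=n_subjects,
            couple_arms=couple_arms,
        )


@dataclass(frozen=True)
class CEAResults:
    """Fitted results: per-arm discounted totals, increments and diagnostics."""

    model: MarkovCEA
    econ: economics.EconResult
    traces: dict[str, engine.CohortTrace]

    @property
    def icer_per_qaly(self) -> float:
        return self.econ.icer_per_qaly

    @property
    def icer_per_ly(self) -> float:
        return self.econ.icer_per_ly

    def nmb(self, wtp: float) -> float:
        return economics.net_monetary_benefit(self.econ, wtp)

    def expected_events(self, per: float = 1000.0) -> dict[str, dict[str, float]]:
        return {name: engine.expected_events(tr, per) for name, tr in self.traces.items()}

    def classification(self) -> str:
        """Cost-effectiveness class at the setting's WTP thresholds."""
        icer = self.econ.icer_per_qaly
        if self.econ.label == "dominant":
            return "dominant"
        if self.econ.label != "icer":
            return self.econ.label
        if icer <= self.model.setting.wtp_1x:
            return "very cost-effective"
        if icer <= self.model.setting.wtp_3x:
            return "cost-effective"
        return "not cost-effective"

    def summary(self) -> str:
        e = self.econ
        s = self.model.setting
        lines = [
            f"Markov cohort CEA: {s.arms[0].name} vs {s.arms[1].name} ({s.label})",
            f"  horizon: {self.model.settings.horizon_cycles} monthly cycles, "
            f"discount {s.econ.discount_rate_annual:.1%}/yr",
            "",
            f"  {'':>22}{e.intervention.arm_name:>16}{e.comparator.arm_name:>16}{'increment':>14}",
            f"  {'cost (US$)':>22}{e.intervention.cost:>16,.0f}{e.comparator.cost:>16,.0f}"
            f"{e.d_cost:>14,.0f}",
            f"  {'QALYs':>22}{e.intervention.qaly:>16.2f}{e.comparator.qaly:>16.2f}"
            f"{e.d_qaly:>14.2f}",
            f"  {'life-years':>22}{e.intervention.life_years:>16.2f}"
            f"{e.comparator.life_years:>16.2f}{e.d_ly:>14.2f}",
            "",
        ]
        if e.label == "icer":
            lines += [
                f"  ICER: {e.icer_per_qaly:,.0f} US$/QALY, {e.icer_per_ly:,.0f} US$/LY",
                f"  classification at WTP {s.wtp_1x:,.0f}/{s.wtp_3x:,.0f}: "
                f"{self.classification()}",
            ]
        else:
            lines.append(f"  result: {e.label}")
        mort = {name: tr.final_mortality for name, tr in self.traces.items()}
        lines.append(
            "  end-of-horizon mortality: "
            + ", ".join(f"{k} {v:.1%}" for k, v in mort.items())
        )
        return "\n".join(lines)
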