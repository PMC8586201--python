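"""Probabilistic sensitivity analysis: joint parameter sampling, repeated
model evaluation, and the cost-effectiveness acceptability curve (CEAC).

Each Monte-Carlo iteration draws every uncertain input from its assigned
distribution (beta for probabilities and utilities, with negative decrements
sampled on the magnitude and negated; gamma for costs).  Two structural
choices matter:

* **Arm coupling.**  The two arms' probabilities for the same event type are
  sampled *comonotonically* — one shared quantile mapped through each arm's
  own beta distribution — so a draw shifts both arms' risks together and
  preserves the relative treatment effect, as when baseline risk and relative
  effect are sampled rather than two independent absolute risks.  Fully
  independent per-arm sampling (``couple_arms=False``) makes the sign of the
  incremental effect itself random in a large share of draws.

* **Subject-level sampling.**  With ``n_subjects`` set, each iteration
  simulates that many individual patients per arm at the drawn parameters
  (death month geometric, cause assigned proportionally, hospitalizations
  binomial over the months alive) and averages their discounted outcomes, so
  the draws carry first-order (sampling) noise of a trial-sized cohort on
  top of second-order parameter uncertainty.  ``n_subjects=None`` evaluates
  the deterministic cohort model instead (pure second-order PSA).

Shared parameters (utilities, chronic and event costs) take one value per
draw across both arms.  Results are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import economics, engine
from .parameters import (
    CountrySetting,
    ModelSettings,
    ParameterDistribution,
    fit_beta,
    fit_gamma,
    set_param,
)

__all__ = [
    "PSAResult",
    "DEFAULT_N_SUBJECTS",
    "default_wtp_grid",
    "sample_parameters",
    "run_psa",
    "ceac",
]

#: subjects per arm per iteration: half the 3,730-patient two-arm trial the
#: transition probabilities are derived from
DEFAULT_N_SUBJECTS = 1865

_COUPLED_LEAVES = ("p_cvd", "p_hhf", "p_ncd")


def default_wtp_grid() -> np.ndarray:
    """US$0 to US$100,000 in steps of US$1,000."""
    return np.arange(0, 100001, 1000, dtype=float)


@dataclass(frozen=True)
class PSAResult:
    """Paired incremental (cost, QALY) draws and the derived CEAC."""

    n_draws: int
    seed: int
    d_cost: np.ndarray
    d_qaly: np.ndarray
    wtp_grid: np.ndarray
    ceac: np.ndarray

    def prob_cost_effective(self, wtp: float) -> float:
        """Fraction of draws with positive NMB at ``wtp``."""
        return float(np.mean(self.d_qaly * wtp - self.d_cost > 0))

    def draws_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"draw": np.arange(1, self.n_draws + 1), "d_cost": self.d_cost, "d_qaly": self.d_qaly}
        )

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid, "prob_cost_effective": self.ceac})


# ---------------------------------------------------------------------------
# Parameter sampling
# ---------------------------------------------------------------------------


def _draw_marginal(dist: ParameterDistribution, rng: np.random.Generator) -> float:
    if dist.family == "fixed" or dist.se == 0:
        return dist.mean
    if dist.family == "beta":
        sign = -1.0 if dist.mean < 0 else 1.0
        a, b = fit_beta(abs(dist.mean), dist.se)
        return sign * float(rng.beta(a, b))
    if dist.family == "gamma":
        shape, scale = fit_gamma(dist.mean, dist.se)
        return float(rng.gamma(shape, scale))
    raise AssertionError(dist.family)


def sample_parameters(
    setting: CountrySetting,
    distributions: dict[str, ParameterDistribution],
    seed: int | np.random.Generator,
    couple_arms: bool = True,
) -> CountrySetting:
    """One joint draw of all uncertain parameters.

    Parameters without an entry in ``distributions`` stay at their base
    value.  With ``couple_arms`` (default) the per-arm probabilities of the
    same event type share one quantile; all other parameters are independent.
    Paths are visited in sorted order, so a given seed always yields the same
    setting.  Infeasible beta moments raise when the distribution is
    constructed, not at draw time.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shared_u = {leaf: rng.uniform() for leaf in _COUPLED_LEAVES} if couple_arms else {}
    out = setting
    for path in sorted(distributions):
        dist = distributions[path]
        leaf = path.split(".")[-1]
        if couple_arms and leaf in shared_u and dist.family == "beta" and dist.se > 0:
            a, b = fit_beta(abs(dist.mean), dist.se)
            value = float(stats.beta.ppf(shared_u[leaf], a, b))
        else:
            value = _draw_marginal(dist, rng)
        out = set_param(out, path, value)
    return out


# ---------------------------------------------------------------------------
# Per-iteration model evaluation
# ---------------------------------------------------------------------------


def _cohort_increments(setting: CountrySetting, settings: ModelSettings) -> tuple[float, float]:
    totals = []
    for arm in setting.arms:
        tr = engine.run_cohort(arm, settings)
        totals.append(economics.accumulate(tr, arm, setting.econ, settings))
    res = economics.compare(totals[0], totals[1])
    return res.d_cost, res.d_qaly


def _subject_increments(
    setting: CountrySetting,
    settings: ModelSettings,
    n_subjects: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Mean incremental cost/QALY over ``n_subjects`` simulated patients per
    arm, under the same accounting conventions as the cohort model.

    Death month is geometric at the arm's monthly all-cause probability
    (cause assigned proportionally); hospitalizations are binomial over the
    months alive, valued at the mean discount factor of those months (the
    within-life timing of hospitalizations is averaged — see methods note).
    """
    econ = setting.econ
    H = settings.horizon_cycles
    cycles = np.arange(1, H + 1)
    disc = economics.discount_factors(cycles, econ.discount_rate_annual, settings.discount_mode)
    w = settings.occupancy_weight
    cum_disc = np.cumsum(disc)

    if settings.age_decrement_basis == "credited":
        elapsed = w * (cycles - 1) / 12.0
    else:
        elapsed = (cycles - 1) / 12.0
    u = np.clip(econ.u_stable + econ.u_age_decrement * elapsed, 0.0, None)

    skip = 1 if settings.first_cycle_event_free else 0

    means = []
    for arm in setting.arms:
        # cumulative per-cycle occupancy rewards for a patient alive through cycle m
        occ_cost = np.cumsum(w * (arm.drug_cost + econ.cost_stable) * disc)
        occ_qaly = np.cumsum(w * u * disc / 12.0)

        p_death = arm.p_cvd + arm.p_ncd
        if p_death > 0:
            death = rng.geometric(p_death, size=n_subjects) + skip
        else:
            death = np.full(n_subjects, H + 1)
        alive_m = np.minimum(death, H)  # cycles with occupancy credit
        died = death <= H

        cost = occ_cost[alive_m - 1].astype(float)
        qaly = occ_qaly[alive_m - 1].astype(float)
        if died.any() and p_death > 0:
            cv = rng.uniform(size=n_subjects) < arm.p_cvd / p_death
            at_death = disc[alive_m - 1]
            cost += np.where(died & cv, econ.cost_pre_cvd * at_death, 0.0)
            cost += np.where(died & ~cv, econ.cost_pre_ncd * at_death, 0.0)

        months_at_risk = np.maximum(alive_m - skip, 0)
        if arm.p_hhf > 0:
            k = rng.binomial(months_at_risk, arm.p_hhf)
            with np.errstate(invalid="ignore", divide="ignore"):
                mean_disc = np.where(
                    months_at_risk > 0,
                    (cum_disc[alive_m - 1] - (cum_disc[skip - 1] if skip else 0.0))
                    / np.maximum(months_at_risk, 1),
                    0.0,
                )
            cost += k * econ.cost_hhf * mean_disc
            qaly += k * econ.u_hhf_decrement / 12.0 * mean_disc
        means.append((cost.mean(), qaly.mean()))

    return means[0][0] - means[1][0], means[0][1] - means[1][1]


# ---------------------------------------------------------------------------
# PSA driver and CEAC
# ---------------------------------------------------------------------------


def run_psa(
    setting: CountrySetting,
    n: int = 1000,
    seed: int = 0,
    distributions: dict[str, ParameterDistribution] | None = None,
    settings: ModelSettings | None = None,
    wtp_grid=None,
    n_subjects: int | None = DEFAULT_N_SUBJECTS,
    couple_arms: bool = True,
) -> PSAResult:
    """``n`` Monte-Carlo iterations of the full two-arm model."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if distributions is None:
        from .parameters import taiwan_distributions

        distributions = taiwan_distributions()
    settings = settings if settings is not None else ModelSettings()
    grid = np.asarray(default_wtp_grid() if wtp_grid is None else wtp_grid, dtype=float)
    if grid.size == 0 or np.any(grid < 0):
        raise ValueError("wtp_grid must be nonempty with values >= 0")

    rng = np.random.default_rng(seed)
    d_cost = np.empty(n)
    d_qaly = np.empty(n)
    for i in range(n):
        drawn = sample_parameters(setting, distributions, rng, couple_arms=couple_arms)
        if n_subjects is None:
            d_cost[i], d_qaly[i] = _cohort_increments(drawn, settings)
        else:
            d_cost[i], d_qaly[i] = _subject_increments(drawn, settings, n_subjects, rng)

    curve = ceac_from_draws(d_cost, d_qaly, grid)
    return PSAResult(
        n_draws=n, seed=seed, d_cost=d_cost, d_qaly=d_qaly, wtp_grid=grid, ceac=curve
    )


def ceac_from_draws(d_cost: np.ndarray, d_qaly: np.ndarray, wtp_grid: np.ndarray) -> np.ndarray:
    nmb = d_qaly[None, :] * wtp_grid[:, None] - d_cost[None, :]
    return (nmb > 0).mean(axis=1)


def ceac(result: PSAResult, wtp_grid) -> np.ndarray:
    """Probability cost-effective at each WTP in ``wtp_grid``."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0 or np.any(grid < 0):
        raise ValueError("wtp_grid must be nonempty with values >= 0")
    return ceac_from_draws(result.d_cost, result.d_qaly, grid)
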