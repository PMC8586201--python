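"""Input types, probability conversion, distribution fitting, config I/O."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from empacea import (
    ArmParameters,
    fit_beta,
    fit_gamma,
    load_config,
    load_setting,
    proportion_to_monthly_prob,
    save_setting,
)
from empacea.parameters import (
    ConfigError,
    ParameterDistribution,
    get_param,
    monthly_prob_to_proportion,
    parameter_paths,
    set_param,
    setting_to_csv,
)

# ---------------------------------------------------------------------------
# proportion -> monthly probability
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "p16, expected, tol",
    [
        (0.0, 0.0, 0.0),
        # 16-month event proportions that back out the Taiwan standard-therapy
        # monthly HHF and CV-death probabilities
        (0.183, 0.012566527, 1e-4),
        (0.108, 0.007131185, 1e-4),
    ],
)
def test_proportion_conversion_matches_constant_hazard(p16, expected, tol):
    assert proportion_to_monthly_prob(p16, 16) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
def test_proportion_conversion_rejects_out_of_range(bad):
    with pytest.raises(ValueError):
        proportion_to_monthly_prob(bad, 16)


def test_proportion_conversion_rejects_zero_followup():
    with pytest.raises(ValueError):
        proportion_to_monthly_prob(0.1, 0)


@given(
    p=st.floats(1e-6, 0.99),
    months=st.integers(1, 240),
)
@hsettings(max_examples=100, deadline=None)
def test_proportion_conversion_round_trips(p, months):
    pm = proportion_to_monthly_prob(p, months)
    assert monthly_prob_to_proportion(pm, months) == pytest.approx(p, abs=1e-12)


@given(
    p=st.floats(1e-4, 0.95),
    delta=st.floats(1e-4, 0.04),
    months=st.integers(1, 120),
)
@hsettings(max_examples=100, deadline=None)
def test_proportion_conversion_monotone(p, delta, months):
    """Strictly increasing in the proportion, strictly decreasing in follow-up."""
    assert proportion_to_monthly_prob(p + delta, months) > proportion_to_monthly_prob(p, months)
    assert proportion_to_monthly_prob(p, months + 1) < proportion_to_monthly_prob(p, months)


# ---------------------------------------------------------------------------
# beta / gamma method-of-moments fits
# ---------------------------------------------------------------------------


def test_fit_beta_symmetric_at_half():
    a, b = fit_beta(0.5, 0.1)
    assert a == pytest.approx(b)


@pytest.mark.parametrize("mean, se", [(0.770, 0.016), (0.012566527, 0.002578038)])
def test_fit_beta_recovers_moments(mean, se):
    a, b = fit_beta(mean, se)
    assert a / (a + b) == pytest.approx(mean, abs=1e-9)
    sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
    assert sd == pytest.approx(se, abs=1e-9)


def test_fit_beta_sample_mean_close_to_target():
    mean, se = 0.012566527, 0.002578038
    a, b = fit_beta(mean, se)
    draws = np.random.default_rng(0).beta(a, b, size=10**6)
    assert abs(draws.mean() - mean) < 3 * se / 1000  # 3 SE of the 1e6-draw mean


@pytest.mark.parametrize("mean, se", [(0.5, 0.5), (0.5, 0.6), (1.2, 0.1), (0.0, 0.1)])
def test_fit_beta_rejects_infeasible_moments(mean, se):
    with pytest.raises(ValueError):
        fit_beta(mean, se)


@pytest.mark.parametrize(
    "mean, se, shape, scale",
    [(450.0, 225.0, 4.0, 112.5), (2887.0, 1443.5, 4.0, 721.75), (7.0, 7.0, 1.0, 7.0)],
)
def test_fit_gamma_closed_form(mean, se, shape, scale):
    got = fit_gamma(mean, se)
    assert got == pytest.approx((shape, scale), abs=1e-12)


@given(mean=st.floats(1e-3, 1e5), ratio=st.floats(0.05, 3.0))
@hsettings(max_examples=200, deadline=None)
def test_fit_gamma_moment_round_trip(mean, ratio):
    se = mean * ratio
    shape, scale = fit_gamma(mean, se)
    assert shape * scale == pytest.approx(mean, rel=1e-9)
    assert np.sqrt(shape) * scale == pytest.approx(se, rel=1e-9)


@given(mean=st.floats(0.01, 0.99), frac=st.floats(0.01, 0.95))
@hsettings(max_examples=200, deadline=None)
def test_fit_beta_moment_round_trip(mean, frac):
    se = frac * np.sqrt(mean * (1 - mean))  # guaranteed feasible
    a, b = fit_beta(mean, se)
    assert a / (a + b) == pytest.approx(mean, rel=1e-9)
    var = a * b / ((a + b) ** 2 * (a + b + 1))
    assert np.sqrt(var) == pytest.approx(se, rel=1e-9)


@pytest.mark.parametrize("mean, se", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
def test_fit_gamma_rejects_nonpositive(mean, se):
    with pytest.raises(ValueError):
        fit_gamma(mean, se)


# ---------------------------------------------------------------------------
# Bundled Taiwan config and config I/O
# ---------------------------------------------------------------------------

TAIWAN_TABLE = {
    "arms.empagliflozin.p_hhf": 0.008811915,
    "arms.empagliflozin.p_cvd": 0.006589325,
    "arms.empagliflozin.p_ncd": 0.002113141,
    "arms.empagliflozin.drug_cost": 35.0,
    "arms.standard.p_hhf": 0.012566527,
    "arms.standard.p_cvd": 0.007131185,
    "arms.standard.p_ncd": 0.002177683,
    "arms.standard.drug_cost": 0.0,
    "econ.u_stable": 0.770,
    "econ.u_age_decrement": -0.0016,
    "econ.u_hhf_decrement": -0.321,
    "econ.cost_stable": 450.0,
    "econ.cost_hhf": 2887.0,
    "econ.cost_pre_cvd": 3430.0,
    "econ.cost_pre_ncd": 3390.0,
    "econ.discount_rate_annual": 0.03,
}


def test_bundled_taiwan_values_exact(setting):
    for path, value in TAIWAN_TABLE.items():
        assert get_param(setting, path) == value, path
    assert setting.wtp_1x == 25000 and setting.wtp_3x == 75000
    assert setting.intervention.name == "empagliflozin"


def test_bundled_taiwan_back_converts_to_valid_trial_proportions(setting):
    """Monthly probabilities imply 16-month event proportions inside (0, 1)."""
    for arm in setting.arms:
        for p in (arm.p_hhf, arm.p_cvd, arm.p_ncd):
            prop = monthly_prob_to_proportion(p, 16)
            assert 0.0 <= prop < 1.0


def test_save_load_round_trip(tmp_path, setting, distributions, settings):
    path = tmp_path / "roundtrip.yaml"
    save_setting(path, setting, distributions=distributions, settings=settings)
    loaded, dists, loaded_settings = load_config(path)
    assert loaded == setting
    assert loaded_settings == settings
    assert set(dists) == set(distributions)
    for key in dists:
        assert dists[key] == distributions[key]


def test_load_rejects_invalid_probability(tmp_path, setting):
    path = tmp_path / "bad.yaml"
    save_setting(path, setting)
    text = path.read_text().replace("0.006589325", "1.2")
    path.write_text(text)
    with pytest.raises(ConfigError, match="p_cvd"):
        load_setting(path)


def test_load_rejects_unknown_key(tmp_path, setting):
    path = tmp_path / "unknown.yaml"
    save_setting(path, setting)
    path.write_text(path.read_text() + "\nextra_section: 1\n")
    with pytest.raises(ConfigError, match="extra_section"):
        load_setting(path)


def test_load_rejects_missing_key(tmp_path, setting):
    path = tmp_path / "missing.yaml"
    save_setting(path, setting)
    path.write_text(path.read_text().replace("cost_hhf:", "cost_hhf_x:"))
    with pytest.raises(ConfigError):
        load_setting(path)


def test_setting_csv_export_lists_every_parameter(setting):
    csv = setting_to_csv(setting)
    for path in parameter_paths(setting):
        assert path in csv


def test_set_param_is_pure(setting):
    new = set_param(setting, "econ.cost_hhf", 1000.0)
    assert get_param(setting, "econ.cost_hhf") == 2887.0
    assert get_param(new, "econ.cost_hhf") == 1000.0


def test_set_param_unknown_path(setting):
    with pytest.raises(KeyError):
        set_param(setting, "econ.nonexistent", 1.0)


def test_arm_invariants_enforced():
    with pytest.raises(ConfigError):
        ArmParameters("x", p_hhf=0.01, p_cvd=0.6, p_ncd=0.5, drug_cost=0.0).validate()
    with pytest.raises(ConfigError):
        ArmParameters("x", p_hhf=-0.01, p_cvd=0.0, p_ncd=0.0, drug_cost=0.0).validate()


def test_parameter_distribution_validates_at_setup():
    with pytest.raises(ConfigError):
        ParameterDistribution("beta", mean=0.5, se=0.6)  # infeasible moments
    with pytest.raises(ConfigError):
        ParameterDistribution("weird", mean=0.5, se=0.1)
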