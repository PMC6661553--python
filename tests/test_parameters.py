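"""Distribution fitting and parameter sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ohca_cea.parameters import (
    CI_WIDTH_SD,
    ParameterError,
    ParameterSet,
    ParameterSpec,
    ci_sd,
    default_specs,
    fit_beta,
    fit_gamma,
    load_specs,
    point_estimates,
    sample_parameters,
)

REGISTRY_NAMES = {
    "cost_prehospital_als",
    "cost_prehospital_ccm_addon",
    "p_survival_hospital_als",
    "cost_ed",
    "p_icu_admission",
    "cost_icu_daily_survivor",
    "los_icu_survivor",
    "cost_icu_daily_death",
    "los_icu_death",
    "cost_nonicu_survivor",
    "cost_nonicu_death",
    "p_survival_discharge_als",
    "p_cpc12",
    "p_5yr_cpc12",
    "p_5yr_cpc34",
    "py_death_cpc12",
    "py_death_cpc34",
    "utility_cpc12",
    "utility_cpc34",
    "annual_cost_cpc12",
    "annual_cost_cpc34",
    "discount_rate",
}


@pytest.mark.parametrize(
    "mean, lo, hi, expected",
    [
        (377.0, 355.0, 399.0, (1128.1049, 0.334189)),
        (1745.0, 1654.0, 1836.0, (1412.6033, 1.235308)),
    ],
)
def test_fit_gamma_moment_matching(mean, lo, hi, expected):
    """Fitted gamma recovers the input mean and the CI-implied sd exactly."""
    shape, scale = fit_gamma(mean, lo, hi)
    assert shape == pytest.approx(expected[0], rel=1e-6)
    assert scale == pytest.approx(expected[1], rel=1e-6)
    assert shape * scale == pytest.approx(mean, rel=1e-12)
    assert math.sqrt(shape) * scale == pytest.approx((hi - lo) / CI_WIDTH_SD, rel=1e-12)


@given(
    mean=st.floats(1.0, 1e5),
    sd=st.floats(0.01, 100.0),
)
@settings(max_examples=100, derandomize=True)
def test_fit_gamma_inverts_ci_construction(mean, sd):
    """A CI built as mean +/- 1.96 sd fits back to exactly that sd."""
    shape, scale = fit_gamma(mean, mean - 1.96 * sd, mean + 1.96 * sd)
    assert math.sqrt(shape) * scale == pytest.approx(sd, rel=1e-9)


@pytest.mark.parametrize(
    "mean, lo, hi, expected",
    [
        (0.26, 0.25, 0.27, (1921.462, 5468.776)),
        (0.65, 0.58, 0.71, (133.806, 72.0494)),
    ],
)
def test_fit_beta_moment_matching(mean, lo, hi, expected):
    alpha, beta = fit_beta(mean, lo, hi)
    assert alpha == pytest.approx(expected[0], rel=1e-5)
    assert beta == pytest.approx(expected[1], rel=1e-5)
    assert alpha / (alpha + beta) == pytest.approx(mean, rel=1e-12)
    var = alpha * beta / ((alpha + beta) ** 2 * (alpha + beta + 1))
    assert math.sqrt(var) == pytest.approx(ci_sd(lo, hi), rel=1e-12)


def test_fit_beta_symmetric_mean_gives_equal_shapes():
    alpha, beta = fit_beta(0.5, 0.5 - 1.96 * 0.1, 0.5 + 1.96 * 0.1)
    assert alpha == pytest.approx(beta, rel=1e-12)


@pytest.mark.parametrize(
    "fit, args",
    [
        (fit_gamma, (-1.0, -2.0, 3.0)),
        (fit_gamma, (10.0, 12.0, 8.0)),
        (fit_beta, (0.5, 0.6, 0.9)),
        (fit_beta, (0.001, 0.0005, 0.15)),  # variance >= mean(1-mean)
    ],
)
def test_fit_rejects_invalid_moments(fit, args):
    with pytest.raises(ParameterError):
        fit(*args)


def test_registry_moment_recovery(specs):
    """Every registry distribution reproduces its printed mean and CI-implied sd."""
    checked = 0
    for spec in specs:
        if spec.family == "fixed":
            continue
        if spec.family == "gamma":
            shape, scale = spec.fitted()
            mean, sd = shape * scale, math.sqrt(shape) * scale
        else:
            alpha, beta = spec.fitted()
            mean = alpha / (alpha + beta)
            sd = math.sqrt(alpha * beta / ((alpha + beta) ** 2 * (alpha + beta + 1)))
        assert mean == pytest.approx(spec.mean, rel=1e-9), spec.name
        assert sd == pytest.approx(spec.sd, rel=1e-9), spec.name
        checked += 1
    assert checked > 0


def test_default_registry_names(specs):
    assert {s.name for s in specs} == REGISTRY_NAMES


def test_point_estimates_match_printed_means(specs):
    pt = point_estimates(specs)
    assert pt["p_survival_discharge_als"] == 0.09
    assert pt["utility_cpc34"] == 0.47
    assert pt["cost_prehospital_ccm_addon"] == 1711.0
    assert point_estimates([]) == ParameterSet({})


def test_sampling_is_deterministic(specs):
    a = sample_parameters(specs, 42)
    b = sample_parameters(specs, 42)
    assert dict(a) == dict(b)
    c = sample_parameters(specs, 43)
    assert dict(a) != dict(c)


def test_fixed_parameters_pass_through(specs):
    fixed = [
        ParameterSpec(name=s.name, mean=s.mean, family="fixed") for s in specs
    ]
    drawn = sample_parameters(fixed, 0)
    assert dict(drawn) == dict(point_estimates(specs))


def test_sampling_respects_support(specs):
    """No negative cost, no probability outside [0, 1], across 1e5 draws."""
    rng = np.random.default_rng(7)
    for spec in specs:
        if spec.family == "gamma":
            shape, scale = spec.fitted()
            draws = rng.gamma(shape, scale, size=100_000)
            assert np.all(draws >= 0.0), spec.name
        elif spec.family == "beta":
            alpha, beta = spec.fitted()
            draws = rng.beta(alpha, beta, size=100_000)
            assert np.all((draws >= 0.0) & (draws <= 1.0)), spec.name


def test_sample_mean_converges_to_fitted_mean(specs):
    spec = next(s for s in specs if s.name == "p_survival_hospital_als")
    rng = np.random.default_rng(11)
    draws = np.array([spec.sample(rng) for _ in range(10_000)])
    se = spec.sd / math.sqrt(draws.size)
    assert abs(draws.mean() - spec.mean) < 3 * se


def test_parameter_set_validation(specs):
    pt = point_estimates(specs)
    pt.validate_against(specs)  # complete set passes
    with pytest.raises(ParameterError):
        ParameterSet({"p_icu_admission": 0.5}).validate_against(specs)
    bad = pt.replace(p_icu_admission=1.5)
    with pytest.raises(ParameterError):
        bad.validate_against(specs)
    with pytest.raises(ParameterError):
        pt.replace(nonexistent=1.0)


def test_spec_rejects_fixed_with_ci():
    with pytest.raises(ParameterError):
        ParameterSpec(name="x", mean=1.0, ci_low=0.5, ci_high=1.5, family="fixed")
    with pytest.raises(ParameterError):
        ParameterSpec(name="x", mean=1.0, family="gamma")


def test_registry_yaml_round_trip(tmp_path, specs):
    """A user-supplied registry file loads to the same specs as the built-in."""
    import yaml

    entries = []
    for s in specs:
        e = {"name": s.name, "mean": s.mean, "family": s.family}
        if s.ci_low is not None:
            e["ci"] = [s.ci_low, s.ci_high]
        entries.append(e)
    path = tmp_path / "params.yaml"
    path.write_text(yaml.safe_dump({"parameters": entries}))
    assert load_specs(path) == default_specs()
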