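"""Health expectancies, initial distributions and life-table invariants."""

import numpy as np
import pytest

from mstlife.cohort import CovariateVector, SubjectHistory
from mstlife.lifetable import (
    annual_probability,
    empirical_initial_distribution,
    life_table,
    state_expectancies,
)
from mstlife.likelihood import transition_probability
from mstlife.model import IntensityModel, ModelSpec, spec_for

COV = CovariateVector(age_at_entry=70.0, sex="male", region="urban")


def death_only_model(rate):
    spec = ModelSpec(transitions=((0, 3),), covariate_effects={})
    return IntensityModel(spec, np.array([np.log(rate)]))


def random_model(rng):
    """Random full-structure model with mild age slopes."""
    spec = spec_for("full", covariates=("age",))
    params = np.concatenate([
        rng.uniform(np.log(0.02), np.log(0.4), size=9),
        rng.uniform(-0.03, 0.08, size=9),
    ])
    return IntensityModel(spec, params)


def test_exponential_expectancy_closed_forms():
    """Constant mortality 0.1/yr: TLE = 1/mu (open horizon) and
    (1 - e^{-mu*A})/mu when truncated at A = 30 years."""
    m = death_only_model(0.1)
    e_open = state_expectancies(m, 0, 0, 65.0, max_age=265.0, grid_step=0.25)
    assert e_open[0].sum() == pytest.approx(10.0, abs=1e-3)
    with pytest.warns(UserWarning, match="truncated"):
        e_30 = state_expectancies(m, 0, 0, 65.0, max_age=95.0, grid_step=0.25)
    assert e_30[0].sum() == pytest.approx((1 - np.exp(-3.0)) / 0.1, abs=1e-3)


def test_annual_probability_definitional(true_model):
    P1 = annual_probability(true_model, 1.0, 0.0, 72.0)
    P2 = transition_probability(true_model, 1.0, 0.0, 72.0, 73.0)
    np.testing.assert_allclose(P1, P2, atol=1e-12)


def test_annual_probability_identity_for_frozen_chain():
    spec = ModelSpec(transitions=((0, 1),), covariate_effects={})
    m = IntensityModel(spec, np.array([-80.0]))
    P = annual_probability(m, 0, 0, 70.0)
    np.testing.assert_allclose(P, np.eye(4), atol=1e-30)


def test_annual_probability_caps_at_max_age(true_model):
    with pytest.warns(UserWarning, match="capping"):
        P = annual_probability(true_model, 0.0, 0.0, 114.6, max_age=115.0)
    np.testing.assert_allclose(
        P, transition_probability(true_model, 0.0, 0.0, 114.6, 115.0), atol=1e-12
    )


def test_empirical_initial_distribution_examples():
    def subj(i, state, sex="male", region="urban", age=65.0):
        cov = CovariateVector(age_at_entry=age, sex=sex, region=region)
        return SubjectHistory(f"s{i}", [age, age + 3], [state, state], cov)

    cohort = [subj(i, 0) for i in range(4)] + [subj(10 + i, 1) for i in range(2)]
    pi = empirical_initial_distribution(cohort, "male", "urban", 65.0)
    np.testing.assert_allclose(pi, [4 / 6, 2 / 6, 0.0])
    # invariant to duplicating every subject
    dup = cohort + [SubjectHistory(f"d{s.id}", s.obs_ages, s.obs_states,
                                   s.covariates, s.death_age) for s in cohort]
    np.testing.assert_allclose(
        empirical_initial_distribution(dup, "male", "urban", 65.0), pi)
    with pytest.raises(ValueError, match="window"):
        empirical_initial_distribution(cohort, "female", "rural", 65.0)


def test_entry_state_proportions_printed_counts():
    """Relative baseline frequencies from printed stratum counts."""
    counts = np.array([2145.0, 1064.0, 629.0])
    pi = counts / counts.sum()
    np.testing.assert_allclose(np.round(pi, 3), [0.559, 0.277, 0.164])


def test_zero_disability_intensities_give_pnd_100():
    """With no disability transitions and some mortality, all remaining life
    is disability-free."""
    spec = ModelSpec(transitions=((0, 3), (1, 3), (2, 3)), covariate_effects={})
    m = IntensityModel(spec, np.log([0.08, 0.08, 0.08]))
    e = state_expectancies(m, 0, 0, 65.0)
    assert e[0, 1] == 0.0 and e[0, 2] == 0.0
    tle = e[0].sum()
    assert 100.0 * e[0, 0] / tle == pytest.approx(100.0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_additivity_and_proportions_random_models(seed):
    rng = np.random.default_rng(seed)
    m = random_model(rng)
    e = state_expectancies(m, rng.integers(0, 2), rng.integers(0, 2), 65.0)
    for r in range(3):
        tle = e[r].sum()
        props = 100.0 * e[r] / tle
        # TLE = ND + MD + SD is exact by construction; proportions close
        assert props.sum() == pytest.approx(100.0, abs=0.1)
        assert np.all(e[r] >= 0.0)


def test_grid_convergence_half_step():
    rng = np.random.default_rng(3)
    m = random_model(rng)
    e1 = state_expectancies(m, 0, 0, 65.0, grid_step=0.25)
    e2 = state_expectancies(m, 0, 0, 65.0, grid_step=0.125)
    rel = np.abs(e1 - e2) / np.maximum(np.abs(e2), 1e-6)
    assert rel[e2 > 0.05].max() < 0.005


def test_scaling_mortality_down_reduces_tle():
    """Uniformly increasing all death intensities strictly decreases TLE."""
    rng = np.random.default_rng(4)
    m = random_model(rng)
    boosted = m.params.copy()
    for i, (r, s) in enumerate(m.spec.transitions):
        if s == 3:
            boosted[i] += np.log(1.5)
    m_hi = IntensityModel(m.spec, boosted)
    e_lo = state_expectancies(m, 0, 0, 65.0)
    e_hi = state_expectancies(m_hi, 0, 0, 65.0)
    assert np.all(e_hi.sum(axis=1) < e_lo.sum(axis=1))


def test_tle_ordering_by_initial_severity():
    """With mortality increasing in severity, a healthier start cannot
    shorten expected life."""
    spec = spec_for("full", covariates=())
    rates = {  # onset/recovery moderate, mortality graded 0.05/0.10/0.25
        (0, 1): 0.10, (0, 2): 0.02, (0, 3): 0.05,
        (1, 0): 0.15, (1, 2): 0.10, (1, 3): 0.10,
        (2, 0): 0.04, (2, 1): 0.10, (2, 3): 0.25,
    }
    m = IntensityModel(spec, np.log([rates[t] for t in spec.transitions]))
    e = state_expectancies(m, 0, 0, 65.0)
    tle = e.sum(axis=1)
    assert tle[0] >= tle[1] >= tle[2]


def test_life_table_pipeline_with_bootstrap(calib_cohort, calib_model):
    """End-to-end life table over the calibration cohort with a small
    bootstrap: tidy layout, additivity, CI ordering."""
    from mstlife.fit import fit_mle

    subjects, _ = calib_cohort
    fit = fit_mle(subjects, calib_model.spec, compute_cov=False)
    table = life_table(fit, subjects, strata=[("male", "urban")],
                       index_ages=[65.0, 85.0], bootstrap_B=5, seed=4)
    assert set(table["quantity"]) == {"TLE", "ND", "MD", "SD", "AD",
                                      "PND", "PMD", "PSD", "PAD"}
    for (init, age), grp in table.groupby(["initial_state", "index_age"]):
        get = lambda q: grp[grp.quantity == q]["estimate"].iloc[0]
        assert get("TLE") == pytest.approx(get("ND") + get("MD") + get("SD"), abs=1e-6)
        assert get("AD") == pytest.approx(get("MD") + get("SD"), abs=1e-9)
        assert get("PND") + get("PMD") + get("PSD") == pytest.approx(100.0, abs=1e-6)
    tle = table[table.quantity == "TLE"]
    assert (tle["lo"] <= tle["hi"]).all()
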