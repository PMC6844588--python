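"""Transition probabilities and the interval-censored panel likelihood."""

import numpy as np
import pytest
from scipy.linalg import expm as scipy_expm

from mstlife.cohort import CovariateVector, SubjectHistory
from mstlife.likelihood import (
    LikelihoodPlan,
    expm_batch,
    grid_segments,
    subject_loglik,
    transition_probability,
)
from mstlife.model import IntensityModel, ModelSpec, spec_for

COV = CovariateVector(age_at_entry=70.0, sex="male", region="urban")


def death_only_model(rate):
    spec = ModelSpec(transitions=((0, 3),), covariate_effects={})
    return IntensityModel(spec, np.array([np.log(rate)]))


def random_constant_model(rng):
    # modest rates: the first-order Euler-product oracle below is accurate
    # to ~ (|Q| t)^2 / 2^17, which needs |Q| t well under 1
    spec = spec_for("full")
    params = np.zeros(spec.n_params)
    params[:9] = rng.uniform(np.log(0.005), np.log(0.04), size=9)
    return IntensityModel(spec, params)


def test_expm_batch_matches_scipy():
    rng = np.random.default_rng(5)
    A = rng.normal(scale=1.5, size=(40, 4, 4))
    expected = np.stack([scipy_expm(a) for a in A])
    np.testing.assert_allclose(expm_batch(A), expected, atol=1e-12)


def test_grid_segments_partition():
    mids, widths = grid_segments(65.2, 68.7, 0.5)
    assert widths.sum() == pytest.approx(3.5)
    assert np.all(widths <= 0.5 + 1e-12)
    # interior segments sit on global cell midpoints, shareable across subjects
    np.testing.assert_allclose(mids[1:-1] % 0.5, 0.25)
    assert grid_segments(65.0, 65.0, 0.5)[0].size == 0


def test_zero_elapsed_time_is_identity(true_model):
    P = transition_probability(true_model, 1.0, 0.0, 70.0, 70.0)
    np.testing.assert_array_equal(P, np.eye(4))


def test_two_state_closed_form():
    """Alive -> dead at rate 0.5/yr over one year: P(alive, alive) = e^-0.5."""
    m = death_only_model(0.5)
    P = transition_probability(m, 0.0, 0.0, 70.0, 71.0)
    assert P[0, 0] == pytest.approx(np.exp(-0.5), abs=1e-12)
    assert P[0, 3] == pytest.approx(1 - np.exp(-0.5), abs=1e-12)
    assert P[3, 3] == 1.0


def test_discretized_chain_oracle():
    """P(t) for constant Q equals the discretized chain (I + Qt/2^16)^(2^16)."""
    rng = np.random.default_rng(11)
    m = random_constant_model(rng)
    t = 2.0
    Q = m.q_matrices([70.0], [0.0], [0.0])[0]
    step = np.eye(4) + Q * t / 2 ** 16
    chain = step
    for _ in range(16):
        chain = chain @ chain
    P = transition_probability(m, 0.0, 0.0, 70.0, 70.0 + t)
    np.testing.assert_allclose(P, chain, atol=1e-6)


def test_transition_matrices_are_stochastic(true_model):
    rng = np.random.default_rng(3)
    for _ in range(20):
        a1 = rng.uniform(65.0, 95.0)
        a2 = a1 + rng.uniform(0.0, 8.0)
        P = transition_probability(true_model, 1.0, 1.0, a1, a2)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(P >= -1e-12) and np.all(P <= 1 + 1e-12)


def test_frozen_chain_contributes_zero():
    """Two same-state observations under Q = 0: log-likelihood log(1) = 0."""
    spec = ModelSpec(transitions=((0, 1),), covariate_effects={})
    m = IntensityModel(spec, np.array([-60.0]))  # rate ~ 0
    subj = SubjectHistory("a", [70.0, 73.0], [0, 0], COV)
    assert subject_loglik(m, subj) == pytest.approx(0.0, abs=1e-20)


def test_exact_death_closed_form():
    """Observation alive then dated death under a pure death model: the
    contribution is the exponential density log(e^{-lam*(d-a)} * lam)."""
    lam, a, d = 0.3, 70.0, 74.2
    m = death_only_model(lam)
    subj = SubjectHistory("a", [a], [0], COV, death_age=d)
    expected = -lam * (d - a) + np.log(lam)
    assert subject_loglik(m, subj) == pytest.approx(expected, abs=1e-10)


def test_structurally_impossible_path_gives_minus_inf(caplog):
    """Observed transition with no connecting arrows yields -inf and a
    diagnostic naming the state pair."""
    spec = ModelSpec(transitions=((1, 0),), covariate_effects={})
    m = IntensityModel(spec, np.array([np.log(0.1)]))
    subj = SubjectHistory("odd", [70.0, 73.0], [0, 1], COV)
    with caplog.at_level("WARNING"):
        ll = subject_loglik(m, subj)
    assert ll == -np.inf
    assert "0 -> 1" in caplog.text


def test_total_loglik_invariant_to_subject_order(calib_cohort, calib_model):
    subjects, _ = calib_cohort
    subjects = subjects[:200]
    spec = calib_model.spec
    plan = LikelihoodPlan.build(subjects, spec)
    ll = plan.per_subject_loglik(calib_model)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(subjects))
    plan2 = LikelihoodPlan.build([subjects[i] for i in perm], spec)
    ll2 = plan2.per_subject_loglik(calib_model)
    # identical per-subject contributions regardless of cohort order
    np.testing.assert_array_equal(ll[perm], ll2)


def test_monte_carlo_path_probability_smoke(true_model):
    """exp(subject log-likelihood) matches the simulated frequency of the
    observed coarse data (moderate n here; the full-scale check runs in the
    acceptance suite)."""
    from mstlife.simulate import simulate_states

    cov = CovariateVector(age_at_entry=70.0, sex="female", region="rural")
    subj = SubjectHistory("t", [70.0, 73.0], [0, 1], cov)
    ll = subject_loglik(true_model, subj, step=0.1)
    snaps, _, _ = simulate_states(true_model, 1.0, 1.0, 70.0, 0, [73.0], 100_000,
                                  np.random.default_rng(7))
    freq = (snaps[:, 0] == 1).mean()
    se = np.sqrt(freq * (1 - freq) / 100_000)
    assert np.exp(ll) == pytest.approx(freq, abs=3 * se)
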