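import numpy as np
import pytest

from mstlife.cohort import CovariateVector, SubjectHistory
from mstlife.model import IntensityModel, ModelSpec
from mstlife.simulate import (
    SimulationScenario,
    calibration_scenario,
    calibration_true_model,
    default_true_model,
    generate,
)


@pytest.fixture(scope="session")
def true_model():
    """Default age-dependent 9-transition ground truth."""
    return default_true_model()


@pytest.fixture(scope="session")
def calib_model():
    """Age-homogeneous no-jump truth of the designed recovery experiment."""
    return calibration_true_model()


@pytest.fixture(scope="session")
def small_cohort():
    """A reusable simulated cohort (n=500) with item-level missingness."""
    scenario = SimulationScenario(
        n=500,
        missing_rates={k: 0.05 for k in (
            "marital", "education", "expenses", "service", "smoking",
            "drinking", "exercise", "diabetes", "heart_disease", "stroke",
        )},
    )
    subjects, truth = generate(scenario, seed=20240901)
    return subjects, truth


@pytest.fixture(scope="session")
def calib_cohort():
    """A reusable cohort from the calibration scenario (n=600)."""
    subjects, truth = generate(calibration_scenario(n=600), seed=20240902)
    return subjects, truth


def make_survival_cohort(rate: float, n: int, seed: int, wave_gap: float = 3.0):
    """Alive/dead toy: exact deaths at exponential times, right censoring at
    one follow-up wave.  Closed-form MLE for the death rate is
    deaths / person-time."""
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n):
        entry = rng.uniform(66.0, 90.0)
        t_death = rng.exponential(1.0 / rate)
        cov = CovariateVector(age_at_entry=entry, sex="male", region="urban")
        if t_death < wave_gap:
            subj = SubjectHistory(f"d{i:04d}", [entry], [0], cov,
                                  death_age=entry + t_death)
        else:
            subj = SubjectHistory(f"d{i:04d}", [entry, entry + wave_gap], [0, 0], cov)
        subjects.append(subj)
    return subjects


@pytest.fixture()
def survival_spec():
    """Single-parameter alive -> dead model specification."""
    return ModelSpec(transitions=((0, 3),), covariate_effects={})


def survival_closed_form_mle(subjects):
    deaths = sum(1 for s in subjects if s.death_age is not None)
    pt = sum(
        (s.death_age - s.obs_ages[0]) if s.death_age is not None
        else (s.obs_ages[-1] - s.obs_ages[0])
        for s in subjects
    )
    return deaths / pt
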