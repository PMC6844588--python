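"""Continuous-time Markov intensity model with proportional covariate effects.

Each allowed transition r -> s has intensity

    q_rs(age, z) = exp( log_baseline_rs + beta_rs . x(age, z) )

where x collects the model covariates: age (continuous, centered at 65, or
two age-band indicators 75-84 / 85-95), female sex, and rural region.  The
reference profile is an urban man aged 65, so each baseline is the log rate
per person-year for that profile.  Rows of the intensity matrix Q sum to
zero and the death row is identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .cohort import CovariateVector
from .states import DEATH, LIVING_STATES, N_STATES

Transition = Tuple[int, int]

#: All six transitions among living states plus the three living->death arrows.
TRANSITIONS_FULL: Tuple[Transition, ...] = (
    (0, 1), (0, 2), (0, 3),
    (1, 0), (1, 2), (1, 3),
    (2, 0), (2, 1), (2, 3),
)
#: Variant forbidding direct jumps between no disability and severe disability.
TRANSITIONS_NO_JUMP: Tuple[Transition, ...] = (
    (0, 1), (0, 3),
    (1, 0), (1, 2), (1, 3),
    (2, 1), (2, 3),
)

STRUCTURES: Dict[str, Tuple[Transition, ...]] = {
    "full": TRANSITIONS_FULL,
    "no-jump": TRANSITIONS_NO_JUMP,
}

AGE_CENTER = 65.0
COVARIATES_LOGLINEAR: Tuple[str, ...] = ("age", "female", "rural")
COVARIATES_BANDS: Tuple[str, ...] = ("age_75_84", "age_85_95", "female", "rural")


class MissingCovariateError(ValueError):
    """A model covariate is missing for a subject; impute before fitting."""


def _validate_transitions(transitions: Sequence[Transition]) -> None:
    for r, s in transitions:
        if r == s:
            raise ValueError(f"self-transition ({r},{s}) not allowed")
        if r == DEATH:
            raise ValueError("death is absorbing: no outgoing transitions allowed")
        if r not in LIVING_STATES or s not in range(N_STATES):
            raise ValueError(f"transition ({r},{s}) outside the 4-state space")


@dataclass(frozen=True)
class ModelSpec:
    """Transition structure plus the covariates acting on each transition.

    ``covariate_effects`` maps a transition to the tuple of covariate names
    with a free log-effect on it; transitions absent from the mapping get no
    covariate effects.  ``age_form`` selects continuous log-linear age
    (``"loglinear"``) or the 65-74 / 75-84 / 85-95 band parameterization
    (``"bands"``).
    """

    transitions: Tuple[Transition, ...] = TRANSITIONS_FULL
    covariate_effects: Dict[Transition, Tuple[str, ...]] = field(default_factory=dict)
    age_form: str = "loglinear"

    def __post_init__(self) -> None:
        _validate_transitions(self.transitions)
        if self.age_form not in ("loglinear", "bands"):
            raise ValueError(f"unknown age_form {self.age_form!r}")
        valid = set(self.covariate_names)
        for trans, covs in self.covariate_effects.items():
            if trans not in self.transitions:
                raise ValueError(f"covariate effect on disallowed transition {trans}")
            for c in covs:
                if c not in valid:
                    raise ValueError(f"unknown covariate {c!r} for age_form {self.age_form!r}")

    @property
    def covariate_names(self) -> Tuple[str, ...]:
        return COVARIATES_LOGLINEAR if self.age_form == "loglinear" else COVARIATES_BANDS

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    @property
    def param_names(self) -> List[str]:
        names = [f"logq_{r}{s}" for r, s in self.transitions]
        for trans in self.transitions:
            for cov in self.covariate_effects.get(trans, ()):
                names.append(f"beta_{trans[0]}{trans[1]}:{cov}")
        return names

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def with_all_covariates(self) -> "ModelSpec":
        """Same structure, with every covariate acting on every transition."""
        effects = {t: self.covariate_names for t in self.transitions}
        return ModelSpec(self.transitions, effects, self.age_form)


def spec_for(structure: str = "full", age_form: str = "loglinear",
             covariates: Optional[Iterable[str]] = None) -> ModelSpec:
    """Convenience constructor: named structure with a shared covariate set."""
    transitions = STRUCTURES[structure]
    base = ModelSpec(transitions=transitions, age_form=age_form)
    covs = tuple(covariates) if covariates is not None else base.covariate_names
    effects = {t: covs for t in transitions}
    return ModelSpec(transitions=transitions, covariate_effects=effects, age_form=age_form)


def design_matrix(spec: ModelSpec, ages: np.ndarray, female: np.ndarray,
                  rural: np.ndarray) -> np.ndarray:
    """(n, n_covariates) design for the model's covariate names."""
    ages = np.asarray(ages, dtype=float)
    female = np.asarray(female, dtype=float)
    rural = np.asarray(rural, dtype=float)
    if spec.age_form == "loglinear":
        cols = [ages - AGE_CENTER, female, rural]
    else:
        cols = [
            ((ages >= 75.0) & (ages < 85.0)).astype(float),
            (ages >= 85.0).astype(float),
            female,
            rural,
        ]
    return np.column_stack(cols)


@dataclass
class IntensityModel:
    """A :class:`ModelSpec` with concrete parameter values."""

    spec: ModelSpec
    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.shape != (self.spec.n_params,):
            raise ValueError(
                f"expected {self.spec.n_params} parameters "
                f"({self.spec.param_names}), got shape {self.params.shape}"
            )
        if not np.all(np.isfinite(self.params)):
            raise ValueError("all log-baselines and effects must be finite")

    @classmethod
    def from_dict(cls, spec: ModelSpec, values: Dict[str, float]) -> "IntensityModel":
        missing = [n for n in spec.param_names if n not in values]
        if missing:
            raise ValueError(f"missing parameter values for {missing}")
        return cls(spec, np.array([values[n] for n in spec.param_names], dtype=float))

    def asdict(self) -> Dict[str, float]:
        return dict(zip(self.spec.param_names, self.params.tolist()))

    @property
    def log_baselines(self) -> np.ndarray:
        return self.params[: self.spec.n_transitions]

    def beta_matrix(self) -> np.ndarray:
        """(n_covariates, n_transitions) dense effect matrix, zeros where a
        covariate does not act on a transition."""
        spec = self.spec
        covs = spec.covariate_names
        B = np.zeros((len(covs), spec.n_transitions))
        idx = spec.n_transitions
        for j, trans in enumerate(spec.transitions):
            for cov in spec.covariate_effects.get(trans, ()):
                B[covs.index(cov), j] = self.params[idx]
                idx += 1
        return B

    def rates(self, ages, female, rural) -> np.ndarray:
        """Transition rates, shape (n, n_transitions), for vector inputs."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        female = np.broadcast_to(np.atleast_1d(np.asarray(female, dtype=float)), ages.shape)
        rural = np.broadcast_to(np.atleast_1d(np.asarray(rural, dtype=float)), ages.shape)
        X = design_matrix(self.spec, ages, female, rural)
        return np.exp(self.log_baselines[None, :] + X @ self.beta_matrix())

    def q_matrices(self, ages, female, rural) -> np.ndarray:
        """Stack of intensity matrices Q, shape (n, 4, 4)."""
        rates = self.rates(ages, female, rural)
        n = rates.shape[0]
        Q = np.zeros((n, N_STATES, N_STATES))
        for j, (r, s) in enumerate(self.spec.transitions):
            Q[:, r, s] = rates[:, j]
        diag = -Q.sum(axis=2)
        Q[:, np.arange(N_STATES), np.arange(N_STATES)] = diag
        return Q


def _profile_indicators(covariates: CovariateVector) -> Tuple[float, float]:
    if covariates.sex is None:
        raise MissingCovariateError(
            "sex is missing for this subject; impute covariates before building Q"
        )
    if covariates.region is None:
        raise MissingCovariateError(
            "region is missing for this subject; impute covariates before building Q"
        )
    return float(covariates.sex == "female"), float(covariates.region == "rural")


def build_Q(model: IntensityModel, covariates: CovariateVector, age: float) -> np.ndarray:
    """Intensity matrix at one covariate profile and age.

    Off-diagonals are the proportional-hazards rates for allowed transitions,
    the diagonal is minus the row sum, the death row is zero.
    """
    if not np.isfinite(age):
        raise ValueError(f"age must be finite, got {age}")
    female, rural = _profile_indicators(covariates)
    return model.q_matrices([age], [female], [rural])[0]
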