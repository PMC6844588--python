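"""Maximum-likelihood fitting of the panel multistate model, with
observed-information covariance and subject-level bootstrap resampling."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
from scipy import optimize

from .cohort import SubjectHistory
from .likelihood import DEFAULT_STEP, LikelihoodPlan
from .model import IntensityModel, ModelSpec
from .states import DEATH

logger = logging.getLogger(__name__)

RATE_FLOOR = 1e-4  # crude-rate initialization floor, per person-year


def crude_rates(subjects: Sequence[SubjectHistory], spec: ModelSpec) -> Dict[tuple, float]:
    """Crude interval transition rates: counts / person-time at risk.

    Living-state transitions count consecutive wave pairs (state r then
    state s); exact deaths are attributed to the last observed living state.
    Person-time in state r sums the interval lengths that start in r.
    Rates are floored at :data:`RATE_FLOOR` so log-initialization is finite.
    """
    counts = {t: 0.0 for t in spec.transitions}
    person_time = {r: 0.0 for r in range(3)}
    for subj in subjects:
        ages, states = subj.obs_ages, subj.obs_states
        for k in range(len(ages) - 1):
            r, s = int(states[k]), int(states[k + 1])
            person_time[r] += ages[k + 1] - ages[k]
            if r != s and (r, s) in counts:
                counts[(r, s)] += 1
        if subj.death_age is not None:
            r = int(states[-1])
            person_time[r] += subj.death_age - ages[-1]
            if (r, DEATH) in counts:
                counts[(r, DEATH)] += 1
    rates = {}
    for (r, s), c in counts.items():
        pt = person_time[r]
        rates[(r, s)] = max(c / pt if pt > 0 else 0.0, RATE_FLOOR)
        if c == 0:
            logger.warning(
                "no observed %d -> %d transitions: parameters for this arrow are "
                "weakly identified", r, s,
            )
    return rates


def initial_params(subjects: Sequence[SubjectHistory], spec: ModelSpec) -> np.ndarray:
    """Crude-rate log baselines, zero covariate effects."""
    rates = crude_rates(subjects, spec)
    x0 = np.zeros(spec.n_params)
    x0[: spec.n_transitions] = [np.log(rates[t]) for t in spec.transitions]
    return x0


@dataclass
class FittedModel:
    """MLE result: point estimates, likelihood, covariance and diagnostics."""

    model: IntensityModel
    loglik: float
    loglik_at_init: float
    converged: bool
    n_iter: int
    n_evals: int
    grad_norm: float
    message: str
    step: float
    init_params: np.ndarray
    nll_trace: List[float] = field(default_factory=list)
    cov: Optional[np.ndarray] = None
    cov_note: str = ""
    seed: Optional[int] = None
    optimizer: str = "L-BFGS-B"

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def params(self) -> np.ndarray:
        return self.model.params

    @property
    def param_names(self) -> List[str]:
        return self.model.spec.param_names

    def stderr(self) -> np.ndarray:
        if self.cov is None:
            raise ValueError("covariance was not computed for this fit")
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, np.inf))

    def wald_ci(self, level: float = 0.95) -> np.ndarray:
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2.0)
        se = self.stderr()
        return np.column_stack([self.params - z * se, self.params + z * se])

    def to_json(self, path=None) -> str:
        payload = {
            "param_names": self.param_names,
            "params": self.params.tolist(),
            "transitions": [list(t) for t in self.spec.transitions],
            "covariate_effects": {
                f"{r}{s}": list(v) for (r, s), v in self.spec.covariate_effects.items()
            },
            "age_form": self.spec.age_form,
            "loglik": self.loglik,
            "loglik_at_init": self.loglik_at_init,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
            "message": self.message,
            "grid_step": self.step,
            "cov": None if self.cov is None else self.cov.tolist(),
            "cov_note": self.cov_note,
            "seed": self.seed,
            "optimizer": self.optimizer,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _neg_loglik_factory(plan: LikelihoodPlan, spec: ModelSpec):
    def nll(x: np.ndarray) -> float:
        ll = plan.loglik(IntensityModel(spec, x))
        if not np.isfinite(ll):
            return 1e12
        return -ll
    return nll


def fd_hessian(f: Callable[[np.ndarray], float], x: np.ndarray,
               rel_step: float = 3e-4) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    p = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p); ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
    for i in range(p):
        ei = np.zeros(p); ei[i] = h[i]
        for j in range(i + 1, p):
            ej = np.zeros(p); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit_mle(
    subjects: Sequence[SubjectHistory],
    spec: ModelSpec,
    init: Optional[np.ndarray] = None,
    step: float = DEFAULT_STEP,
    compute_cov: bool = True,
    maxiter: int = 500,
    gtol: float = 1e-5,
    seed: Optional[int] = None,
) -> FittedModel:
    """Maximize the interval-censored panel likelihood by L-BFGS-B.

    Subjects are sorted by id before summation (fixed, documented order).
    Starting values default to crude-rate log intensities with zero
    covariate effects.  The parameter covariance is the inverse of the
    finite-difference observed information at the optimum; set
    ``compute_cov=False`` to skip it (e.g. inside bootstrap replicates).

    Non-convergence is flagged on the result, never silently dropped; a
    non-finite likelihood at the starting values raises with a hint to use
    crude-rate initialization.
    """
    subjects = sorted(subjects, key=lambda s: s.id)
    plan = LikelihoodPlan.build(subjects, spec, step=step)
    nll = _neg_loglik_factory(plan, spec)
    x0 = initial_params(subjects, spec) if init is None else np.asarray(init, dtype=float)
    f0 = nll(x0)
    if not np.isfinite(f0) or f0 >= 1e12:
        raise ValueError(
            "log-likelihood is not finite at the starting values; "
            "use crude-rate initialization (init=None) or check the structure"
        )
    trace: List[float] = [f0]
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B",
        callback=lambda xk: trace.append(nll(xk)),
        options={"maxiter": maxiter, "gtol": gtol, "maxcor": 25},
    )
    model = IntensityModel(spec, res.x)
    cov = None
    cov_note = ""
    if compute_cov:
        H = fd_hessian(nll, res.x)
        try:
            cov = np.linalg.inv(H)
            if np.any(np.diag(cov) < 0):
                cov_note = "observed information not positive definite; variances clipped"
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
            cov_note = "observed information singular; pseudo-inverse used"
    fitted = FittedModel(
        model=model,
        loglik=-float(res.fun),
        loglik_at_init=-float(f0),
        converged=bool(res.success),
        n_iter=int(res.nit),
        n_evals=int(res.nfev),
        grad_norm=float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan,
        message=str(res.message),
        step=step,
        init_params=x0,
        nll_trace=trace,
        cov=cov,
        cov_note=cov_note,
        seed=seed,
    )
    if not fitted.converged:
        logger.warning("fit did not converge: %s", fitted.message)
    return fitted


@dataclass
class BootstrapResult:
    """Percentile bootstrap CI for a statistic of the fitted model."""

    lo: np.ndarray
    hi: np.ndarray
    replicates: np.ndarray     # (n_success, k)
    B: int
    seed: Optional[int]
    n_failures: int
    failure_rate: float
    unreliable: bool
    substream_ids: List[int]

    @property
    def ci(self) -> np.ndarray:
        return np.column_stack([self.lo, self.hi])


def bootstrap(
    subjects: Sequence[SubjectHistory],
    spec: ModelSpec,
    statistic: Callable[[FittedModel], np.ndarray],
    B: int = 499,
    seed: Optional[int] = None,
    step: float = DEFAULT_STEP,
    init: Optional[np.ndarray] = None,
    maxiter: int = 500,
    failure_threshold: float = 0.2,
    statistic_takes_data: bool = False,
) -> BootstrapResult:
    """Percentile 95% CI by resampling subjects (not rows) with replacement.

    Each of the ``B`` replicates (default 499) draws n subjects with
    replacement, refits the model and evaluates ``statistic`` on the refit.
    Replicates that raise or fail to converge are recorded; a failure rate
    above ``failure_threshold`` flags the interval as unreliable.  Randomness
    comes from per-replicate substreams spawned from ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    n = len(subjects)
    subjects = sorted(subjects, key=lambda s: s.id)
    if init is None:
        base = fit_mle(subjects, spec, step=step, compute_cov=False, maxiter=maxiter)
        init = base.params
    streams = np.random.SeedSequence(seed).spawn(B)
    values: List[np.ndarray] = []
    n_failures = 0
    for b, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        idx = rng.integers(0, n, size=n)
        resample = [subjects[i] for i in idx]
        try:
            refit = fit_mle(resample, spec, init=init, step=step,
                            compute_cov=False, maxiter=maxiter)
            if not refit.converged:
                raise RuntimeError("replicate did not converge")
            stat = statistic(refit, resample) if statistic_takes_data else statistic(refit)
            values.append(np.atleast_1d(np.asarray(stat, dtype=float)).ravel())
        except Exception as err:  # noqa: BLE001 - replicate failures are data
            n_failures += 1
            logger.info("bootstrap replicate %d failed: %s", b, err)
    if not values:
        raise RuntimeError("every bootstrap replicate failed")
    reps = np.vstack(values)
    lo, hi = np.percentile(reps, [2.5, 97.5], axis=0)
    failure_rate = n_failures / B
    unreliable = failure_rate > failure_threshold
    if unreliable:
        logger.warning("bootstrap failure rate %.1f%% exceeds %.0f%%: CI unreliable",
                       100 * failure_rate, 100 * failure_threshold)
    return BootstrapResult(
        lo=lo, hi=hi, replicates=reps, B=B, seed=seed,
        n_failures=n_failures, failure_rate=failure_rate, unreliable=unreliable,
        substream_ids=list(range(B)),
    )
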