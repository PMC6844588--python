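"""Annual transition probabilities, multistate life tables and health
expectancies.

Expected remaining years in state s for a person in state r at an index age
a0 are obtained by integrating the transition probabilities over age,

    e_rs = integral_{a0}^{a_max} P_rs(a0, u) du,

evaluated with the trapezoidal rule on an age grid (default 0.25-year step,
default cap 115 years).  Total life expectancy from state r is the sum over
living s.  Population-averaged expectancies weight the per-initial-state
rows by the empirical baseline state distribution of the stratum.
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .cohort import SubjectHistory
from .fit import BootstrapResult, FittedModel, bootstrap
from .likelihood import DEFAULT_STEP, expm_batch, transition_probability
from .model import IntensityModel
from .states import LIVING_STATES, N_STATES

logger = logging.getLogger(__name__)

DEFAULT_MAX_AGE = 115.0
DEFAULT_GRID_STEP = 0.25
DEFAULT_INDEX_AGES = (65.0, 75.0, 85.0, 95.0)

QUANTITIES = ("TLE", "ND", "MD", "SD", "AD", "PND", "PMD", "PSD", "PAD")


def _as_model(fit: Union[FittedModel, IntensityModel]) -> IntensityModel:
    return fit.model if isinstance(fit, FittedModel) else fit


def annual_probability(
    fit: Union[FittedModel, IntensityModel],
    female: float,
    rural: float,
    age: float,
    step: float = DEFAULT_STEP,
    max_age: float = DEFAULT_MAX_AGE,
) -> np.ndarray:
    """One-year transition probability matrix P(age, age + 1).

    Ages beyond ``max_age`` are capped with a warning (no extrapolation of
    the fitted age trend past the supported range).
    """
    end = age + 1.0
    if end > max_age:
        warnings.warn(
            f"annual probability at age {age} extrapolates beyond max_age "
            f"{max_age}; capping", stacklevel=2,
        )
        end = max_age
    return transition_probability(_as_model(fit), female, rural, age, end, step=step)


def annual_probability_curves(
    fit: Union[FittedModel, IntensityModel],
    female: float,
    rural: float,
    ages: Sequence[float],
    step: float = DEFAULT_STEP,
) -> pd.DataFrame:
    """Tidy frame of the nine living-state annual transition probabilities
    (plus living -> death) over ``ages``, for curve plotting/export."""
    rows = []
    for age in ages:
        P = annual_probability(fit, female, rural, age, step=step)
        for r in LIVING_STATES:
            for s in range(N_STATES):
                if r == s:
                    continue
                rows.append({"age": age, "from_state": r, "to_state": s,
                             "probability": P[r, s]})
    return pd.DataFrame(rows)


def empirical_initial_distribution(
    subjects: Sequence[SubjectHistory],
    sex: str,
    region: str,
    index_age: float,
    window: float = 2.5,
) -> np.ndarray:
    """Relative frequencies of living states among baseline observations.

    Counts each subject's entry state if the subject belongs to the
    (sex, region) stratum and entered within ``index_age +/- window`` years.
    """
    counts = np.zeros(3)
    for subj in subjects:
        cov = subj.covariates
        if cov.sex != sex or cov.region != region:
            continue
        if abs(subj.entry_age - index_age) <= window:
            counts[subj.entry_state] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError(
            f"no baseline observations for {sex}/{region} within "
            f"{index_age} +/- {window} years; widen the window"
        )
    return counts / total


def state_expectancies(
    fit: Union[FittedModel, IntensityModel],
    female: float,
    rural: float,
    index_age: float,
    max_age: float = DEFAULT_MAX_AGE,
    grid_step: float = DEFAULT_GRID_STEP,
    survival_warn_threshold: float = 0.01,
) -> np.ndarray:
    """Expected years in each living state by initial state.

    Returns a (3, 3) matrix ``e[r, s]``: expected years spent in living
    state s between ``index_age`` and ``max_age`` for a person in state r at
    ``index_age``, computed by accumulating the transition-probability
    product along the grid and integrating with the trapezoidal rule.
    Warns when the survival probability at ``max_age`` still exceeds
    ``survival_warn_threshold`` (truncated expectancies).
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if max_age <= index_age:
        raise ValueError("max_age must exceed index_age")
    model = _as_model(fit)
    grid = np.arange(index_age, max_age + grid_step / 2, grid_step)
    if grid[-1] < max_age - 1e-9:
        grid = np.append(grid, max_age)
    n_pts = len(grid)
    mids = 0.5 * (grid[:-1] + grid[1:])
    widths = np.diff(grid)
    Q = model.q_matrices(mids, np.full_like(mids, female), np.full_like(mids, rural))
    E = expm_batch(Q * widths[:, None, None])
    # running products P(index_age, grid[k]) for all k
    occupancy = np.zeros((3, 3))
    P = np.eye(N_STATES)
    prev_living = P[:3, :3].copy()
    for k in range(n_pts - 1):
        P = P @ E[k]
        living = P[:3, :3]
        occupancy += 0.5 * widths[k] * (prev_living + living)
        prev_living = living.copy()
    survival = P[:3, :3].sum(axis=1)
    if np.any(survival > survival_warn_threshold):
        warnings.warn(
            f"survival probability at max_age {max_age} is up to "
            f"{survival.max():.3f} > {survival_warn_threshold}; "
            "expectancies are truncated", stacklevel=2,
        )
    return occupancy


def _lifetable_quantities(e: np.ndarray, pi: Optional[np.ndarray]) -> Dict[str, Dict[str, float]]:
    """TLE/ND/MD/SD/AD and proportions per initial state and population."""
    out: Dict[str, Dict[str, float]] = {}

    def pack(row: np.ndarray) -> Dict[str, float]:
        nd, md, sd = row
        tle = nd + md + sd
        ad = md + sd
        with np.errstate(invalid="ignore", divide="ignore"):
            props = [100.0 * x / tle if tle > 0 else np.nan for x in (nd, md, sd, ad)]
        return {
            "TLE": tle, "ND": nd, "MD": md, "SD": sd, "AD": ad,
            "PND": props[0], "PMD": props[1], "PSD": props[2], "PAD": props[3],
        }

    for r in LIVING_STATES:
        out[str(r)] = pack(e[r])
    if pi is not None:
        out["population"] = pack(pi @ e)
    return out


def _flatten_stratum(quantities: Dict[str, Dict[str, float]]) -> np.ndarray:
    return np.array(
        [quantities[init][q] for init in quantities for q in QUANTITIES]
    )


def life_table(
    fit: FittedModel,
    subjects: Sequence[SubjectHistory],
    strata: Optional[Iterable[Tuple[str, str]]] = None,
    index_ages: Sequence[float] = DEFAULT_INDEX_AGES,
    max_age: float = DEFAULT_MAX_AGE,
    grid_step: float = DEFAULT_GRID_STEP,
    window: float = 2.5,
    bootstrap_B: int = 0,
    seed: Optional[int] = None,
    likelihood_step: float = DEFAULT_STEP,
) -> pd.DataFrame:
    """Multistate life table: health expectancies per stratum and index age.

    One row per (sex, region, index age, initial state, quantity), where the
    initial state is ``0``/``1``/``2`` or ``population`` (averaged with the
    stratum's empirical baseline distribution).  With ``bootstrap_B > 0``
    percentile 95% CIs are attached by resampling subjects and re-running
    the whole fit -> expectancy pipeline on each replicate.
    """
    if strata is None:
        strata = [(sex, region) for region in ("urban", "rural") for sex in ("male", "female")]
    strata = list(strata)
    index_ages = list(index_ages)

    def compute_all(model_like, cohort) -> Tuple[List[dict], np.ndarray]:
        rows, flat = [], []
        for sex, region in strata:
            female, rural = float(sex == "female"), float(region == "rural")
            for age0 in index_ages:
                e = state_expectancies(model_like, female, rural, age0,
                                       max_age=max_age, grid_step=grid_step)
                try:
                    pi = empirical_initial_distribution(cohort, sex, region, age0, window)
                except ValueError:
                    pi = None
                    logger.warning("empty baseline window for %s/%s at %s; "
                                   "population-averaged rows skipped", sex, region, age0)
                quantities = _lifetable_quantities(e, pi)
                for init, qdict in quantities.items():
                    for q, value in qdict.items():
                        rows.append({
                            "sex": sex, "region": region, "index_age": age0,
                            "initial_state": init, "quantity": q, "estimate": value,
                        })
                        flat.append(value)
        return rows, np.asarray(flat)

    rows, _ = compute_all(fit, subjects)
    table = pd.DataFrame(rows)
    table["lo"] = np.nan
    table["hi"] = np.nan

    if bootstrap_B > 0:
        def statistic(refit: FittedModel, resample) -> np.ndarray:
            return compute_all(refit, resample)[1]

        boot: BootstrapResult = bootstrap(
            subjects, fit.spec, statistic, B=bootstrap_B, seed=seed,
            step=likelihood_step, init=fit.params, statistic_takes_data=True,
        )
        if len(boot.lo) == len(table):
            table["lo"] = boot.lo
            table["hi"] = boot.hi
        else:
            logger.warning("bootstrap statistic length varied across replicates; "
                           "CIs omitted")
    return table


def render_life_table(table: pd.DataFrame) -> str:
    """Aligned-text rendering grouped by stratum and index age."""
    lines = []
    for (sex, region, age0), grp in table.groupby(["sex", "region", "index_age"]):
        lines.append(f"== {region} {sex}, index age {age0:g} ==")
        for init, igrp in grp.groupby("initial_state"):
            parts = []
            for q in QUANTITIES:
                row = igrp[igrp["quantity"] == q]
                if row.empty or not np.isfinite(row["estimate"].iloc[0]):
                    continue
                val = row["estimate"].iloc[0]
                unit_years = q in ("TLE", "ND", "MD", "SD", "AD")
                text = f"{q}={val:.2f}" if unit_years else f"{q}={val:.1f}%"
                if np.isfinite(row["lo"].iloc[0]):
                    text += f" ({row['lo'].iloc[0]:.2f},{row['hi'].iloc[0]:.2f})"
                parts.append(text)
            lines.append(f"  start={init}: " + "  ".join(parts))
    return "\n".join(lines)
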