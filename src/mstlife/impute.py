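"""Multiple imputation of baseline covariates by predictive mean matching.

Each incomplete variable is regressed (on a numeric working coding) on the
other predictors; a missing value is replaced by the observed value of a
donor drawn uniformly from the k nearest neighbors in predicted score, so
every imputed value is a legal observed category.  Five imputed datasets
are generated by default and downstream results are pooled by the plain
entrywise mean across imputations (no between-imputation variance is
propagated; Rubin's rules are deliberately not applied — see the methods
note).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .cohort import CATEGORICAL_LEVELS, CovariateVector, SubjectHistory

logger = logging.getLogger(__name__)

DEFAULT_PREDICTORS: Tuple[str, ...] = ("age",) + tuple(CATEGORICAL_LEVELS)


@dataclass(frozen=True)
class ImputationConfig:
    """PMM settings: m imputations (default 5), donor pool size k (default
    5), predictor set and seed."""

    m: int = 5
    k: int = 5
    predictors: Tuple[str, ...] = DEFAULT_PREDICTORS
    n_sweeps: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")


def _working_codes(frame: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    """Numeric working coding: age as-is, categoricals as level indices
    (ordinal for ordered variables such as education)."""
    out = pd.DataFrame(index=frame.index)
    for var in variables:
        if var == "age":
            out[var] = frame[var].astype(float)
        else:
            levels = CATEGORICAL_LEVELS[var]
            mapping = {lvl: float(i) for i, lvl in enumerate(levels)}
            out[var] = frame[var].map(mapping)
    return out


def impute_frame(
    frame: pd.DataFrame,
    config: ImputationConfig = ImputationConfig(),
) -> List[pd.DataFrame]:
    """PMM-impute the categorical columns of a one-row-per-subject frame.

    ``frame`` must contain an ``age`` column plus (a subset of) the
    categorical covariates; missing entries are NaN/None.  Returns ``m``
    completed copies.  Same seed, same input -> bit-identical output.
    """
    variables = [v for v in config.predictors if v in frame.columns]
    incomplete = [v for v in variables if v != "age" and frame[v].isna().any()]
    for var in incomplete:
        if frame[var].notna().sum() == 0:
            raise ValueError(f"variable {var!r} has no observed values to donate from")
    if frame["age"].isna().any():
        raise ValueError("age must be complete (missingness only in declared covariates)")

    streams = np.random.SeedSequence(config.seed).spawn(config.m)
    completed: List[pd.DataFrame] = []
    for m_idx, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        out = frame.copy()
        work = _working_codes(out, variables)
        col_means = work.mean(skipna=True)
        filled = work.fillna(col_means)
        for _ in range(config.n_sweeps):
            for var in incomplete:
                obs_mask = frame[var].notna().to_numpy()
                mis_mask = ~obs_mask
                if not mis_mask.any():
                    continue
                predictors = [p for p in variables if p != var]
                X = np.column_stack(
                    [np.ones(len(frame))] + [filled[p].to_numpy(dtype=float) for p in predictors]
                )
                y = work[var].to_numpy(dtype=float)
                degenerate = np.linalg.matrix_rank(X[obs_mask]) < X.shape[1]
                if degenerate:
                    logger.warning(
                        "degenerate predictor matrix for %r; falling back to "
                        "marginal donor draws", var,
                    )
                    donors_idx = np.nonzero(obs_mask)[0]
                    picks = rng.integers(0, donors_idx.size, size=int(mis_mask.sum()))
                    donor_rows = donors_idx[picks]
                else:
                    beta, *_ = np.linalg.lstsq(X[obs_mask], y[obs_mask], rcond=None)
                    yhat = X @ beta
                    obs_idx = np.nonzero(obs_mask)[0]
                    mis_idx = np.nonzero(mis_mask)[0]
                    dist = np.abs(yhat[mis_idx][:, None] - yhat[obs_idx][None, :])
                    k = min(config.k, obs_idx.size)
                    nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
                    # deterministic donor pools: order the k nearest by distance
                    order = np.argsort(
                        np.take_along_axis(dist, nearest, axis=1), axis=1, kind="stable"
                    )
                    nearest = np.take_along_axis(nearest, order, axis=1)
                    picks = rng.integers(0, k, size=mis_idx.size)
                    donor_rows = obs_idx[nearest[np.arange(mis_idx.size), picks]]
                out.loc[out.index[mis_mask], var] = frame[var].to_numpy()[donor_rows]
                # refresh working codes so later variables in the sweep see
                # the imputed values (chained equations)
                filled[var] = _working_codes(out, [var])[var]
        completed.append(out)
    return completed


def impute(
    cohort: Sequence[SubjectHistory],
    config: ImputationConfig = ImputationConfig(),
) -> List[List[SubjectHistory]]:
    """PMM multiple imputation of a cohort's baseline covariates.

    Returns ``m`` completed cohorts; observation histories are untouched
    (disability states and death times are never imputed).  With no missing
    values the m outputs equal the input.
    """
    rows = []
    for subj in cohort:
        row = {"age": subj.covariates.age_at_entry}
        row.update({k: subj.covariates.get(k) for k in CATEGORICAL_LEVELS})
        rows.append(row)
    frame = pd.DataFrame(rows)
    completed = impute_frame(frame, config)
    cohorts: List[List[SubjectHistory]] = []
    for filled in completed:
        new_cohort = []
        for subj, (_, row) in zip(cohort, filled.iterrows()):
            cov = CovariateVector(
                age_at_entry=subj.covariates.age_at_entry,
                **{k: (None if pd.isna(row[k]) else str(row[k])) for k in CATEGORICAL_LEVELS},
            )
            new_cohort.append(
                SubjectHistory(
                    id=subj.id,
                    obs_ages=subj.obs_ages.copy(),
                    obs_states=subj.obs_states.copy(),
                    covariates=cov,
                    death_age=subj.death_age,
                )
            )
        cohorts.append(new_cohort)
    return cohorts


PoolInput = Union[np.ndarray, pd.DataFrame, pd.Series]


def pool(results: Sequence[PoolInput]) -> PoolInput:
    """Entrywise arithmetic mean of m result tables of identical shape.

    This is the stated pooling rule for the sensitivity analysis (plain
    mean of the per-imputation results); between-imputation variance is not
    combined.
    """
    if len(results) == 0:
        raise ValueError("nothing to pool")
    first = results[0]
    if isinstance(first, (pd.DataFrame, pd.Series)):
        for r in results[1:]:
            if not isinstance(r, type(first)) or r.shape != first.shape:
                raise ValueError("pooled results must share type and shape")
        stacked = np.stack([np.asarray(r, dtype=float) for r in results])
        mean = stacked.mean(axis=0)
        if isinstance(first, pd.DataFrame):
            return pd.DataFrame(mean, index=first.index, columns=first.columns)
        return pd.Series(mean, index=first.index, name=first.name)
    arrays = [np.asarray(r, dtype=float) for r in results]
    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise ValueError(f"shape mismatch in pooled results: {a.shape} vs {shape}")
    return np.mean(arrays, axis=0)


def write_imputed(cohorts: Sequence[Sequence[SubjectHistory]], path) -> pd.DataFrame:
    """Write m imputed cohorts as one long CSV with an ``imputation`` column."""
    from .cohort import write_panel

    frames = []
    for i, cohort in enumerate(cohorts, start=1):
        df = write_panel(cohort, None)
        df.insert(0, "imputation", i)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if path is not None:
        out.to_csv(path, index=False)
    return out
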