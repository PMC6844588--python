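"""Cox proportional-hazards analysis of disability onset.

Mild and severe disability are merged into a single "any disability" event.
Subjects free of disability at entry are followed to the first wave at which
they are observed disabled (event, time = right endpoint of the censoring
interval) or censored at their last disability assessment.  Time since
entry is the time scale; entry age is a covariate, so the four nested
adjustment models can control for it.

The partial likelihood is maximized by ``statsmodels`` ``PHReg`` (Newton
iteration); Breslow tie handling is the default because wave-synchronized
event times are heavily tied, with Efron selectable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CATEGORICAL_LEVELS, SubjectHistory

logger = logging.getLogger(__name__)

MISSING_LEVEL = "missing"

#: Factors reported in the hazard-ratio table, with their reference level first.
ONSET_FACTORS: Tuple[str, ...] = (
    "sex", "education", "marital", "smoking", "drinking", "exercise",
    "expenses", "service", "diabetes", "heart_disease", "stroke",
)

#: Nested adjustment sets: Model1 univariate; Model2 adds entry age, sex and
#: region; Model3 adds the sociodemographic/behavioral factors; Model4 adds
#: the chronic diseases.
ADJUSTMENT_SETS: Dict[str, Tuple[str, ...]] = {
    "Model1": (),
    "Model2": ("age", "sex", "region"),
    "Model3": ("age", "sex", "region", "education", "marital", "smoking",
               "drinking", "exercise", "expenses", "service"),
    "Model4": ("age", "sex", "region", "education", "marital", "smoking",
               "drinking", "exercise", "expenses", "service",
               "diabetes", "heart_disease", "stroke"),
}


@dataclass
class OnsetReport:
    n_total: int
    n_included: int
    n_disabled_at_entry: int
    n_no_followup: int
    n_events: int


def prepare_onset_dataset(
    subjects: Sequence[SubjectHistory],
) -> Tuple[pd.DataFrame, OnsetReport]:
    """Time-to-first-disability records for subjects disability-free at entry.

    Event time is the gap from entry to the first wave observed in state 1
    or 2 (interval right-endpoint convention).  Subjects dying or lost while
    still disability-free are censored at their last disability assessment;
    subjects with no follow-up assessment (single observation then death)
    carry no onset information and are excluded, counted in the report.
    """
    rows: List[dict] = []
    n_disabled = n_nofup = n_events = 0
    for subj in subjects:
        if subj.entry_state != 0:
            n_disabled += 1
            continue
        disabled_idx = np.nonzero(subj.obs_states[1:] > 0)[0]
        if disabled_idx.size:
            k = int(disabled_idx[0]) + 1
            time = float(subj.obs_ages[k] - subj.entry_age)
            event = 1
            n_events += 1
        else:
            time = float(subj.obs_ages[-1] - subj.entry_age)
            event = 0
        if time <= 0:
            n_nofup += 1
            continue
        row = {"id": subj.id, "time": time, "event": event,
               "age": subj.covariates.age_at_entry}
        row.update({f: subj.covariates.get(f) for f in CATEGORICAL_LEVELS})
        rows.append(row)
    report = OnsetReport(
        n_total=len(subjects),
        n_included=len(rows),
        n_disabled_at_entry=n_disabled,
        n_no_followup=n_nofup,
        n_events=n_events,
    )
    df = pd.DataFrame(rows)
    return df, report


def missing_dummies(records: pd.DataFrame,
                    factors: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Give every missing categorical value its own explicit level.

    No record is dropped for covariate missingness; the "missing" group gets
    its own coefficient in the regression models.
    """
    out = records.copy()
    for factor in (factors if factors is not None else CATEGORICAL_LEVELS):
        if factor in out.columns:
            out[factor] = out[factor].where(out[factor].notna(), MISSING_LEVEL)
    return out


def _levels_with_missing(records: pd.DataFrame, factor: str) -> List[str]:
    levels = list(CATEGORICAL_LEVELS[factor])
    if (records[factor] == MISSING_LEVEL).any():
        levels.append(MISSING_LEVEL)
    return levels


def _design(records: pd.DataFrame, covariates: Sequence[str]) -> Tuple[np.ndarray, List[Tuple[str, str]]]:
    cols, names = [], []
    for cov in covariates:
        if cov == "age":
            cols.append(records["age"].to_numpy(dtype=float))
            names.append(("age", ""))
        else:
            levels = _levels_with_missing(records, cov)
            for lvl in levels[1:]:  # first level is the reference
                cols.append((records[cov] == lvl).to_numpy(dtype=float))
                names.append((cov, lvl))
    return np.column_stack(cols), names


@dataclass
class CoxFit:
    """One fitted adjustment model: per-level coefficients, HRs and CIs."""

    label: str
    table: pd.DataFrame      # factor, level, coef, se, HR, lo, hi, reference
    n: int
    n_events: int
    loglik: float
    score_norm: float
    ties: str
    converged: bool = True

    def hr(self, factor: str, level: str) -> float:
        row = self.table[(self.table["factor"] == factor) & (self.table["level"] == level)]
        if row.empty:
            raise KeyError(f"no row for {factor}={level}")
        return float(row["HR"].iloc[0])


def fit_cox(
    records: pd.DataFrame,
    covariates: Sequence[str],
    ties: str = "breslow",
    label: str = "custom",
) -> CoxFit:
    """Fit one Cox model on onset records with the given covariate set.

    Categorical covariates are dummy-coded against their declared reference
    levels (an explicit ``missing`` level is kept if present); ``age`` is the
    continuous entry age.  Breslow tie handling by default, Efron
    selectable.  Raises on zero events; flags likely monotone-likelihood
    separation (runaway coefficients) with the offending covariate.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    n_events = int(records["event"].sum())
    if n_events == 0:
        raise ValueError("no onset events in the dataset")
    X, names = _design(records, covariates)
    model = sm.PHReg(
        records["time"].to_numpy(dtype=float), X,
        status=records["event"].to_numpy(dtype=int), ties=ties,
    )
    result = model.fit(disp=False)
    params = np.asarray(result.params)
    se = np.asarray(result.bse)
    score = model.score(params)
    score_norm = float(np.max(np.abs(score)))
    converged = True
    for (factor, lvl), coef in zip(names, params):
        if abs(coef) > 10:
            converged = False
            logger.warning(
                "possible monotone-likelihood separation for %s=%s (coef=%.1f)",
                factor, lvl, coef,
            )

    rows = []
    seen_factors = []
    for cov in covariates:
        if cov == "age":
            continue
        if cov not in seen_factors:
            seen_factors.append(cov)
    for factor in seen_factors:
        ref = CATEGORICAL_LEVELS[factor][0]
        rows.append({"factor": factor, "level": ref, "coef": 0.0, "se": np.nan,
                     "HR": 1.0, "lo": np.nan, "hi": np.nan, "reference": True})
    for (factor, lvl), coef, s in zip(names, params, se):
        if factor == "age":
            rows.append({"factor": "age", "level": "", "coef": coef, "se": s,
                         "HR": float(np.exp(coef)), "lo": float(np.exp(coef - 1.96 * s)),
                         "hi": float(np.exp(coef + 1.96 * s)), "reference": False})
        else:
            rows.append({"factor": factor, "level": lvl, "coef": coef, "se": s,
                         "HR": float(np.exp(coef)), "lo": float(np.exp(coef - 1.96 * s)),
                         "hi": float(np.exp(coef + 1.96 * s)), "reference": False})
    table = pd.DataFrame(rows)
    return CoxFit(
        label=label, table=table, n=len(records), n_events=n_events,
        loglik=float(model.loglike(params)), score_norm=score_norm,
        ties=ties, converged=converged,
    )


def hazard_table(
    records: pd.DataFrame,
    factors: Sequence[str] = ONSET_FACTORS,
    ties: str = "breslow",
) -> pd.DataFrame:
    """Hazard ratios for every factor under the four nested models.

    For each factor and model, the fitted covariate set is the union of the
    model's adjustment set and the factor itself; the factor's per-level HR
    (95% CI) is reported, reference rows as 1.00.  Returns a tidy frame
    ``factor, level, model, HR, lo, hi, reference``.
    """
    records = missing_dummies(records, factors)
    rows = []
    for model_label, adjust in ADJUSTMENT_SETS.items():
        for factor in factors:
            covs = list(adjust)
            if factor not in covs:
                covs.append(factor)
            fit = fit_cox(records, covs, ties=ties, label=model_label)
            sub = fit.table[fit.table["factor"] == factor]
            for _, row in sub.iterrows():
                rows.append({
                    "factor": factor, "level": row["level"], "model": model_label,
                    "HR": row["HR"], "lo": row["lo"], "hi": row["hi"],
                    "reference": row["reference"],
                })
    return pd.DataFrame(rows)


def render_hazard_table(table: pd.DataFrame) -> str:
    """Text rendering: one block per factor, columns Model1..Model4."""
    lines = []
    models = list(ADJUSTMENT_SETS)
    for factor, fgrp in table.groupby("factor", sort=False):
        lines.append(f"{factor}")
        for level, lgrp in fgrp.groupby("level", sort=False):
            cells = []
            for m in models:
                row = lgrp[lgrp["model"] == m]
                if row.empty:
                    cells.append("")
                elif row["reference"].iloc[0]:
                    cells.append("1.00")
                else:
                    cells.append(
                        f"{row['HR'].iloc[0]:.2f}"
                        f"({row['lo'].iloc[0]:.2f}~{row['hi'].iloc[0]:.2f})"
                    )
            lines.append(f"  {level:>12}  " + "  ".join(f"{c:>18}" for c in cells))
    return "\n".join(lines)
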