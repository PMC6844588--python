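"""Panel-cohort data model, long-format CSV I/O and descriptive summaries.

A cohort is a collection of :class:`SubjectHistory` objects: each subject is
seen at a handful of survey waves (ages in years, living disability states
only), may have an exactly dated death between waves, and carries baseline
covariates recorded at entry.  Subjects lost to follow-up are right-censored
at their last observation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .states import LIVING_STATES

logger = logging.getLogger(__name__)

MIN_ENTRY_AGE = 65.0
MAX_ENTRY_AGE = 95.0

#: Categorical covariates with their legal levels; the first level is the
#: reference level used in regression models.
CATEGORICAL_LEVELS: Dict[str, Tuple[str, ...]] = {
    "sex": ("male", "female"),
    "region": ("urban", "rural"),
    "marital": ("others", "married"),
    "education": ("0y", "1-6y", "7+y"),
    "expenses": ("insufficient", "sufficient"),
    "service": ("inadequate", "adequate"),
    "smoking": ("no", "yes"),
    "drinking": ("no", "yes"),
    "exercise": ("no", "yes"),
    "diabetes": ("no", "yes"),
    "heart_disease": ("no", "yes"),
    "stroke": ("no", "yes"),
}

COVARIATE_COLUMNS: Tuple[str, ...] = tuple(CATEGORICAL_LEVELS)

PANEL_COLUMNS: Tuple[str, ...] = ("subject_id", "age", "state", "death_age") + COVARIATE_COLUMNS


class PanelFormatError(ValueError):
    """Hard error for malformed panel files (unknown state codes, deaths
    preceding observations, conflicting covariates)."""


@dataclass(frozen=True)
class CovariateVector:
    """Baseline covariates of one subject; ``None`` marks an explicitly
    missing categorical answer, never silently defaulted."""

    age_at_entry: float
    sex: Optional[str] = None
    region: Optional[str] = None
    marital: Optional[str] = None
    education: Optional[str] = None
    expenses: Optional[str] = None
    service: Optional[str] = None
    smoking: Optional[str] = None
    drinking: Optional[str] = None
    exercise: Optional[str] = None
    diabetes: Optional[str] = None
    heart_disease: Optional[str] = None
    stroke: Optional[str] = None

    def __post_init__(self) -> None:
        if not (MIN_ENTRY_AGE <= self.age_at_entry <= MAX_ENTRY_AGE):
            raise ValueError(
                f"age_at_entry {self.age_at_entry} outside [{MIN_ENTRY_AGE}, {MAX_ENTRY_AGE}]"
            )
        for name, levels in CATEGORICAL_LEVELS.items():
            value = getattr(self, name)
            if value is not None and value not in levels:
                raise ValueError(f"unknown level {value!r} for covariate {name!r}")

    def get(self, name: str) -> Optional[str]:
        return getattr(self, name)

    def asdict(self) -> Dict[str, object]:
        return dataclasses.asdict(self)


@dataclass
class SubjectHistory:
    """Ordered panel observations of one subject.

    ``obs_ages`` are strictly increasing ages (years) at interview; the
    corresponding ``obs_states`` are living states only.  ``death_age`` is
    the exactly reported death age, strictly after the last interview, or
    ``None`` for subjects alive (or lost) at last contact.
    """

    id: str
    obs_ages: np.ndarray
    obs_states: np.ndarray
    covariates: CovariateVector
    death_age: Optional[float] = None

    def __post_init__(self) -> None:
        self.obs_ages = np.asarray(self.obs_ages, dtype=float)
        self.obs_states = np.asarray(self.obs_states, dtype=int)
        self.validate()

    def validate(self) -> None:
        if self.obs_ages.shape != self.obs_states.shape or self.obs_ages.ndim != 1:
            raise ValueError(f"subject {self.id}: ages/states shape mismatch")
        if len(self.obs_ages) == 0:
            raise ValueError(f"subject {self.id}: no observations")
        if np.any(np.diff(self.obs_ages) <= 0):
            raise ValueError(f"subject {self.id}: observation ages not strictly increasing")
        if not np.all(np.isin(self.obs_states, LIVING_STATES)):
            bad = self.obs_states[~np.isin(self.obs_states, LIVING_STATES)]
            raise ValueError(f"subject {self.id}: non-living observed state(s) {bad.tolist()}")
        if self.death_age is not None and self.death_age <= self.obs_ages[-1]:
            raise PanelFormatError(
                f"subject {self.id}: death age {self.death_age} not after last "
                f"observation at {self.obs_ages[-1]}"
            )
        if self.n_information_points < 2:
            raise ValueError(
                f"subject {self.id}: fewer than 2 information points "
                "(needs >=2 observations, or >=1 observation plus a death)"
            )

    @property
    def n_obs(self) -> int:
        return len(self.obs_ages)

    @property
    def n_information_points(self) -> int:
        return self.n_obs + (1 if self.death_age is not None else 0)

    @property
    def entry_age(self) -> float:
        return float(self.obs_ages[0])

    @property
    def entry_state(self) -> int:
        return int(self.obs_states[0])


@dataclass
class IngestReport:
    """Per-file diagnostics: which subjects were excluded and why."""

    n_read: int = 0
    n_kept: int = 0
    excluded: List[Tuple[str, str]] = field(default_factory=list)

    def exclude(self, subject_id: str, reason: str) -> None:
        self.excluded.append((subject_id, reason))
        logger.info("excluding subject %s: %s", subject_id, reason)


def _first_non_null(series: pd.Series):
    non_null = series.dropna()
    return None if non_null.empty else non_null.iloc[0]


def read_panel(
    path,
    column_map: Optional[Dict[str, str]] = None,
) -> Tuple[List[SubjectHistory], IngestReport]:
    """Read a long-format panel CSV into validated subject histories.

    Parameters
    ----------
    path
        CSV with one row per subject-wave.  Expected columns (renameable via
        ``column_map``, a mapping from canonical name to file column):
        ``subject_id, age, state, death_age`` plus the baseline covariates.
    column_map
        Optional mapping ``canonical -> file column name``.

    Returns
    -------
    (subjects, report)
        Valid histories sorted by id, and an :class:`IngestReport` naming
        every excluded subject.  Unknown state codes and deaths dated before
        an observation raise :class:`PanelFormatError` (hard errors);
        subjects with non-monotone ages or fewer than two information points
        are excluded with a diagnostic.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    required = {"subject_id", "age", "state"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise PanelFormatError(f"panel file missing required columns: {sorted(missing_cols)}")

    bad_states = df["state"].dropna()
    bad_states = bad_states[~bad_states.astype(int).isin(LIVING_STATES)]
    if not bad_states.empty:
        row = bad_states.index[0]
        raise PanelFormatError(
            f"unknown state code {int(bad_states.iloc[0])} at file row {row + 2} "
            f"(subject {df.loc[row, 'subject_id']}); living states are {LIVING_STATES}"
        )

    report = IngestReport(n_read=df["subject_id"].nunique())
    subjects: List[SubjectHistory] = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("age", kind="stable")
        ages = grp["age"].to_numpy(dtype=float)
        if np.any(np.diff(ages) <= 0):
            report.exclude(str(sid), "non-monotone observation ages")
            continue
        states = grp["state"].to_numpy(dtype=int)
        death_age = None
        if "death_age" in grp.columns:
            death_age = _first_non_null(grp["death_age"])
            death_age = None if death_age is None or pd.isna(death_age) else float(death_age)
        if death_age is not None and death_age <= ages[-1]:
            raise PanelFormatError(
                f"subject {sid}: death age {death_age} on or before last observation "
                f"at age {ages[-1]}"
            )
        cov_kwargs: Dict[str, object] = {"age_at_entry": float(ages[0])}
        for name in COVARIATE_COLUMNS:
            if name in grp.columns:
                value = _first_non_null(grp[name])
                cov_kwargs[name] = None if value is None or pd.isna(value) else str(value)
        n_info = len(ages) + (1 if death_age is not None else 0)
        if n_info < 2:
            report.exclude(str(sid), "fewer than 2 information points (no follow-up)")
            continue
        try:
            subjects.append(
                SubjectHistory(
                    id=str(sid),
                    obs_ages=ages,
                    obs_states=states,
                    covariates=CovariateVector(**cov_kwargs),
                    death_age=death_age,
                )
            )
        except PanelFormatError:
            raise
        except ValueError as err:
            report.exclude(str(sid), str(err))
    report.n_kept = len(subjects)
    return subjects, report


def write_panel(subjects: Sequence[SubjectHistory], path) -> pd.DataFrame:
    """Write histories back to the long CSV format read by :func:`read_panel`."""
    rows = []
    for subj in subjects:
        cov = subj.covariates
        for age, state in zip(subj.obs_ages, subj.obs_states):
            row = {
                "subject_id": subj.id,
                "age": age,
                "state": int(state),
                "death_age": subj.death_age,
            }
            for name in COVARIATE_COLUMNS:
                row[name] = cov.get(name)
            rows.append(row)
    df = pd.DataFrame(rows, columns=list(PANEL_COLUMNS))
    if path is not None:
        df.to_csv(path, index=False)
    return df


def cohort_frame(subjects: Sequence[SubjectHistory]) -> pd.DataFrame:
    """One row per subject: entry age/state, follow-up and baseline covariates."""
    rows = []
    for subj in subjects:
        row = {
            "subject_id": subj.id,
            "entry_age": subj.entry_age,
            "entry_state": subj.entry_state,
            "n_obs": subj.n_obs,
            "death_age": subj.death_age,
        }
        row.update({k: subj.covariates.get(k) for k in COVARIATE_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows)


def percentage_of_nonmissing(counts: Sequence[float]) -> List[float]:
    """Percentages of level counts over the nonmissing total, 1-decimal display."""
    total = float(np.sum(counts))
    if total == 0:
        return [0.0 for _ in counts]
    return [round(100.0 * c / total, 1) for c in counts]


def descriptive_table(subjects: Sequence[SubjectHistory]) -> pd.DataFrame:
    """Region x sex descriptive summary of the cohort at entry.

    Returns a tidy frame with columns ``region, sex, variable, level, count,
    pct, mean, sd``: one ``N``/``entry_age`` row per stratum plus one row per
    level of every categorical covariate and of the entry disability state.
    Percentages use the stratum's nonmissing denominator for that variable;
    display rounding is one decimal for percentages and kept full precision
    in ``count``/``mean``/``sd``.
    """
    if len(subjects) == 0:
        raise ValueError("descriptive_table requires a nonempty cohort")
    frame = cohort_frame(subjects)
    entry_levels = {"entry_state": ("0", "1", "2")}
    frame["entry_state"] = frame["entry_state"].astype(str)

    rows = []
    for region in CATEGORICAL_LEVELS["region"]:
        for sex in CATEGORICAL_LEVELS["sex"]:
            sub = frame[(frame["region"] == region) & (frame["sex"] == sex)]
            rows.append(
                {
                    "region": region, "sex": sex, "variable": "N", "level": "",
                    "count": len(sub), "pct": np.nan, "mean": np.nan, "sd": np.nan,
                }
            )
            mean = sub["entry_age"].mean() if len(sub) else np.nan
            sd = sub["entry_age"].std(ddof=1) if len(sub) > 1 else np.nan
            rows.append(
                {
                    "region": region, "sex": sex, "variable": "entry_age", "level": "",
                    "count": len(sub), "pct": np.nan, "mean": mean, "sd": sd,
                }
            )
            variables = {
                name: levels
                for name, levels in CATEGORICAL_LEVELS.items()
                if name not in ("sex", "region")
            }
            variables.update(entry_levels)
            for name, levels in variables.items():
                observed = sub[name].dropna() if len(sub) else pd.Series([], dtype=object)
                counts = [int((observed == lvl).sum()) for lvl in levels]
                pcts = percentage_of_nonmissing(counts)
                for lvl, cnt, pct in zip(levels, counts, pcts):
                    rows.append(
                        {
                            "region": region, "sex": sex, "variable": name, "level": lvl,
                            "count": cnt, "pct": pct, "mean": np.nan, "sd": np.nan,
                        }
                    )
    return pd.DataFrame(rows)


def render_descriptive_table(table: pd.DataFrame) -> str:
    """Aligned-text rendering of :func:`descriptive_table` output."""
    lines = []
    for (region, sex), grp in table.groupby(["region", "sex"], sort=False):
        n_row = grp[grp["variable"] == "N"].iloc[0]
        age_row = grp[grp["variable"] == "entry_age"].iloc[0]
        lines.append(f"== {region} {sex}  (N={int(n_row['count'])}) ==")
        if np.isfinite(age_row["mean"]):
            lines.append(f"  entry age: {age_row['mean']:.1f} ± {age_row['sd']:.1f}")
        for variable, vgrp in grp[~grp["variable"].isin(["N", "entry_age"])].groupby(
            "variable", sort=False
        ):
            lines.append(f"  {variable}:")
            for _, row in vgrp.iterrows():
                lines.append(f"    {row['level']:>12}  {int(row['count']):6d} ({row['pct']:.1f})")
    return "\n".join(lines)
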