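"""Interval-censored panel likelihood for the 4-state Markov model.

Observation scheme: living states are seen only at wave ages (the exact
moment of disability transitions is unknown), deaths are exactly dated but
the state at the moment of death is unknown.  A subject observed in state r
at age a1 and state s at age a2 contributes log P_rs(a1, a2); a death at age
d after a last living observation in state r at age a contributes
log sum_j P_rj(a, d) * q_{j,death}(d) over living j.  Censored subjects
contribute nothing after their last observation.

Age dependence of Q is handled by freezing Q on cells of a global age grid
(default cell width 0.5 years, Q evaluated at the cell midpoint) and
multiplying the cell-wise matrix exponentials.  The midpoint rule makes the
freezing error second order in the cell width.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .cohort import SubjectHistory
from .model import IntensityModel, ModelSpec, _profile_indicators
from .states import DEATH, N_STATES

logger = logging.getLogger(__name__)

DEFAULT_STEP = 0.5


def expm_batch(A: np.ndarray) -> np.ndarray:
    """Matrix exponential of a stack of small matrices.

    Scaling-and-squaring with a Taylor polynomial: the stack is scaled so the
    largest infinity norm is below 0.5, a degree-13 Taylor series is applied
    (truncation error < 1e-13 at that norm), then squared back.  Exact for
    the 4x4 intensity matrices used here; validated against
    ``scipy.linalg.expm`` in the test suite.
    """
    A = np.asarray(A, dtype=float)
    single = A.ndim == 2
    if single:
        A = A[None]
    n = A.shape[0]
    if n == 0:
        return A.copy()
    norm = np.abs(A).sum(axis=2).max() if A.size else 0.0
    s = max(0, int(math.ceil(math.log2(norm / 0.5))) if norm > 0.5 else 0)
    As = A / (2.0 ** s)
    eye = np.broadcast_to(np.eye(A.shape[1]), A.shape)
    T = eye.copy()
    for k in range(13, 0, -1):
        T = eye + (As @ T) / k
    for _ in range(s):
        T = T @ T
    return T[0] if single else T


def grid_segments(a1: float, a2: float, step: float) -> Tuple[np.ndarray, np.ndarray]:
    """Split [a1, a2] at global grid knots (multiples of ``step``).

    Returns (midpoints, widths) of the sub-segments in order.  Interior
    segments have width ``step`` and grid-cell midpoints, so they can be
    shared across subjects; at most the two edge segments are partial.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if a2 < a1:
        raise ValueError(f"need a1 <= a2, got {a1} > {a2}")
    if a2 - a1 <= 1e-12:
        return np.empty(0), np.empty(0)
    eps = 1e-9
    first = math.floor(a1 / step + eps) + 1
    last = math.ceil(a2 / step - eps) - 1
    interior = step * np.arange(first, last + 1, dtype=float)
    bounds = np.concatenate([[a1], interior, [a2]])
    widths = np.diff(bounds)
    keep = widths > 1e-12
    mids = 0.5 * (bounds[:-1] + bounds[1:])
    return mids[keep], widths[keep]


def transition_probability(
    model: IntensityModel,
    female: float,
    rural: float,
    a1: float,
    a2: float,
    step: float = DEFAULT_STEP,
) -> np.ndarray:
    """Transition probability matrix P(a1, a2) for one covariate profile.

    Product of matrix exponentials of the age-frozen intensity matrix over
    grid cells of width <= ``step``; the identity when ``a1 == a2``.
    """
    mids, widths = grid_segments(a1, a2, step)
    if len(mids) == 0:
        return np.eye(N_STATES)
    Q = model.q_matrices(mids, np.full_like(mids, female), np.full_like(mids, rural))
    E = expm_batch(Q * widths[:, None, None])
    P = np.eye(N_STATES)
    for k in range(len(mids)):
        P = P @ E[k]
    _check_stochastic(P)
    return P


def _check_stochastic(P: np.ndarray, tol: float = 1e-8) -> None:
    rows = P.sum(axis=-1)
    if np.any(np.abs(rows - 1.0) > tol) or np.any(P < -tol) or np.any(P > 1 + tol):
        raise FloatingPointError(
            f"transition matrix failed stochasticity check (row sums {rows})"
        )


@dataclass
class LikelihoodPlan:
    """Precomputed span/segment layout of a cohort for fast re-evaluation.

    Built once per (cohort, grid step); evaluating the log-likelihood for new
    parameter values then needs only one batched matrix-exponential call over
    the deduplicated grid segments.  Subjects are laid out in the order
    given (fit code sorts by id), which fixes the summation order.
    """

    spec: ModelSpec
    step: float
    n_subjects: int
    subject_ids: List[str]
    # spans
    span_subject: np.ndarray      # (nspan,) subject index
    span_kind: np.ndarray         # 0 = living->living, 1 = last living->death
    span_r: np.ndarray
    span_s: np.ndarray            # target state for kind 0, -1 for deaths
    span_death_age: np.ndarray    # nan for kind 0
    span_female: np.ndarray
    span_rural: np.ndarray
    # segments (CSR over spans), deduplicated
    seg_offsets: np.ndarray       # (nspan+1,)
    seg_unique_idx: np.ndarray    # (nseg,) index into unique segment table
    uniq_mid: np.ndarray
    uniq_width: np.ndarray
    uniq_female: np.ndarray
    uniq_rural: np.ndarray

    @classmethod
    def build(
        cls,
        subjects: Sequence[SubjectHistory],
        spec: ModelSpec,
        step: float = DEFAULT_STEP,
    ) -> "LikelihoodPlan":
        sub_idx: List[int] = []
        kind: List[int] = []
        r_: List[int] = []
        s_: List[int] = []
        dage: List[float] = []
        fem: List[float] = []
        rur: List[float] = []
        seg_mid: List[np.ndarray] = []
        seg_width: List[np.ndarray] = []
        seg_counts: List[int] = []

        def add_span(i, a1, a2, kd, r, s, female, rural):
            mids, widths = grid_segments(a1, a2, step)
            sub_idx.append(i)
            kind.append(kd)
            r_.append(r)
            s_.append(s if s is not None else -1)
            dage.append(a2 if kd == 1 else np.nan)
            fem.append(female)
            rur.append(rural)
            seg_mid.append(mids)
            seg_width.append(widths)
            seg_counts.append(len(mids))

        for i, subj in enumerate(subjects):
            female, rural = _profile_indicators(subj.covariates)
            ages, states = subj.obs_ages, subj.obs_states
            for k in range(len(ages) - 1):
                add_span(i, ages[k], ages[k + 1], 0, int(states[k]), int(states[k + 1]),
                         female, rural)
            if subj.death_age is not None:
                add_span(i, ages[-1], float(subj.death_age), 1, int(states[-1]), None,
                         female, rural)

        nspan = len(sub_idx)
        offsets = np.zeros(nspan + 1, dtype=np.int64)
        offsets[1:] = np.cumsum(seg_counts)
        all_mid = np.concatenate(seg_mid) if nspan else np.empty(0)
        all_width = np.concatenate(seg_width) if nspan else np.empty(0)
        span_of_seg = np.repeat(np.arange(nspan), seg_counts) if nspan else np.empty(0, int)
        fem_arr = np.asarray(fem)
        rur_arr = np.asarray(rur)
        key = np.column_stack(
            [
                np.round(all_mid, 9),
                np.round(all_width, 9),
                fem_arr[span_of_seg],
                rur_arr[span_of_seg],
            ]
        ) if nspan else np.empty((0, 4))
        uniq, inverse = np.unique(key, axis=0, return_inverse=True)
        return cls(
            spec=spec,
            step=step,
            n_subjects=len(subjects),
            subject_ids=[s.id for s in subjects],
            span_subject=np.asarray(sub_idx, dtype=np.int64),
            span_kind=np.asarray(kind, dtype=np.int64),
            span_r=np.asarray(r_, dtype=np.int64),
            span_s=np.asarray(s_, dtype=np.int64),
            span_death_age=np.asarray(dage),
            span_female=fem_arr,
            span_rural=rur_arr,
            seg_offsets=offsets,
            seg_unique_idx=inverse.astype(np.int64),
            uniq_mid=uniq[:, 0],
            uniq_width=uniq[:, 1],
            uniq_female=uniq[:, 2],
            uniq_rural=uniq[:, 3],
        )

    # ------------------------------------------------------------------
    def span_probabilities(self, model: IntensityModel) -> np.ndarray:
        """P(a1, a2) for every span, shape (nspan, 4, 4)."""
        nspan = len(self.span_subject)
        P = np.broadcast_to(np.eye(N_STATES), (nspan, N_STATES, N_STATES)).copy()
        if len(self.uniq_mid) == 0:
            return P
        Q = model.q_matrices(self.uniq_mid, self.uniq_female, self.uniq_rural)
        E_uniq = expm_batch(Q * self.uniq_width[:, None, None])
        counts = np.diff(self.seg_offsets)
        max_count = int(counts.max()) if nspan else 0
        for j in range(max_count):
            sel = np.nonzero(counts > j)[0]
            seg_ids = self.seg_unique_idx[self.seg_offsets[sel] + j]
            P[sel] = P[sel] @ E_uniq[seg_ids]
        return P

    def per_subject_loglik(self, model: IntensityModel) -> np.ndarray:
        """Log-likelihood contribution of each subject, in plan order.

        Structurally impossible observations (probability exactly zero under
        the model structure) yield ``-inf`` for that subject, with a logged
        diagnostic naming the offending state pair.
        """
        if model.spec != self.spec:
            raise ValueError("model spec does not match the plan's spec")
        P = self.span_probabilities(model)
        nspan = len(self.span_subject)
        span_ll = np.zeros(nspan)

        obs = self.span_kind == 0
        if obs.any():
            p = P[obs, self.span_r[obs], self.span_s[obs]]
            with np.errstate(divide="ignore"):
                span_ll[obs] = np.where(p > 0, np.log(np.maximum(p, 1e-300)), -np.inf)
            if np.any(p <= 0):
                for i in np.nonzero(obs)[0][p <= 0]:
                    logger.warning(
                        "zero-probability observed transition %d -> %d for subject %s "
                        "under the chosen structure",
                        self.span_r[i], self.span_s[i],
                        self.subject_ids[self.span_subject[i]],
                    )
        death = self.span_kind == 1
        if death.any():
            idx = np.nonzero(death)[0]
            d_age = self.span_death_age[idx]
            rates = model.rates(d_age, self.span_female[idx], self.span_rural[idx])
            q_death = np.zeros((len(idx), N_STATES))
            for j, (r, s) in enumerate(model.spec.transitions):
                if s == DEATH:
                    q_death[:, r] = rates[:, j]
            dens = np.einsum("ij,ij->i", P[idx, self.span_r[idx], :], q_death)
            with np.errstate(divide="ignore"):
                span_ll[idx] = np.where(dens > 0, np.log(np.maximum(dens, 1e-300)), -np.inf)
            if np.any(dens <= 0):
                for i in idx[dens <= 0]:
                    logger.warning(
                        "zero-density exact death from last state %d for subject %s",
                        self.span_r[i], self.subject_ids[self.span_subject[i]],
                    )
        out = np.zeros(self.n_subjects)
        np.add.at(out, self.span_subject, span_ll)
        return out

    def loglik(self, model: IntensityModel) -> float:
        """Total cohort log-likelihood (sum over subjects in plan order)."""
        return float(self.per_subject_loglik(model).sum())


def subject_loglik(
    model: IntensityModel,
    subject: SubjectHistory,
    step: float = DEFAULT_STEP,
) -> float:
    """Log-likelihood contribution of one subject under ``model``."""
    plan = LikelihoodPlan.build([subject], model.spec, step=step)
    return float(plan.per_subject_loglik(model)[0])
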