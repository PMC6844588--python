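"""Synthetic CLHLS-like cohort generator with known ground truth.

Emulates the design features of a long-running elderly panel survey:
staggered entry at ages 65-95, interview waves about three years apart,
disability states observed only at waves, exactly dated deaths between
waves (family-reported), dropout, and item-level covariate missingness.
Trajectories follow a user-chosen 4-state intensity model, so every
downstream estimator can be checked against the generating truth.

Default magnitudes echo the phenomena reported for such cohorts (rising
onset and mortality with age, female excess disability incidence, male
excess mortality, rural recovery advantage) without claiming any particular
fitted values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cohort import CovariateVector, SubjectHistory, write_panel
from .model import IntensityModel, ModelSpec, TRANSITIONS_NO_JUMP, spec_for
from .states import DEATH, LIVING_STATES, N_STATES

logger = logging.getLogger(__name__)

DEFAULT_MICRO_STEP = 0.1

#: Baseline rates per person-year at the reference profile (urban man aged
#: 65) and log-linear age slopes, one row per directed transition.
DEFAULT_BASE_RATES: Dict[Tuple[int, int], Tuple[float, float]] = {
    (0, 1): (0.06, 0.07),
    (0, 2): (0.01, 0.08),
    (0, 3): (0.02, 0.09),
    (1, 0): (0.25, -0.05),
    (1, 2): (0.05, 0.07),
    (1, 3): (0.04, 0.08),
    (2, 0): (0.06, -0.08),
    (2, 1): (0.12, -0.03),
    (2, 3): (0.15, 0.07),
}

#: Sparse covariate effects: female raises disability onset and lowers
#: mortality; rural raises recovery rates and no-disability mortality.
DEFAULT_FEMALE_EFFECTS: Dict[Tuple[int, int], float] = {
    (0, 1): 0.25, (0, 3): -0.35, (1, 3): -0.35, (2, 3): -0.30,
}
DEFAULT_RURAL_EFFECTS: Dict[Tuple[int, int], float] = {
    (1, 0): 0.20, (2, 1): 0.15, (0, 3): 0.10,
}

#: Baseline state distributions (no/mild/severe) per (sex, region) stratum,
#: echoing published entry-state frequencies for Chinese elderly panels.
DEFAULT_ENTRY_STATE_PROBS: Dict[Tuple[str, str], Tuple[float, float, float]] = {
    ("male", "urban"): (0.559, 0.277, 0.164),
    ("female", "urban"): (0.402, 0.374, 0.224),
    ("male", "rural"): (0.540, 0.348, 0.112),
    ("female", "rural"): (0.377, 0.451, 0.172),
}

#: Marginal frequencies of the non-modelled baseline covariates.
DEFAULT_COVARIATE_FREQS: Dict[str, Dict[str, float]] = {
    "marital": {"others": 0.613, "married": 0.387},
    "education": {"0y": 0.574, "1-6y": 0.319, "7+y": 0.107},
    "expenses": {"insufficient": 0.206, "sufficient": 0.794},
    "service": {"inadequate": 0.097, "adequate": 0.903},
    "smoking": {"no": 0.778, "yes": 0.222},
    "drinking": {"no": 0.785, "yes": 0.215},
    "exercise": {"no": 0.678, "yes": 0.322},
    "diabetes": {"no": 0.975, "yes": 0.025},
    "heart_disease": {"no": 0.912, "yes": 0.088},
    "stroke": {"no": 0.943, "yes": 0.057},
}


def default_true_model(structure: str = "full") -> IntensityModel:
    """The generator's default ground-truth intensity model."""
    spec = spec_for(structure)
    transitions = spec.transitions
    effects = {}
    for t in transitions:
        covs = ["age"]
        if t in DEFAULT_FEMALE_EFFECTS:
            covs.append("female")
        if t in DEFAULT_RURAL_EFFECTS:
            covs.append("rural")
        effects[t] = tuple(covs)
    spec = ModelSpec(transitions=transitions, covariate_effects=effects)
    values = {}
    for r, s in transitions:
        base, age_slope = DEFAULT_BASE_RATES[(r, s)]
        values[f"logq_{r}{s}"] = float(np.log(base))
        values[f"beta_{r}{s}:age"] = age_slope
        if (r, s) in DEFAULT_FEMALE_EFFECTS:
            values[f"beta_{r}{s}:female"] = DEFAULT_FEMALE_EFFECTS[(r, s)]
        if (r, s) in DEFAULT_RURAL_EFFECTS:
            values[f"beta_{r}{s}:rural"] = DEFAULT_RURAL_EFFECTS[(r, s)]
    return IntensityModel.from_dict(spec, values)


#: Age-homogeneous truth for the parameter-recovery and coverage studies:
#: the interval-censoring machinery is exercised without the age trend, so
#: every parameter is strongly identified at n = 2000 (see docs/methods.md).
CALIBRATION_RATES: Dict[Tuple[int, int], float] = {
    (0, 1): 0.15, (0, 3): 0.06,
    (1, 0): 0.20, (1, 2): 0.12, (1, 3): 0.10,
    (2, 1): 0.15, (2, 3): 0.30,
}
CALIBRATION_EFFECTS: Dict[Tuple[int, int], Dict[str, float]] = {
    (0, 1): {"female": 0.25},
    (1, 0): {"rural": 0.20},
    (2, 3): {"female": -0.30},
}


def calibration_true_model(zero_effects: bool = False) -> IntensityModel:
    """Ground truth of the designed parameter-recovery experiment.

    No-jump structure, constant-in-age rates of realistic elderly-cohort
    magnitude, female effect on disability onset and severe-state mortality,
    rural effect on mild-state recovery.  With ``zero_effects`` the covariate
    structure is kept but all effects are zero (Wald-coverage study).
    """
    spec = ModelSpec(
        transitions=TRANSITIONS_NO_JUMP,
        covariate_effects={t: tuple(e) for t, e in CALIBRATION_EFFECTS.items()},
    )
    values = {f"logq_{r}{s}": float(np.log(v)) for (r, s), v in CALIBRATION_RATES.items()}
    for (r, s), effs in CALIBRATION_EFFECTS.items():
        for cov, val in effs.items():
            values[f"beta_{r}{s}:{cov}"] = 0.0 if zero_effects else val
    return IntensityModel.from_dict(spec, values)


def calibration_scenario(n: int = 2000, zero_effects: bool = False) -> "SimulationScenario":
    """Designed recovery experiment: n subjects, 5 waves at 3-year spacing,
    balanced allocation over initial living states (equal thirds, the
    information-maximizing design), 5% per-wave dropout, no covariate
    missingness."""
    balanced = {key: (1 / 3, 1 / 3, 1 / 3) for key in DEFAULT_ENTRY_STATE_PROBS}
    return SimulationScenario(
        n=n,
        true_model=calibration_true_model(zero_effects=zero_effects),
        entry_state_probs=balanced,
        dropout=0.05,
        missing_rates={},
    )


@dataclass
class SimulationScenario:
    """Everything needed to generate one synthetic cohort."""

    n: int = 2000
    entry_age_range: Tuple[float, float] = (65.0, 95.0)
    p_female: float = 0.5
    p_rural: float = 0.605
    covariate_freqs: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_FREQS.items()}
    )
    entry_state_probs: Dict[Tuple[str, str], Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ENTRY_STATE_PROBS)
    )
    true_model: IntensityModel = field(default_factory=default_true_model)
    wave_offsets: Tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 12.0)
    dropout: float = 0.10
    missing_rates: Dict[str, float] = field(
        default_factory=lambda: {k: 0.002 for k in DEFAULT_COVARIATE_FREQS}
    )
    micro_step: float = DEFAULT_MICRO_STEP

    def __post_init__(self) -> None:
        if not 0 <= self.dropout <= 1:
            raise ValueError("dropout probability must lie in [0, 1]")
        if any(b <= a for a, b in zip(self.wave_offsets, self.wave_offsets[1:])):
            raise ValueError("wave offsets must be strictly increasing")
        for name, freqs in self.covariate_freqs.items():
            total = sum(freqs.values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(f"covariate frequencies for {name!r} sum to {total}")


def simulate_trajectory(
    model: IntensityModel,
    female: float,
    rural: float,
    entry_age: float,
    entry_state: int,
    horizon: float,
    rng: np.random.Generator,
    micro_step: float = DEFAULT_MICRO_STEP,
) -> List[Tuple[float, int]]:
    """Gillespie-style forward simulation of one trajectory.

    Age dependence is honored by freezing Q over ``micro_step``-year cells
    (evaluated at the cell midpoint); holding times are exponential at the
    frozen rate, redrawn each cell (exact for the cell-frozen process).
    Returns the event list ``[(age, state), ...]`` starting with the entry
    event and ending with death or the last pre-horizon event.
    """
    if entry_state not in LIVING_STATES:
        raise ValueError("entry state must be a living state")
    if not np.isfinite(horizon):
        raise ValueError("a finite horizon is required")
    age, state = float(entry_age), int(entry_state)
    events = [(age, state)]
    while age < horizon - 1e-12 and state != DEATH:
        dt = min(micro_step, horizon - age)
        Q = model.q_matrices([age + dt / 2.0], [female], [rural])[0]
        lam = -Q[state, state]
        if lam <= 0:
            age += dt
            continue
        t = rng.exponential(1.0 / lam)
        if t >= dt:
            age += dt
            continue
        age += t
        probs = Q[state].copy()
        probs[state] = 0.0
        probs = np.maximum(probs, 0.0)
        probs /= probs.sum()
        state = int(rng.choice(N_STATES, p=probs))
        events.append((age, state))
    return events


def simulate_states(
    model: IntensityModel,
    female: float,
    rural: float,
    entry_age: float,
    entry_state: int,
    snapshot_ages: Sequence[float],
    n: int,
    rng: np.random.Generator,
    micro_step: float = DEFAULT_MICRO_STEP,
    occupancy: bool = False,
) -> Tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """Vectorized simulation of many trajectories from one profile.

    Returns ``(states, death_ages, occupancy)``: ``states`` has shape
    (n, len(snapshot_ages)) with the state (death coded 3) at each snapshot
    age; ``death_ages`` is nan for survivors; ``occupancy`` (if requested)
    holds exact person-years spent in each living state up to the horizon,
    shape (n, 3).  The same micro-cell freezing as
    :func:`simulate_trajectory`; multiple transitions within a cell are
    resolved exactly.  Snapshot ages are snapped to the micro grid.
    """
    snapshot_ages = np.asarray(snapshot_ages, dtype=float)
    horizon = float(snapshot_ages.max())
    n_cells = int(round((horizon - entry_age) / micro_step))
    snap_cells = np.round((snapshot_ages - entry_age) / micro_step).astype(int)
    if np.any(np.abs(entry_age + snap_cells * micro_step - snapshot_ages) > 1e-6):
        logger.info("snapshot ages snapped to the %.3f-year simulation grid", micro_step)

    states = np.full(n, entry_state, dtype=np.int64)
    death_age = np.full(n, np.nan)
    occ = np.zeros((n, 3)) if occupancy else None
    snapshots = np.empty((n, len(snapshot_ages)), dtype=np.int64)
    if 0 in snap_cells:
        snapshots[:, snap_cells == 0] = entry_state

    for cell in range(n_cells):
        a = entry_age + cell * micro_step
        Q = model.q_matrices([a + micro_step / 2.0], [female], [rural])[0]
        lam_by_state = -np.diag(Q)
        jump = np.maximum(Q, 0.0)
        np.fill_diagonal(jump, 0.0)
        row_sums = jump.sum(axis=1, keepdims=True)
        jump_cdf = np.cumsum(
            np.divide(jump, row_sums, out=np.zeros_like(jump), where=row_sums > 0),
            axis=1,
        )
        remaining = np.full(n, micro_step)
        active = np.nonzero(states != DEATH)[0]
        while active.size:
            lam = lam_by_state[states[active]]
            movers_mask = np.zeros(active.size, dtype=bool)
            t = np.full(active.size, np.inf)
            pos = lam > 0
            t[pos] = rng.exponential(1.0, size=int(pos.sum())) / lam[pos]
            movers_mask = t < remaining[active]
            stay = active[~movers_mask]
            if occupancy and stay.size:
                live_stay = stay[states[stay] != DEATH]
                occ[live_stay, states[live_stay]] += remaining[live_stay]
            movers = active[movers_mask]
            if movers.size:
                if occupancy:
                    occ[movers, states[movers]] += t[movers_mask]
                remaining[movers] -= t[movers_mask]
                u = rng.random(movers.size)
                cdf = jump_cdf[states[movers]]
                new_states = (u[:, None] > cdf).sum(axis=1)
                states[movers] = new_states
                died = movers[new_states == DEATH]
                death_age[died] = a + (micro_step - remaining[died])
            active = movers[states[movers] != DEATH]
        hits = np.nonzero(snap_cells == cell + 1)[0]
        if hits.size:
            snapshots[:, hits] = states[:, None]
    return snapshots, death_age, occ


def sample_waves(
    trajectory: List[Tuple[float, int]],
    schedule: Sequence[float],
    dropout: float,
    missing_rates: Dict[str, float],
    covariates: CovariateVector,
    rng: np.random.Generator,
    subject_id: str = "s",
) -> Tuple[Optional[SubjectHistory], bool]:
    """Observe a trajectory at scheduled wave ages with dropout and
    item-level covariate missingness.

    Death is recorded exactly when it precedes the next scheduled contact of
    a subject still under follow-up; dropped-out subjects yield no further
    information (including deaths).  Returns ``(history, flagged)`` where
    ``flagged`` marks subjects with fewer than two information points
    (history ``None``), mirroring the exclusion of pre-first-follow-up
    dropouts.
    """
    event_ages = np.array([e[0] for e in trajectory])
    event_states = np.array([e[1] for e in trajectory])
    death_age = None
    if event_states[-1] == DEATH:
        death_age = float(event_ages[-1])

    obs_ages: List[float] = []
    obs_states: List[int] = []
    recorded_death: Optional[float] = None
    for w, wave_age in enumerate(schedule):
        # dropout first: a dropped-out subject yields no death report either,
        # keeping the censoring mechanism non-informative
        if w > 0 and rng.random() < dropout:
            break
        if death_age is not None and death_age <= wave_age:
            recorded_death = death_age
            break
        k = int(np.searchsorted(event_ages, wave_age + 1e-12) - 1)
        obs_ages.append(float(wave_age))
        obs_states.append(int(event_states[k]))

    n_info = len(obs_ages) + (1 if recorded_death is not None else 0)
    if len(obs_ages) == 0 or n_info < 2:
        return None, True

    cov_kwargs = covariates.asdict()
    for name, rate in missing_rates.items():
        if cov_kwargs.get(name) is not None and rng.random() < rate:
            cov_kwargs[name] = None
    history = SubjectHistory(
        id=subject_id,
        obs_ages=np.asarray(obs_ages),
        obs_states=np.asarray(obs_states),
        covariates=CovariateVector(**cov_kwargs),
        death_age=recorded_death,
    )
    return history, False


def _draw_categorical(rng: np.random.Generator, levels: Sequence[str],
                      probs: Sequence[float], size: int) -> np.ndarray:
    return rng.choice(np.asarray(levels, dtype=object), size=size, p=np.asarray(probs))


def generate(
    scenario: SimulationScenario,
    seed: Optional[int] = None,
    outdir: Optional[Path] = None,
    truth_trajectories: int = 20000,
    truth_index_age: float = 65.0,
    truth_max_age: float = 115.0,
) -> Tuple[List[SubjectHistory], Dict]:
    """Generate a cohort plus a ground-truth sidecar.

    The sidecar records the true parameters, the seed, exclusion counts and
    trajectory-averaged true life-table quantities (mean residual life and
    state occupancies at ``truth_index_age`` per stratum), the reference
    against which fitted life tables can be judged.  With ``outdir`` set,
    writes ``cohort.csv`` (long panel format) and ``truth.json``.
    """
    master = np.random.SeedSequence(seed)
    cov_rng, traj_rng, wave_rng, truth_rng = (
        np.random.default_rng(s) for s in master.spawn(4)
    )
    n = scenario.n
    lo, hi = scenario.entry_age_range
    entry_ages = cov_rng.uniform(lo, hi, size=n)
    sexes = np.where(cov_rng.random(n) < scenario.p_female, "female", "male")
    regions = np.where(cov_rng.random(n) < scenario.p_rural, "rural", "urban")
    other_covs = {
        name: _draw_categorical(cov_rng, list(freqs), list(freqs.values()), n)
        for name, freqs in scenario.covariate_freqs.items()
    }
    entry_states = np.empty(n, dtype=int)
    for i in range(n):
        probs = np.asarray(scenario.entry_state_probs[(sexes[i], regions[i])], dtype=float)
        entry_states[i] = cov_rng.choice(3, p=probs / probs.sum())

    horizon_offset = scenario.wave_offsets[-1] + 1e-9
    subjects: List[SubjectHistory] = []
    n_flagged = 0
    width = len(str(n))
    for i in range(n):
        female = float(sexes[i] == "female")
        rural = float(regions[i] == "rural")
        traj = simulate_trajectory(
            scenario.true_model, female, rural, entry_ages[i], int(entry_states[i]),
            horizon=entry_ages[i] + horizon_offset, rng=traj_rng,
            micro_step=scenario.micro_step,
        )
        cov = CovariateVector(
            age_at_entry=float(entry_ages[i]),
            sex=str(sexes[i]), region=str(regions[i]),
            **{k: str(v[i]) for k, v in other_covs.items()},
        )
        schedule = [entry_ages[i] + off for off in scenario.wave_offsets]
        history, flagged = sample_waves(
            traj, schedule, scenario.dropout, scenario.missing_rates, cov,
            wave_rng, subject_id=f"S{i:0{width}d}",
        )
        if flagged:
            n_flagged += 1
        else:
            subjects.append(history)

    truth_lifetable = {}
    for (sex, region), probs in scenario.entry_state_probs.items():
        female, rural = float(sex == "female"), float(region == "rural")
        probs = np.asarray(probs, dtype=float)
        probs = probs / probs.sum()
        init_states = truth_rng.choice(3, size=truth_trajectories, p=probs)
        occ_total = np.zeros(3)
        horizon = truth_max_age
        for state in range(3):
            m = int((init_states == state).sum())
            if m == 0:
                continue
            _, _, occ = simulate_states(
                scenario.true_model, female, rural, truth_index_age, state,
                [horizon], m, truth_rng, micro_step=scenario.micro_step,
                occupancy=True,
            )
            occ_total += occ.sum(axis=0)
        occ_mean = occ_total / truth_trajectories
        truth_lifetable[f"{region}_{sex}"] = {
            "index_age": truth_index_age,
            "TLE": float(occ_mean.sum()),
            "ND": float(occ_mean[0]),
            "MD": float(occ_mean[1]),
            "SD": float(occ_mean[2]),
            "n_trajectories": truth_trajectories,
        }

    truth = {
        "seed": seed,
        "n_requested": n,
        "n_kept": len(subjects),
        "n_flagged_for_exclusion": n_flagged,
        "true_params": scenario.true_model.asdict(),
        "transitions": [list(t) for t in scenario.true_model.spec.transitions],
        "age_form": scenario.true_model.spec.age_form,
        "wave_offsets": list(scenario.wave_offsets),
        "dropout": scenario.dropout,
        "true_lifetable": truth_lifetable,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_panel(subjects, outdir / "cohort.csv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    return subjects, truth
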