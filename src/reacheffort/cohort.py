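"""Synthetic subject cohorts and stochastic-observer experiment simulation.

Subjects are drawn from population normals over the effort/choice
parameters (alpha, beta, gamma), truncated to positivity.  Each simulated
observer plays the full adaptive staircase experiment: conditions are
interleaved uniformly at random among incomplete tracks, and each trial's
binary choice is a Bernoulli draw from the probit choice probability.  The
output is a tidy trial table (one row per binary choice) plus a
ground-truth sidecar of the generating parameters, kept separate so that
fitting code cannot accidentally consume it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effort import (
    PARAM_FLOOR,
    Exp1GenParams,
    ForcePair,
    SubjectParams,
    UtilityModel,
    choice_probability,
    generative_effort_exp1,
    utility,
)
from .staircase import (
    Condition,
    StaircaseState,
    init_staircase_pair,
    staircase_complete,
    update_staircase,
)

__all__ = [
    "PopulationParams",
    "Cohort",
    "draw_population",
    "simulate_choice",
    "run_experiment",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = [
    "subject_id", "experiment", "session", "condition_id", "staircase_id",
    "trial_index", "F_R_N", "F_T_N", "direction", "amplitude_mm",
    "duration_window_ms", "n_ref_repeats", "choice",
]


@dataclass(frozen=True)
class PopulationParams:
    """Hierarchical population means and SDs for (alpha, beta, gamma).

    Defaults describe a cohort with quadratic force dependence (mu_alpha=2),
    a sizeable zero-force effort offset and moderate choice noise; each
    default sits inside the plausible range for the task.
    """

    mu_alpha: float = 2.0
    sigma_alpha: float = 0.3
    mu_beta: float = 14.0
    sigma_beta: float = 5.0
    mu_gamma: float = 2.5
    sigma_gamma: float = 1.0

    def __post_init__(self) -> None:
        if min(self.sigma_alpha, self.sigma_beta, self.sigma_gamma) <= 0:
            raise ValueError("population SDs must be positive")


@dataclass
class Cohort:
    """Named subjects with their generating parameters."""

    subjects: dict[str, SubjectParams]
    seed: int
    exp1_params: dict[str, Exp1GenParams] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects)


def draw_population(pop: PopulationParams, n_subjects: int, seed: int,
                    exp1_coeffs: tuple[float, float] | None = None) -> Cohort:
    """Draw a reproducible cohort from the population normals.

    Draws are truncated at a small positive floor so every subject has a
    valid (alpha, beta, gamma).  When ``exp1_coeffs = (c_in, c_out)`` is
    given, matching single-movement generative parameters are attached.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    subjects: dict[str, SubjectParams] = {}
    exp1: dict[str, Exp1GenParams] = {}
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        alpha = max(rng.normal(pop.mu_alpha, pop.sigma_alpha), PARAM_FLOOR)
        beta = max(rng.normal(pop.mu_beta, pop.sigma_beta), PARAM_FLOOR)
        gamma = max(rng.normal(pop.mu_gamma, pop.sigma_gamma), PARAM_FLOOR)
        subjects[sid] = SubjectParams(alpha=alpha, beta=beta, gamma=gamma)
        if exp1_coeffs is not None:
            exp1[sid] = Exp1GenParams(alpha=alpha, beta=beta,
                                      c_in=exp1_coeffs[0], c_out=exp1_coeffs[1])
    return Cohort(subjects=subjects, seed=seed, exp1_params=exp1)


def simulate_choice(pair: ForcePair, p: SubjectParams,
                    model: UtilityModel | str, rng: np.random.Generator) -> str:
    """One Bernoulli choice: 'reference' with the probit probability."""
    prob_ref = choice_probability(pair, p, model)
    return "reference" if rng.random() < prob_ref else "test"


def _exp1_choice_probability(cond: Condition, f_test: float, p: SubjectParams,
                             g: Exp1GenParams, model: UtilityModel,
                             duration_of) -> float:
    """Probit choice for single-vs-single comparisons under the generative
    duration/direction-scaled effort."""
    from scipy.special import ndtr

    d_ref, d_test = duration_of(cond)
    dir_test = "outward" if cond.direction == "inward" else "inward"
    e_ref = generative_effort_exp1(cond.f_ref, d_ref, cond.direction, g)
    e_test = generative_effort_exp1(f_test, d_test, dir_test, g)
    du = utility(e_ref, model) - utility(e_test, model)
    return float(ndtr(du / p.gamma))


def _default_durations(cond: Condition) -> tuple[float, float]:
    """Representative movement durations (s) for reference and test movements.

    Uses duration-window midpoints; in the duration session the reference is
    the mid window and the test the condition's window, elsewhere both share
    the condition window.
    """
    mid = lambda w: 0.5 * (w[0] + w[1]) / 1000.0
    if cond.session == "duration":
        from .staircase import EXP1_DURATION_WINDOWS_MS
        return mid(EXP1_DURATION_WINDOWS_MS["mid"]), mid(cond.duration_window_ms)
    d = mid(cond.duration_window_ms)
    return d, d


def run_experiment(cohort: Cohort, design: list[Condition],
                   model: UtilityModel | str = UtilityModel.LOG_DIFFERENCE,
                   seed: int = 0) -> pd.DataFrame:
    """Play every subject through the full staircase experiment.

    For each subject, a staircase pair per condition runs to completion
    (7 inversions per track); trials are interleaved uniformly at random
    among incomplete tracks, mirroring the randomly interleaved condition
    presentation.  Returns the tidy trial table.
    """
    model = UtilityModel(model)
    rng = np.random.default_rng(seed)
    rows = []
    for sid, p in cohort.subjects.items():
        tracks: list[tuple[Condition, int, StaircaseState]] = []
        for cond in design:
            lo, hi = init_staircase_pair(cond)
            tracks.append((cond, 0, lo))
            tracks.append((cond, 1, hi))
        trial_index = 0
        active = [i for i in range(len(tracks))]
        while active:
            k = active[rng.integers(len(active))]
            cond, track_id, state = tracks[k]
            f_test = state.current_force
            if cond.experiment == 2 or cond.n_ref_repeats > 1:
                pair = ForcePair(f_ref=cond.f_ref, f_test=f_test,
                                 n_ref_repeats=cond.n_ref_repeats)
                choice = simulate_choice(pair, p, model, rng)
            else:
                g = cohort.exp1_params.get(sid) or Exp1GenParams(
                    alpha=p.alpha, beta=p.beta)
                prob_ref = _exp1_choice_probability(
                    cond, f_test, p, g, model, _default_durations)
                choice = "reference" if rng.random() < prob_ref else "test"
            new_state = update_staircase(state, choice)
            tracks[k] = (cond, track_id, new_state)
            rows.append({
                "subject_id": sid,
                "experiment": cond.experiment,
                "session": cond.session,
                "condition_id": cond.condition_id,
                "staircase_id": track_id,
                "trial_index": trial_index,
                "F_R_N": cond.f_ref,
                "F_T_N": f_test,
                "direction": cond.direction,
                "amplitude_mm": cond.amplitude_mm,
                "duration_window_ms": f"{cond.duration_window_ms[0]:g}-{cond.duration_window_ms[1]:g}",
                "n_ref_repeats": cond.n_ref_repeats,
                "choice": choice,
            })
            trial_index += 1
            if staircase_complete(new_state):
                active.remove(k)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def ground_truth_table(cohort: Cohort) -> pd.DataFrame:
    """Generating parameters per subject, for the sidecar file."""
    rows = [{"subject_id": sid, "alpha": p.alpha, "beta": p.beta, "gamma": p.gamma}
            for sid, p in cohort.subjects.items()]
    return pd.DataFrame(rows)
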