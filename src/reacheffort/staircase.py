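"""Adaptive staircase task engine for the binary effort-choice experiments.

Each task condition runs a pair of one-up one-down staircases over the test
movement's resistive force (step 2 N, one track starting at 0 N, the other
at 16 N to compensate manipulator hysteresis).  Choosing the reference
action decrements the next test force of that track; choosing the test
movement increments it.  Forces are clamped to [0, 16] N; staying at a
boundary for two consecutive trials counts as one inversion so that clamped
tracks still terminate.  A track is complete after 7 inversions, and the
average test force over all inversion trials of the pair estimates the
equivalent (isoeffort) force.

Two designs are provided: single-vs-single comparisons with amplitude or
duration manipulations (reference forces 6/10 N), and doubled-vs-single
comparisons at fixed kinematics (reference forces 0/3/6/9 N).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StaircaseError",
    "InsufficientDataError",
    "StaircaseState",
    "Condition",
    "TimingRule",
    "DEFAULT_STEP_N",
    "DEFAULT_BOUNDS_N",
    "DEFAULT_N_INVERSIONS",
    "init_staircase_pair",
    "update_staircase",
    "staircase_complete",
    "equivalent_force_from_inversions",
    "hold_duration",
    "experiment1_design",
    "experiment2_design",
    "EXP1_AMPLITUDES_MM",
    "EXP1_DURATION_WINDOWS_MS",
    "EXP2_REFERENCE_FORCES_N",
]

DEFAULT_STEP_N = 2.0
DEFAULT_BOUNDS_N = (0.0, 16.0)
DEFAULT_N_INVERSIONS = 7

# Single-movement sessions: three amplitudes at fixed duration window, or
# three duration windows at fixed amplitude; the middle level is the
# reference movement in each session.
EXP1_AMPLITUDES_MM = {"low": 120.0, "mid": 160.0, "high": 200.0}
EXP1_DURATION_WINDOWS_MS = {
    "low": (0.0, 800.0),
    "mid": (800.0, 1300.0),
    "high": (1300.0, 2000.0),
}
EXP1_AMPLITUDE_SESSION_WINDOW_MS = (800.0, 1250.0)
EXP1_REFERENCE_FORCES_N = (6.0, 10.0)
EXP2_REFERENCE_FORCES_N = (0.0, 3.0, 6.0, 9.0)
EXP2_AMPLITUDE_MM = 120.0
EXP2_DURATION_WINDOW_MS = (800.0, 1300.0)


class StaircaseError(RuntimeError):
    """Invalid staircase transition (e.g. updating a completed track)."""


class InsufficientDataError(ValueError):
    """Not enough inversion data to estimate an equivalent force."""


@dataclass(frozen=True)
class Condition:
    """One task condition (a staircase pair runs per condition)."""

    experiment: int
    session: str            # "amplitude" | "duration" | "none"
    f_ref: float            # reference movement force, N
    direction: str          # "inward" | "outward"
    test_level: str         # "low" | "high" | "none"
    amplitude_mm: float
    duration_window_ms: tuple[float, float]
    n_ref_repeats: int
    condition_id: str = ""

    def with_id(self, cid: str) -> "Condition":
        return replace(self, condition_id=cid)


@dataclass
class StaircaseState:
    """Mutable-on-copy state of one adaptive track.

    ``history`` records (presented force, choice) per trial;
    ``inversion_forces`` the test force at each inversion trial.
    """

    current_force: float
    step: float = DEFAULT_STEP_N
    bounds: tuple[float, float] = DEFAULT_BOUNDS_N
    last_move: str = "none"           # "up" | "down" | "none"
    inversion_count: int = 0
    boundary_streak: int = 0
    n_inversions_required: int = DEFAULT_N_INVERSIONS
    history: list = field(default_factory=list)
    inversion_forces: list = field(default_factory=list)

    def copy(self) -> "StaircaseState":
        s = replace(self)
        s.history = list(self.history)
        s.inversion_forces = list(self.inversion_forces)
        return s


def init_staircase_pair(condition: Condition,
                        step: float = DEFAULT_STEP_N,
                        bounds: tuple[float, float] = DEFAULT_BOUNDS_N,
                        n_inversions: int = DEFAULT_N_INVERSIONS,
                        ) -> tuple[StaircaseState, StaircaseState]:
    """Two fresh tracks, one at each force boundary (0 and 16 N)."""
    lo, hi = bounds
    mk = lambda f0: StaircaseState(current_force=f0, step=step, bounds=bounds,
                                   n_inversions_required=n_inversions)
    return mk(lo), mk(hi)


def staircase_complete(s: StaircaseState) -> bool:
    """A track terminates once it has accumulated 7 inversions."""
    return s.inversion_count >= s.n_inversions_required


def update_staircase(s: StaircaseState, choice: str) -> StaircaseState:
    """Apply one trial outcome and return the next track state.

    ``choice`` is the subject's pick: "reference" lowers the next test force
    by one step, "test" raises it.  The applied (post-clamp) move defines
    inversions: a direction change of the applied step counts one inversion
    at the current force; a force pinned at a boundary for two consecutive
    trials counts one inversion instead (never both for the same trial).
    """
    if staircase_complete(s):
        raise StaircaseError("staircase already complete")
    if choice not in ("reference", "test"):
        raise ValueError(f"choice must be 'reference' or 'test', got {choice!r}")

    out = s.copy()
    out.history.append((s.current_force, choice))

    lo, hi = s.bounds
    proposed = s.current_force + (s.step if choice == "test" else -s.step)
    new_force = min(max(proposed, lo), hi)
    moved = new_force != s.current_force

    if moved:
        out.boundary_streak = 0
        move = "up" if new_force > s.current_force else "down"
        if s.last_move != "none" and move != s.last_move:
            out.inversion_count += 1
            out.inversion_forces.append(s.current_force)
        out.last_move = move
    else:
        # clamped at a boundary: count the streak, one inversion per 2 trials
        out.boundary_streak = s.boundary_streak + 1
        if out.boundary_streak >= 2:
            out.inversion_count += 1
            out.inversion_forces.append(s.current_force)
            out.boundary_streak = 0

    out.current_force = new_force
    return out


def equivalent_force_from_inversions(*tracks: StaircaseState,
                                     skip_first: int = 0) -> float:
    """Mean test force over all inversion trials, pooled over a track pair.

    ``skip_first`` optionally discards the first inversions of each track
    (a common psychophysics practice); the default pools all of them.
    """
    forces: list[float] = []
    for t in tracks:
        forces.extend(t.inversion_forces[skip_first:])
    if not forces:
        raise InsufficientDataError("no staircase inversions recorded")
    return float(np.mean(forces))


@dataclass(frozen=True)
class TimingRule:
    """Per-session trial timing.

    Single-movement sessions hold the target for 100 + d_mmax - d_m ms so
    every subtrial lasts equally long within a session; the doubled-movement
    experiment instead pads every subtrial to a fixed 4,000 ms total.
    """

    d_mmax_ms: float = 2000.0
    hold_base_ms: float = 100.0
    exp2_total_ms: float = 4000.0


def hold_duration(d_m_ms: float, rule: TimingRule, experiment: int = 1) -> float:
    """Target-hold (experiment 1) or waiting (experiment 2) duration in ms."""
    if experiment == 1:
        if d_m_ms > rule.d_mmax_ms:
            raise ValueError(
                f"movement duration {d_m_ms} ms exceeds session maximum {rule.d_mmax_ms} ms")
        return rule.hold_base_ms + rule.d_mmax_ms - d_m_ms
    if experiment == 2:
        if d_m_ms >= rule.exp2_total_ms:
            raise ValueError("movement duration exceeds the fixed subtrial duration")
        return rule.exp2_total_ms - d_m_ms
    raise ValueError(f"unknown experiment {experiment!r}")


def subtrial_duration(d_m_ms: float, rule: TimingRule, experiment: int) -> float:
    """Total subtrial duration: movement plus hold/waiting time."""
    return d_m_ms + hold_duration(d_m_ms, rule, experiment)


def experiment1_design(session: str) -> list[Condition]:
    """Eight conditions: 2 reference forces x 2 directions x 2 test levels.

    In the amplitude session the reference movement has the middle amplitude
    (160 mm) and the test movement a low or high amplitude at a common
    duration window; the duration session swaps the roles.
    """
    if session not in ("amplitude", "duration"):
        raise ValueError(f"session must be 'amplitude' or 'duration', got {session!r}")
    conds = []
    for f_ref in EXP1_REFERENCE_FORCES_N:
        for direction in ("inward", "outward"):
            for level in ("low", "high"):
                if session == "amplitude":
                    amp = EXP1_AMPLITUDES_MM[level]
                    win = EXP1_AMPLITUDE_SESSION_WINDOW_MS
                else:
                    amp = EXP1_AMPLITUDES_MM["mid"]
                    win = EXP1_DURATION_WINDOWS_MS[level]
                cid = f"e1-{session}-F{f_ref:g}-{direction}-{level}"
                conds.append(Condition(
                    experiment=1, session=session, f_ref=f_ref,
                    direction=direction, test_level=level, amplitude_mm=amp,
                    duration_window_ms=win, n_ref_repeats=1, condition_id=cid))
    return conds


def experiment2_design() -> list[Condition]:
    """Eight conditions: 4 reference forces (0/3/6/9 N) x 2 directions.

    The reference action is a doubled movement; amplitudes and duration
    windows are fixed across conditions (120 mm, 800-1,300 ms).
    """
    conds = []
    for f_ref in EXP2_REFERENCE_FORCES_N:
        for direction in ("inward", "outward"):
            cid = f"e2-F{f_ref:g}-{direction}"
            conds.append(Condition(
                experiment=2, session="none", f_ref=f_ref, direction=direction,
                test_level="none", amplitude_mm=EXP2_AMPLITUDE_MM,
                duration_window_ms=EXP2_DURATION_WINDOW_MS, n_ref_repeats=2,
                condition_id=cid))
    return conds
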