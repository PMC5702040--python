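"""Track-based avoidance-response detection.

The detector replicates a turn-angle analysis of whale movement: tracks are
downsampled to 20 s (the pulse interval), headings computed, and maximal
runs of same-sign heading increments segmented into turns. A turn is a
potential avoidance response if it is >= 90 deg, ends during a session, and
is followed by persistent movement away from the ship's trackline (mean
absolute heading relative to the ship's course in [0, 100) deg). Its
significance is the empirical tail probability of the turn magnitude under
the distribution of same-direction turns in 4 h of baseline data, with a
Bonferroni-corrected level alpha / (number of tests on the experiment).
Feeding state is assigned from lunge events in the window from 10 min
before session start until response onset (or session end).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .tracks import Experiment, Session, heading_deg, wrap_angle_deg

STEP_S = 20.0
BASELINE_SPAN_S = 4 * 3600.0
MIN_PERSISTENCE_STEPS = 3
AWAY_REL_HEADING_MAX_DEG = 100.0
TURN_THRESHOLD_DEG = 90.0


def downsample_and_heading(
    track: pd.DataFrame, step_s: float = STEP_S
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a track to ``step_s`` and derive headings.

    Returns ``(times, headings)`` where ``headings[i]`` is the heading of
    movement over [times[i], times[i] + step_s], degrees clockwise from
    north; one fewer heading than resampled positions.
    """
    t = track["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("track needs at least two points")
    if np.min(np.diff(t)) > step_s + 1e-9:
        raise ValueError("track must be sampled at least as finely as step_s")
    grid = np.arange(t[0], t[-1] + 1e-9, step_s)
    if len(grid) < 2:
        raise ValueError("track too short to downsample")
    x = np.interp(grid, t, track["x_m"].to_numpy())
    y = np.interp(grid, t, track["y_m"].to_numpy())
    headings = heading_deg(np.diff(x), np.diff(y))
    return grid[:-1], headings


def relative_heading(whale_heading_deg, ship_course_deg):
    """Smallest absolute angular difference, degrees in [0, 180]."""
    return np.abs(wrap_angle_deg(np.asarray(whale_heading_deg, float) - ship_course_deg))


@dataclass(frozen=True)
class TurnSegment:
    """A maximal run of same-sign heading increments."""

    start_index: int  # heading index at which the turn begins
    end_index: int  # heading index at which the turn ends
    direction: str  # "clockwise" | "counterclockwise"
    magnitude_deg: float
    start_time_s: float | None = None
    end_time_s: float | None = None

    @property
    def signed_magnitude_deg(self) -> float:
        return self.magnitude_deg if self.direction == "clockwise" else -self.magnitude_deg


def segment_turns(
    headings: Sequence[float], times: Sequence[float] | None = None
) -> list[TurnSegment]:
    """Split a heading sequence into maximal same-sign turns.

    Heading increments are wrapped to (-180, 180]; zero increments break
    runs without forming turns. The magnitude is the cumulative unsigned
    heading change of the run.
    """
    h = np.asarray(headings, dtype=float)
    if h.size < 2:
        raise ValueError("need at least two headings")
    inc = wrap_angle_deg(np.diff(h))
    # dead-band against atan2 rounding jitter on held-heading segments
    inc[np.abs(inc) < 1e-9] = 0.0
    t = np.asarray(times, dtype=float) if times is not None else None
    turns: list[TurnSegment] = []
    i = 0
    while i < inc.size:
        s = np.sign(inc[i])
        if s == 0:
            i += 1
            continue
        j = i
        while j + 1 < inc.size and np.sign(inc[j + 1]) == s:
            j += 1
        mag = float(abs(inc[i : j + 1].sum()))
        turns.append(
            TurnSegment(
                start_index=i,
                end_index=j + 1,
                direction="clockwise" if s > 0 else "counterclockwise",
                magnitude_deg=mag,
                start_time_s=float(t[i]) if t is not None else None,
                end_time_s=float(t[j + 1]) if t is not None else None,
            )
        )
        i = j + 1
    return turns


def candidate_avoidance(
    turn: TurnSegment,
    session_window: tuple[float, float],
    post_turn_relative_headings: Sequence[float],
    min_persistence_steps: int = MIN_PERSISTENCE_STEPS,
    threshold_deg: float = TURN_THRESHOLD_DEG,
) -> bool:
    """Does a turn meet the potential-avoidance criteria?

    Magnitude >= 90 deg, turn end inside the session window, and mean
    post-turn heading relative to the ship course in [0, 100) deg over the
    persistence window (turn end to session end, at least
    ``min_persistence_steps`` steps).
    """
    if turn.magnitude_deg < threshold_deg:
        return False
    if turn.end_time_s is None or not (
        session_window[0] <= turn.end_time_s <= session_window[1]
    ):
        return False
    rel = np.asarray(post_turn_relative_headings, dtype=float)
    if rel.size == 0:
        warnings.warn("empty post-turn persistence window; not a candidate")
        return False
    if rel.size < min_persistence_steps:
        warnings.warn(
            f"persistence window has {rel.size} < {min_persistence_steps} steps"
        )
        return False
    return float(rel.mean()) < AWAY_REL_HEADING_MAX_DEG


def empirical_turn_p(turn_magnitude: float, baseline_turns: Sequence[float]) -> float:
    """Add-one empirical tail probability of a turn magnitude.

    p = (1 + #{baseline >= magnitude}) / (1 + n_baseline); the add-one
    convention avoids p = 0 with finite baseline samples.
    """
    base = np.asarray(baseline_turns, dtype=float)
    if base.size == 0:
        raise ValueError("no baseline turns to form the empirical null")
    return float((1 + np.sum(base >= turn_magnitude)) / (1 + base.size))


@dataclass(frozen=True)
class AvoidanceCall:
    """A candidate turn with its empirical-null decision."""

    turn: TurnSegment
    persistent_away: bool
    p_value: float
    alpha_corrected: float
    is_avoidance: bool
    onset_s: float
    session_type: str | None = None


def classify_avoidance(
    candidates: Sequence[tuple[TurnSegment, float]],
    n_tests_on_experiment: int,
    alpha: float = 0.05,
    session_types: Sequence[str] | None = None,
) -> list[AvoidanceCall]:
    """Bonferroni decision: avoidance iff p < alpha / n_tests."""
    if n_tests_on_experiment <= 0:
        raise ValueError("n_tests_on_experiment must be positive")
    if n_tests_on_experiment < len(candidates):
        raise ValueError("n_tests must cover all candidates tested")
    level = alpha / n_tests_on_experiment
    calls = []
    for k, (turn, p) in enumerate(candidates):
        calls.append(
            AvoidanceCall(
                turn=turn,
                persistent_away=True,
                p_value=p,
                alpha_corrected=level,
                is_avoidance=p < level,
                onset_s=turn.start_time_s,
                session_type=session_types[k] if session_types else None,
            )
        )
    return calls


@dataclass(frozen=True)
class FeedingState:
    state: str  # "feeding" | "non_feeding"
    window: tuple[float, float]


def assign_feeding_state(
    lunge_times: Sequence[float],
    session_window: tuple[float, float],
    onset_s: float | None = None,
) -> FeedingState:
    """Feeding iff >= 1 lunge from 10 min before session start until the
    response onset, or session end when no response was scored."""
    start, end = session_window
    hi = onset_s if onset_s is not None else end
    window = (start - 600.0, hi)
    lunges = np.asarray(lunge_times, dtype=float)
    feeding = bool(np.any((lunges >= window[0]) & (lunges <= window[1])))
    return FeedingState("feeding" if feeding else "non_feeding", window)


# ---------------------------------------------------------------------------
# experiment-level detection


def _baseline_turns(
    turns: list[TurnSegment],
    session: Session,
    exclude_windows: list[tuple[float, float]],
    span_s: float = BASELINE_SPAN_S,
) -> list[TurnSegment]:
    """Turns in the baseline period preceding a session.

    The baseline window extends ``span_s`` before session start; turns
    overlapping any experimental session window are excluded (baseline data
    are the pre-control period and inter-session gaps).
    """
    lo = session.start_s - span_s
    out = []
    for turn in turns:
        if turn.start_time_s is None:
            continue
        if not (lo <= turn.start_time_s and turn.end_time_s < session.start_s):
            continue
        if any(t0 - 1e-9 <= turn.end_time_s and turn.start_time_s <= t1 + 1e-9
               for t0, t1 in exclude_windows):
            continue
        out.append(turn)
    return out


def detect_experiment(
    exp: Experiment,
    alpha: float = 0.05,
    direction_matching: str = "match",
    min_persistence_steps: int = MIN_PERSISTENCE_STEPS,
) -> list[AvoidanceCall]:
    """Run avoidance detection over every session of an experiment.

    ``direction_matching`` selects the empirical null: ``"match"`` uses
    baseline turns of the candidate's rotational direction;
    ``"pooled_one_direction"`` always uses clockwise baseline turns (one
    direction only, reducing autocorrelation). The Bonferroni denominator
    is the number of candidate turns evaluated across all sessions of the
    experiment.
    """
    if direction_matching not in ("match", "pooled_one_direction"):
        raise ValueError(f"unknown direction_matching {direction_matching!r}")
    times, headings = downsample_and_heading(exp.whale_track)
    turns = segment_turns(headings, times)
    session_windows = [(s.start_s, s.end_s) for s in exp.sessions]

    candidates: list[tuple[TurnSegment, float]] = []
    stypes: list[str] = []
    for sess in exp.sessions:
        window = (sess.start_s, sess.end_s)
        course = sess.ship_course_deg
        for turn in turns:
            if turn.end_time_s is None or not (window[0] <= turn.end_time_s <= window[1]):
                continue
            if turn.magnitude_deg < TURN_THRESHOLD_DEG:
                continue
            post = headings[
                (times >= turn.end_time_s) & (times < sess.end_s)
            ]
            if not candidate_avoidance(
                turn, window, relative_heading(post, course), min_persistence_steps
            ):
                continue
            base = _baseline_turns(turns, sess, session_windows)
            if direction_matching == "match":
                base = [b for b in base if b.direction == turn.direction]
            else:
                base = [b for b in base if b.direction == "clockwise"]
            if not base:
                warnings.warn(
                    f"no baseline turns for session {sess.session_type}; candidate skipped"
                )
                continue
            p = empirical_turn_p(turn.magnitude_deg, [b.magnitude_deg for b in base])
            candidates.append((turn, p))
            stypes.append(sess.session_type)

    if not candidates:
        return []
    return classify_avoidance(candidates, len(candidates), alpha, stypes)


def calls_to_frame(calls: Sequence[AvoidanceCall], exp: Experiment) -> pd.DataFrame:
    """Tabulate avoidance calls with feeding state, one row per call."""
    rows = []
    for call in calls:
        sess = next(
            (s for s in exp.sessions if s.session_type == call.session_type), None
        )
        feeding = None
        if sess is not None:
            feeding = assign_feeding_state(
                sess.lunge_times_s,
                (sess.start_s, sess.end_s),
                call.onset_s if call.is_avoidance else None,
            ).state
        rows.append(
            {
                "whale_id": exp.whale_id,
                "session_type": call.session_type,
                "turn_start_s": call.turn.start_time_s,
                "turn_end_s": call.turn.end_time_s,
                "direction": call.turn.direction,
                "magnitude_deg": call.turn.magnitude_deg,
                "p_value": call.p_value,
                "alpha_corrected": call.alpha_corrected,
                "is_avoidance": call.is_avoidance,
                "feeding_state": feeding,
            }
        )
    return pd.DataFrame(rows)
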