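"""Synthetic whale tracks, ship intercept approaches and full experiments.

Tracks are pandas DataFrames with columns ``time_s, x_m, y_m, depth_m`` in a
local flat-earth east/north frame (metres; depth positive down). Headings are
degrees clockwise from north. The generator emulates the statistical
structure the downstream analysis assumes:

* baseline whale movement as a correlated random walk on a 20 s grid with
  wrapped-normal turn increments, a sinusoidal-plus-noise dive cycle and
  Poisson feeding-lunge times;
* avoidance responses as an instantaneous heading rotation at onset followed
  by a held heading at elevated horizontal speed (~1.3 m/s observed);
* the ship's straight intercept approach at 4.1 m/s, with each 10-minute
  session starting 1.25 km from the predicted whale intercept.

An experiment is a no-sonar control followed by two sonar sessions
(RampUp1+RampUp2 or RampUp1+FullPower), separated by at least one hour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .schedule import (
    SESSION_DURATION_S,
    TransmissionScheme,
    scheme_for_session,
)

SHIP_SPEED_MPS = 4.1
SESSION_START_RANGE_M = 1250.0
SOURCE_DEPTH_M = 50.0
STEP_INTERVAL_S = 20.0
BASELINE_DURATION_S = 4 * 3600.0
SESSION_GAP_S = 3600.0

TRACK_COLUMNS = ["time_s", "x_m", "y_m", "depth_m"]


def heading_deg(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Heading of displacement (east dx, north dy), degrees CW from north."""
    return np.degrees(np.arctan2(dx, dy)) % 360.0


def wrap_angle_deg(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-180, 180]."""
    return -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)


@dataclass(frozen=True)
class BaselineParams:
    """Parameters of the baseline (undisturbed) whale movement model.

    Defaults follow typical humpback-scale movement: ~1 m/s horizontal
    speed, directional travel (wrapped-normal heading increments, s.d.
    12 deg per 20 s step, under which large persistent turns are rare
    baseline events), shallow feeding dives cycling over ~5 minutes, and
    a feeding-lunge rate of 10 per hour.
    """

    step_interval_s: float = STEP_INTERVAL_S
    speed_mean_mps: float = 1.0
    speed_sd_mps: float = 0.3
    speed_min_mps: float = 0.05
    turn_sd_deg: float = 12.0
    dive_depth_m: float = 30.0
    dive_period_s: float = 300.0
    depth_noise_m: float = 2.0
    lunge_rate_per_h: float = 10.0

    def validate(self) -> None:
        for name in ("step_interval_s", "speed_mean_mps", "dive_depth_m", "dive_period_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("speed_sd_mps", "turn_sd_deg", "depth_noise_m", "lunge_rate_per_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def generate_baseline_track(
    params: BaselineParams,
    duration_s: float,
    seed: int | np.random.Generator,
    start_xy: tuple[float, float] = (0.0, 0.0),
    initial_heading_deg: float | None = None,
) -> pd.DataFrame:
    """Generate a baseline whale track as a correlated random walk.

    Positions are emitted on the ``step_interval_s`` grid from t=0 to
    ``duration_s`` inclusive. Heading increments are wrapped normal with
    s.d. ``turn_sd_deg``; per-step speeds are truncated normal. The dive
    profile is sinusoidal with additive noise, clipped at the surface.
    """
    params.validate()
    if duration_s < 2 * params.step_interval_s:
        raise ValueError("duration must cover at least two steps")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    times = np.arange(0.0, duration_s + 0.5 * params.step_interval_s, params.step_interval_s)
    n_steps = len(times) - 1
    h0 = rng.uniform(0.0, 360.0) if initial_heading_deg is None else initial_heading_deg
    increments = rng.normal(0.0, params.turn_sd_deg, size=n_steps)
    headings = (h0 + np.concatenate([[0.0], np.cumsum(increments[:-1])])) % 360.0
    speeds = np.clip(
        rng.normal(params.speed_mean_mps, params.speed_sd_mps, size=n_steps),
        params.speed_min_mps,
        None,
    )
    step_len = speeds * params.step_interval_s
    dx = step_len * np.sin(np.radians(headings))
    dy = step_len * np.cos(np.radians(headings))
    x = start_xy[0] + np.concatenate([[0.0], np.cumsum(dx)])
    y = start_xy[1] + np.concatenate([[0.0], np.cumsum(dy)])

    phase = rng.uniform(0.0, 2 * np.pi)
    depth = 0.5 * params.dive_depth_m * (1.0 - np.cos(2 * np.pi * times / params.dive_period_s + phase))
    depth = np.clip(depth + rng.normal(0.0, params.depth_noise_m, size=len(times)), 0.0, None)

    return pd.DataFrame({"time_s": times, "x_m": x, "y_m": y, "depth_m": depth})


def draw_lunge_times(
    track: pd.DataFrame, rate_per_h: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson feeding-lunge times over the track span, at depth > 0.5 m.

    Lunge detection upstream only reports events below 0.5 m depth, so
    candidate times falling in surface intervals are discarded.
    """
    t0, t1 = float(track["time_s"].iloc[0]), float(track["time_s"].iloc[-1])
    n = rng.poisson(rate_per_h * (t1 - t0) / 3600.0)
    times = np.sort(rng.uniform(t0, t1, size=n))
    depths = np.interp(times, track["time_s"], track["depth_m"])
    return times[depths > 0.5]


def track_heading_at(track: pd.DataFrame, time_s: float, step_s: float = STEP_INTERVAL_S) -> float:
    """Heading of the track over the step ending at ``time_s``."""
    t = track["time_s"].to_numpy()
    x0, y0 = (
        np.interp(time_s - step_s, t, track["x_m"]),
        np.interp(time_s - step_s, t, track["y_m"]),
    )
    x1, y1 = np.interp(time_s, t, track["x_m"]), np.interp(time_s, t, track["y_m"])
    return float(heading_deg(np.array(x1 - x0), np.array(y1 - y0)))


def inject_avoidance(
    track: pd.DataFrame,
    onset_s: float,
    turn_deg: float,
    speed_mps: float,
    away_heading_rule: str = "hold_turn",
    ship_course_deg: float | None = None,
    response_duration_s: float | None = None,
) -> pd.DataFrame:
    """Overwrite a track from ``onset_s`` with an avoidance response.

    The heading at onset is rotated by ``turn_deg`` (positive clockwise) and
    then held; horizontal speed is set to ``speed_mps``. With
    ``away_heading_rule="enforce_away"`` and a ship course, the rotation
    direction is flipped if the mirrored turn lands the held heading within
    [0, 100) deg of the ship course and the original does not, matching the
    persistence criterion of the avoidance detector. The response lasts
    ``response_duration_s`` (default: to the end of the track); afterwards
    the original relative displacements resume from the displaced position.
    """
    t = track["time_s"].to_numpy()
    if not (t[0] < onset_s < t[-1]):
        raise ValueError("onset_s must lie strictly inside the track span")
    if turn_deg == 0.0 and away_heading_rule == "hold_turn" and speed_mps is None:
        return track.copy()

    base_heading = track_heading_at(track, onset_s)
    new_heading = (base_heading + turn_deg) % 360.0
    if away_heading_rule == "enforce_away":
        if ship_course_deg is None:
            raise ValueError("enforce_away requires ship_course_deg")
        rel = abs(wrap_angle_deg(new_heading - ship_course_deg))
        alt = (base_heading - turn_deg) % 360.0
        rel_alt = abs(wrap_angle_deg(alt - ship_course_deg))
        if rel >= 100.0 and rel_alt < 100.0:
            new_heading = alt
    elif away_heading_rule != "hold_turn":
        raise ValueError(f"unknown away_heading_rule {away_heading_rule!r}")

    out = track.copy()
    idx = np.where(t > onset_s)[0]
    if idx.size == 0:
        return out
    end_s = t[-1] if response_duration_s is None else onset_s + response_duration_s
    x = out["x_m"].to_numpy().copy()
    y = out["y_m"].to_numpy().copy()
    # anchor: interpolated position at onset
    x_on = float(np.interp(onset_s, t, x))
    y_on = float(np.interp(onset_s, t, y))
    ux = math.sin(math.radians(new_heading))
    uy = math.cos(math.radians(new_heading))
    in_resp = idx[t[idx] <= end_s + 1e-9]
    for i in in_resp:
        d = speed_mps * (t[i] - onset_s)
        x[i] = x_on + d * ux
        y[i] = y_on + d * uy
    after = idx[t[idx] > end_s + 1e-9]
    if after.size:
        # resume original relative motion from the displaced endpoint
        j = in_resp[-1] if in_resp.size else int(np.searchsorted(t, onset_s))
        shift_x = x[j] - track["x_m"].iloc[j]
        shift_y = y[j] - track["y_m"].iloc[j]
        x[after] = track["x_m"].to_numpy()[after] + shift_x
        y[after] = track["y_m"].to_numpy()[after] + shift_y
    out["x_m"] = x
    out["y_m"] = y
    return out


@dataclass(frozen=True)
class InterceptPlan:
    course_deg: float
    session_start_s: float
    intercept_point: tuple[float, float]
    time_to_intercept_s: float
    feasible: bool


def estimate_velocity(fixes: pd.DataFrame, n_fixes: int = 3) -> np.ndarray:
    """Least-squares constant-velocity estimate from the last ``n_fixes``."""
    sub = fixes.tail(n_fixes)
    if len(sub) < 2:
        return np.zeros(2)
    t = sub["time_s"].to_numpy()
    A = np.column_stack([t - t[0], np.ones_like(t)])
    vx = np.linalg.lstsq(A, sub["x_m"].to_numpy(), rcond=None)[0][0]
    vy = np.linalg.lstsq(A, sub["y_m"].to_numpy(), rcond=None)[0][0]
    return np.array([vx, vy])


def plan_intercept(
    whale_position: Sequence[float],
    whale_velocity: Sequence[float],
    ship_position: Sequence[float],
    ship_speed_mps: float = SHIP_SPEED_MPS,
    start_range_m: float = SESSION_START_RANGE_M,
) -> InterceptPlan:
    """Solve the constant-velocity pursuit for the ship's straight approach.

    Finds the earliest time at which a ship sailing straight at
    ``ship_speed_mps`` from ``ship_position`` can meet a whale moving at
    constant ``whale_velocity`` from ``whale_position``; the session is
    scheduled to start when the ship is ``start_range_m`` from the intercept
    point. With no feasible intercept (whale as fast as the ship and
    diverging) the plan falls back to the closest-point-of-approach course
    toward the whale's predicted position and is flagged infeasible.
    """
    p = np.asarray(whale_position, dtype=float)
    v = np.asarray(whale_velocity, dtype=float)
    s = np.asarray(ship_position, dtype=float)
    d = p - s
    a = float(v @ v) - ship_speed_mps**2
    b = 2.0 * float(d @ v)
    c = float(d @ d)
    t_int: float | None = None
    if abs(a) < 1e-12:
        if abs(b) > 1e-12:
            t = -c / b
            t_int = t if t > 0 else None
    else:
        disc = b * b - 4 * a * c
        if disc >= 0:
            roots = [(-b - math.sqrt(disc)) / (2 * a), (-b + math.sqrt(disc)) / (2 * a)]
            pos = [r for r in roots if r > 1e-9]
            t_int = min(pos) if pos else None
    if t_int is None:
        # fall back: aim at the whale's position at the unimpeded transit time
        t_cpa = math.sqrt(c) / ship_speed_mps if c > 0 else 0.0
        target = p + v * t_cpa
        course = float(heading_deg(np.array(target[0] - s[0]), np.array(target[1] - s[1])))
        return InterceptPlan(course, 0.0, (float(target[0]), float(target[1])), t_cpa, False)
    target = p + v * t_int
    course = float(heading_deg(np.array(target[0] - s[0]), np.array(target[1] - s[1])))
    start = max(0.0, t_int - start_range_m / ship_speed_mps)
    return InterceptPlan(course, start, (float(target[0]), float(target[1])), float(t_int), True)


def make_ship_track(
    start_xy: Sequence[float],
    course_deg: float,
    start_s: float,
    duration_s: float = SESSION_DURATION_S,
    speed_mps: float = SHIP_SPEED_MPS,
    step_s: float = STEP_INTERVAL_S,
    source_depth_m: float = SOURCE_DEPTH_M,
) -> pd.DataFrame:
    """Straight constant-speed ship track over one session window."""
    times = np.arange(start_s, start_s + duration_s + 0.5 * step_s, step_s)
    d = speed_mps * (times - start_s)
    ux = math.sin(math.radians(course_deg))
    uy = math.cos(math.radians(course_deg))
    return pd.DataFrame(
        {
            "time_s": times,
            "x_m": start_xy[0] + d * ux,
            "y_m": start_xy[1] + d * uy,
            "depth_m": np.full_like(times, source_depth_m),
        }
    )


@dataclass
class Session:
    """One 10-minute experimental session of a whale."""

    session_type: str  # Control | RampUp1 | RampUp2 | FullPower
    start_s: float
    scheme: TransmissionScheme
    ship_track: pd.DataFrame
    group_id: str
    whale_id: str
    lunge_times_s: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def end_s(self) -> float:
        return self.start_s + SESSION_DURATION_S

    @property
    def ship_course_deg(self) -> float:
        dx = self.ship_track["x_m"].iloc[-1] - self.ship_track["x_m"].iloc[0]
        dy = self.ship_track["y_m"].iloc[-1] - self.ship_track["y_m"].iloc[0]
        return float(heading_deg(np.array(dx), np.array(dy)))


@dataclass
class Experiment:
    """A whale's full experiment: continuous track plus its sessions."""

    whale_id: str
    group_id: str
    whale_track: pd.DataFrame
    sessions: list[Session]
    lunge_times_s: np.ndarray
    injected_responses: list[dict] = field(default_factory=list)

    def whale_track_for(self, session: Session, pad_s: float = 0.0) -> pd.DataFrame:
        m = (self.whale_track["time_s"] >= session.start_s - pad_s) & (
            self.whale_track["time_s"] <= session.end_s + pad_s
        )
        return self.whale_track.loc[m].reset_index(drop=True)


DESIGNS = {
    "RampUp1+RampUp2": ["Control", "RampUp1", "RampUp2"],
    "RampUp1+FullPower": ["Control", "RampUp1", "FullPower"],
}


def make_experiment(
    seed: int,
    design: str = "RampUp1+RampUp2",
    respond_flags: Sequence[bool] = (False, False),
    feeding_flags: Sequence[bool] | None = None,
    params: BaselineParams | None = None,
    response_turn_deg: float = 135.0,
    response_speed_mps: float = 1.3,
    whale_id: str | None = None,
    group_id: str | None = None,
) -> Experiment:
    """Generate one synthetic controlled-exposure experiment.

    The whale receives 4 h of baseline movement, then a no-sonar control
    and two sonar sessions at >= 1 h spacing. ``respond_flags`` selects which
    of the two sonar sessions carries an injected avoidance response
    (onset mid-way through the ramp phase, turn magnitude
    ``response_turn_deg`` in the rotation direction that carries the whale
    away from the ship's trackline, held at ``response_speed_mps``).
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {sorted(DESIGNS)}")
    params = params or BaselineParams()
    rng = np.random.default_rng(seed)
    whale_id = whale_id or f"syn{seed:05d}a"
    group_id = group_id or f"g{seed:05d}"

    session_types = DESIGNS[design]
    starts = [
        BASELINE_DURATION_S + i * (SESSION_DURATION_S + SESSION_GAP_S)
        for i in range(len(session_types))
    ]
    total = starts[-1] + SESSION_DURATION_S + 600.0
    track = generate_baseline_track(params, total, rng)
    lunges = draw_lunge_times(track, params.lunge_rate_per_h, rng)

    sessions: list[Session] = []
    injected: list[dict] = []
    respond = [False] + list(respond_flags)
    for stype, start, do_respond in zip(session_types, starts, respond):
        fixes = track[track["time_s"] < start]
        vel = estimate_velocity(fixes)
        p_now = fixes.iloc[-1][["x_m", "y_m"]].to_numpy(dtype=float)
        # place the ship on a random approach azimuth, 1.25 km short of the
        # intercept of the whale's predicted constant-velocity course
        approach = rng.uniform(0.0, 360.0)
        t_i = SESSION_START_RANGE_M / SHIP_SPEED_MPS + 5.0
        intercept = p_now + vel * t_i
        ux = math.sin(math.radians(approach))
        uy = math.cos(math.radians(approach))
        ship_start = intercept - SESSION_START_RANGE_M * np.array([ux, uy])
        plan = plan_intercept(p_now, vel, ship_start)
        ship = make_ship_track(ship_start, plan.course_deg, start)
        sess = Session(stype, start, scheme_for_session(stype), ship, group_id, whale_id)
        if do_respond and stype != "Control":
            onset = start + float(rng.uniform(120.0, 240.0))
            course = sess.ship_course_deg
            base_h = track_heading_at(track, onset)
            # rotate in the direction whose held heading moves the whale away
            # from the ship's trackline; a whale already heading along the
            # ship's course cannot satisfy the away criterion with a fixed
            # turn magnitude, which is recorded in the compliance flag
            sign = float(rng.choice([-1.0, 1.0]))
            rel = abs(wrap_angle_deg(base_h + sign * response_turn_deg - course))
            rel_alt = abs(wrap_angle_deg(base_h - sign * response_turn_deg - course))
            if rel >= 100.0 and rel_alt < 100.0:
                sign, rel = -sign, rel_alt
            track = inject_avoidance(
                track,
                onset,
                sign * response_turn_deg,
                response_speed_mps,
                response_duration_s=sess.end_s - onset,
            )
            injected.append(
                {
                    "session_type": stype,
                    "onset_s": onset,
                    "turn_deg": sign * response_turn_deg,
                    "speed_mps": response_speed_mps,
                    "held_rel_heading_deg": rel,
                    "away_compliant": rel < 100.0,
                }
            )
        sessions.append(sess)

    if feeding_flags is not None:
        lunges = _impose_feeding(lunges, track, sessions, feeding_flags, rng)
    for sess in sessions:
        m = (lunges >= sess.start_s - 600.0) & (lunges <= sess.end_s)
        sess.lunge_times_s = lunges[m]
    return Experiment(whale_id, group_id, track, sessions, lunges, injected)


def _impose_feeding(
    lunges: np.ndarray,
    track: pd.DataFrame,
    sessions: list[Session],
    feeding_flags: Sequence[bool],
    rng: np.random.Generator,
) -> np.ndarray:
    """Force presence/absence of lunges around the two sonar sessions."""
    out = list(lunges)
    for sess, feed in zip(sessions[1:], feeding_flags):
        lo, hi = sess.start_s - 600.0, sess.end_s
        out = [t for t in out if not (lo <= t <= hi)]
        if feed:
            t = sess.start_s - 300.0
            depth = float(np.interp(t, track["time_s"], track["depth_m"]))
            if depth <= 0.5:  # nudge to a submerged instant
                sub = track[(track["time_s"] >= lo) & (track["time_s"] <= hi)]
                deep = sub[sub["depth_m"] > 0.5]
                t = float(deep["time_s"].iloc[0]) if len(deep) else t
            out.append(t)
    return np.sort(np.array(out))


# ---------------------------------------------------------------------------
# CSV / manifest I/O


def write_track_csv(track: pd.DataFrame, path: str | Path) -> None:
    track[TRACK_COLUMNS].to_csv(path, index=False)


def read_track_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV {path} missing columns {missing}")
    return df[TRACK_COLUMNS]


def write_experiment(exp: Experiment, outdir: str | Path) -> Path:
    """Write an experiment as track CSVs, scheme YAMLs and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_track_csv(exp.whale_track, outdir / f"{exp.whale_id}_whale.csv")
    manifest: dict = {
        "whale_id": exp.whale_id,
        "group_id": exp.group_id,
        "whale_track": f"{exp.whale_id}_whale.csv",
        "lunge_times_s": [float(t) for t in exp.lunge_times_s],
        "sessions": [],
    }
    for i, sess in enumerate(exp.sessions):
        ship_name = f"{exp.whale_id}_s{i}_ship.csv"
        scheme_name = f"{exp.whale_id}_s{i}_scheme.yaml"
        write_track_csv(sess.ship_track, outdir / ship_name)
        sess.scheme.to_yaml(outdir / scheme_name)
        manifest["sessions"].append(
            {
                "session_type": sess.session_type,
                "start_s": float(sess.start_s),
                "scheme": scheme_name,
                "ship_track": ship_name,
            }
        )
    path = outdir / f"{exp.whale_id}_manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def read_experiment(manifest_path: str | Path) -> Experiment:
    manifest_path = Path(manifest_path)
    payload = yaml.safe_load(manifest_path.read_text())
    root = manifest_path.parent
    whale_track = read_track_csv(root / payload["whale_track"])
    lunges = np.array(payload.get("lunge_times_s", []), dtype=float)
    sessions = []
    for s in payload["sessions"]:
        sess = Session(
            s["session_type"],
            float(s["start_s"]),
            TransmissionScheme.from_yaml(root / s["scheme"]),
            read_track_csv(root / s["ship_track"]),
            payload["group_id"],
            payload["whale_id"],
        )
        m = (lunges >= sess.start_s - 600.0) & (lunges <= sess.end_s)
        sess.lunge_times_s = lunges[m]
        sessions.append(sess)
    return Experiment(
        payload["whale_id"], payload["group_id"], whale_track, sessions, lunges
    )
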