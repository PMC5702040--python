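"""Per-pulse received levels and session risk indicators.

For each transmitted pulse the received sound pressure level and sound
exposure level follow

    SPL = SL - PL        SEL = SL_E - PL

with PL the propagation loss over the source-whale slant range. Session
risk indicators are the maximum SPL over pulses (SPL_max), the cumulative
sound exposure level SEL_cum = 10*log10(sum of single-pulse exposures
E = 10^(SEL/10)), and the minimum slant range R_min evaluated on the full
interpolated tracks at 1 s resolution (a proximity metric, not tied to
pulse times).

Propagation loss is pluggable: the shipped default is spherical spreading
(optionally with linear absorption); a range-by-depth grid read from CSV
with bilinear interpolation accommodates externally modelled fields.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .schedule import TransmissionScheme, build_full_power_scheme
from .tracks import SOURCE_DEPTH_M, Session

#: ramp-up sessions transmit 0.43 dB more total source energy than
#: full-power sessions; subtracted from ramp-up SEL_cum so protocol-level
#: differences reflect behaviour only
RAMPUP_SELCUM_ADJUST_DB = 0.43


def propagation_loss_spherical(
    range_m: np.ndarray | float, absorption_dB_per_km: float = 0.0
) -> np.ndarray | float:
    """Spherical-spreading loss 20*log10(r/1 m) plus linear absorption."""
    r = np.asarray(range_m, dtype=float)
    if np.any(r <= 0):
        raise ValueError("range must be positive")
    out = 20.0 * np.log10(r) + absorption_dB_per_km * r / 1000.0
    return float(out) if np.isscalar(range_m) else out


class SphericalSpreading:
    """Pluggable PL model: spherical spreading with optional absorption."""

    def __init__(self, absorption_dB_per_km: float = 0.0):
        self.absorption_dB_per_km = absorption_dB_per_km

    def __call__(self, range_m, depth_m=None):
        return propagation_loss_spherical(range_m, self.absorption_dB_per_km)


class GridPL:
    """Bilinear interpolation of an externally computed PL field.

    The CSV holds ``range_m, depth_m, PL_dB`` triples on a rectilinear
    range-by-depth grid (e.g. exported from a ray-trace run).
    """

    def __init__(self, ranges_m: np.ndarray, depths_m: np.ndarray, pl_dB: np.ndarray):
        self._interp = RegularGridInterpolator(
            (np.asarray(ranges_m, float), np.asarray(depths_m, float)),
            np.asarray(pl_dB, float),
            bounds_error=False,
            fill_value=None,
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "GridPL":
        df = pd.read_csv(path)
        piv = df.pivot(index="range_m", columns="depth_m", values="PL_dB")
        return cls(piv.index.to_numpy(), piv.columns.to_numpy(), piv.to_numpy())

    def __call__(self, range_m, depth_m):
        pts = np.column_stack(
            [np.atleast_1d(np.asarray(range_m, float)), np.atleast_1d(np.asarray(depth_m, float))]
        )
        out = self._interp(pts)
        return float(out[0]) if np.isscalar(range_m) else out


def slant_range(source: Sequence[float], whale: Sequence[float]) -> float:
    """Euclidean 3-D distance between source and whale (x, y, depth)."""
    d = np.asarray(source, dtype=float) - np.asarray(whale, dtype=float)
    r = float(np.sqrt(d @ d))
    if r == 0.0:
        raise ValueError("coincident source and whale positions (range 0)")
    return r


@dataclass(frozen=True)
class PulseExposure:
    """Received levels of one pulse at the whale."""

    index: int
    time_s: float
    slant_range_m: float
    PL: float
    SPL: float
    SEL: float

    @property
    def E(self) -> float:
        """Single-pulse sound exposure, µPa² s."""
        return 10.0 ** (self.SEL / 10.0)


@dataclass(frozen=True)
class RiskIndicators:
    """Session risk indicators; levels are None for no-sonar sessions."""

    SPL_max: float | None
    SEL_cum: float | None
    R_min: float
    session_type: str | None = None
    rampup_adjusted: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "SPL_max_dB": self.SPL_max,
                    "SEL_cum_dB": self.SEL_cum,
                    "R_min_m": self.R_min,
                    "session_type": self.session_type,
                    "rampup_adjusted": self.rampup_adjusted,
                },
                indent=2,
            )
        )


def _interp_track(track: pd.DataFrame, times: np.ndarray) -> tuple[np.ndarray, ...]:
    t = track["time_s"].to_numpy()
    return (
        np.interp(times, t, track["x_m"].to_numpy()),
        np.interp(times, t, track["y_m"].to_numpy()),
        np.interp(times, t, track["depth_m"].to_numpy()),
    )


def compute_exposure(
    scheme: TransmissionScheme,
    ship_track: pd.DataFrame,
    whale_track: pd.DataFrame,
    pl_model: Callable = None,
    source_depth_m: float = SOURCE_DEPTH_M,
    session_start_s: float | None = None,
    r_min_resolution_s: float = 1.0,
) -> tuple[list[PulseExposure], RiskIndicators]:
    """Received levels per pulse and the session risk indicators.

    Track positions are interpolated linearly to pulse times; the source
    sits at ``source_depth_m`` below the ship position. Pulse times in the
    scheme are relative to session start, taken as the first ship-track
    time unless given. R_min is evaluated on a 1 s grid over the overlap of
    the two tracks regardless of the pulse schedule.
    """
    pl_model = pl_model or SphericalSpreading()
    t0 = float(ship_track["time_s"].iloc[0]) if session_start_s is None else session_start_s
    pulse_times = scheme.times_s + t0

    span = (
        max(float(ship_track["time_s"].iloc[0]), float(whale_track["time_s"].iloc[0])),
        min(float(ship_track["time_s"].iloc[-1]), float(whale_track["time_s"].iloc[-1])),
    )
    for i, tp in enumerate(pulse_times):
        if not (span[0] - 1e-9 <= tp <= span[1] + 1e-9):
            raise ValueError(
                f"pulse {i} at t={tp:.1f} s outside the covered track span {span}"
            )

    exposures: list[PulseExposure] = []
    for i, (pulse, tp) in enumerate(zip(scheme.pulses, pulse_times)):
        sx, sy, _ = _interp_track(ship_track, np.array([tp]))
        wx, wy, wz = _interp_track(whale_track, np.array([tp]))
        r = slant_range((sx[0], sy[0], source_depth_m), (wx[0], wy[0], wz[0]))
        pl = float(pl_model(r, wz[0]))
        exposures.append(
            PulseExposure(i, float(tp), r, pl, pulse.SL - pl, pulse.SL_E - pl)
        )

    grid = np.arange(span[0], span[1] + 0.5 * r_min_resolution_s, r_min_resolution_s)
    sx, sy, _ = _interp_track(ship_track, grid)
    wx, wy, wz = _interp_track(whale_track, grid)
    ranges = np.sqrt((sx - wx) ** 2 + (sy - wy) ** 2 + (source_depth_m - wz) ** 2)
    r_min = float(np.min(ranges))

    if exposures:
        spl_max = max(e.SPL for e in exposures)
        sel_cum = 10.0 * np.log10(sum(e.E for e in exposures))
    else:
        spl_max = sel_cum = None
    return exposures, RiskIndicators(spl_max, sel_cum, r_min, scheme.name)


def exposures_to_frame(exposures: list[PulseExposure]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pulse": e.index,
                "time_s": e.time_s,
                "slant_range_m": e.slant_range_m,
                "PL_dB": e.PL,
                "SPL_dB": e.SPL,
                "SEL_dB": e.SEL,
            }
            for e in exposures
        ]
    )


def simulate_fullpower_outcome(
    session: Session,
    whale_track: pd.DataFrame,
    pl_model: Callable = None,
    source_depth_m: float = SOURCE_DEPTH_M,
) -> tuple[list[PulseExposure], RiskIndicators]:
    """Exposure the whale would have received under the full-power scheme.

    Applies the full-power transmission scheme to the observed ship and
    whale tracks of a no-sonar control session; behaviour is unchanged, so
    R_min equals the control's observed proximity.
    """
    exposures, ind = compute_exposure(
        build_full_power_scheme(),
        session.ship_track,
        whale_track,
        pl_model,
        source_depth_m,
        session_start_s=session.start_s,
    )
    return exposures, replace(ind, session_type="full_power")


def apply_bias_correction(
    modelled_levels: Sequence[float],
    measured_levels: Sequence[float] | None = None,
    fixed_offset: float | None = None,
) -> tuple[np.ndarray, float]:
    """Shift modelled levels by the mean measured-minus-modelled offset.

    Either paired ``measured_levels`` (from which the mean offset is
    estimated) or a ``fixed_offset`` must be given. Offsets are maintained
    separately per indicator by the caller (e.g. +5.8 dB for SPL_max and
    +2.2 dB for SEL_cum in the reference calibration).
    """
    modelled = np.asarray(modelled_levels, dtype=float)
    if (measured_levels is None) == (fixed_offset is None):
        raise ValueError("give exactly one of measured_levels or fixed_offset")
    if measured_levels is not None:
        measured = np.asarray(measured_levels, dtype=float)
        if measured.shape != modelled.shape:
            raise ValueError("measured and modelled levels must pair one-to-one")
        offset = float(np.mean(measured - modelled))
    else:
        offset = float(fixed_offset)
    return modelled + offset, offset


def adjust_rampup_selcum(indicators: RiskIndicators) -> RiskIndicators:
    """Subtract the 0.43 dB ramp-up source-energy surplus from SEL_cum.

    Idempotent per record: an already-adjusted record is returned unchanged,
    as is a non-ramp-up session (with a warning).
    """
    if indicators.session_type != "ramp_up":
        warnings.warn("SEL_cum adjustment applies to ramp-up sessions only; unchanged")
        return indicators
    if indicators.rampup_adjusted:
        warnings.warn("SEL_cum already adjusted; unchanged")
        return indicators
    if indicators.SEL_cum is None:
        return indicators
    return replace(
        indicators, SEL_cum=indicators.SEL_cum - RAMPUP_SELCUM_ADJUST_DB, rampup_adjusted=True
    )


def propagate_position_uncertainty(
    scheme: TransmissionScheme,
    ship_track: pd.DataFrame,
    whale_track: pd.DataFrame,
    horiz_sd_m: float,
    depth_sd_m: float = 1.0,
    n_draws: int = 100,
    seed: int | np.random.Generator = 0,
    pl_model: Callable = None,
    source_depth_m: float = SOURCE_DEPTH_M,
    session_start_s: float | None = None,
) -> dict:
    """Monte Carlo propagation of whale-position uncertainty.

    Each draw perturbs every whale track point by an isotropic horizontal
    normal (s.d. ``horiz_sd_m``) and a normal depth error (s.d.
    ``depth_sd_m``, the tag pressure-sensor precision, ~1 m), then
    recomputes SPL_max and SEL_cum. Returns per-indicator means and s.d.
    """
    if horiz_sd_m < 0 or depth_sd_m < 0:
        raise ValueError("standard deviations must be non-negative")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spl, sel = [], []
    n_pts = len(whale_track)
    for _ in range(n_draws):
        pert = whale_track.copy()
        pert["x_m"] = pert["x_m"] + rng.normal(0.0, horiz_sd_m, n_pts) if horiz_sd_m else pert["x_m"]
        pert["y_m"] = pert["y_m"] + rng.normal(0.0, horiz_sd_m, n_pts) if horiz_sd_m else pert["y_m"]
        if depth_sd_m:
            pert["depth_m"] = np.clip(pert["depth_m"] + rng.normal(0.0, depth_sd_m, n_pts), 0.0, None)
        _, ind = compute_exposure(
            scheme, ship_track, pert, pl_model, source_depth_m, session_start_s
        )
        spl.append(ind.SPL_max)
        sel.append(ind.SEL_cum)
    spl_a, sel_a = np.asarray(spl), np.asarray(sel)
    return {
        "SPL_max_mean": float(spl_a.mean()),
        "SPL_max_sd": float(spl_a.std(ddof=1)) if n_draws > 1 else 0.0,
        "SEL_cum_mean": float(sel_a.mean()),
        "SEL_cum_sd": float(sel_a.std(ddof=1)) if n_draws > 1 else 0.0,
        "n_draws": n_draws,
        "SPL_max_draws": spl_a,
        "SEL_cum_draws": sel_a,
    }
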