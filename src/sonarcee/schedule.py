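"""Sonar transmission schedules and source-level energetics.

A 10-minute experimental session uses one of three transmission schemes:

* ``ramp_up`` — pulses every 20 s for the whole session; the source level
  (SL, dB re. 1 µPa m) rises from 152 to 214 dB over the first 5 minutes
  (shortened 0.5 s pulses, effective duration T = 0.47 s), then stays at
  214 dB (1 s pulses, T = 0.93 s).
* ``full_power`` — silent first 5 minutes, then 214 dB pulses every 20 s.
* ``control`` — no transmissions; the ship approach alone.

Energy source level follows SL_E = SL + 10·log10(T / t0) with t0 = 1 s,
and scheme totals sum single-pulse energies in the linear domain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import yaml

#: reference duration for energy source level, seconds
T0_S = 1.0
#: pulse repetition interval, seconds
PULSE_INTERVAL_S = 20.0
#: session duration, seconds
SESSION_DURATION_S = 600.0
#: ramp phase duration, seconds
RAMP_PHASE_S = 300.0
#: source levels, dB re. 1 µPa m
SL_START_DB = 152.0
SL_FULL_DB = 214.0
#: effective pulse durations (gradual waveform onset/offset), seconds
T_RAMP_S = 0.47
T_FULL_S = 0.93
#: nominal pulse durations, seconds
DUR_RAMP_S = 0.5
DUR_FULL_S = 1.0

SCHEME_NAMES = ("ramp_up", "full_power", "control")


@dataclass(frozen=True)
class Pulse:
    """One sonar emission.

    Parameters
    ----------
    time_s : float
        Emission time in seconds from session start.
    SL : float
        Source level, dB re. 1 µPa m (mean-square pressure basis).
    nominal_duration_s : float
        Nominal pulse duration, s.
    effective_duration_s : float
        Effective duration T entering the energy source level, s.
    """

    time_s: float
    SL: float
    nominal_duration_s: float
    effective_duration_s: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.SL):
            raise ValueError("pulse SL must be finite")
        if not 0.0 < self.effective_duration_s <= self.nominal_duration_s:
            raise ValueError(
                "effective duration must satisfy 0 < T <= nominal duration"
            )
        if self.time_s < 0:
            raise ValueError("pulse time must be >= 0")

    @property
    def SL_E(self) -> float:
        """Energy source level of this pulse, dB re. 1 µPa² m² s."""
        return energy_source_level(self.SL, self.effective_duration_s)


@dataclass(frozen=True)
class TransmissionScheme:
    """An ordered pulse sequence forming one transmission scheme."""

    name: str
    pulses: tuple[Pulse, ...] = ()
    pulse_interval_s: float = PULSE_INTERVAL_S

    def __post_init__(self) -> None:
        if self.name not in SCHEME_NAMES:
            raise ValueError(f"unknown scheme name {self.name!r}")
        times = np.array([p.time_s for p in self.pulses])
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("pulse times must be strictly increasing")
        if times.size and (times[0] < 0 or times[-1] >= SESSION_DURATION_S):
            raise ValueError("pulses must lie in [0, 600) s")
        if self.name == "control" and times.size:
            raise ValueError("control scheme carries no pulses")

    def __len__(self) -> int:
        return len(self.pulses)

    @property
    def times_s(self) -> np.ndarray:
        return np.array([p.time_s for p in self.pulses])

    def to_records(self) -> list[dict]:
        return [
            {
                "time_s": float(p.time_s),
                "SL_dB": float(p.SL),
                "duration_s": float(p.nominal_duration_s),
                "effective_duration_s": float(p.effective_duration_s),
            }
            for p in self.pulses
        ]

    @classmethod
    def from_records(
        cls, name: str, records: Iterable[dict], pulse_interval_s: float = PULSE_INTERVAL_S
    ) -> "TransmissionScheme":
        pulses = tuple(
            Pulse(r["time_s"], r["SL_dB"], r["duration_s"], r["effective_duration_s"])
            for r in records
        )
        return cls(name, pulses, pulse_interval_s)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "pulse_interval_s": self.pulse_interval_s,
            "pulses": self.to_records(),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TransmissionScheme":
        payload = yaml.safe_load(Path(path).read_text())
        return cls.from_records(
            payload["name"], payload["pulses"], payload.get("pulse_interval_s", PULSE_INTERVAL_S)
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "pulse_interval_s": self.pulse_interval_s,
            "pulses": self.to_records(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TransmissionScheme":
        payload = json.loads(Path(path).read_text())
        return cls.from_records(
            payload["name"], payload["pulses"], payload.get("pulse_interval_s", PULSE_INTERVAL_S)
        )


def _linear_db_steps(n: int) -> np.ndarray:
    """Ramp source levels, linear in dB from 152 to 214 across n pulses."""
    return np.linspace(SL_START_DB, SL_FULL_DB, n)


def build_ramp_up_scheme(
    step_rule: Callable[[int], Sequence[float]] | str = "linear_db",
    include_t0_pulse: bool = True,
) -> TransmissionScheme:
    """Build the ramp-up scheme: 15 rising pulses then 15 full-power pulses.

    Parameters
    ----------
    step_rule : callable or {"linear_db", "constant"}
        Maps the number of ramp pulses to their source levels. The default
        interpolates linearly in dB from 152 to 214; ``"constant"`` holds
        214 dB throughout (degenerate, equals an extended full-power phase).
    include_t0_pulse : bool
        Whether a pulse is emitted at t = 0 s. With the default 20 s grid
        this yields pulses at t = 0, 20, …, 580 s.
    """
    ramp_times = np.arange(0.0, RAMP_PHASE_S, PULSE_INTERVAL_S)
    if not include_t0_pulse:
        ramp_times = ramp_times[1:]
    n_ramp = len(ramp_times)
    if step_rule == "linear_db":
        ramp_sls = _linear_db_steps(n_ramp)
    elif step_rule == "constant":
        ramp_sls = np.full(n_ramp, SL_FULL_DB)
    elif callable(step_rule):
        ramp_sls = np.asarray(step_rule(n_ramp), dtype=float)
        if ramp_sls.shape != (n_ramp,):
            raise ValueError("step_rule must return one SL per ramp pulse")
    else:
        raise ValueError(f"unknown step_rule {step_rule!r}")

    pulses = [
        Pulse(t, sl, DUR_RAMP_S, T_RAMP_S) for t, sl in zip(ramp_times, ramp_sls)
    ]
    full_times = np.arange(RAMP_PHASE_S, SESSION_DURATION_S, PULSE_INTERVAL_S)
    pulses += [Pulse(t, SL_FULL_DB, DUR_FULL_S, T_FULL_S) for t in full_times]
    return TransmissionScheme("ramp_up", tuple(pulses))


def build_full_power_scheme() -> TransmissionScheme:
    """Build the full-power scheme: silence, then 15 pulses at 214 dB."""
    times = np.arange(RAMP_PHASE_S, SESSION_DURATION_S, PULSE_INTERVAL_S)
    pulses = tuple(Pulse(t, SL_FULL_DB, DUR_FULL_S, T_FULL_S) for t in times)
    return TransmissionScheme("full_power", pulses)


def build_control_scheme() -> TransmissionScheme:
    """The no-sonar control: the ship approach with zero pulses."""
    return TransmissionScheme("control", ())


def energy_source_level(SL: float, T: float) -> float:
    """Energy source level SL_E = SL + 10·log10(T / t0), t0 = 1 s.

    Parameters
    ----------
    SL : float
        Source level on the mean-square pressure basis, dB re. 1 µPa m.
    T : float
        Effective pulse duration, s; must be positive.
    """
    if T <= 0:
        raise ValueError("effective duration T must be positive")
    return SL + 10.0 * np.log10(T / T0_S)


def total_energy_source_level(scheme: TransmissionScheme) -> float:
    """Total SL_E over all pulses: 10·log10(Σ 10^(SL_E,i / 10))."""
    if len(scheme) == 0:
        raise ValueError("scheme has no pulses; total SL_E undefined")
    sle = np.array([p.SL_E for p in scheme.pulses])
    return 10.0 * np.log10(np.sum(10.0 ** (sle / 10.0)))


def scheme_for_session(session_type: str) -> TransmissionScheme:
    """Map a session type (Control/RampUp1/RampUp2/FullPower) to its scheme."""
    if session_type in ("RampUp1", "RampUp2"):
        return build_ramp_up_scheme()
    if session_type == "FullPower":
        return build_full_power_scheme()
    if session_type == "Control":
        return build_control_scheme()
    raise ValueError(f"unknown session type {session_type!r}")
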