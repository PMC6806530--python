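"""Discrete-time growth-chamber control simulation.

Reproduces the controller's actuator logic, not chamber thermodynamics:
a PID loop drives a first-order temperature plant; CO2 uses bang-bang
dual actuation (solenoid adds, scrubber fan removes, never both in one
step) around a deadband; irrigation is an additive-only closed loop that
only ever opens a drip valve; dampers interlock with the vestibule
curtain while the rover images.

Real controller gains, deadbands, and actuator rates are unpublished;
the defaults here are tuned for stability at a 1-minute step and are all
overridable through :class:`ControllerConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ChamberState",
    "Setpoints",
    "ScheduleProgram",
    "ControllerConfig",
    "Disturbances",
    "ActuatorReport",
    "step",
    "run_schedule",
    "imaging_interlock",
    "DEFAULT_LED_MIX",
]

T_MIN, T_MAX = 10.0, 44.0
RH_MIN_SET = 40.0
CO2_MIN, CO2_MAX = 150.0, 5000.0

#: Default 7-channel LED mix as fractions of total output
#: (cool white, warm white, royal blue, green, red, deep red, far red).
DEFAULT_LED_MIX = (0.22, 0.22, 0.14, 0.06, 0.12, 0.16, 0.09)


class SetpointError(ValueError):
    pass


class ScheduleError(ValueError):
    pass


@dataclass(frozen=True)
class ChamberState:
    """Instantaneous chamber environment vector."""

    T: float = 22.0                  # degC
    RH: float = 60.0                 # %
    CO2: float = 400.0               # PPM
    VWC: float = 30.0                # % volumetric water content
    led_levels: tuple[float, ...] = DEFAULT_LED_MIX
    curtain: str = "down"            # "up" | "down"
    door: str = "closed"             # "open" | "closed"
    dampers: str = "open"            # "open" | "closed"

    def __post_init__(self) -> None:
        if not 0.0 <= self.VWC <= 100.0:
            raise SetpointError("VWC must be within [0, 100] %")
        if self.CO2 <= 0:
            raise SetpointError("CO2 must be > 0")
        if len(self.led_levels) != 7 or any(
                not 0.0 <= v <= 1.0 for v in self.led_levels):
            raise SetpointError("led_levels must be 7 fractions in [0, 1]")
        for name in ("curtain",):
            if self.curtain not in ("up", "down"):
                raise SetpointError("curtain must be 'up' or 'down'")
        if self.door not in ("open", "closed"):
            raise SetpointError("door must be 'open' or 'closed'")
        if self.dampers not in ("open", "closed"):
            raise SetpointError("dampers must be 'open' or 'closed'")


@dataclass(frozen=True)
class Setpoints:
    """Validated control targets within the chamber operating envelope."""

    T_set: float = 25.0
    RH_set: float = 60.0
    CO2_set: float = 400.0
    VWC_set: float = 30.0
    led_schedule: tuple[float, ...] = DEFAULT_LED_MIX

    def __post_init__(self) -> None:
        if not T_MIN <= self.T_set <= T_MAX:
            raise SetpointError(
                f"T_set {self.T_set} outside [{T_MIN}, {T_MAX}] degC")
        if not RH_MIN_SET <= self.RH_set <= 100.0:
            raise SetpointError(
                f"RH_set {self.RH_set} outside [{RH_MIN_SET}, 100] % "
                "(controllable down to 40% between 15 and 30 degC)")
        if not CO2_MIN <= self.CO2_set <= CO2_MAX:
            raise SetpointError(
                f"CO2_set {self.CO2_set} outside [{CO2_MIN}, {CO2_MAX}] PPM")
        if not 0.0 <= self.VWC_set <= 100.0:
            raise SetpointError("VWC_set must be within [0, 100] %")
        if len(self.led_schedule) != 7 or any(
                not 0.0 <= v <= 1.0 for v in self.led_schedule):
            raise SetpointError("led_schedule must be 7 fractions in [0, 1]")

    def patched(self, patch: Mapping) -> "Setpoints":
        d = {
            "T_set": self.T_set, "RH_set": self.RH_set,
            "CO2_set": self.CO2_set, "VWC_set": self.VWC_set,
            "led_schedule": self.led_schedule,
        }
        d.update(patch)
        if "led_schedule" in d:
            d["led_schedule"] = tuple(d["led_schedule"])
        return Setpoints(**d)


@dataclass(frozen=True)
class ControllerConfig:
    # PID gains for the temperature loop, per minute
    kp: float = 0.3
    ki: float = 0.02
    kd: float = 0.0
    u_max_c_per_min: float = 2.0
    co2_deadband_ppm: float = 25.0
    co2_add_ppm_per_min: float = 40.0      # solenoid
    co2_remove_ppm_per_min: float = 20.0   # scrubber fan, deliberately slower
    vwc_add_pct_per_min: float = 0.5
    rh_rate_pct_per_min: float = 1.0


@dataclass(frozen=True)
class Disturbances:
    """Per-minute drift rates applied before control action."""

    co2_drawdown_ppm_per_min: float = 0.0     # plant photosynthetic draw
    evapotranspiration_pct_per_min: float = 0.0
    thermal_leak_per_min: float = 0.0          # fractional pull toward ambient
    ambient_T: float = 20.0


@dataclass(frozen=True)
class PIDState:
    integral: float = 0.0
    prev_error: float | None = None


@dataclass(frozen=True)
class ActuatorReport:
    heater_cmd_c_per_min: float
    co2_solenoid: bool
    co2_fan: bool
    drip_valve: bool
    water_flux_pct: float        # controller-attributed, always >= 0
    pid: PIDState


def step(
    state: ChamberState,
    sp: Setpoints,
    dt_min: float,
    disturbances: Disturbances | None = None,
    config: ControllerConfig | None = None,
    pid: PIDState | None = None,
) -> tuple[ChamberState, ActuatorReport]:
    """Advance the chamber one control step of ``dt_min`` minutes.

    Setpoints are validated at construction; disturbances (plant CO2
    draw-down, evapotranspiration, thermal leakage toward ambient) apply
    before the actuators respond.
    """
    if dt_min <= 0:
        raise ValueError("dt must be > 0")
    dist = disturbances or Disturbances()
    cfg = config or ControllerConfig()
    pid = pid or PIDState()

    # --- temperature: PID on a first-order plant
    T = state.T + dt_min * dist.thermal_leak_per_min * (dist.ambient_T - state.T)
    err = sp.T_set - T
    integral = pid.integral + err * dt_min
    deriv = 0.0 if pid.prev_error is None else (err - pid.prev_error) / dt_min
    u = cfg.kp * err + cfg.ki * integral + cfg.kd * deriv
    u = float(np.clip(u, -cfg.u_max_c_per_min, cfg.u_max_c_per_min))
    T = float(np.clip(T + u * dt_min, T_MIN, T_MAX))

    # --- CO2: solenoid adds, scrubber fan removes; mutually exclusive
    co2 = max(state.CO2 - dist.co2_drawdown_ppm_per_min * dt_min, 1.0)
    solenoid = fan = False
    if co2 < sp.CO2_set - cfg.co2_deadband_ppm:
        solenoid = True
        co2 += min(cfg.co2_add_ppm_per_min * dt_min, sp.CO2_set - co2)
    elif co2 > sp.CO2_set + cfg.co2_deadband_ppm:
        fan = True
        co2 -= min(cfg.co2_remove_ppm_per_min * dt_min, co2 - sp.CO2_set)

    # --- irrigation: additive-only; valve open iff below setpoint
    vwc = max(state.VWC - dist.evapotranspiration_pct_per_min * dt_min, 0.0)
    valve = vwc < sp.VWC_set
    flux = min(cfg.vwc_add_pct_per_min * dt_min, sp.VWC_set - vwc) if valve else 0.0
    vwc = min(vwc + flux, 100.0)

    # --- humidity: rate-limited tracking within sensor bounds
    rh_delta = float(np.clip(sp.RH_set - state.RH,
                             -cfg.rh_rate_pct_per_min * dt_min,
                             cfg.rh_rate_pct_per_min * dt_min))
    rh = float(np.clip(state.RH + rh_delta, 0.0, 100.0))

    nxt = replace(state, T=T, RH=rh, CO2=co2, VWC=vwc,
                  led_levels=tuple(sp.led_schedule))
    report = ActuatorReport(
        heater_cmd_c_per_min=u,
        co2_solenoid=solenoid,
        co2_fan=fan,
        drip_valve=valve,
        water_flux_pct=flux,
        pid=PIDState(integral=integral, prev_error=err),
    )
    return nxt, report


def imaging_interlock(state: ChamberState, rover_event: str) -> ChamberState:
    """Damper/curtain interlock while the rover images the chamber.

    Opening the curtain closes the airflow dampers (to stop leaf
    flutter); closing the curtain reopens them.  Idempotent.
    """
    if rover_event == "curtain_open":
        return replace(state, curtain="up", dampers="closed")
    if rover_event == "curtain_close":
        return replace(state, curtain="down", dampers="open")
    raise ValueError(f"unknown rover event {rover_event!r}")


@dataclass(frozen=True)
class ScheduleProgram:
    """Per-chamber 24 h schedule of setpoint patches.

    ``events`` are (clock hour in [0, 24), setpoint patch) pairs;
    ``photoperiod_offset_h`` shifts every event so different chambers run
    the same virtual day at staggered wall-clock times.
    """

    events: tuple[tuple[float, Mapping], ...] = ()
    photoperiod_offset_h: float = 0.0
    base: Setpoints = field(default_factory=Setpoints)

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(not 0.0 <= t < 24.0 for t in times):
            raise ScheduleError("event times must lie within [0, 24) h")
        if times != sorted(times):
            raise ScheduleError("events must be time-ordered")
        seen: dict[float, dict] = {}
        for t, patch in self.events:
            prev = seen.setdefault(t, {})
            for key, val in patch.items():
                if key in prev and prev[key] != val:
                    raise ScheduleError(
                        f"conflicting patches for {key!r} at t={t} h")
                prev[key] = val


def run_schedule(
    programs: Mapping[str, ScheduleProgram],
    horizon_h: float,
    dt_min: float = 1.0,
    seed: int = 0,
    initial: Mapping[str, ChamberState] | None = None,
    disturbances: Disturbances | None = None,
    config: ControllerConfig | None = None,
) -> tuple[dict[str, pd.DataFrame], list[dict]]:
    """Simulate several chambers over a horizon under their schedules.

    Returns per-chamber trace frames (one row per step with setpoints,
    process values and digital actuator states, mirroring a per-minute
    controller log) and a combined event log.  Deterministic for fixed
    ``(programs, seed)``.
    """
    if horizon_h <= 0:
        raise ScheduleError("horizon must be > 0")
    initial = dict(initial or {})
    # seed reserved for stochastic disturbances; the default pipeline is
    # noise-free but the stream is created so traces stay reproducible
    # when noise is configured.
    np.random.default_rng(seed)

    traces: dict[str, pd.DataFrame] = {}
    event_log: list[dict] = []
    n_steps = int(round(horizon_h * 60.0 / dt_min))

    for name, prog in programs.items():
        state = initial.get(name, ChamberState())
        sp = prog.base
        pid = PIDState()
        rows = []
        for i in range(n_steps):
            t_min = i * dt_min
            clock_h = (t_min / 60.0) % 24.0
            prev_clock = ((t_min - dt_min) / 60.0) % 24.0 if i else None
            for ev_time, patch in prog.events:
                shifted = (ev_time + prog.photoperiod_offset_h) % 24.0
                if _fires(prev_clock, clock_h, shifted, i):
                    sp = sp.patched(patch)
                    event_log.append({
                        "chamber": name,
                        "t_hours": t_min / 60.0,
                        "clock_h": shifted,
                        "patch": dict(patch),
                    })
            state, rep = step(state, sp, dt_min, disturbances, config, pid)
            pid = rep.pid
            rows.append({
                "t_hours": (i + 1) * dt_min / 60.0,
                "T": state.T, "RH": state.RH, "CO2": state.CO2,
                "VWC": state.VWC,
                "T_set": sp.T_set, "RH_set": sp.RH_set,
                "CO2_set": sp.CO2_set, "VWC_set": sp.VWC_set,
                "heater_cmd": rep.heater_cmd_c_per_min,
                "co2_solenoid": rep.co2_solenoid,
                "co2_fan": rep.co2_fan,
                "drip_valve": rep.drip_valve,
                "water_flux": rep.water_flux_pct,
                "curtain": state.curtain,
                "dampers": state.dampers,
            })
        traces[name] = pd.DataFrame(rows)
    event_log.sort(key=lambda e: (e["t_hours"], e["chamber"]))
    return traces, event_log


def _fires(prev_clock: float | None, clock: float, ev: float, i: int) -> bool:
    """Did the clock cross the event time during this step?"""
    if prev_clock is None:
        return ev <= clock if i == 0 else False
    if prev_clock < clock:
        return prev_clock < ev <= clock
    return ev > prev_clock or ev <= clock      # midnight wrap
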