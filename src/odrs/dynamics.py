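"""Dynamic model of one pneumatic injection cycle.

The cycle has two mechanical regimes, separated by the needle piston hitting
its stop ring:

``INSERTING``
    The control valve opens and gas flows from the reservoir into the lower
    fluid compartment.  The antidote is incompressible, so fluid-piston
    motion is rigidly geared to needle-piston motion by the area ratio
    ``A_fluid / A_needle``; the coupled assembly (chassis mass, spring and
    dashpot to the chassis, membrane/tissue resistance at the needle tip)
    accelerates under the net pneumatic force.  No drug flows through the
    needle in this regime.

``INFUSING``
    The stop ring fixes the needle assembly at full stroke (full 8 mm
    insertion).  Further fluid-piston travel forces drug through the needle;
    laminar Hagen-Poiseuille flow gives ``Q = (P_fluid - P_tissue) / R`` with
    ``R = 8 mu L / (pi r^4)``.  The regime is viscous-dominated, so piston
    inertia is neglected and the piston velocity is slaved to the flow.

Gas is treated as isothermal and ideal; each compartment's inventory is
tracked as a pressure-volume product (Pa*m^3), which Boyle's law keeps
constant under expansion and makes conservation across the valve exact by
construction.  The valve is a linear conductance: the volumetric flow is
``C_v * (P_upstream - P_downstream)`` metered at upstream pressure.

Integration uses LSODA with root-finding event detection for the phase
switch, dose completion and reservoir exhaustion; trajectories are exported
on a 1 ms grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .geometry import ATM_PA, DeviceConfig, DomainError, validate

__all__ = [
    "Phase",
    "DeviceState",
    "Trajectory",
    "IntegrationError",
    "initial_state",
    "needle_resistance",
    "tissue_force",
    "derivatives",
    "simulate_cycle",
    "insertion_depth",
]

_RTOL = 1e-8
_ATOL = 1e-10
_OUTPUT_DT = 1e-3  # s


class Phase(str, Enum):
    READY = "READY"
    INSERTING = "INSERTING"
    INFUSING = "INFUSING"
    DONE = "DONE"


class IntegrationError(RuntimeError):
    """The ODE solver failed or the state became non-finite."""


@dataclass(frozen=True)
class DeviceState:
    """Instantaneous mechanical state of the injector (SI units)."""

    t: float = 0.0
    x_main: float = 0.0        # fluid-piston position, m
    v_main: float = 0.0        # m/s
    x_needle: float = 0.0      # injection-piston travel from stow, m
    v_needle: float = 0.0      # m/s
    pv_lower: float = 0.0      # gas inventory of lower compartment, Pa*m^3
    pv_reservoir: float = 0.0  # gas inventory of reservoir, Pa*m^3
    v_injected: float = 0.0    # cumulative injected volume, m^3
    phase: Phase = Phase.READY

    def replace(self, **changes) -> "DeviceState":
        return replace(self, **changes)


def initial_state(config: DeviceConfig) -> DeviceState:
    """READY state: piston at its initial displacement, lower compartment at
    the fluid-side initial pressure, reservoir fully charged."""
    validate(config)
    x0 = config.fluid_piston_initial_displacement_m
    v_lower = config.fluid_piston_area_m2 * x0 + config.dead_volume_m3
    return DeviceState(
        x_main=x0,
        pv_lower=config.fluid_initial_pressure_pa * v_lower,
        pv_reservoir=config.gas_initial_pressure_pa * config.gas_reservoir_volume_m3,
        phase=Phase.READY,
    )


def needle_resistance(config: DeviceConfig) -> float:
    """Hydraulic resistance of the hypodermic needle, Pa*s/m^3.

    Hagen-Poiseuille: ``R = 8 mu L / (pi r^4)`` with dynamic viscosity
    ``mu = nu * rho``.  For the 30-gauge, 8 mm needle with 0.6 mm bore this
    is ~1.64e9 Pa*s/m^3.
    """
    r = config.needle_radius_m
    if r <= 0:
        raise DomainError(f"needle radius must be positive, got {r!r}")
    mu = config.dynamic_viscosity_pa_s
    return 8.0 * mu * config.needle_length_m / (math.pi * r**4)


def tissue_force(depth: float, velocity: float, config: DeviceConfig) -> float:
    """Resistance at the needle tip as a function of piston travel, N.

    ``depth`` is the needle-piston travel from the stowed position (m).
    While the tip crosses the protective membrane (travel below the membrane
    standoff) the resistance is a puncture bump peaking at
    ``puncture_force``; past the membrane the tip is in tissue and feels
    elastic (``stiffness``) plus viscous (``damping``) resistance.  The bump
    is shaped as a half-sine so the force is zero at first contact and
    continuous at membrane breakthrough.
    """
    if depth < 0:
        raise DomainError(f"needle depth must be non-negative, got {depth!r}")
    if depth == 0.0:
        return 0.0
    p = config.tissue_force_params
    s = config.membrane_standoff_m
    force = 0.0
    if s > 0 and depth < s:
        force += p.puncture_force * math.sin(math.pi * depth / s)
    force += p.stiffness * max(0.0, depth - s)
    force += p.damping * max(0.0, velocity)
    return force


def insertion_depth(state: DeviceState, config: DeviceConfig) -> float:
    """Needle penetration into tissue, mm.

    Piston travel minus the membrane standoff, floored at zero and capped at
    the needle length (the tip cannot insert past its own length).
    """
    depth_m = max(0.0, state.x_needle - config.membrane_standoff_m)
    return min(depth_m, config.needle_length_m) / 1e-3


# ----------------------------------------------------------------------
# right-hand sides
# ----------------------------------------------------------------------


def _valve_pv_flow(p_res: float, p_low: float, conductance: float) -> float:
    """PV transfer rate through the valve, Pa*m^3/s (positive into the lower
    compartment).  Volumetric flow C_v*dP metered at upstream pressure."""
    if p_res >= p_low:
        return conductance * (p_res - p_low) * p_res
    return -conductance * (p_low - p_res) * p_low


def _lower_pressure(x_main: float, pv_lower: float, config: DeviceConfig) -> float:
    return pv_lower / (config.fluid_piston_area_m2 * x_main + config.dead_volume_m3)


def _inserting_rhs(t, y, config: DeviceConfig, x_seg0: float, xn_seg0: float, valve_open: bool):
    x, v, pvl, pvr, _ = y
    a_f = config.fluid_piston_area_m2
    ratio = config.coupling_ratio
    p_low = _lower_pressure(x, pvl, config)

    xn = xn_seg0 + ratio * (x - x_seg0)
    vn = ratio * v
    resist = (
        config.spring_constant * xn
        + config.dashpot_coefficient * vn
        + tissue_force(max(0.0, xn), vn, config)
    )
    f_net = a_f * (p_low - ATM_PA) - ratio * resist
    acc = f_net / config.chassis_mass_kg
    dx = v
    # one-sided stop at the stowed position: the assembly cannot retract
    # below its starting point
    if x <= x_seg0 and v <= 0.0:
        dx = max(0.0, v)
        acc = max(0.0, acc)

    flow = _valve_pv_flow(pvr / config.gas_reservoir_volume_m3, p_low,
                          config.valve_conductance) if valve_open else 0.0
    return [dx, acc, flow, -flow, 0.0]


def _infusing_rhs(t, y, config: DeviceConfig, resistance: float, valve_open: bool):
    x, _, pvl, pvr, _ = y
    a_f = config.fluid_piston_area_m2
    p_low = _lower_pressure(x, pvl, config)
    dp = p_low - (ATM_PA + config.subcutaneous_pressure_pa)
    q = max(0.0, dp) / resistance  # tissue does not flow back through the needle
    flow = _valve_pv_flow(pvr / config.gas_reservoir_volume_m3, p_low,
                          config.valve_conductance) if valve_open else 0.0
    return [q / a_f, 0.0, flow, -flow, q]


def derivatives(state: DeviceState, config: DeviceConfig, valve_open: bool) -> dict:
    """Time derivatives of a :class:`DeviceState` under the phase dynamics.

    Returns a dict with keys ``x_main, v_main, x_needle, v_needle, pv_lower,
    pv_reservoir, v_injected``.  READY (valve closed) and DONE states are
    equilibria with all derivatives zero.
    """
    values = [state.x_main, state.v_main, state.pv_lower, state.pv_reservoir,
              state.v_injected]
    if not all(math.isfinite(v) for v in values):
        raise IntegrationError(f"non-finite state encountered: {state!r}")

    zeros = dict.fromkeys(
        ("x_main", "v_main", "x_needle", "v_needle", "pv_lower", "pv_reservoir",
         "v_injected"), 0.0)
    if state.phase in (Phase.DONE,) or (state.phase is Phase.READY and not valve_open):
        return zeros

    y = [state.x_main, state.v_main, state.pv_lower, state.pv_reservoir, state.v_injected]
    if state.phase in (Phase.READY, Phase.INSERTING):
        x_seg0 = state.x_main - (state.x_needle / config.coupling_ratio)
        dx, acc, fl, nfl, _ = _inserting_rhs(state.t, y, config, x_seg0, 0.0, valve_open)
        return {
            "x_main": dx,
            "v_main": acc,
            "x_needle": config.coupling_ratio * dx,
            "v_needle": config.coupling_ratio * acc,
            "pv_lower": fl,
            "pv_reservoir": nfl,
            "v_injected": 0.0,
        }
    resistance = needle_resistance(config)
    dx, _, fl, nfl, q = _infusing_rhs(state.t, y, config, resistance, valve_open)
    return {
        "x_main": dx,
        "v_main": 0.0,
        "x_needle": 0.0,
        "v_needle": 0.0,
        "pv_lower": fl,
        "pv_reservoir": nfl,
        "v_injected": q,
    }


# ----------------------------------------------------------------------
# trajectory container
# ----------------------------------------------------------------------

_TRAJECTORY_COLUMNS = (
    "t_s", "x_main_m", "v_main_ms", "x_needle_m", "v_needle_ms",
    "p_lower_pa", "p_fluid_pa", "flow_m3s", "v_injected_ml", "force_n", "phase",
)


@dataclass
class Trajectory:
    """Time-indexed record of one injection cycle plus derived channels."""

    t: np.ndarray
    x_main: np.ndarray
    v_main: np.ndarray
    x_needle: np.ndarray
    v_needle: np.ndarray
    pv_lower: np.ndarray
    pv_reservoir: np.ndarray
    v_injected: np.ndarray
    p_lower: np.ndarray
    p_fluid: np.ndarray
    flow: np.ndarray
    force: np.ndarray
    phase: np.ndarray          # array of str
    events: list               # (t, label) pairs
    final_state: DeviceState
    stalled: bool

    @property
    def duration(self) -> float:
        """Elapsed time from valve opening to the end of the cycle, s."""
        return float(self.t[-1] - self.t[0])

    @property
    def injected_ml(self) -> float:
        return float(self.v_injected[-1] - self.v_injected[0]) / 1e-6

    @property
    def peak_force_n(self) -> float:
        return float(np.max(self.force))

    def event_time(self, label: str) -> float | None:
        for t, lab in self.events:
            if lab == label:
                return t
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.t,
            "x_main_m": self.x_main,
            "v_main_ms": self.v_main,
            "x_needle_m": self.x_needle,
            "v_needle_ms": self.v_needle,
            "p_lower_pa": self.p_lower,
            "p_fluid_pa": self.p_fluid,
            "flow_m3s": self.flow,
            "v_injected_ml": self.v_injected / 1e-6,
            "force_n": self.force,
            "phase": self.phase,
        })


# ----------------------------------------------------------------------
# cycle simulation
# ----------------------------------------------------------------------


def _segment_grid(t0: float, t1: float) -> np.ndarray:
    n = max(2, int(math.ceil((t1 - t0) / _OUTPUT_DT)) + 1)
    return np.linspace(t0, t1, n)


def simulate_cycle(config: DeviceConfig, initial: DeviceState | None = None) -> Trajectory:
    """Integrate one full injection cycle (valve opens at ``initial.t``).

    Starts from READY (first dose: needle stowed) or from the terminal state
    of a previous cycle (needle already at full stroke; the cycle is pure
    infusion).  The cycle ends when the programmed ``dose_volume`` has been
    delivered (DONE), when the fluid piston exhausts its stroke, or when the
    gas budget stalls the device before dose completion — the latter two
    leave ``stalled=True`` and the phase short of DONE.
    """
    validate(config)
    if initial is None:
        initial = initial_state(config)
    resistance = needle_resistance(config)
    a_f = config.fluid_piston_area_m2
    ratio = config.coupling_ratio
    stroke_main = config.fluid_piston_stroke_m
    stroke_needle = config.needle_piston_stroke_m
    target = initial.v_injected + config.dose_volume_m3

    t = initial.t
    y = [initial.x_main, initial.v_main, initial.pv_lower, initial.pv_reservoir,
         initial.v_injected]
    x_needle0 = initial.x_needle
    t_end = initial.t + config.max_cycle_time

    seg_t, seg_y, seg_phase, seg_xn = [], [], [], []
    events: list[tuple[float, str]] = []
    stalled = False
    phase = Phase.DONE

    # ---- insertion segment (skipped when the needle is already at stroke)
    if x_needle0 < stroke_needle - 1e-12:
        x_seg0 = y[0]

        def hit_stop(tt, yy, *args):
            return (x_needle0 + ratio * (yy[0] - x_seg0)) - stroke_needle
        hit_stop.terminal = True
        hit_stop.direction = 1

        sol = solve_ivp(
            _inserting_rhs, (t, t_end), y, method="LSODA",
            args=(config, x_seg0, x_needle0, True),
            events=[hit_stop], dense_output=True, rtol=_RTOL, atol=_ATOL,
        )
        if not sol.success:
            raise IntegrationError(f"insertion segment failed: {sol.message}")
        t1 = float(sol.t[-1])
        grid = _segment_grid(t, t1)
        ys = sol.sol(grid)
        seg_t.append(grid)
        seg_y.append(ys)
        seg_phase.append(np.full(grid.size, Phase.INSERTING.value, dtype=object))
        seg_xn.append(np.clip(x_needle0 + ratio * (ys[0] - x_seg0), 0.0, stroke_needle))
        y = [float(v) for v in sol.y[:, -1]]
        t = t1
        if sol.t_events[0].size:
            events.append((t, "insertion_complete"))
            # plastic impact at the stop ring: the assembly's momentum is
            # absorbed, velocities reset
            y[1] = 0.0
            x_needle0 = stroke_needle
        else:
            stalled = True
            phase = Phase.INSERTING
            events.append((t, "timeout"))

    # ---- infusion segment
    if not stalled:
        y[1] = 0.0

        def dose_complete(tt, yy, *args):
            return yy[4] - target
        dose_complete.terminal = True
        dose_complete.direction = 1

        def reservoir_exhausted(tt, yy, *args):
            return yy[0] - stroke_main
        reservoir_exhausted.terminal = True
        reservoir_exhausted.direction = 1

        sol = solve_ivp(
            _infusing_rhs, (t, t_end), y, method="LSODA",
            args=(config, resistance, True),
            events=[dose_complete, reservoir_exhausted],
            dense_output=True, rtol=_RTOL, atol=_ATOL,
        )
        if not sol.success:
            raise IntegrationError(f"infusion segment failed: {sol.message}")
        t1 = float(sol.t[-1])
        grid = _segment_grid(t, t1)
        ys = sol.sol(grid)
        seg_t.append(grid)
        seg_y.append(ys)
        seg_phase.append(np.full(grid.size, Phase.INFUSING.value, dtype=object))
        seg_xn.append(np.full(grid.size, stroke_needle))
        y = [float(v) for v in sol.y[:, -1]]
        t = t1
        if sol.t_events[0].size:
            events.append((t, "dose_complete"))
            phase = Phase.DONE
        elif sol.t_events[1].size:
            events.append((t, "reservoir_exhausted"))
            stalled = True
            phase = Phase.INFUSING
        else:
            events.append((t, "timeout"))
            stalled = True
            phase = Phase.INFUSING

    # ---- assemble trajectory (drop duplicated segment-join samples)
    ts = np.concatenate(seg_t)
    yy = np.concatenate(seg_y, axis=1)
    phases = np.concatenate(seg_phase)
    xns = np.concatenate(seg_xn)
    keep = np.ones(ts.size, dtype=bool)
    keep[1:] = np.diff(ts) > 0
    ts, yy, phases, xns = ts[keep], yy[:, keep], phases[keep], xns[keep]

    x_main, v_main, pvl, pvr, vinj = yy
    inserting = phases == Phase.INSERTING.value
    v_needle = np.where(inserting, ratio * v_main, 0.0)
    p_lower = pvl / (a_f * x_main + config.dead_volume_m3)
    flow = np.where(
        ~inserting,
        np.maximum(0.0, p_lower - (ATM_PA + config.subcutaneous_pressure_pa)) / resistance,
        0.0,
    )
    force = np.array([
        tissue_force(max(0.0, xn), vn, config) for xn, vn in zip(xns, v_needle)
    ])
    # fluid pressure: during insertion the fluid column only reacts the
    # needle-side resistance; during infusion it carries the lower pressure
    a_n = config.needle_piston_area_m2
    resist_needle = (config.spring_constant * xns + config.dashpot_coefficient * v_needle
                     + force)
    p_fluid = np.where(inserting, ATM_PA + resist_needle / a_n, p_lower)

    final = DeviceState(
        t=float(ts[-1]),
        x_main=float(x_main[-1]),
        v_main=0.0,
        x_needle=float(xns[-1]),
        v_needle=0.0,
        pv_lower=float(pvl[-1]),
        pv_reservoir=float(pvr[-1]),
        v_injected=float(vinj[-1]),
        phase=phase,
    )
    return Trajectory(
        t=ts, x_main=x_main, v_main=v_main, x_needle=xns, v_needle=v_needle,
        pv_lower=pvl, pv_reservoir=pvr, v_injected=vinj,
        p_lower=p_lower, p_fluid=p_fluid, flow=flow, force=force,
        phase=phases, events=events, final_state=final, stalled=stalled,
    )
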