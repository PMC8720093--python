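"""Dose-controller logic: trigger, alert, and the three-dose schedule.

The microcontroller watches the streaming SpO2 signal.  At the first sample
at or below the 90 % threshold it simultaneously emits the 911 alert (logged
here as an ALERT event; transport is out of scope) and commands dose 1.  It
then re-checks the saturation at 5-minute intervals: continued desaturation
earns another dose, up to three in total, after which the controller is
EXHAUSTED (first responders are assumed on scene by the fourth interval).
If the wearer recovers above threshold at a re-check, the episode closes and
the controller takes no further action until the device is explicitly
reset — a fresh episode needs a fresh device (needle, reservoir, gas).

Wearer screening implements the device's selection criteria: no history or
exam evidence of cardiac/pulmonary disease, and resting SpO2 of at least
93 % (the accepted lower limit of normal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

from .dynamics import DeviceState, Phase, Trajectory, initial_state, simulate_cycle
from .geometry import DeviceConfig, validate
from .physiology import PhysiologySimulator, ScenarioParams, SpO2Trace

__all__ = [
    "Mode",
    "EventKind",
    "ControllerState",
    "Event",
    "WearerProfile",
    "ScreeningResult",
    "SequencingError",
    "SignalError",
    "ProfileError",
    "RESTING_SPO2_MIN",
    "step",
    "run_closed_loop",
    "ClosedLoopResult",
    "screen_wearer",
]

#: minimum resting SpO2 (percent) for device eligibility
RESTING_SPO2_MIN = 93.0


class Mode(str, Enum):
    MONITORING = "MONITORING"
    TRIGGERED = "TRIGGERED"          # transient: a dose command is in flight
    AWAITING_RECHECK = "AWAITING_RECHECK"
    EXHAUSTED = "EXHAUSTED"


class EventKind(str, Enum):
    ALERT = "ALERT"
    DOSE = "DOSE"
    DEVICE_FAULT = "DEVICE_FAULT"


class SequencingError(ValueError):
    """Samples arrived out of time order."""


class SignalError(ValueError):
    """An SpO2 sample was outside [0, 100]."""


class ProfileError(ValueError):
    """A wearer profile is missing a required field."""


@dataclass(frozen=True)
class Event:
    t: float
    kind: EventKind
    spo2: float
    dose_index: int | None = None  # 1..max_doses, DOSE only

    def to_record(self) -> dict:
        rec = {"t_s": self.t, "kind": self.kind.value,
               "dose_index": self.dose_index, "spo2_pct": self.spo2}
        if self.kind is EventKind.ALERT:
            rec["gps"] = None  # transport out of scope; placeholder field
        return rec


@dataclass(frozen=True)
class ControllerState:
    mode: Mode = Mode.MONITORING
    doses_given: int = 0
    last_dose_time: float | None = None
    alert_sent: bool = False
    armed: bool = True            # cleared when an episode ends in recovery
    last_sample_time: float | None = None
    below_count: int = 0          # consecutive sub-threshold samples

    def replace(self, **changes) -> "ControllerState":
        return replace(self, **changes)


def step(controller: ControllerState, t: float, spo2: float,
         config: DeviceConfig) -> tuple[ControllerState, list[Event]]:
    """Advance the controller by one SpO2 sample; returns new state + events.

    Pure state machine: the DOSE events it emits are commands — actually
    driving the injector (and noticing stalls) is :func:`run_closed_loop`'s
    job.
    """
    if controller.last_sample_time is not None and t < controller.last_sample_time:
        raise SequencingError(
            f"sample at t={t} precedes previous sample at t={controller.last_sample_time}")
    if not (0.0 <= spo2 <= 100.0):
        raise SignalError(f"SpO2 sample {spo2!r} outside [0, 100]")

    below = spo2 <= config.spo2_threshold
    ctrl = controller.replace(
        last_sample_time=t,
        below_count=controller.below_count + 1 if below else 0,
    )
    events: list[Event] = []

    if ctrl.mode is Mode.EXHAUSTED or not ctrl.armed:
        return ctrl, events

    if ctrl.mode is Mode.MONITORING:
        if below and ctrl.below_count >= config.persistence_samples:
            if not ctrl.alert_sent:
                events.append(Event(t=t, kind=EventKind.ALERT, spo2=spo2))
            events.append(Event(t=t, kind=EventKind.DOSE, spo2=spo2, dose_index=1))
            ctrl = ctrl.replace(
                mode=Mode.AWAITING_RECHECK if config.max_doses > 1 else Mode.EXHAUSTED,
                doses_given=1, last_dose_time=t, alert_sent=True)
        return ctrl, events

    if ctrl.mode is Mode.AWAITING_RECHECK:
        # evaluate the threshold at the first sample at-or-after the re-check
        # instant last_dose_time + redose_interval
        if t >= ctrl.last_dose_time + config.redose_interval:
            if below:
                idx = ctrl.doses_given + 1
                events.append(Event(t=t, kind=EventKind.DOSE, spo2=spo2, dose_index=idx))
                ctrl = ctrl.replace(
                    doses_given=idx, last_dose_time=t,
                    mode=Mode.EXHAUSTED if idx >= config.max_doses
                    else Mode.AWAITING_RECHECK)
            else:
                # recovered: episode over until the device is reset
                ctrl = ctrl.replace(mode=Mode.MONITORING, armed=False)
        return ctrl, events

    return ctrl, events


# ----------------------------------------------------------------------
# closed loop
# ----------------------------------------------------------------------

@dataclass
class ClosedLoopResult:
    log: list[Event]
    trajectories: list[Trajectory]
    controller: ControllerState
    trace: SpO2Trace
    device: DeviceState


def run_closed_loop(trace: SpO2Trace | None, config: DeviceConfig,
                    scenario: ScenarioParams | None = None,
                    duration: float | None = None, rate: float = 1.0,
                    seed: int | None = None) -> ClosedLoopResult:
    """Feed an SpO2 signal to the controller and drive the injector.

    Two signal sources:

    * an explicit :class:`~odrs.physiology.SpO2Trace` (open-loop signal), or
    * ``scenario`` + ``duration`` (+ ``seed``): samples are generated on the
      fly by :class:`~odrs.physiology.PhysiologySimulator`; when the
      scenario has ``pk_feedback`` each delivered dose feeds back into the
      wearer's saturation.

    Each DOSE command runs :func:`~odrs.dynamics.simulate_cycle` from the
    injector's terminal state of the previous cycle.  A stalled cycle logs a
    DEVICE_FAULT event (and no physiological dose); monitoring continues.
    """
    validate(config)
    if (trace is None) == (scenario is None):
        raise ValueError("provide exactly one of trace or scenario")

    sim: PhysiologySimulator | None = None
    if scenario is not None:
        if duration is None or duration <= 0:
            raise ValueError("scenario mode requires a positive duration")
        sim = PhysiologySimulator(scenario, rate=rate, seed=seed)
        n = int(round(duration * rate))
        times = [i / rate for i in range(n)]
    else:
        times = list(trace.times)

    ctrl = ControllerState()
    device = initial_state(config)
    log: list[Event] = []
    trajectories: list[Trajectory] = []

    for i, t in enumerate(times):
        spo2 = sim.sample(t) if sim is not None else float(trace.values[i])
        ctrl, events = step(ctrl, t, spo2, config)
        for ev in events:
            log.append(ev)
            if ev.kind is not EventKind.DOSE:
                continue
            traj = simulate_cycle(config, device.replace(t=t))
            trajectories.append(traj)
            device = traj.final_state
            if traj.stalled:
                log.append(Event(t=traj.final_state.t, kind=EventKind.DEVICE_FAULT,
                                 spo2=spo2))
            elif sim is not None and scenario.pk_feedback:
                sim.notify_dose(traj.final_state.t)

    out_trace = sim.trace() if sim is not None else trace
    return ClosedLoopResult(log=log, trajectories=trajectories, controller=ctrl,
                            trace=out_trace, device=device)


# ----------------------------------------------------------------------
# wearer screening
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class WearerProfile:
    """Screening inputs: clinical history, exam findings, baseline oximetry."""

    cardiac_or_pulmonary_history: bool | None = None
    exam_heart_lung_findings: bool | None = None
    resting_spo2: float | None = None


@dataclass(frozen=True)
class ScreeningResult:
    eligible: bool
    reasons: tuple[str, ...] = ()


def screen_wearer(profile: WearerProfile) -> ScreeningResult:
    """Apply the device's selection criteria to a wearer profile.

    Eligible iff there is no cardiac/pulmonary disease history, no heart or
    lung findings on exam, and resting SpO2 is at least 93 %.  Every failed
    criterion is reported by name.
    """
    for name in ("cardiac_or_pulmonary_history", "exam_heart_lung_findings",
                 "resting_spo2"):
        if getattr(profile, name) is None:
            raise ProfileError(f"wearer profile is missing required field {name!r}")
    reasons = []
    if profile.cardiac_or_pulmonary_history:
        reasons.append("cardiac or pulmonary disease history")
    if profile.exam_heart_lung_findings:
        reasons.append("exam findings of heart or lung disease")
    if profile.resting_spo2 < RESTING_SPO2_MIN:
        reasons.append(f"resting SpO2 < {RESTING_SPO2_MIN:g}%")
    return ScreeningResult(eligible=not reasons, reasons=tuple(reasons))
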