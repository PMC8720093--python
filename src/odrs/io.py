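"""Configuration files, trace/trajectory/event round-tripping, scenario runs.

File formats
------------
* device + scenario config: YAML (or JSON) with ``device:`` and optional
  ``scenario:`` mappings whose keys are exactly the dataclass field names;
  unknown keys are rejected by name.  Two presets ship with the package:
  ``table1`` (the published parameter table verbatim) and ``default`` (the
  calibrated three-dose-feasible variant).
* SpO2 trace: CSV ``t_s,spo2_pct`` with a ``# seed=...`` comment header.
* trajectory: CSV with the fixed channel header, floats printed ``%.12g``.
* controller log: JSON Lines, one event per line.
* run manifest: JSON summarising a scenario run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .controller import ClosedLoopResult, Event, EventKind, run_closed_loop
from .dynamics import Trajectory, insertion_depth
from .geometry import DeviceConfig, TissueForceParams, validate
from .physiology import ScenarioParams, SpO2Trace

__all__ = [
    "ConfigFileError",
    "ParseError",
    "UnknownKeyError",
    "PRESETS",
    "SCENARIO_PRESETS",
    "load_config",
    "preset_path",
    "scenario_preset",
    "write_trace",
    "read_trace",
    "write_trajectory",
    "read_trajectory",
    "write_events",
    "read_events",
    "RunManifest",
    "run_scenario",
]

log = logging.getLogger("odrs")

_FLOAT_FMT = "%.12g"


class ConfigFileError(ValueError):
    """Problem reading a configuration file."""


class ParseError(ConfigFileError):
    """The file is not valid YAML/JSON."""


class UnknownKeyError(ConfigFileError):
    """The file contains a key that is not a configuration field."""


PRESETS = ("default", "table1")


def preset_path(name: str) -> Path:
    if name not in PRESETS:
        raise ConfigFileError(f"unknown preset {name!r}; available: {PRESETS}")
    return Path(str(resources.files("odrs").joinpath(f"presets/{name}.yaml")))


def _build(cls, data: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise UnknownKeyError(
            f"unknown key {sorted(unknown)[0]!r} in {context} section")
    return cls(**data)


def load_config(path_or_preset) -> tuple[DeviceConfig, ScenarioParams | None]:
    """Load and validate a configuration file (or a named preset).

    Returns the device configuration and, when the file carries a
    ``scenario:`` section, the scenario parameters.  Distinct errors:
    :class:`ParseError` for malformed files, :class:`UnknownKeyError` for
    unrecognised keys, and :class:`~odrs.geometry.ConfigError` for values
    that fail physical validation.
    """
    path = preset_path(path_or_preset) if str(path_or_preset) in PRESETS \
        else Path(path_or_preset)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ParseError(f"{path} must contain a mapping, got {type(raw).__name__}")
    unknown = set(raw) - {"device", "scenario"}
    if unknown:
        raise UnknownKeyError(f"unknown top-level key {sorted(unknown)[0]!r} in {path}")

    device_data = dict(raw.get("device", {}))
    if "tissue_force_params" in device_data and isinstance(
            device_data["tissue_force_params"], dict):
        device_data["tissue_force_params"] = _build(
            TissueForceParams, device_data["tissue_force_params"],
            "tissue_force_params")
    config = _build(DeviceConfig, device_data, "device")
    validate(config)

    scenario = None
    if "scenario" in raw:
        scenario = _build(ScenarioParams, dict(raw["scenario"]), "scenario").validated()
    return config, scenario


# ----------------------------------------------------------------------
# scenario presets
# ----------------------------------------------------------------------

def scenario_preset(name: str) -> tuple[ScenarioParams, float]:
    """Named scenario -> (parameters, suggested duration in seconds)."""
    presets = {
        # quiet baseline in the normal band, no overdose
        "normal": (ScenarioParams(), 600.0),
        # overdose at t=60 s, no antidote response: desaturation persists
        # through all three re-checks
        "overdose-persistent": (
            ScenarioParams(overdose_onset=60.0), 800.0),
        # overdose at t=60 s with fast-absorbing antidote: saturation is back
        # above threshold by the first re-check, so a single dose suffices
        "overdose-recovery": (
            ScenarioParams(overdose_onset=60.0, pk_feedback=True,
                           absorption_rate=60.0, recovery_rate=0.02,
                           effect_ec50=0.1), 900.0),
    }
    if name not in presets:
        raise ConfigFileError(
            f"unknown scenario {name!r}; available: {sorted(presets)}")
    return presets[name]


SCENARIO_PRESETS = ("normal", "overdose-persistent", "overdose-recovery")


# ----------------------------------------------------------------------
# trace / trajectory / event files
# ----------------------------------------------------------------------

def write_trace(trace: SpO2Trace, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# seed={'' if trace.seed is None else trace.seed}\n")
        fh.write("t_s,spo2_pct\n")
        for t, v in zip(trace.times, trace.values):
            fh.write(f"{t:.12g},{v:.12g}\n")


def read_trace(path) -> SpO2Trace:
    path = Path(path)
    seed = None
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("# seed="):
            tail = first.strip().split("=", 1)[1]
            seed = int(tail) if tail else None
            frame = pd.read_csv(fh)
        else:
            fh.seek(0)
            frame = pd.read_csv(fh)
    return SpO2Trace(times=frame["t_s"].to_numpy(),
                     values=frame["spo2_pct"].to_numpy(), seed=seed)


def write_trajectory(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_events(events: list[Event], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for ev in events:
            fh.write(json.dumps(ev.to_record()) + "\n")


def read_events(path) -> list[dict]:
    with Path(path).open() as fh:
        return [json.loads(line) for line in fh if line.strip()]


# ----------------------------------------------------------------------
# scenario runner
# ----------------------------------------------------------------------

@dataclasses.dataclass
class RunManifest:
    config_sha256: str
    scenario: str
    seed: int | None
    version: str
    outputs: list
    dose_summaries: list
    total_doses: int
    alert_time_s: float | None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _config_hash(config: DeviceConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _dose_summary(index: int, trigger_t: float, traj: Trajectory,
                  config: DeviceConfig) -> dict:
    return {
        "dose_index": index,
        "trigger_t_s": trigger_t,
        "cycle_duration_s": traj.duration,
        "injected_ml": traj.injected_ml,
        "peak_force_n": traj.peak_force_n,
        "insertion_depth_mm": insertion_depth(traj.final_state, config),
        "stalled": traj.stalled,
    }


def summarize_result(result: ClosedLoopResult, config: DeviceConfig) -> tuple[list, float | None]:
    doses = [ev for ev in result.log if ev.kind is EventKind.DOSE]
    summaries = [
        _dose_summary(ev.dose_index, ev.t, traj, config)
        for ev, traj in zip(doses, result.trajectories)
    ]
    alerts = [ev.t for ev in result.log if ev.kind is EventKind.ALERT]
    return summaries, (alerts[0] if alerts else None)


def run_scenario(config: DeviceConfig, scenario: str | ScenarioParams,
                 seed: int | None, out_dir, duration: float | None = None,
                 rate: float = 1.0) -> RunManifest:
    """Generate a scenario signal, run the closed loop, write all artifacts.

    Writes the SpO2 trace CSV, one trajectory CSV per dose, the controller
    event log (JSONL) and a run manifest (JSON) into ``out_dir``; returns
    the manifest.
    """
    validate(config)
    if isinstance(scenario, str):
        name = scenario
        params, preset_duration = scenario_preset(scenario)
        duration = duration if duration is not None else preset_duration
    else:
        name = "custom"
        params = scenario.validated()
        if duration is None:
            raise ValueError("custom scenarios require an explicit duration")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("running scenario %s (seed=%s, duration=%gs)", name, seed, duration)

    result = run_closed_loop(None, config, scenario=params, duration=duration,
                             rate=rate, seed=seed)

    outputs = []
    trace_file = out_dir / "trace.csv"
    write_trace(result.trace, trace_file)
    outputs.append(trace_file.name)

    for i, traj in enumerate(result.trajectories, start=1):
        tfile = out_dir / f"trajectory_dose{i}.csv"
        write_trajectory(traj, tfile)
        outputs.append(tfile.name)

    events_file = out_dir / "events.jsonl"
    write_events(result.log, events_file)
    outputs.append(events_file.name)

    summaries, alert_t = summarize_result(result, config)
    manifest = RunManifest(
        config_sha256=_config_hash(config),
        scenario=name,
        seed=seed,
        version=__version__,
        outputs=outputs,
        dose_summaries=summaries,
        total_doses=len(summaries),
        alert_time_s=alert_t,
    )
    manifest.write(out_dir / "manifest.json")
    log.info("scenario %s: %d dose(s), alert at %s", name,
             manifest.total_doses, manifest.alert_time_s)
    return manifest
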