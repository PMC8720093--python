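"""Synthetic pulse-oximetry physiology.

Generates the SpO2 signals the dose controller consumes and provides the
oxyhemoglobin dissociation mapping between SpO2 and arterial oxygen partial
pressure (PaO2).

Signal model
------------
A healthy wearer holds SpO2 in the accepted normal band of 93-97 %, modelled
as a mean level plus a slow diurnal sinusoid and Gaussian sensor noise.  An
opioid overdose appears as a precipitous desaturation: from ``overdose_onset``
the deterministic component ramps down at ``desaturation_rate`` toward a
``floor``.  Crossing 90 % SpO2 — corresponding to PaO2 of roughly 60 mmHg on
the dissociation curve — is the pathological threshold at which the device
fires.

Antidote response (optional, ``pk_feedback``)
---------------------------------------------
Each subcutaneous nalmefene dose follows a one-compartment model with
first-order absorption and first-order elimination at half-life 8 h.  The
receptor-level effect is the saturable fraction ``f = C / (C + EC50)``; it
simultaneously removes the opioid's desaturation drive (scaled by ``1 - f``)
and relaxes the accumulated saturation deficit at ``recovery_rate * f``.
Dose contributions superpose in concentration.

The deterministic deficit is stepped with the explicit Euler rule on the
sample grid (exact for the piecewise-linear no-dose ramp), which makes the
offline generator and the sample-by-sample closed-loop simulator produce
identical signals for identical dose times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.optimize import brentq

from .geometry import DomainError

__all__ = [
    "ScenarioParams",
    "SpO2Trace",
    "severinghaus_sao2",
    "inverse_severinghaus",
    "nalmefene_concentration",
    "generate_trace",
    "apply_dose_response",
    "PhysiologySimulator",
]


# ----------------------------------------------------------------------
# oxyhemoglobin dissociation curve
# ----------------------------------------------------------------------

def severinghaus_sao2(pao2):
    """Hemoglobin oxygen saturation (fraction) at a given PaO2 (mmHg).

    Severinghaus closed form ``S = 1 / (23400 / (P^3 + 150 P) + 1)``,
    strictly increasing in PaO2.
    """
    p = np.asarray(pao2, dtype=float)
    if np.any(p <= 0):
        raise DomainError(f"PaO2 must be positive, got {pao2!r}")
    s = 1.0 / (23400.0 / (p**3 + 150.0 * p) + 1.0)
    return float(s) if np.isscalar(pao2) else s


def inverse_severinghaus(sao2):
    """PaO2 (mmHg) at a given saturation fraction: numerical inverse of
    :func:`severinghaus_sao2`.  At 90 % saturation this is ~58.7 mmHg, the
    conventional "SpO2 90 % is PaO2 about 60 mmHg" correspondence."""

    def _invert(s: float) -> float:
        if not (0.0 < s < 1.0):
            raise DomainError(f"saturation must lie in (0, 1), got {s!r}")
        # monotone cubic: P^3 + 150 P = 23400 s / (1 - s)
        rhs = 23400.0 * s / (1.0 - s)
        hi = max(1.0, rhs ** (1.0 / 3.0) + 1.0)
        return brentq(lambda p: p**3 + 150.0 * p - rhs, 0.0, hi, xtol=1e-12, rtol=1e-15)

    if np.isscalar(sao2):
        return _invert(float(sao2))
    return np.array([_invert(float(s)) for s in np.asarray(sao2, dtype=float)])


# ----------------------------------------------------------------------
# scenario parameters / traces
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioParams:
    """Parameters of the synthetic SpO2 scenario.

    Baseline is the normal 93-97 % band: ``baseline_mean`` (default 95 %)
    with a slow diurnal sinusoid of ``diurnal_amplitude`` and Gaussian noise
    ``baseline_noise_sd`` per sample.  ``overdose_onset=None`` means no
    overdose.  Desaturation proceeds at ``desaturation_rate`` %/min down to
    ``floor``.  PK/PD fields are used only when ``pk_feedback`` is true.
    """

    baseline_mean: float = 95.0          # percent
    baseline_noise_sd: float = 0.5       # percent
    diurnal_amplitude: float = 0.5       # percent
    diurnal_period: float = 86_400.0     # s
    overdose_onset: float | None = None  # s
    desaturation_rate: float = 2.0       # percent/min (illustrative)
    floor: float = 70.0                  # percent
    pk_feedback: bool = False
    nalmefene_half_life: float = 8.0     # h, plasma elimination half-life
    absorption_rate: float = 6.0         # 1/h, subcutaneous absorption; inf = bolus
    effect_ec50: float = 0.25            # concentration units of one unit dose
    recovery_rate: float = 0.01          # 1/s, deficit relaxation at full effect

    def validated(self) -> "ScenarioParams":
        if not (93.0 - 3.0 * self.baseline_noise_sd - self.diurnal_amplitude <= self.baseline_mean
                <= 97.0 + 3.0 * self.baseline_noise_sd + self.diurnal_amplitude) \
                or not (0.0 < self.baseline_mean <= 100.0):
            raise DomainError(
                f"baseline_mean {self.baseline_mean!r} is outside the normal 93-97% band")
        if self.baseline_noise_sd < 0 or self.diurnal_amplitude < 0:
            raise DomainError("noise and diurnal amplitudes must be non-negative")
        if self.floor < 0:
            raise DomainError(f"floor must be non-negative, got {self.floor!r}")
        if self.nalmefene_half_life <= 0:
            raise DomainError(f"half-life must be positive, got {self.nalmefene_half_life!r}")
        if self.desaturation_rate < 0 or self.recovery_rate < 0:
            raise DomainError("rates must be non-negative")
        return self

    def replace(self, **changes) -> "ScenarioParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SpO2Trace:
    """Sampled SpO2 time series (percent) with its generating recipe."""

    times: np.ndarray
    values: np.ndarray
    seed: int | None = None
    params: ScenarioParams | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape:
            raise DomainError("times and values must have matching length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise DomainError("times must be strictly increasing")
        if v.size and (v.min() < 0.0 or v.max() > 100.0):
            raise DomainError("SpO2 values must lie in [0, 100]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


def nalmefene_concentration(t, dose_times, params: ScenarioParams):
    """Plasma concentration (unit-dose scale) at time ``t`` (s) from doses
    given at ``dose_times`` (s).

    One-compartment, first-order absorption ``ka`` and elimination
    ``ke = ln 2 / t_half``; ``absorption_rate = inf`` degenerates to an
    intravenous bolus ``exp(-ke tau)``.  Doses superpose.
    """
    t = np.asarray(t, dtype=float)
    ke = math.log(2.0) / (params.nalmefene_half_life * 3600.0)
    ka = params.absorption_rate / 3600.0 if math.isfinite(params.absorption_rate) else math.inf
    c = np.zeros_like(t)
    for td in dose_times:
        tau = t - td
        active = tau > 0
        if not np.any(active):
            continue
        tau = np.where(active, tau, 0.0)
        if math.isinf(ka):
            ci = np.exp(-ke * tau)
        elif abs(ka - ke) < 1e-18:
            ci = ka * tau * np.exp(-ke * tau)
        else:
            ci = ka / (ka - ke) * (np.exp(-ke * tau) - np.exp(-ka * tau))
        c += np.where(active, ci, 0.0)
    return float(c) if c.ndim == 0 else c


def _deterministic_path(times: np.ndarray, params: ScenarioParams,
                        dose_times: tuple[float, ...]) -> np.ndarray:
    """Noise-free SpO2 path: diurnal baseline minus the desaturation deficit,
    stepped with the forward Euler rule on the sample grid."""
    baseline = params.baseline_mean + params.diurnal_amplitude * np.sin(
        2.0 * math.pi * times / params.diurnal_period)
    if params.overdose_onset is None:
        return baseline

    onset = params.overdose_onset
    drive = params.desaturation_rate / 60.0  # percent/s
    max_deficit = max(0.0, params.baseline_mean - params.floor)
    conc = nalmefene_concentration(times, dose_times, params) if dose_times else \
        np.zeros_like(times)
    effect = conc / (conc + params.effect_ec50)

    deficit = np.zeros_like(times)
    d = 0.0
    for i in range(1, times.size):
        dt = times[i] - times[i - 1]
        if times[i - 1] >= onset:
            f = effect[i - 1]
            d += dt * (drive * (1.0 - f) - params.recovery_rate * f * d)
            d = min(max(d, 0.0), max_deficit)
        deficit[i] = d
    return baseline - deficit


def generate_trace(params: ScenarioParams, duration: float, rate: float = 1.0,
                   seed: int | None = None) -> SpO2Trace:
    """Sample a synthetic SpO2 trace of ``duration`` seconds at ``rate`` Hz.

    Identical ``seed`` and parameters give an identical trace.  Values are
    clipped to [0, 100].
    """
    params = params.validated()
    if duration <= 0 or rate <= 0:
        raise DomainError("duration and rate must be positive")
    times = np.arange(0.0, duration, 1.0 / rate)
    values = _deterministic_path(times, params, ())
    if params.baseline_noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, params.baseline_noise_sd, size=times.size)
    values = np.clip(values, 0.0, 100.0)
    return SpO2Trace(times=times, values=values, seed=seed, params=params)


def apply_dose_response(trace: SpO2Trace, dose_times, params: ScenarioParams) -> SpO2Trace:
    """Overlay the antidote response for doses at ``dose_times`` on a trace.

    Requires ``pk_feedback``.  The deterministic path is regenerated with the
    dose-driven recovery term and the trace's noise (reproduced from its
    seed) is re-applied; with an empty ``dose_times`` the trace is returned
    unchanged.
    """
    params = params.validated()
    if not params.pk_feedback:
        raise DomainError("apply_dose_response requires pk_feedback=True")
    dose_times = tuple(float(t) for t in dose_times)
    if not dose_times:
        return trace
    t0, t1 = float(trace.times[0]), float(trace.times[-1])
    for td in dose_times:
        if not (t0 <= td <= t1):
            raise DomainError(f"dose time {td!r} outside trace span [{t0}, {t1}]")
    values = _deterministic_path(trace.times, params, dose_times)
    if params.baseline_noise_sd > 0:
        rng = np.random.default_rng(trace.seed)
        values = values + rng.normal(0.0, params.baseline_noise_sd, size=trace.times.size)
    values = np.clip(values, 0.0, 100.0)
    return SpO2Trace(times=trace.times, values=values, seed=trace.seed, params=params)


class PhysiologySimulator:
    """Sample-by-sample SpO2 generator for closed-loop runs.

    Produces the same signal as :func:`generate_trace` /
    :func:`apply_dose_response` for the same seed, parameters and dose
    times, but advances one sample at a time so the dose controller's
    actions can feed back into the wearer's physiology.
    """

    def __init__(self, params: ScenarioParams, rate: float = 1.0,
                 seed: int | None = None):
        self.params = params.validated()
        self.rate = rate
        self.seed = seed
        self._rng = np.random.default_rng(seed)
        self.dose_times: list[float] = []
        self._deficit = 0.0
        self._last_t: float | None = None
        self._times: list[float] = []
        self._values: list[float] = []

    def notify_dose(self, t: float) -> None:
        """Record an antidote dose delivered at time ``t``."""
        self.dose_times.append(float(t))

    def sample(self, t: float) -> float:
        """SpO2 at time ``t`` (samples must be requested in increasing order)."""
        p = self.params
        baseline = p.baseline_mean + p.diurnal_amplitude * math.sin(
            2.0 * math.pi * t / p.diurnal_period)
        if p.overdose_onset is not None and self._last_t is not None \
                and self._last_t >= p.overdose_onset:
            dt = t - self._last_t
            if p.pk_feedback and self.dose_times:
                c = nalmefene_concentration(self._last_t, self.dose_times, p)
                f = c / (c + p.effect_ec50)
            else:
                f = 0.0
            drive = p.desaturation_rate / 60.0
            d = self._deficit + dt * (drive * (1.0 - f)
                                      - p.recovery_rate * f * self._deficit)
            self._deficit = min(max(d, 0.0), max(0.0, p.baseline_mean - p.floor))
        value = baseline - self._deficit
        if p.baseline_noise_sd > 0:
            value += self._rng.normal(0.0, p.baseline_noise_sd)
        value = min(max(value, 0.0), 100.0)
        self._last_t = t
        self._times.append(t)
        self._values.append(value)
        return value

    def trace(self) -> SpO2Trace:
        """All samples generated so far, as a trace."""
        return SpO2Trace(times=np.array(self._times), values=np.array(self._values),
                         seed=self.seed, params=self.params)
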