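"""Device geometry and configuration.

The injector is a pneumatic burst-release device: a compressed-gas reservoir,
gated by a control valve, pressurises the lower half of the main fluid
cylinder and drives the fluid piston upward.  The antidote above the piston is
forced into the injection compartment, whose piston carries a 30-gauge, 8 mm
hypodermic needle through a sterile protective membrane into subcutaneous
tissue.  A stop ring limits needle travel; once the needle is fully inserted
the remaining piston travel meters drug through the needle.

This module holds the device configuration (in the mixed practical units the
design is specified in: cm, mm, atm, cSt, g), validates its physical
self-consistency, and provides the capacity arithmetic used for design
checks: antidote reservoir capacity, external package length, and the
isothermal gas budget.

All simulation code works in SI; the ``*_si``/``*_m``/``*_pa`` properties on
:class:`DeviceConfig` perform the conversion exactly once.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict, replace

__all__ = [
    "ATM_PA",
    "ConfigError",
    "DomainError",
    "GasBudgetWarning",
    "TissueForceParams",
    "DeviceConfig",
    "table1_config",
    "default_config",
    "validate",
    "reservoir_capacity",
    "required_length",
    "gas_displaceable_volume",
]

#: standard atmosphere, Pa
ATM_PA = 101_325.0
_CM = 1e-2
_MM = 1e-3
_CM3 = 1e-6
_ML = 1e-6
_CST = 1e-6  # centistokes -> m^2/s


class ConfigError(ValueError):
    """A device configuration is not physically self-consistent."""


class DomainError(ValueError):
    """An operation was called outside its physical domain."""


class GasBudgetWarning(UserWarning):
    """Compressed-gas reservoir cannot displace the full dosing schedule."""


@dataclass(frozen=True)
class TissueForceParams:
    """Needle/tissue interaction model parameters.

    puncture_force : N
        Peak resistance while the needle tip crosses the protective membrane.
    stiffness : N/m
        Elastic resistance of subcutaneous tissue per metre of insertion.
    damping : N*s/m
        Viscous resistance of tissue to insertion velocity.
    """

    puncture_force: float = 1.0
    stiffness: float = 150.0
    damping: float = 10.0


@dataclass(frozen=True)
class DeviceConfig:
    """Full mechanical + dosing configuration of the injector.

    Fields are stored in the units the device is specified in (cm, mm, atm,
    cSt, g, ml, s).  Defaults are the shipped calibrated preset; the
    as-published parameter table is available via :func:`table1_config`.
    """

    # --- main fluid cylinder / piston (antidote reservoir) ---
    fluid_piston_radius: float = 1.07        # cm
    fluid_piston_stroke: float = 1.1         # cm
    fluid_piston_initial_displacement: float = 0.01  # cm
    dead_volume: float = 1e-5                # cm^3
    fluid_initial_pressure: float = 1.0      # atm (lower compartment at rest)

    # --- injection (needle) cylinder / piston ---
    needle_piston_radius: float = 0.5        # cm
    needle_piston_stroke: float = 1.1        # cm
    needle_inner_diameter: float = 0.6       # mm
    needle_length: float = 8.0               # mm

    # --- chassis mechanics ---
    chassis_mass: float = 500.0              # g
    spring_constant: float = 11.0            # N/m
    dashpot_coefficient: float = 11.0        # N*s/m

    # --- compressed gas storage ---
    gas_initial_pressure: float = 20.0       # atm (see validate(); 5 atm in the published table)
    gas_radius: float = 0.3                  # cm
    gas_height: float = 0.9                  # cm

    # --- drug fluid properties (nalmefene solution) ---
    fluid_viscosity: float = 0.658           # cSt (kinematic)
    fluid_density: float = 992.562           # kg/m^3

    # --- package arithmetic ---
    wall_allowance_length: float = 0.86      # cm

    # --- design parameters not in the published table ---
    membrane_standoff: float | None = None   # mm; None -> stroke - needle_length
    valve_conductance: float = 8e-14         # m^3/(s*Pa), calibrated (see docs/methods.md)
    tissue_force_params: TissueForceParams = field(default_factory=TissueForceParams)
    subcutaneous_pressure: float = 0.0       # atm gauge back-pressure at the needle tip
    max_cycle_time: float = 10.0             # s, integration cap per injection cycle

    # --- dosing schedule / trigger ---
    dose_volume: float = 1.0                 # ml
    max_doses: int = 3
    redose_interval: float = 300.0           # s
    spo2_threshold: float = 90.0             # percent
    persistence_samples: int = 1             # consecutive sub-threshold samples to trigger

    # ------------------------------------------------------------------
    # derived quantities (SI)
    # ------------------------------------------------------------------
    @property
    def fluid_piston_area_m2(self) -> float:
        return math.pi * (self.fluid_piston_radius * _CM) ** 2

    @property
    def needle_piston_area_m2(self) -> float:
        return math.pi * (self.needle_piston_radius * _CM) ** 2

    @property
    def coupling_ratio(self) -> float:
        """Kinematic gain fluid piston -> needle piston (incompressible fluid)."""
        return self.fluid_piston_area_m2 / self.needle_piston_area_m2

    @property
    def fluid_piston_stroke_m(self) -> float:
        return self.fluid_piston_stroke * _CM

    @property
    def fluid_piston_initial_displacement_m(self) -> float:
        return self.fluid_piston_initial_displacement * _CM

    @property
    def needle_piston_stroke_m(self) -> float:
        return self.needle_piston_stroke * _CM

    @property
    def dead_volume_m3(self) -> float:
        return self.dead_volume * _CM3

    @property
    def needle_radius_m(self) -> float:
        return 0.5 * self.needle_inner_diameter * _MM

    @property
    def needle_length_m(self) -> float:
        return self.needle_length * _MM

    @property
    def membrane_standoff_mm(self) -> float:
        """Distance from the stowed needle tip to the skin surface, mm.

        Defaults to ``needle_piston_stroke - needle_length`` so that a full
        piston stroke yields exactly full needle insertion.
        """
        if self.membrane_standoff is not None:
            return self.membrane_standoff
        return self.needle_piston_stroke / _MM * _CM - self.needle_length

    @property
    def membrane_standoff_m(self) -> float:
        return self.membrane_standoff_mm * _MM

    @property
    def chassis_mass_kg(self) -> float:
        return self.chassis_mass * 1e-3

    @property
    def dynamic_viscosity_pa_s(self) -> float:
        return self.fluid_viscosity * _CST * self.fluid_density

    @property
    def gas_reservoir_volume_m3(self) -> float:
        return math.pi * (self.gas_radius * _CM) ** 2 * (self.gas_height * _CM)

    @property
    def gas_initial_pressure_pa(self) -> float:
        return self.gas_initial_pressure * ATM_PA

    @property
    def fluid_initial_pressure_pa(self) -> float:
        return self.fluid_initial_pressure * ATM_PA

    @property
    def subcutaneous_pressure_pa(self) -> float:
        return self.subcutaneous_pressure * ATM_PA

    @property
    def dose_volume_m3(self) -> float:
        return self.dose_volume * _ML

    def replace(self, **changes) -> "DeviceConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)


def table1_config() -> DeviceConfig:
    """The device exactly as published: 5 atm gas reservoir.

    This gas budget cannot complete the three-dose schedule (see
    :func:`validate`, which warns); it is kept as a named preset so the
    published parameter set remains reproducible, including its stall.
    """
    return DeviceConfig(gas_initial_pressure=5.0)


def default_config() -> DeviceConfig:
    """Calibrated preset: published mechanics, gas budget raised to 20 atm
    so the full three-dose schedule is pneumatically feasible."""
    return DeviceConfig()


_POSITIVE_FIELDS = (
    "fluid_piston_radius",
    "fluid_piston_stroke",
    "fluid_piston_initial_displacement",
    "dead_volume",
    "fluid_initial_pressure",
    "needle_piston_radius",
    "needle_piston_stroke",
    "needle_inner_diameter",
    "needle_length",
    "chassis_mass",
    "gas_initial_pressure",
    "gas_radius",
    "gas_height",
    "fluid_viscosity",
    "fluid_density",
    "dose_volume",
)

_NON_NEGATIVE_FIELDS = (
    "spring_constant",
    "dashpot_coefficient",
    "wall_allowance_length",
    "subcutaneous_pressure",
)


def validate(config: DeviceConfig) -> DeviceConfig:
    """Check a configuration for physical self-consistency.

    Raises :class:`ConfigError` naming the offending field on hard errors;
    emits a :class:`GasBudgetWarning` when the isothermal gas budget cannot
    displace ``dose_volume * max_doses`` against 1 atm (the device would
    stall mid-schedule but is still simulatable).
    """
    for name in _POSITIVE_FIELDS:
        value = getattr(config, name)
        if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
            raise ConfigError(f"{name} must be strictly positive, got {value!r}")
    for name in _NON_NEGATIVE_FIELDS:
        value = getattr(config, name)
        if not (isinstance(value, (int, float)) and math.isfinite(value) and value >= 0):
            raise ConfigError(f"{name} must be non-negative, got {value!r}")
    if not (0.0 < config.spo2_threshold < 100.0):
        raise ConfigError(
            f"spo2_threshold must lie in (0, 100), got {config.spo2_threshold!r}"
        )
    if config.max_doses < 1:
        raise ConfigError(f"max_doses must be >= 1, got {config.max_doses!r}")
    if config.redose_interval <= 0:
        raise ConfigError(f"redose_interval must be positive, got {config.redose_interval!r}")
    if config.valve_conductance <= 0:
        raise ConfigError(f"valve_conductance must be positive, got {config.valve_conductance!r}")
    tp = config.tissue_force_params
    if tp.puncture_force < 0 or tp.stiffness < 0 or tp.damping < 0:
        raise ConfigError(f"tissue_force_params must be non-negative, got {tp!r}")
    if config.membrane_standoff_mm < 0:
        raise ConfigError(
            f"membrane_standoff must be non-negative, got {config.membrane_standoff_mm!r} mm"
        )
    # full insertion must be reachable within the piston stroke
    stroke_mm = config.needle_piston_stroke * _CM / _MM
    if stroke_mm < config.needle_length + config.membrane_standoff_mm - 1e-9:
        raise ConfigError(
            "needle_piston_stroke must cover needle_length + membrane_standoff: "
            f"{stroke_mm:g} mm < {config.needle_length:g} + {config.membrane_standoff_mm:g} mm"
        )
    capacity = reservoir_capacity(config, _validated=True)
    if config.dose_volume * config.max_doses > capacity + 1e-9:
        raise ConfigError(
            f"dose_volume*max_doses ({config.dose_volume * config.max_doses:g} ml) "
            f"exceeds reservoir capacity ({capacity:g} ml)"
        )
    budget = gas_displaceable_volume(config, 1.0, _validated=True)
    if budget < config.dose_volume * config.max_doses:
        warnings.warn(
            f"gas budget {budget:.3f} cm^3 at 1 atm back-pressure is below the "
            f"{config.dose_volume * config.max_doses:g} ml dosing schedule; "
            "the device will stall before completing all doses",
            GasBudgetWarning,
            stacklevel=2,
        )
    return config


def reservoir_capacity(config: DeviceConfig, *, _validated: bool = False) -> float:
    """Maximum antidote volume of the upper fluid compartment, ml.

    The swept cylinder volume pi * r^2 * stroke; with the published radius
    1.07 cm and stroke 1.1 cm this is ~3.956 ml, enough for three 1 ml doses.
    """
    if not _validated:
        validate(config)
    return math.pi * config.fluid_piston_radius**2 * config.fluid_piston_stroke


def required_length(config: DeviceConfig, *, include_walls: bool = False) -> float:
    """Length of the package needed by the side-by-side cylinders, cm.

    The fluid and injection cylinders sit side by side, so the internal
    length is the sum of their diameters (3.14 cm with published radii).
    With ``include_walls`` the wall allowance is added, giving the external
    package length (~4 cm).
    """
    validate(config)
    length = 2.0 * config.fluid_piston_radius + 2.0 * config.needle_piston_radius
    if include_walls:
        length += config.wall_allowance_length
    return length


def gas_displaceable_volume(
    config: DeviceConfig, back_pressure: float, *, _validated: bool = False
) -> float:
    """Maximum volume the gas reservoir can fill at >= ``back_pressure``, cm^3.

    Isothermal ideal-gas (Boyle) expansion from the cylindrical reservoir:
    ``V = P0*V_res/back_pressure - V_res``, floored at zero.  ``back_pressure``
    is absolute, in atm, and must be >= 1 atm.
    """
    if not _validated:
        validate(config)
    if back_pressure < 1.0:
        raise DomainError(f"back_pressure must be >= 1 atm, got {back_pressure!r}")
    v_res = math.pi * config.gas_radius**2 * config.gas_height
    return max(0.0, config.gas_initial_pressure * v_res / back_pressure - v_res)
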