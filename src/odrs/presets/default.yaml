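# Calibrated default preset: published mechanics with the gas budget raised
# to 20 atm so that the full three-dose schedule (insertion travel plus
# 3 x 1 ml) remains above atmospheric driving pressure, and with the valve
# conductance pinned so one full cycle (needle insertion + 1 ml infusion)
# completes within the 1.2 s design milestone.
device:
  fluid_piston_radius: 1.07          # cm
  fluid_piston_stroke: 1.1           # cm
  fluid_piston_initial_displacement: 0.01  # cm
  dead_volume: 1.0e-5                # cm^3
  fluid_initial_pressure: 1.0        # atm
  needle_piston_radius: 0.5          # cm
  needle_piston_stroke: 1.1          # cm
  needle_inner_diameter: 0.6         # mm
  needle_length: 8.0                 # mm (30 gauge)
  chassis_mass: 500.0                # g
  spring_constant: 11.0              # N/m
  dashpot_coefficient: 11.0          # N*s/m
  gas_initial_pressure: 20.0         # atm  <- raised for three-dose feasibility
  gas_radius: 0.3                    # cm
  gas_height: 0.9                    # cm
  fluid_viscosity: 0.658             # cSt
  fluid_density: 992.562             # kg/m^3
  wall_allowance_length: 0.86        # cm
  membrane_standoff: 3.0             # mm (stroke - needle length)
  valve_conductance: 8.0e-14         # m^3/(s*Pa), calibrated
  tissue_force_params:
    puncture_force: 1.0              # N
    stiffness: 150.0                 # N/m
    damping: 10.0                    # N*s/m
  dose_volume: 1.0                   # ml
  max_doses: 3
  redose_interval: 300.0             # s
  spo2_threshold: 90.0               # percent
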