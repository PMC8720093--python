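# Device parameters exactly as published (simulation and device parameter
# table).  Note: the 5 atm gas reservoir cannot displace the full three-dose
# schedule; loading this preset emits a gas-budget warning and simulated
# cycles stall.  Use the "default" preset for a pneumatically feasible device.
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
  gas_initial_pressure: 5.0          # atm  <- published value
  gas_radius: 0.3                    # cm
  gas_height: 0.9                    # cm
  fluid_viscosity: 0.658             # cSt
  fluid_density: 992.562             # kg/m^3
  wall_allowance_length: 0.86        # cm
  dose_volume: 1.0                   # ml
  max_doses: 3
  redose_interval: 300.0             # s
  spo2_threshold: 90.0               # percent
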