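"""Simulate one injection cycle and report the design milestones.

The pneumatic cycle: the valve opens, compressed gas drives the fluid
piston, the geared needle piston punches the 8 mm needle through the
membrane into tissue, the stop ring halts it, and the remaining piston
travel meters 1 ml of nalmefene through the needle.
"""

import odrs

config = odrs.default_config()
traj = odrs.simulate_cycle(config)

t_ins = traj.event_time("insertion_complete")
print(f"needle fully inserted at      {t_ins:.3f} s after trigger")
print(f"cycle complete at             {traj.duration:.3f} s (design target ~1.2 s)")
print(f"antidote delivered            {traj.injected_ml:.4f} ml (target 1 ml)")
print(f"insertion depth               "
      f"{odrs.insertion_depth(traj.final_state, config):.1f} mm (target 8 mm)")
print(f"peak needle force             {traj.peak_force_n:.2f} N (design: > 1 N)")

# The trajectory carries every channel on a 1 ms grid; export it like the
# CLI would with: odrs.write_trajectory(traj, "cycle.csv")
frame = traj.to_frame()
print(f"\ntrajectory: {len(frame)} samples, channels: {', '.join(frame.columns)}")
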