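"""Closed-loop overdose scenarios: persistent desaturation vs recovery.

A synthetic wearer holds SpO2 in the normal 93-97 % band until an overdose
starts a desaturation ramp.  The controller fires at the first sample at or
below 90 %, logging the 911 alert and dose 1 together, then re-checks every
5 minutes.  With no antidote response it delivers all three doses; with the
pharmacokinetic feedback model (8 h elimination half-life, fast subcutaneous
absorption) saturation recovers before the first re-check and one dose
suffices.
"""

import odrs

config = odrs.default_config()

for name in ("overdose-persistent", "overdose-recovery"):
    params, duration = odrs.scenario_preset(name)
    result = odrs.run_closed_loop(None, config, scenario=params,
                                  duration=duration, seed=1)
    doses = [e for e in result.log if e.kind is odrs.EventKind.DOSE]
    alerts = [e for e in result.log if e.kind is odrs.EventKind.ALERT]
    print(f"\n{name}:")
    for ev in alerts:
        print(f"  ALERT  at t={ev.t:7.1f} s (SpO2 {ev.spo2:.1f} %)")
    for ev in doses:
        print(f"  DOSE {ev.dose_index} at t={ev.t:7.1f} s (SpO2 {ev.spo2:.1f} %)")
    print(f"  final SpO2 {result.trace.values[-1]:.1f} %, "
          f"controller {result.controller.mode.value}, "
          f"total injected {result.device.v_injected / 1e-6:.2f} ml")
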