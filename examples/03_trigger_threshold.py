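"""Why 90 %: the dissociation curve behind the trigger threshold, plus
wearer screening.

SpO2 90 % sits at the onset of hypoxia; on the Severinghaus oxyhemoglobin
dissociation curve it corresponds to an arterial oxygen partial pressure of
roughly 60 mmHg (normal 80-100 mmHg).  Screening excludes wearers whose
resting SpO2 is already below 93 %, the accepted lower limit of normal.
"""

import odrs
from odrs.controller import WearerProfile

for spo2 in (97, 95, 93, 90, 88):
    pao2 = odrs.inverse_severinghaus(spo2 / 100.0)
    print(f"SpO2 {spo2:2d} %  ->  PaO2 {pao2:5.1f} mmHg")

print("\nwearer screening (no history/exam flags):")
for resting in (95.0, 93.0, 92.0):
    res = odrs.screen_wearer(WearerProfile(False, False, resting))
    verdict = "eligible" if res.eligible else f"ineligible: {', '.join(res.reasons)}"
    print(f"  resting SpO2 {resting:.0f} %  ->  {verdict}")
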