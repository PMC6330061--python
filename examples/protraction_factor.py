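"""Lea-Catcheside dose-protraction factor for different delivery patterns.

G scales the quadratic (repairable) term of the LQ model: G = 1 for an
acute exposure, smaller when delivery is slow compared with sublethal-damage
repair (half-time 1.5 h here).
"""

import numpy as np

from celldose.radiobiology import DoseRateProfile, lea_catcheside_g

mu = np.log(2) / 1.5  # repair rate, 1/h

for label, profile in [
    ("1 h linear uptake ramp", DoseRateProfile.linear_uptake(1.0)),
    ("1 h constant rate", DoseRateProfile.constant(1.0)),
    ("24 h linear uptake ramp", DoseRateProfile.linear_uptake(24.0)),
    ("decay-only tail (In-111, 60 d)", DoseRateProfile.decay_only(2.8047, 60.0)),
]:
    g = lea_catcheside_g(profile, mu)
    print(f"{label:32s} G = {g:.3f}")

print()
print("The 1 h uptake ramp barely protracts the dose (G ~ 0.89), while dose")
print("delivered over days by physical decay alone is almost fully repaired")
print("between hits (G ~ 0.01): the quadratic LQ term is suppressed 100-fold.")
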