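"""Synthetic internalization time course -> cumulated activity.

Generates a noisy two-compartment uptake curve, integrates it by the
trapezoidal rule, and extends it with a physical-decay tail.
"""

from celldose.kinetics import cumulated_activity, decay_extrapolation
from celldose.synthetic import SyntheticUptakeSpec, generate_timecourse

spec = SyntheticUptakeSpec(
    plateaus_Bq={"N": 0.05, "Cy": 0.12, "Cs": 0.08},
    sampling_times_h=(1.0, 24.0), shape="linear", noise_cv=0.1, seed=7)
curves = generate_timecourse(spec)

for comp in ("N", "Cy", "Cs", "cell"):
    c = curves[comp]
    acum = cumulated_activity(c, 24.0)
    samples = ", ".join(f"{t:.0f} h: {a * 1e3:.1f} mBq"
                        for t, a in zip(c.times_h, c.activities_Bq))
    print(f"{comp:4s} [{samples}]  cumulated (24 h) = {acum:.1f} Bq s")

a24 = curves["cell"].activities_Bq[-1]
tail = decay_extrapolation(a24, half_life_days=2.8047, horizon_days=14.0)
print(f"\ndecay-only tail after 24 h (14 d horizon): {tail:.0f} Bq s extra")
print("Uptake noise is multiplicative (10% CV); the tail assumes no further")
print("internalization, only In-111 physical decay (half-life 2.80 d).")
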