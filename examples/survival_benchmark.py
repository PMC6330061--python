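"""Surviving fraction and TCP for a benchmark exposure.

Runs the 24 h In-111-EGF exposure of an MDA-MB-468 spheroid (uniform
uptake, measured cumulated activities) through the three survival models:
(1) LQ with reference-radiation alpha/beta, (2) plus RBE 4 on nuclear
self-dose, (3) plus the Lea-Catcheside factor.  A 500-cell spheroid keeps
this example quick; population statistics tighten with more cells.
"""

from celldose.pipeline import run_survival

for model in (1, 2, 3):
    run = run_survival("MDA-468/EGF/24h", model, n_cells=500, seed=1)
    print(f"model {model}: SF = {run.sf:.3f}   TCP = {run.tcp:.3g}   "
          f"G = {run.result.G:.3f}   mean dose = {run.dose.total.mean():.2f} Gy")

print()
print("Model 1 leaves ~13% of cells surviving; weighting the nuclear")
print("self-dose by RBE 4 (model 2) drops survival to ~1%, matching the")
print("clonogenic measurement.  The peripheral-uptake counterpart:")
run = run_survival("MDA-468/EGF/24h", 2, n_cells=500, seed=1,
                   spatial="peripheral")
print(f"peripheral model 2: SF = {run.sf:.3f}  TCP = {run.tcp:.3g}")
print("Interior cells escape irradiation almost entirely (weak cross-fire),")
print("so tumor control collapses even though shell cells are overkilled.")
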