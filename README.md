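# celldose

Cellular dosimetry and tumor-control modeling for Auger-electron emitters in
spheroid micrometastases.

Targeted radionuclide therapy with Auger-electron emitters such as ¹¹¹In
deposits most of its energy within micrometers of each decay, so the
biological effect of a radiolabeled peptide or antibody depends critically on
*where* the activity sits — which cells of a micrometastasis are labeled, and
in which subcellular compartment.  `celldose` is a Python library for
radiobiologists and medical physicists that models this chain end to end:

1. **Dose-point kernel** — the ¹¹¹In electron line spectrum (Auger,
   Coster-Kronig and internal-conversion electrons) is transported in liquid
   water under a straight-track continuous-slowing-down approximation,
   giving the radial absorbed dose per decay `k(r)`.
2. **Cellular S values** — following the MIRD cellular schema, the mean
   nuclear dose per decay `S(N←σ)` is computed for sources σ uniform in the
   nucleus (N), cytoplasm (Cy) or on the cell surface (Cs) of a
   concentric-sphere cell, by a deterministic kernel-moment quadrature
   verified against a brute-force Monte Carlo track-sampling oracle.
3. **Spheroid geometry** — cells with correlated, empirically distributed
   radii are arranged by a random-close-packing pipeline (monodisperse
   densification to the jamming fraction ≈ 0.64, then carving and rescaling
   to the loose packing of real spheroids), and activity is assigned
   uniformly or to the peripheral rim as seen by microautoradiography.
4. **Survival and TCP** — per-cell dose `D_i = Σ_σ Ã_σ S_i(N←σ)` + neighbor
   cross-fire feeds the linear-quadratic model
   `SP_i = exp[−(α D_i + β G D_i²)]` with the Lea-Catcheside protraction
   factor `G`; population surviving fraction is `SF = ⟨SP_i⟩` and tumor
   control probability `TCP = Π_i (1 − SP_i)`.

Three survival-model iterations are provided: (1) reference α/β as fitted
from acute γ irradiation; (2) a relative biological effectiveness factor
(default 4) applied to the nucleus→nucleus self-dose; (3) model 2 with the
protraction factor applied to the quadratic term.

## Worked example

```python
from celldose.pipeline import run_survival

for model in (1, 2, 3):
    run = run_survival("MDA-468/EGF/24h", model, n_cells=500, seed=1)
    print(f"model {model}: SF = {run.sf:.3f}  TCP = {run.tcp:.3g}  "
          f"G = {run.result.G:.3f}")
```

prints

```
model 1: SF = 0.135   TCP = 1.6e-33    G = 1.000
model 2: SF = 0.010   TCP = 0.00598   G = 1.000
model 3: SF = 0.012   TCP = 0.00264   G = 0.169
```

— a 500-cell MDA-MB-468 spheroid uniformly loaded with the measured 24 h
¹¹¹In-EGF cumulated activities (19,558 Bq·s per cell, 3,688 Bq·s in the
nucleus).  Under model 1 about 13% of cells survive, dominated by the
largest nuclei (lowest dose per decay); weighting the nuclear self-dose by
RBE 4 drops the surviving fraction to ~1%, in line with clonogenic
measurements.  Switching the same scenario to peripheral-only uptake leaves
interior cells essentially unirradiated and drives TCP to zero — spatial
distribution, not total activity, decides tumor control.

The `examples/` directory holds short narrative scripts, one per
capability: `single_cell_svalues.py`, `pack_spheroid.py`,
`protraction_factor.py`, `survival_benchmark.py`,
`synthetic_timecourse.py`.  A thin CLI mirrors the pipeline:

```bash
celldose svalues --mode single
celldose pack --cell-line MDA-468 --n-cells 2000 --seed 1 --out runs/
celldose tcp MDA-468/EGF/24h --n-cells 2000 --out runs/
```

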