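# Methods

## Scope and model chain

`celldose` predicts clonogenic survival and tumor control probability (TCP)
for micrometastasis-scale cell assemblies exposed to an electron-emitting
radionuclide, with ¹¹¹In as the bundled reference emitter.  The chain is:

electron spectrum → dose-point kernel in water → cellular S values →
packed-spheroid per-cell dose → linear-quadratic (LQ) survival → SF / TCP.

Photon emissions are excluded throughout: at cellular distances their
absorbed fraction is negligible next to the Auger/conversion-electron dose.

## Electron transport model

The kernel uses a straight-track continuous-slowing-down approximation
(CSDA): an electron of initial energy `E0` travels in a straight line,
depositing `S_col(E(x))` per unit path until its CSDA range `R(E0)` is
exhausted.  Averaging over isotropic emission gives the point kernel

    k(r) = Σ_k y_k · S_col(E_k(r)) / (4 π r² ρ),   r < R(E_k),

with `E_k(r)` the residual energy at path length `r` (by inversion of the
range–energy relation).  Energy is conserved by construction; the test
suite checks `∫ 4πr²ρ k dr` against the spectrum total to 1%.

This deliberately omits multiple scattering, straggling and secondary
electron transport.  Straight tracks overestimate penetration near the end
of range, which matters most for sources several micrometers from the
target; in practice the dominant terms (nuclear and cytoplasmic self-dose
of short-range Augers) are insensitive, and single-cell nuclear S values
land within ~5% of published condensed-history Monte Carlo values.  The
largest observed deviation is the cell-surface S value of the
largest-geometry cell line (~+20%), where the source-to-nucleus gap is
comparable to the K-Auger range — a known CSDA failure mode, documented as
a limitation.

Radial grid: logarithmic from 0.01 μm to just past the maximum range, with
per-line refinement of each line's deposition span and end-of-range spike.
Energy deposited within the first 0.01 μm (sub-keV Auger/Coster-Kronig
electrons) is booked as a "local" deposit credited at the decay site.

### Data fixtures

* `in111_electron_lines.tsv` — a 12-line synthetic condensation of the
  ¹¹¹In electron spectrum assembled from published evaluated decay data
  (conversion-electron intensities of the 171/245 keV transitions; K/L/M
  Auger and Coster-Kronig yields pooled into mean-energy lines).  Total
  electron energy 34.9 keV per decay, ~14.5 electrons per decay.
* `water_stopping_range.tsv` — collisional stopping power of electrons in
  liquid water: ICRU-37/ESTAR anchor values for E ≥ 10 keV, and below
  10 keV an analytic branch matched to the Cole empirical range–energy
  relation, joined continuously.  CSDA ranges are integrated from the
  stopping-power column and are therefore self-consistent with it.

## Cellular S values

Cells are concentric spheres (nucleus radius `R_n` inside cell radius
`R_c`), unit-density water, with the standard MIRD cellular source regions:
uniform in nucleus volume (N), uniform in the cytoplasmic shell (Cy),
uniform on the cell surface (Cs); the target is always the nucleus.

The production path is a *kernel-moment quadrature*: the average of `k`
over a target sphere of radius `R` seen from a source point at distance `a`
has the closed form

    Φ(a,R) = 3/(4R³) · [ 4C₂(R−a)⁺ + ((R²−a²)ΔC₁ + 2aΔC₂ − ΔC₃)/a ],

where `C_n(d) = ∫₀^d k(u) uⁿ du` are cumulative kernel moments and the
differences are taken over the window `[|R−a|, R+a]`.  Each S value is then
a one-dimensional Gauss–Legendre integral over source radii.  Because
`Φ` varies on the scale of the shortest electron ranges (~0.01 μm) near the
nucleus surface, the source integral uses graded panels clustered at the
boundary; a refinement check (doubling the per-panel order) guards
convergence and raises an error reporting the achieved tolerance.

The independent verification route is a brute-force Monte Carlo oracle:
decay positions sampled in the source region, isotropic directions, energy
tallied along straight CSDA tracks through the target sphere by chord
geometry.  Quadrature and oracle agree to <2% over random geometries (test
suite); both routes share only the spectrum and stopping-power data.

Cross-fire between cells uses the same `Φ`: beyond twice the mean cell
diameter a neighbor's source region is treated as a point at its cell
center (`Φ` is still averaged exactly over the target nucleus); closer
pairs get a full source-region quadrature correction.  The two treatments
agree to ~1% at the switch distance for ¹¹¹In.  Per-cell "effective" S
values fold the summed cross-fire from all neighbors (uniform-labeling
convention) into population mean ± SD.

## Spheroid geometry

Packing proceeds in two stages:

1. *Monodisperse densification* — equal spheres in a periodic box are grown
   stepwise while a force-biased collective-rearrangement relaxation (pair
   push-apart with momentum, occasional shake moves, inner-radius fallback)
   removes overlaps; the process stalls at a jamming fraction of ~0.63
   (random close packing).  This replaces an event-driven molecular-
   dynamics compression with a vectorized scheme of the same physical
   intent; the structures are disordered, hard-core valid (center distances
   ≥ 2r(1−10⁻³)) and deterministic per seed.
2. *Carving, radius assignment, rescaling* — a ball (cluster) or disk
   (monolayer) of `n` centers is carved; radii are drawn from a truncated
   correlated bivariate normal (default correlation 0.7, location-corrected
   truncation so sample means match the specified means); larger cells are
   assigned to roomier sites (rank-preserving in nearest-neighbor
   distance); centers are rescaled so the realized cell-volume fraction
   matches the target.

Defaults: cluster volume fraction 0.17 (loosely associated spheroids, as
the bundled cell lines form), monolayer area fraction 0.50 (subconfluent
culture), peripheral shell depth two mean cell diameters.  All are
configurable.  Overlap repair after radius assignment nudges the rare
violating pair apart; an audit (gap ≥ −0.01·min radius) must pass on every
emitted model.

## Kinetics

Cumulated activity Ã is the trapezoidal integral of the piecewise-linear
time–activity curve anchored at A(0) = 0 (zero uptake at exposure start).
Measured two-point data (1 h, 24 h) invert uniquely back to the sampled
activities, which is used to continue a curve into the decay-only regime:
Ã(t) gains `A_end (1 − e^{−λt})/λ` with λ = ln2 / 2.8047 d for ¹¹¹In.
Whole-cell minus nuclear activity is split between cytoplasm and membrane
50/50 by default (`cy_fraction` exposes the assumption; the subcellular
fractionation data do not resolve it, and the 1 h sensitivity is small).
Measured activities are taken as live activities; no additional decay
correction is applied inside the measurement window.

## Survival and TCP

Per-cell dose is the MIRD sum `D_i = Σ_σ Ã_σ,i S_i(N←σ)` plus cross-fire
from all labeled neighbors; unlabeled cells receive cross-fire only.  The
three model iterations:

1. `SP = exp(−(αD + βD²))` with reference α/β;
2. nuclear self-dose multiplied by `RBE_nucleus` (default 4) before
   entering the exponent — the factor applies to the dose, hence to both
   LQ terms;
3. model 2 with the Lea-Catcheside `G` on the quadratic term.

`G` has closed forms for constant-rate and linear-ramp exposures (with
series guards against cancellation at small `μT`) and a numeric
double-integral route for arbitrary piecewise-linear profiles, exact per
linear segment; closed and numeric routes agree to 10⁻⁴.  The linear
uptake ramp is the default 1 h profile (G = 0.89 at repair half-time
1.5 h); 24 h exposures use the piecewise-linear profile through the two
measured uptake points; decay-only tails append an exponential segment and
use the numeric route for the combined profile.

`SF = mean(SP_i)`; `TCP = Π(1 − SP_i)` accumulated as `Σ log1p(−SP_i)`
(a cell with SP = 1 forces TCP = 0 exactly).  The dose-histogram report
bins cells at 0.5 Gy (default) with a per-bin TCP factor whose product is
the population TCP; empty bins carry the empty-product value 1.

## Benchmark scenarios and synthetic data

The scenario registry bundles, for three carcinoma cell lines and two
¹¹¹In-labeled agents at 1 h / 24 h: measured cell/nucleus radius
distributions, α/β from acute ¹³⁷Cs irradiation, whole-cell and nuclear
cumulated activities, and the spatial pattern (uniform vs peripheral rim)
observed by microautoradiography.  Experimental surviving fractions are
bundled for comparison only and never feed the pipeline.

The synthetic generator emulates internalization assays: linear or
saturating uptake to compartment plateaus, sampled at chosen times, with
multiplicative lognormal noise of specified CV (default conditions: 1 h and
24 h sampling, noiseless unless requested).  It reproduces compartment
structure and measurement noise, but not efflux, receptor saturation
kinetics, or intratumoral diffusion gradients — passing tests demonstrate
correct bookkeeping and statistical behavior of the pipeline, not the
biology of any particular agent.

## Validation problem sizes

The test suite validates population survival on 2,000-cell clusters (five
seeds), packing density at 2,000 spheres, and oracle agreement on 10 random
geometries at 2.5×10⁵ Monte Carlo samples per S value; examples use
500-cell spheroids.  These sizes give seed-to-seed SF scatter well below
the reported tolerances while keeping runs desk-scale; larger assemblies
(10⁴ cells) are supported and only tighten the statistics.

## Known limitations

* CSDA straight-track transport: no scattering/straggling; largest error
  for surface sources at large cell radii (observed ~+20% on one published
  cell-surface S value).
* The jamming fraction of the densification stage (~0.63) sits at the low
  end of the random-close-packing range reported for monodisperse spheres.
* The cytoplasm/membrane activity split is an assumption (default 50/50).
* TCP uses the deterministic product formula; stochastic (binomial) TCP
  sampling, cell-cycle and oxygenation effects, and bystander signaling are
  out of scope.
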