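# Methods

`feathermorph` simulates how a feather's vane shape — the widths of the
rachis, the two vanes and the barb generative zone (BGZ), and the angle at
which barbs meet the shaft — emerges from molecular signalling on the
epithelial cylinder of a growing feather follicle. The cylinder is
unrolled onto the periodic unit interval `x ∈ [0, 1)`: `x = 0` is the
anterior (rachis) midline, `x = 0.5` the posterior midline where the BGZ
sits, the lateral vane occupies `(0, 0.5)` and the medial vane `(0.5, 1)`.
This convention keeps anterior–posterior gradients continuous on the
circle and confines the wrap discontinuity of lateral–medial gradients to
the rachis, where branching is suppressed anyway.

The package has two dynamical layers and three analysis layers.

## 1. Regulatory layer (nine-species reaction–diffusion system)

The signalling model couples a retinoic-acid (RA) processing module to
three diffusible ligands. Dynamic species: extracellular RA (`RA_o`,
diffusible), intracellular RA (`RA_i`), free RA receptor (`R`), the
RA–receptor signalling complex (`RAR`), free CRABP1 (`BP`), the
RA–CRABP1 complex (`RABP`), and diffusible `WNT`, `GDF` (GDF10) and
`GREM` (GREM1). CYP26B1 (`CYP`) is a prescribed spatial profile, not a
dynamic variable.

Per node (diffusible species additionally get `D_i ∂²/∂x²` via the
periodic second-order Laplacian):

    d[RA_o]/dt = g_RAo(x) − (r_RAo + k_p)·[RA_o]
    d[RA_i]/dt = (1 − β)·k_p·[RA_o] − bindR − bindBP − r_RAi1·[RA_i]
    d[R]/dt    = B_R − r_R1·[R] − bindR + hand_ab − hand_ba
    d[RAR]/dt  = bindR − hand_ab + hand_ba − r_R2·[RAR]
    d[BP]/dt   = g_BP(x) − r_BP1·[BP] − bindBP − hand_ab + hand_ba
                 + r_RAi2·[RABP] + cyp(x)·[RABP]·r_cyp
    d[RABP]/dt = bindBP + hand_ab − hand_ba
                 − (r_BP2 + r_RAi2 + r_cyp·cyp(x))·[RABP]
    d[WNT]/dt  = g_WNT(x) − r_WNT·[WNT]
    d[GDF]/dt  = V_GDF·H⁺(WNT; k1, n1)·H⁻(RAR; k4, n4) + B_GDF − r_GDF·[GDF]
    d[GREM]/dt = V_GREM·H⁻(WNT; k2, n2)·F(RAR)·H⁻(GDF; k5, n5)
                 + B_GREM − r_GREM·[GREM]

with `bindR = k_on·[RA_i][R] − k_off·[RAR]`,
`bindBP = m_on·[RA_i][BP] − m_off·[RABP]`,
`H⁺(u; k, n) = uⁿ/(kⁿ + uⁿ)`, `H⁻ = kⁿ/(kⁿ + uⁿ)` and
`F(RAR) = floor + (1 − floor)·H⁻(RAR; k3, n3)`.

Modelling choices that were genuinely open:

* **Carrier hand-off is mass action.** RA is exchanged between the
  receptor and CRABP1 carriers at rates `j_alpha` (RAR + BP → RABP + R)
  and `j_beta` (RABP + R → RAR + BP). A first-order hand-off independent
  of the receiving free pool can drive that pool negative; mass action
  respects availability and keeps all pools non-negative without
  clamping.
* **CYP26B1 degrades the CRABP1-bound pool** (`cyp_target="bound"`):
  CRABP1 shuttles RA either to receptors or to the degrading enzyme, so
  the enzyme acts on the channelled pool and recycles free CRABP1. A
  config flag moves the degradation to free `RA_i` instead.
* **The RA signal is shuttle-dominated.** `k_on` (direct RA_i–receptor
  binding) defaults to 0.005, small against `m_on = 5`; RAR is formed
  mainly through the CRABP1 route (`j_beta`). This makes the steady RA
  signal respond to the CRABP1 and CYP26B1 levels — the quantities the
  presets vary — rather than being floored by a carrier-independent
  route.
* **RA repression of GREM1 is partial** (`rar_grem_floor = 0.55`): under
  saturating RA signal, GREM1 production falls to 55% of maximum rather
  than zero, matching a dose-dependent rather than all-or-none
  repression. This is what lets BGZ width vary continuously with RA level
  and lets opposing lateral–medial gradients tilt the GREM1 bump instead
  of switching it off.
* **Hill-link wiring** is a config table: `k1/n1` WNT→GDF10 activation,
  `k2/n2` WNT⊣GREM1, `k3/n3` RA-signal⊣GREM1, `k4/n4` RA-signal⊣GDF10
  (deliberately weak, `k4 = 1`), `k5/n5` GDF10⊣GREM1. Rewiring requires
  only editing `config/defaults.yaml`.

**Graded inputs.** Spatially dependent quantities follow
`a·exp(v·arg)`: the anterior–posterior argument is the circumferential
distance `d(x) = min(x, 1 − x)` from the rachis midline (continuous on
the circle); the lateral–medial argument is `x − 0.5` (monotone across
both vanes). `v = 0` reduces to the constant `a`, the single amplitude
the named presets quote. WNT production is anterior-peaked
(`a = 1, v = −12`); CRABP1 production and the CYP26B1 profile carry the
preset amplitudes/slopes; RA_o production is constant by default.

**Presets.** All numeric defaults live in `config/defaults.yaml`; each
named preset overrides only the CRABP1/CYP26B1 amplitudes (artificial
units) and, for the gradient presets, the shared slope magnitude
`v = ±8` with opposing signs (CRABP1 rising medially, CYP26B1 falling).
The documented amplitude pairs: high RA 1.1/0.02, low RA 0.005/0.2,
steep 0.006/5, intermediate 0.03/0.5, shallow 0.06/0.3. The steep →
shallow asymmetry continuum arises because these pairs place the RA
signal progressively differently against the GREM1 sensitivity range
`k3`. `grem1_overexpression` raises `V_GREM` to 1.6;
`dnrar_block` cuts receptor production to `B_R = 0.005` (a strong
dominant-negative), which collapses the RA signal and phenocopies the
low-RA regime.

**Numerics.** Second-order central differences in space, classical
fourth-order Runge–Kutta in time with `dt ≤ 0.4·dx²/(2·max Dᵢ)` (also
capped at 0.02 for the reaction stiffness; the steep preset uses 0.01
because its CYP26B1 profile reaches ≈ 270 at the wrap). Steady state is
declared when the max-norm residual stays below `1e-8` for 100
consecutive steps (cap 2×10⁵ steps at the default N = 200; presets
converge in 1–4×10³ steps). There is no positivity clamping: a field
dipping below −1e−9 raises an error naming the species, node and step —
the signal that `dt` is too large. Non-convergence returns a flagged
result, not an exception.

## 2. Branching layer (activator–inhibitor model)

A diffusible self-activating activator `A` drives a diffusible inhibitor
`B` and a non-diffusible inhibitor `C`; both inhibit `A`. With
`H(u) = u^{n_G}/(s_G^{n_G} + u^{n_G})`:

    dA/dt = D_A ∇²A + s·A²/((1 + s_A A²)(1 + s_C C)
            (1 + s_B B (1 − g_grem H(GREM)))) + b_A − r_A A
    dB/dt = D_B ∇²B + c_B·A²/(1 + s_A A²) + b_B (1 + g_gdf H(GDF)) − r_B B
    dC/dt = b_C·A²/(1 + s_A A²) − r_C C

Steady GREM1 relieves the B-mediated inhibition of A (gain `g_grem`,
strictly the B term), letting A run high and disordered in the BGZ;
steady GDF10 raises basal B production (gain `g_gdf`), extinguishing
discrete peaks at the rachis. With both profiles zero the coupled step is
bit-identical to the uncoupled model. `c_B` (scale of the A-activated B
production) and the two gains are package parameters exposing couplings
whose strengths the underlying description leaves free. The ambiguous
placement of `s_C` defaults to the inhibition factor `(1 + s_C C)`; a
config flag moves it into C's production saturation.

Integration is forward Euler with `dt = 0.2·dx²/max(D_A, D_B)`. The
default (feather) parameter set sits in an oscillatory finite-wavenumber
regime (slow C, `r_C = 0.04`): activator peaks nucleate at the BGZ edges
and travel toward the rachis at constant speed — the travelling waves
that give barbs their helical pitch. Three additional near-Turing
variants (`turing_a/b/c`, fast C decoupled via `b_C = 0`) produce
stationary stripes used for wavelength diagnostics.

**Linear-stability oracle.** `dispersion_relation` linearizes the
reactions about the active homogeneous fixed point (found by
multi-start root finding; the largest-A root, since the system is
typically bistable with a low basal state) and subtracts
`q² diag(D_A, D_B, 0)`; `most_unstable_mode` maximizes growth over the
integer circumferential modes. An option replaces `q²` with the discrete
Laplacian symbol `(2 − 2cos(q dx))/dx²`.

**Wavelength-selection check.** Saturated nonlinear patterns select a
spike count near, not exactly at, the linear argmax; on a unit circle the
mode number is quantized, so the check averages the late-time dominant
wavelength over an ensemble of 7 noise seeds and compares the mean to the
most-unstable wavelength. The three variant sets put the selected mode at
k ≈ 20–23 (9–10 grid points per wavelength at N = 200), where one-mode
granularity (≈ 1/k² ≈ 0.002) is well below the one-grid-spacing
tolerance; integration is 4×10⁴ Euler steps per run, long past amplitude
saturation.

## 3. Vane geometry

* **Zones.** Rachis = contiguous run around `x = 0` with GDF10 above an
  absolute threshold; BGZ = contiguous run around the GREM1 maximum above
  its threshold; the rest is vane, split lateral/medial by which arc ends
  at the BGZ. Default thresholds (0.4410, 0.4675) are 50% of the
  symmetric preset's steady maxima, frozen in config as absolute numbers
  so that cross-preset comparisons ("BGZ widens when GREM1 rises") are
  meaningful; `"auto"` switches to 50% of the profile's own range. The
  asymmetry index is `(medial − lateral)/(medial + lateral)` vane width.
* **Wave speed.** Mean spatial wavelength (dominant peak of Hann-windowed
  periodograms averaged over the analysis window, parabolic peak
  interpolation) times mean temporal frequency (same estimator on the
  zone-centre time traces). A phase-drift cross-check — the slope of the
  dominant spatial mode's phase over time — must agree within 10% or a
  quality warning is attached to the result. Stationary patterns report
  frequency 0 by a temporal-variance test.
* **Helical angle.** `θ = arctan(W/V)` in degrees; the barb–rachis angle
  adds the maturation expansion angle `β_expand` (config, default 20°),
  which is a material property of barbs, not modelled. Barb length is
  vane arc width / sin(barb–rachis angle).
* **Cell-shape feedback.** Mean RA signal per side maps to a cell aspect
  ratio `ρ(RAR) = 1 + (ρ_max − 1)·k_ρ²/(k_ρ² + RAR²)` (low RA →
  elongated, defaults ρ_max = 3, k_ρ = 0.2); elongation multiplies the
  outgrowth rate V by ρ and divides the activator diffusivity by
  λ(ρ)², with λ(ρ) = 1 + κ(ρ − 1) fitted on synthetic lattices. Both
  multipliers are exactly 1 at ρ = 1. Both mechanisms sharpen the
  helical angle on the low-RA side.
* **Silhouette.** Per proximal–distal slice `z = V·t`, half-widths are
  vane arc widths projected by sin(barb–rachis angle); barbs are drawn as
  straight segments at that angle; output SVG/PNG.

## 4. Tortuosity

Tortuosity `λ = L/C`: shortest path between two points through the
tissue over the straight chord. The walkable set is the centroid
adjacency graph — cells sharing a boundary edge are connected, edge
weight the centroid distance — and `L` adds the end segments from the
query points to their cells' centroids. `λ` is floored at 1 (the
centroid detour can undercut the chord at short range; a physical path
cannot). Apparent diffusivity is `D* = D/λ²`. `mean_tortuosity` averages
100 seeded point pairs with chords ≥ 5 mean cell diameters along a fixed
axis. Cell shape metrics use best-fit-ellipse aspect ratios from the
polygon's second area moments and shoelace areas.

## 5. Candidate screen

For gene × sample TPM tables with two groups (narrow-vane vs wide-vane
tissue) and paired replicates, a gene passes when (i) the higher group's
mean over the lower's exceeds 1.8 (strict), (ii) the higher group's mean
TPM exceeds 25 (strict), and (iii) every replicate pair changes in the
same direction. The fold change floors the lower mean at a pseudocount
of 1 TPM — this handles zeros and leaves verdicts exactly scale
invariant once abundances clear the floor, which an additive pseudocount
would not.

## 6. Synthetic data

All generators take explicit seeds and return their ground truth.

* `synthetic_kymograph`: travelling sine `sin(2π(x − wt)/λ₀)` plus
  optional Gaussian noise; the wavelength must divide the circumference
  integrally (no spectral leakage in fixtures).
* `generate_cell_lattice`: Voronoi tessellation of a jittered square
  grid (jitter 0.1 of the pitch), domain scaled by `stretch` along the
  proximal–distal axis. Stretch 1 gives mean aspect ≈ 1.1; stretch 2
  reads back ≈ 1.9 from the moments; tortuosity along the perpendicular
  axis rises monotonically with stretch. Larger jitter makes cells
  rounder and was rejected because it erases the anisotropy the stretch
  parameter is supposed to impose.
* `generate_expression_table`: log-uniform baselines with antisymmetric
  replicate scatter so group means sit exactly at the planted fold
  change; non-passing genes cycle through the three single-failure modes
  (fold change in [1.1, 1.7], abundance capped at 20 TPM, one flipped
  replicate pair).

What the synthetic data does not emulate: sequencing noise models
(dispersion, library size), real epithelial segmentation artefacts,
curvature of the follicle, or biological replicate correlation
structure. Passing tests therefore demonstrate correctness of the
estimators and filters on idealized inputs, not robustness to the noise
of real measurements.

## Problem sizes and determinism

Default grid N = 200 (dx = 0.005). Regulatory steady states converge in
1–4×10³ RK4 steps (~1–3 s each); branching runs use 4×10⁴–1.2×10⁵ Euler
steps. Convergence-order studies use N ∈ {50, 100, 200} against the
analytic diffusion solution (spatial) and dt-halving against an
adaptive eighth-order reference integrator (temporal; the test
configuration keeps all rates of comparable magnitude so the refinement
sequence sits in the asymptotic range). Every stochastic element is an
explicitly seeded initial condition; runs are bit-reproducible given the
seed, and pipeline manifests are byte-identical across repeats up to the
recorded wall-clock time.

## Known limitations

* 1-D circumference only: no proximal–distal PDE coupling, follicle
  mechanics, or 2-D cylinder surface; the silhouette is a geometric
  projection, not a growth simulation.
* The regulatory equations are a reconstruction from the species list
  and parameter roles of the underlying description (the printed display
  equations were not available in the extraction); parameter values are
  package calibrations except the preset amplitudes quoted above.
* Wave-speed estimation needs several spatial and temporal periods in
  the analysed zone; narrow vane zones near onset give noisy speeds (the
  cross-check warning flags these).
* The emarginated-notch change of vane width over growth time is only
  representable as piecewise preset switching (per-slice zone maps in
  the silhouette renderer), not as a dynamic process.
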