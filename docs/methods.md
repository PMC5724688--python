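# Methods

This note documents the models in `canophot`, the defaults they ship with,
and what the synthetic stand does and does not establish.

## 1. Canopy geometry

A stand is a `plants_x × plants_y` grid of plants at `row_spacing ×
plant_spacing` (default 0.25 × 0.20 m, 20 plants m⁻²). Each plant carries
several whorls ("tillers") of five leaf ranks; rank 1 is the flag leaf.
A blade is a strip of `segments` quads along a centreline whose local
inclination declines linearly from the base angle (droop parameter
`curvature`; 0 = straight). Width tapers as `w(s) = w_max·(1 − s²)`, so the
one-sided blade area is `(2/3)·length·w_max` analytically; mesh area matches
within discretisation error (<1% at 8 segments). The default rank geometry
(heights 0.28–0.85 m, lengths 0.30–0.44 m, widths 17–20 mm, inclinations
40–75°) is illustrative of a booting-stage paddy stand — the measured
dimensions of any particular cultivar are not reproduced — and gives
LAI ≈ 3.4 with 7 tillers. Architecture factors scale leaf angle (clamped to
[0°, 90°]), plant height, and blade width (LAI route, leaf count and angles
preserved). Construction is a pure function of (spec, seed); the seed only
jitters plant positions and blade azimuths.

Chlorophyll is assigned per facet: `uniform`, or `profiled` with a relative
rank × along-blade table (declining with rank and from blade base to tip,
a measured-like gradient) rescaled so the area-weighted mean hits the target
exactly.

## 2. Light environment

Solar position uses Spencer's declination series with the local solar hour
angle. Clear-sky PAR: beam-normal PPFD `S₀·τ^m` with S₀ = 2550 µmol m⁻² s⁻¹
(extraterrestrial PAR), τ = 0.75, air mass `m = 1/cos z`; horizontal diffuse
`0.3·(1 − τ^m)·S₀·cos z`. At Shanghai latitude on DOY 235 this peaks near
1960 µmol m⁻² s⁻¹ total horizontal at noon — a realistic clear summer day.
The diffuse sky is a standard overcast sky (SOC) radiance, `L ∝ (1+2cosθ)/3`.

The ray tracer launches direct rays from a plane above the stand and
SOC-sampled diffuse rays, with the plot tiled periodically in x and y
(extended-field boundary). Triangles live in a 2D uniform grid over the
periodic cell; rays walk cells by DDA and wrap at the boundary. At a leaf
hit, energy splits deterministically into absorbed / reflected / transmitted
per that facet's optics; scattered components continue as cosine-sampled
(Lambertian, no specular term) rays up to `max_bounces` (default 3) with a
1% per-ray energy cutoff. Whatever is neither absorbed by leaves or soil nor
escapes upward is tallied as `lost`, so the energy audit is exact by
construction and the closure test (leaf + soil + escape = injected within
1%) bounds the bounce-truncation error. Soil is a Lambertian absorber with
reflectance 0 by default. The estimator is unbiased in ray density; facet
noise scales as (hits)^(−1/2).

Extinction coefficients are fitted by binning facets into 10 bins of
cumulative LAI from the top (Beer's law is defined on downward cumulative
leaf area, not geometric height) and regressing log mean PPFD on depth.
On a homogeneous stand with a spherical leaf-angle distribution the fit
recovers the turbid-medium value G/cos z = 0.5 within sampling error.

## 3. Leaf optics and chlorophyll accounting

Per-PSII chlorophyll: cores of 37 (PSII) and 95 (PSI) chlorophylls, 14 per
LHC unit, n₁ LHC units on each photosystem, PSI/PSII ρ = 1.4 by default, so
`Chl = [PSII]·(170 + 33.6·n₁)`; the inverse map (n₁ from a chlorophyll
target) is exact algebra and errors below the core-only minimum.

Broadband PAR absorbance follows a saturating curve
`a(Chl) = a_max·(1 − e^(−Chl/Chl₀))` with `a_max = 0.96` and Chl₀ solved so
`a(494.7) = 0.90` (healthy rice flag leaf); the instrument-fitted optics
equations behind the original measurements are not published, so this
documented stand-in is config-replaceable. The unabsorbed fraction splits
1:1 between reflectance and transmittance. A SPAD ↔ chlorophyll calibration
(`chl = 99·(e^{0.042·SPAD} − 1)`, exact inverse) covers readings up to 60.
Consequence worth noting: this curve forces absorbance 0.64 at 0.4× the
default chlorophyll, so the incident-light quantum yield *must* drop ~20%
under antenna reduction; a flatter (unpublished) absorbance curve would
leave it nearer constant.

## 4. Leaf photosynthesis

Seven pools: Rubisco, other Calvin–Benson enzymes (CE), electron transport
chain + ATP synthase (ETCF) in g m⁻²; PSII, PSI, LHCII, LHCI in µmol m⁻².
Defaults for a flag leaf: 1.8 / 0.9 / 0.7 g m⁻², PSII 0.8 µmol m⁻²
(n₁ ≈ 13.3 at 494.7 µmol Chl). Capacities: `Vcmax = 50.9·Rubisco` (3.5 s⁻¹ ×
8 sites / 550 kDa) capped by `160·CE`; chain capacity `Jmax = 280·ETCF`
µmol e⁻ m⁻² s⁻¹. CO₂/O₂ kinetics at 25 °C (Γ* = 42.75, Kc = 404.9,
Ko = 278.4, O = 210), `c_i = 280` µmol mol⁻¹ (0.7 × ambient; no stomatal
model), dark respiration 1.0 µmol m⁻² s⁻¹. Temperature is accepted as an
argument but no response is applied. Nitrogen: 0.16 g N per g protein for
the mass pools; 0.056, 0.093 and 0.005 g N per µmol for PSII, PSI and LHC
(350 kDa, 580 kDa and 26.5 kDa complexes, LHC including chlorophyll N).

**Excitation partitioning.** Absorbed PAR splits evenly between
photosystems (state transitions assumed to keep excitation balanced). At
PSII, a lake model with open-centre fraction q gives

    f_p(q) = q·k_p / (q·k_p + σ·(k_f + k_d) + k_npq·(1 − q))

with σ the antenna chlorophyll per PSII relative to the default (basal
fluorescence/heat losses scale with antenna size) and regulated quenching
`k_npq = k_npq_max·(1 − q)` independent of antenna size (the PsbS/
xanthophyll machinery is not proportional to LHC count). q solves the
steady-state balance `I_PSII·f_p(q) = k_r·(1 − q)` (unique root, vectorised
bisection), where `k_r = min(J_sink/[PSII], 300 s⁻¹)` — the cap is the
intrinsic reopening ceiling of a centre, and is what makes the light-response
initial slope *fall* when photosystem number is reduced, as observed.
Constants: k_p = 1, k_f = 0.05, k_d = 0.1548 (dark-adapted f_p = 0.83 at the
default antenna — the canonical maximal PSII yield), k_npq_max = 1.4 (chosen
so the leaf is capacity-limited, not quench-limited, at saturating light;
ΦPSII ≈ 0.16 at 2000 µmol m⁻² s⁻¹, in the measured range). These are
calibrations, not measured data.

Assimilation is `min(W_c, W_j) − R_d` with `W_j` from the realised electron
flux. Behavioural consequences, all tested: photochemistry fraction falls
with light and rises as antenna shrinks; the absolute photochemical flux at
saturation is antenna-invariant within 10%; antenna reduction raises the
absorbed-light initial slope while photosystem-number reduction lowers both
slopes; saturated assimilation is independent of antenna size.

**Linear calibration (pool → P_max, φ).** Simulated light-response curves
are fitted with a four-parameter nonrectangular hyperbola (NRH; θ default
0.8) and regressed on pools: capacity pools co-scaled 0.6–1.4× for the three
P_max relations; the photosystem complex co-scaled 0.85–1.15× for the φ–PSII
relation (the physiological range of photosystem density — beyond it the
saturating absorbance leaves the locally-linear regime). Both R² exceed
0.98. The light grid carries dense low-light points so the fitted φ tracks
the true initial slope.

## 5. Nitrogen profile and acclimation

Daily incident light integrals per facet drive
`N_LA = (N_LA^fl − n_b)·(I/I_fl)^b + n_b` (clipped to [n_b, N_LA^fl]); the
flag-leaf reference is the median-height tercile of rank-1 facets. The
exponent uses the power form `b = β·GAI^(−α)` (β = 0.8, α = 0.45 defaults;
the linear form `β·GAI − α` is a config option since the printed source form
is ambiguous). Defaults: flag-leaf N 1.55 g m⁻², basal 0.40 g m⁻²;
photosynthetic machinery holds 55% of leaf N (matching the default pool set,
0.846 g N m⁻² at the flag).

**Free optimizer (module level).** For a nitrogen budget and diurnal light
course, a 1-D frontier sweeps the allocation fraction x between capacity
pools and the photosystem complex (base proportions preserved on each side,
so nitrogen is conserved exactly along the frontier). Each point carries
P_max from the linear Rubisco relation and φ from the *exact* concave
absorbance/antenna map — extrapolating the linear φ fit far below its
calibration range under-penalises shedding photosystems (its positive
intercept dominates) and collapses every optimum onto a degenerate
chlorophyll-free boundary; the concave map restores interior optima. Daily
carbon is the uniform-step quadrature of the NRH response; the argmax is
returned, ties toward lower P_max. The optimizer reproduces the classic
acclimation direction (low growth light → higher φ, lower P_max) and matches
a dense brute-force search within one grid cell.

**Pipeline acclimation (chlorophyll-constrained).** The default stand is
defined by its measured-type chlorophyll (mean 494.7 µmol m⁻²), so in the
pipeline the photosystem side of each facet is sized to its assigned
chlorophyll and the remaining budget goes to capacity pools. Where the
photosystem side alone would exceed a shaded facet's budget, chlorophyll is
trimmed so at least 10% of the budget stays in the carbon machinery. (A
fully free optimizer under this optics world settles at ~200–350 µmol Chl —
it independently asserts that the default chlorophyll is supra-optimal,
which is the hypothesis the scenario engine is built to probe, but it cannot
then serve to *define* the default stand.)

## 6. Scenarios and integration

From the default (acclimated) pools, each scenario multiplies facet
chlorophyll by 0.4–1.2 via the antenna route, with either `lhc_only`
(freed LHC nitrogen discarded) or `constant_total_n` (freed ΔN spread over
the other five pools in proportion to their nitrogen, iterated with the
antenna re-solve until both the chlorophyll target and nitrogen conservation
hold to <10⁻⁹; when redistribution would push photosystem number past the
n₁ = 0 boundary, photosystems pin at the core-only ceiling and capacity
pools take the rest). Light is re-traced with the modified optics; the
mechanistic leaf model runs per facet and time step;
`A_c = Σ_f Σ_t A·area·Δt / ground area`, canopy photosynthetic N counts the
seven pools only, and `NUE = A_c / N` by definition (checked to machine
precision).

On the full default stand (LAI ≈ 3.4, Shanghai, DOY 235, 10⁵ rays m⁻² per
step), reducing chlorophyll to 40%: `lhc_only` raises A_c ≈ 7% and NUE
≈ 31%; `constant_total_n` raises both ≈ 26%. The reinvestment strategy
dominates plain removal at every multiplier, uptake falls above the default
chlorophyll (1.2×), and the 0.4×-with-reinvestment gain is positive in every
cell of the architecture × latitude robustness grid, larger at higher LAI.
The relative benefits shrink somewhat as ray density rises (better-resolved
scattered light benefits the default canopy's lower leaves most), so
scaled-down runs report slightly larger gains.

## 7. Numerical choices and limitations

- Tolerances: open-fraction bisection 60 iterations; reallocation
  convergence 10⁻⁹ relative N; NRH fits bounded (φ < 0.125, θ ∈ (0.01, 1)).
- Ray budgets: production 10⁵ rays m⁻² per 0.5 h step (≈1 s/step on the
  default 5 000-facet stand); tests and the robustness grid run scaled-down
  stands (fewer tillers/segments, coarser steps, 10⁴–5×10⁴ rays) — this
  changes Monte-Carlo noise and absolute A_c slightly but none of the
  orderings asserted.
- The synthetic stand emulates plausible paddy geometry and nitrogen, not
  any measured cultivar: green tests establish mechanisms, conservation
  laws, and scenario *orderings*, not absolute field values. Absolute A_c
  (≈0.74 mol m⁻² d⁻¹ daily) is in the realistic range but not validated
  against gas exchange.
- Not modelled: stems/panicles, within-canopy CO₂ gradients, stomatal and
  temperature responses, NPQ induction/relaxation dynamics, spectral
  (per-wavelength) transport, chlorophyll a/b distinction, seasonal growth.
- One known tension: with the pinned saturating absorbance curve, the
  incident-light initial slope necessarily drops ~20% at 0.4× chlorophyll
  (antenna route), and the NUE gain under `lhc_only` (~31%) overshoots the
  ~14% a lower-LHC-share parameterisation would give, while the
  `constant_total_n` gain (~26%) falls short of 30% because capacity here
  responds linearly — not superlinearly — to reinvested nitrogen. These
  trace to the unpublished optics/composition tables this package replaces
  with documented literature-typical values.
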