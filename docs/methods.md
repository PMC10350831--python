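# Models, parameters and numerical choices

This note documents the scientific models behind `envgrowth`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical details that matter for reproducing results.

## Shape model

Cells are treated as spherocylinders: a cylinder of length `L − W` capped
by two hemispheres of diameter `W`. This gives closed forms

- surface `S = π W L`
- volume `V = π W² L / 4 − π W³ / 12`
- projected (2D silhouette) area `W (L − W) + π (W/2)²`

which reduce correctly to the sphere at `L = W` and are linear/strictly
monotone in `L`. The closed forms are verified in the test suite against
numerical surface- and solid-of-revolution integration to 1e-9 relative
error on a 20 × 20 grid of `(L, W)`.

**Mask morphometry.** The centerline is the ridge of the Euclidean distance
transform: the skeleton of the mask, pruned to its longest endpoint-to-
endpoint path (any residual side branch beyond a 3-pixel spur tolerance
flags the cell as non-rod-like and excludes the frame), resampled, lightly
Savitzky–Golay smoothed, and extended at both ends along the local tangent
to the subpixel marching-squares contour so that `L` is the pole-to-pole
arc length. `W` is the median full chord normal to the centerline over its
central 60% — the two-sided chord rather than twice the nearest-boundary
distance, because the discrete skeleton can sit a fraction of a pixel off
the true axis. One scalar width per frame follows the convention of
single-cell morphometry tools that report one width per cell per time
point; the exact meshed-diameter definition of those tools is not restated
here, and the chord-median is the documented substitute. On analytically
rasterised masks at 0.05 μm pixels, `L` and `W` are recovered within one
pixel, which bounds the shape error propagated into `S` and `V`.

**Curvature.** The centerline is resampled to uniform 0.1 μm arc-length
spacing; κ is the mean |Δθ/Δs| of the tangent angle. The angular
*increments* (not the angle itself) are Gaussian-smoothed (σ = 2 samples):
a circular arc has constant increments, so this estimator is bias-free in
both the arc and straight-line limits, and sampled circles with radii
1–10 μm give 1/R within 1%. The sign of κ is discarded; only unsigned
curvature enters the analyses.

## Dry mass from quantitative phase

Interferometric phase microscopy measures the optical path delay caused by
intracellular dry matter. The integrated phase is the sum of strictly
positive pixel values inside the cell mask — the positive-pixel rule
doubles as background rejection for a zero-mean background, and no local
background subtraction is applied. Mass follows the linear calibration

    M = f · λ / (2π α) · Φ · A_px

with wavelength λ (default 0.55 μm), specific refractive increment
α = 0.18 μm³/pg (the standard literature value for cellular dry matter),
pixel area `A_px`, and a dimensionless correction factor `f` (default 1)
that absorbs instrument-specific optical artefacts. `f` is declared, not
fitted: estimating it would require an optical simulation of a specific
microscope, which is outside this package's scope. Reconstruction of phase
images from raw interferometric frames (the 6-step π/2 phase-shifting
algebra) is likewise hardware-specific and out of scope; the pipeline
starts from phase images.

## Growth rates and population aggregation

Time traces of M, S, V, L, W are filtered with a Gaussian of standard
deviation σ (reflecting boundaries; σ = 0 is the identity; a σ above half
the trace duration is clipped with a warning). The default σ is 2 frames;
per-experiment values are configurable. The relative (logarithmic) growth
rate uses the symmetric difference

    λ_X(t_{i+1/2}) = 2 (X_{i+1} − X_i) / ((X_{i+1} + X_i) Δt_i),

and rates are then smoothed with the same filter as the quantities. On an
exact exponential this estimator equals `(2/Δt) tanh(λΔt/2)`; its relative
bias is `(λΔt)²/12` to leading order (0.08% at λΔt = 0.1), which the test
suite asserts.

**Lysis** is called at the first frame-over-frame relative drop of the
(lightly smoothed) mass or volume trace exceeding 30%, placed at the
preceding interval midpoint; subsequent frames are excluded. The 30%
threshold is a package choice: lysis appears in the data as a
discontinuity, and the generator's single-frame collapse to 35% makes the
calls unambiguous, while ordinary observation noise (a few percent) never
trips it.

**Aggregation.** Population curves are aligned to a per-cell event — the
MreB-motion stop when a track-based call is available, otherwise the
configured drug-addition time — and each cell's smoothed quantity is
normalised to its interpolated value at the event, so every curve passes
through 1 at time 0. The mean and the standard error of the mean (sample
SD, ddof = 1, over the cells contributing at each aligned time point) are
reported; display bands are mean ± 2·SE for growth quantities and
mean ± 2·SD for the curvature-vs-length cohorts. Cells drop out of the
average after lysis. Smoothing *before* normalisation matters: normalising
by a single noisy frame would imprint that frame's noise on the whole
curve as a persistent offset.

## MreB activity and motion-stop calling

MreB rotation reports active cell-wall insertion, so its arrest is the
proxy for synthesis arrest. The chain mirrors the standard single-particle
workflow:

1. **Detection** — single-scale Laplacian-of-Gaussian matched to a 0.15 μm
   spot diameter; local maxima above an automatic threshold (4 robust
   standard deviations of the filtered frame — the absolute intensity
   threshold of the original workflow is not published, so a
   scale-free criterion is used) with quadratic subpixel refinement.
   Spots closer than the spot size merge into one detection.
2. **Linking** — greedy nearest-neighbour assignment against a
   constant-velocity prediction (velocity exponentially averaged over the
   track history, damping localisation noise), radius 0.06 μm and 1 gap
   frame for 1 s movies, 0.12 μm and 2 gaps for 2 s movies. This
   approximates a linear-motion LAP/Kalman tracker; at the spot densities
   involved (mean spacing ≫ search radius) the global assignment and the
   greedy one coincide, which the noiseless-scene test checks exactly.
3. **Smoothing & persistence filter** — track coordinates are
   Savitzky–Golay filtered (span 7, polynomial order 2; order is a package
   choice, span follows the workflow); tracks shorter than the span pass
   through unsmoothed and then fail the step criterion. Kept tracks need
   ≥ 7 steps and ≥ 0.2 μm end-to-end distance. Decisions are verified
   against an exhaustive brute-force re-application of the rule on 1,000
   random tracks.
4. **Activity** — `A = Σ smoothed path lengths / (segmented area · time)`
   in μm⁻¹ min⁻¹, evaluated in sliding 2-min windows with 1-min stride
   (the original workflow computes one number per movie; windowing
   localises the stop and is a declared extension). Steps straddling a
   window edge contribute pro-rata by time.
5. **Stop call** — the first window centre with `A < 0.08 μm⁻¹ min⁻¹`.
   On synthetic scenes the call lands within one window of the programmed
   arrest without localisation noise and within two windows at the default
   0.01 μm noise.

Localisation noise inflates smoothed path lengths (a random-walk
contribution adds in quadrature to the directed step), so measured
activity sits slightly above the programmed `density × speed × duration`
expectation — about +10% at the default 10 nm/s track speed and 10 nm
noise. This bias is inherent to path-length statistics at step-level
SNR ≈ 1 and affects the absolute activity, not the sharp drop at arrest
that the stop call detects.

## Agarose-pad diffusion

Perturbations reach cells on a pad by diffusion, modelled in 1D across the
pad height with a single effective D (agarose treated as free solution).

- **Stacked-pad osmotic ramp**: both faces impermeable. The solution is
  the cosine eigenfunction series with coefficients integrated exactly
  over the piecewise-constant initial profile; 400 terms by default (the
  tail is negligible for t ≳ seconds, and at exactly t = 0 the solver
  returns the initial profile itself, avoiding Gibbs ringing at the layer
  interface). The concentration at the coverslip decays monotonically to
  the volume-weighted mean of the layers. For the reference geometry —
  1 mm at 970 mOsm under 3 mm at 145 mOsm — the equilibrium is
  351.25 mOsm and the 20-min decrease at the coverslip is ≈ 493 mOsm with
  D = 1.5×10⁻⁵ cm²/s (aqueous NaCl near 25–30 °C, a literature value; the
  decrease moves by < 3% across 1.4–1.7×10⁻⁵).
- **Droplet delivery**: a fixed concentration at the top face (the most
  conservative reading of a large equilibrated droplet) over a no-flux
  bottom, solved by finite differences; a finite-reservoir alternative is
  expressible as a thin high-concentration top layer in the no-flux
  configuration. For vancomycin (D = 2.83×10⁻⁶ cm²/s, 1.5 mm pad) the
  fixed-top model puts 1% of the final concentration at the coverslip at
  ~8 min; a concentrated-droplet model gives ~5 min. The droplet's true
  volume and concentration ratio to the pad are not pinned down, so both
  variants are provided and the answer is reported with its model variant.
- **Numerics**: the finite-difference solver is Crank–Nicolson on 401
  nodes with four backward-Euler startup steps (Rannacher damping of the
  initial discontinuity) and a step targeting ~1e-4 relative error on the
  diffusive timescale; layer-interface nodes take the midpoint of the
  adjacent layers. Series and finite differences agree to < 0.01 mOsm on
  the reference ramp; mass is conserved to ≪ 0.01% and the discrete
  maximum principle holds.
- `time_to_fraction` bisects the solver for the first time a position
  reaches a given fraction of its long-time concentration; the approach
  must be monotone at the queried position, which holds for the delivery
  geometries modelled.

## Bending and straightening

The package uses a deliberately minimal differential-growth model — no
equations were published for the verbal mechanism, so the model here is
the simplest one realising it. The cell is reduced to two edges a width
`W` apart whose growth rates respond linearly to the difference between
actual and plastic curvature, `λ(1 ± β (κ_a − κ_p) W/2)`, acting on the
edges' rest lengths:

- **Confinement** (κ_a clamped to the chamber curvature κ_d):
  `dκ_p/dt = λβ (κ_d − κ_p)`, so κ_p relaxes exponentially to κ_d with
  rate λβ. The annular chambers used experimentally (outer Ø 8 μm, inner
  Ø 2 μm) have centerline radius 2.5 μm, hence the default
  κ_d = 0.4 μm⁻¹.
- **Release** (free cell, κ_a = κ_p, strain excess on the inner edge):
  `dκ_p/dt = −λ γ_s κ_p` with the straightening exponent γ_s = β·c, c a
  geometry factor. With `dL/dt = λL` this gives the power law
  `κ_p = κ_p0 (L/L0)^{−γ_s}`, i.e. `κ_p L^{γ_s}` is conserved — the
  integrator maintains this invariant to 1e-6 at dt = 0.01 min.

Elastic (instantaneous, reversible) curvature is dropped: the
osmotic-shock release protocol demonstrates that the retained curvature is
plastic, and that is the modelled quantity. No numeric γ_s has been
published; the cohort analysis therefore reports *relative* curvature
versus relative length and tests only the model's internal consistency
(collapse onto the power law; log-log regression recovers a programmed
γ_s within 10% from 20 cells with 5% multiplicative noise) and the null
comparison — treated and untreated cohorts with equal γ_s produce
indistinguishable mean ± 2·SD bands, the signature that straightening does
not require wall synthesis. The analysis window starts at the treated
cohort's MreB-stop time so that only post-arrest dynamics enter the
comparison. Whether drug treatment should also reduce λ is left to the
scenario configuration. Cells with zero initial curvature (undefined
normalisation) or shrinking length are excluded with a warning.

## What the synthetic-data generator emulates

`synthgen` produces data with exactly the structure the analyses assume,
so that every pipeline stage has programmed ground truth to recover:

- **Biomass & surface**: `M(t) = M₀ exp(∫λ_M dt)` with optional piecewise
  rate shifts; `S = (S/M)·M` *exactly*, through arrest and shifts — S/M
  constancy is built in, so any measured deviation is attributable to the
  pipeline. Defaults: λ_M = 0.01 min⁻¹ (~69 min doubling, minimal-medium
  growth at 30 °C), S/M = 19 μm²/pg and M₀ = 0.5 pg, W₀ = 1 μm (giving a
  ~3 μm cell of typical dry-mass density ~0.3 pg/μm³).
- **Arrest phenomenology**: width constant before arrest, then widening
  exponentially at 0.0025 min⁻¹ (+10% over 40 min, within the observed
  qualitative range); length from spherocylinder inversion `L = S/(πW)`;
  lysis when the post-arrest surface gain reaches a programmed fraction
  (default 20%, within the observed 15–30%), modelled as a single-frame
  collapse of mass and volume to 35% — an idealisation that makes
  detection tests unambiguous.
- **Observation noise**: multiplicative log-normal per frame and per
  quantity, independent across quantities, default CV 2%. Real
  measurement noise is not characterised quantitatively in the source
  data; 1–3% is typical for quantitative-phase mass and contour-based
  shape estimates. Independence across quantities is a simplification —
  real S, V, L, W derive from one contour and co-fluctuate.
- **MreB tracks**: straight constant-velocity segments (circumferential
  geometry ignored — the activity statistic is direction-blind), Poisson
  nucleation at `density × area` per minute, fixed 0.5 min lifetime,
  default speed 0.6 μm/min (10 nm/s) and density 0.7 μm⁻² min⁻¹ giving a
  pre-arrest activity expectation of 0.21 μm⁻¹ min⁻¹, comfortably above
  the 0.08 stop threshold; positions freeze at the programmed arrest,
  leaving 0.01 μm localisation jitter that the persistence filter
  rejects.
- **Rendering**: per frame a binary spherocylinder mask and a phase image
  distributing the ground-truth mass over the projected chord thickness,
  normalised so integrated positive phase inverts to the mass exactly
  through the calibration; optional zero-mean Gaussian background. No
  point-spread function, no phase-contrast halo, no cell division (the
  experiments block division genetically or pharmacologically).
- **Osmotic width response**: relative width
  `1 + g_e ΔΠ(t) + r_p ∫ΔΠ dt'` with elastic gain `g_e` and plastic rate
  `r_p`; `calibrate_ramp_gains` sets `g_e` from the step-shock observation
  (2.5% at 520 mOsm) and `r_p` so the total 20-min ramp widening is 8%.
  This is phenomenological — no turgor-pressure constitutive law is
  implied, because turgor itself is not quantified.

Everything is a pure function of the scenario seed; per-cell seeds are
derived deterministically. Passing recovery tests on these data shows the
pipeline is internally correct under the stated noise model; it does not
validate segmentation on real phase-contrast images, optical corrections,
or biological variability beyond the programmed structure.

## Problem sizes used in tests

The test suite and the acceptance script run at deliberately modest sizes
chosen to exercise every code path with tight statistics: cohorts of 20
cells × 60 one-minute frames, MreB scenes of ~50 μm² × 20 min at 1 s
sampling, 1,000-track filter checks, 20 × 20 geometry grids and 401-node
diffusion solves. These match the scale of a single microscopy experiment
(10–70 cells per condition).

## Known limitations

- The width proxy (median normal chord) and the skeleton-based centerline
  are substitutes for mesh-based morphometry tools; agreement is within
  one pixel on synthetic masks but has not been benchmarked on real
  phase-contrast segmentations.
- The greedy linker is a fidelity bound on global LAP assignment; it is
  exact at low density but will fragment tracks in crowded scenes.
- Absolute MreB activity carries a noise-dependent positive bias (above);
  comparisons should rely on relative changes and threshold crossings.
- The diffusion model is 1D with a single effective D: no pad-edge
  effects, evaporation, or agarose tortuosity.
- The bending model predicts only relative curvature dynamics; β and γ_s
  are free parameters, not derived from wall mechanics.
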