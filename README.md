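# envgrowth

Quantification of single-cell envelope growth in rod-shaped bacteria.

Rod-shaped Gram-negative bacteria such as *Escherichia coli* must expand
their envelope — outer membrane, peptidoglycan wall, inner membrane — as
biomass accumulates. A central experimental observation is that the surface
area *S* of a growing, nondividing cell stays proportional to its dry mass
*M* even when peptidoglycan insertion is pharmacologically arrested: the
surface-to-mass ratio *S/M* is conserved through drug treatment, nutrient
shifts, and continued post-arrest growth up to abrupt lysis, while the cell
slowly widens. `envgrowth` implements the measurement chain needed to make
and check that kind of claim from time-lapse microscopy, together with a
synthetic-data generator so the whole pipeline runs and is tested without
any external data.

The package is aimed at microbial biophysicists analysing single-cell
time-lapse data: phase-contrast masks, quantitative-phase images and
cytoskeletal particle tracks.

## What it computes

- **Morphometry** (`envgrowth.geometry`) — length *L*, width *W*, centerline
  and curvature κ from masks/contours, with the spherocylinder closed forms
  `S = πWL` and `V = πW²L/4 − πW³/12`.
- **Dry mass** (`envgrowth.quantphase`) — integrated positive phase Φ to
  mass via `M = f · λ/(2πα) · Φ · A_px` with refractive increment
  α = 0.18 μm³/pg.
- **Growth kinetics** (`envgrowth.kinetics`) — Gaussian-filtered traces,
  relative rates `λ_X(t_{i+1/2}) = 2(X_{i+1}−X_i)/((X_{i+1}+X_i)Δt)`
  for X ∈ {M, S, V, L, W}, lysis detection, and event-aligned population
  means ± 2·SE.
- **MreB activity** (`envgrowth.mrebtrack`) — LoG spot detection, predictive
  nearest-neighbour linking, Savitzky–Golay track smoothing, persistence
  filtering (≥ 7 steps, ≥ 0.2 μm end-to-end), the activity statistic
  `A = Σ track lengths / (cell area · time)` and motion-stop calling at the
  threshold A* = 0.08 μm⁻¹ min⁻¹.
- **Pad diffusion** (`envgrowth.diffusion`) — layered 1D diffusion for
  agarose-pad osmotic ramps (cosine-series + Crank–Nicolson cross-check)
  and droplet-delivered compounds, with time-to-fraction queries.
- **Bending/straightening** (`envgrowth.bending`) — a minimal
  strain-coupled differential-growth model: in confinement
  `κ_p(t) = κ_d + (κ_p0 − κ_d)e^{−λβt}`, on release
  `κ_p = κ_p0 (L/L0)^{−γ_s}`.
- **Synthetic data** (`envgrowth.synthgen`) — trajectories, MreB track
  tables, rendered phase/mask stacks and osmotic ramps with programmed
  ground truth for every event the analysis must recover.

## Worked example

Simulate a cohort of 20 cells whose cell-wall synthesis arrests at
t = 30 min, then check that the measured relative S/M curve stays flat
through arrest while the width rises:

```python
import numpy as np
from envgrowth import synthgen, kinetics

scen = synthgen.GrowthScenario(arrest_time=30.0, seed=1)
pop = synthgen.simulate_population(scen, duration=60.0, dt=1.0, n_cells=20)

sm = kinetics.align_and_aggregate(pop, "surface_to_mass", event="mreb_stop")
w = kinetics.align_and_aggregate(pop, "width_um", event="mreb_stop")
sel = sm[(sm.t_aligned_min >= -20) & (sm.t_aligned_min <= 20)]
print(f"relative S/M over [-20, +20] min: "
      f"{sel['mean'].min():.4f} .. {sel['mean'].max():.4f}")
print(f"relative width at +20 min: "
      f"{np.interp(20.0, w.t_aligned_min, w['mean']):.4f}")
```

prints

```
relative S/M over [-20, +20] min: 1.0000 .. 1.0100
relative width at +20 min: 1.0412
```

i.e. the aggregated surface-to-mass ratio deviates by at most 1% from
constancy across the arrest (the generator builds S ∝ M in, so any
deviation is pipeline error), while the cell width has risen by ~4%
twenty minutes after arrest.

The same chain is available from the shell:

```sh
envgrowth simulate -c scenario.yaml -o dataset/
envgrowth analyze  -d dataset/ -o results/
envgrowth padflux  -c pad.yaml -o ramp/
envgrowth report   -r results/
```

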