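# Methods

## The model

`thermodrift` simulates a community of planktonic microbes in a 2-D
surface-ocean slab. Species are identical except for their optimum
temperature `T_opt`. Individual cells are advected by gridded currents,
spread by a diffusive random walk, and divide and die at rates set by the
local temperature and the local population size.

**Thermal performance.** Growth follows a quadratic niche under an
exponential envelope,

    μ(T) = a · e^{bT} · [1 − ((T − z)/(w/2))²]   (d⁻¹),

with the quadratic center `z` solved per species so that the maximum of
μ lies exactly at `T_opt`: with h = w/2 and
x = [√(1+(bh)²) − 1]/(bh), z = T_opt − h·x. Two structural consequences
drive everything else: maximum growth rises exponentially with the
optimum (μmax ratios equal e^{bΔT_opt} exactly), so the locally
best-adapted species is outcompeted by a slightly warmer-adapted
neighbor; and the curve is steeper above the optimum than below it, so
exceeding one's optimum is penalized more than falling short. μ is
negative outside the niche and the negative part acts as an additional
per-capita loss.

**Demography.** Per step Δt (default 0.3 d), an agent divides with
probability p = max(0, μ·(1 − N/K))·Δt, where N is its cell's total
population and K the uniform carrying capacity ("competing for carrying
capacity" as an implicit resource), and dies with probability
q = 1 − e^{−(d + max(0, −μ))·Δt}. The exponential waiting-time form is
used for death because the out-of-niche loss is unbounded; it agrees
with the linear form to first order and keeps q < 1 in arbitrarily
hostile cells. Division uses the linear form and the engine refuses to
run when p could exceed 1. Daughters inherit position, species and both
temperature histories (the model tracks lineage memory, so inheritance
is the meaningful choice; the alternative — resetting daughters to the
local temperature — would shorten apparent memory by one generation).

**Temperature history.** Each individual carries two exponentially
weighted moving averages of the temperature it has experienced,

    T_hist ← (1 − αΔt)·T_hist + αΔt·T_loc ,

with α floored at 0 (the update is a convex combination) and αΔt ≤ 1
enforced. For T_hist(g), α is the individual's current growth rate: a
biomass-weighted lifetime record. For T_hist(s), α is |s| of the
individual's cell, where the selection rate s is the growth-rate gap
between the cell's two most abundant species: the time scale on which
community dominance can turn over. s is applied per individual with a
cell-level α (the most literal per-individual reading is ill-defined
because s is a community property), and |s| is capped at the largest
attainable growth rate so the EMA weight stays in range even during
transient dominance flips between far-apart species.

**The differential.** A paired experiment — one run with advection, one
without, otherwise identical — yields per-cell time-averaged optimum
temperatures of the most abundant species, `T_opt(a)` and `T_opt(na)`.
Their difference ΔT_opt is the advective temperature differential:
positive where currents import warm-selected populations (poleward
western-boundary jets), negative in equatorward return flows. Time
averaging is applied to the per-snapshot most-abundant maps and then
subtracted (not to abundances first), matching how the differential is
defined from archived map products. The atlas bundles ΔT_opt with the
history fields, ΔT_hist(s) = T_hist(s) − T_loc, the time-mean local
temperature, and the poleward velocity (+v in the northern hemisphere,
−v in the southern), keyed by population-mean growth rate; CSV column
names carry the rate in hundredths (`TOPTA028` = T_opt(a) at 0.28 d⁻¹).

## The synthetic ocean

The generator produces a closed rectangular basin (default 20×20 cells
of 2°, spanning 6–46°N) with a single wind-driven-style gyre: a
streamfunction with an exponential western boundary layer gives a
narrow poleward jet (peak ≈ 0.2–0.4 m s⁻¹) on the western wall and a
broad, slow equatorward return across the interior and east.
Temperature is a linear meridional gradient (28 °C at the equatorward
edge to 4 °C at the poleward edge) plus a sinusoidal seasonal cycle that
adds between 0 and 5 °C above the baseline, so the field stays within
the stated bounds [T_pole, T_equator + amplitude]. Snapshots are emitted
every 3 days.

The streamfunction is sampled at cell centers (with a zero ring outside
the walls) and differenced with centered differences in the spherical
metric (u = −ψ_φ/R, v = ψ_λ/(R cosφ)). Because the two difference
operators act on different axes they commute, and the centered-difference
spherical divergence cancels exactly — the discrete field is
non-divergent to round-off, which is what conserves particle mass
without a full ocean model.

**Unsteadiness matters.** A perfectly steady gyre has closed
streamlines. Along a closed trajectory the cumulative growth-rate
difference between two species is proportional to the loop-averaged
difference, so the most abundant species on the loop is the
loop-average optimum *at any growth rate* — the differential's
growth-rate dependence degenerates. Real surface circulation is
unsteady and stirs water across mean streamlines, giving trajectories a
finite memory horizon. The generator therefore meanders the gyre
seasonally: the streamfunction pattern is displaced by up to 10% of the
basin width, zonal and meridional displacements in quadrature (period
365 d). This is the standard idealization for chaotic surface stirring,
and it restores the regime in which slow-growing communities (long
memory) carry a large differential and fast-growing ones a small one.

What the synthetic basin does **not** emulate: mesoscale eddies, open
boundaries, coastlines and shelves, vertical motion, and realistic
current magnitudes outside the jet. Passing tests on this ocean show
the mechanism (upstream selection memory) and the machinery, not
quantitative agreement with any real current system.

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| envelope exponent b | 0.063 | °C⁻¹ | Eppley-like envelope slope |
| niche width w | 30 | °C | full quadratic width |
| envelope scale a | calibrated | d⁻¹ | bisected to the target mean growth |
| death rate d | 0.2 × target | d⁻¹ | see below |
| carrying capacity K | agents / ocean cells | cell⁻¹ | uniform |
| Δt | 0.3 | d | keeps αΔt ∈ (0,1) and p ≤ 1 |
| snapshot interval | 3 | d | forcing and output cadence |
| diffusivity D | 500 | m² s⁻¹ | sub-grid stirring at 2°; a choice, not fitted |
| species | 50 from −5.2 in 0.8 steps | °C | top of grid at 34.0 °C |
| duration | 12 y (desk), 31 y conceptual | — | first 4 y discarded from atlas averages |

The published species grid is stated as 50 species spanning −5.2 to
36.2 °C in 0.8 °C steps, which is arithmetically inconsistent (49 steps
of 0.8 from −5.2 end at 34.0). The package takes (n_species, t_min,
step) from config with defaults (50, −5.2, 0.8) and does not attempt to
resolve the inconsistency.

**Calibration.** The envelope scale `a` is adjusted by bisection (in log
space) until the abundance-weighted mean growth rate over the final full
year of a two-year burn-in matches the target (0.14 d⁻¹ for
heterotrophic bacteria, 0.65 d⁻¹ for phytoplankton) within 5%. The
burn-in runs on the deterministic Eulerian twin by default, which makes
the bisection noise-free; an IBM burn-in is available. Candidate scales
that would violate the p ≤ 1 stability bound are treated as above-target
so the bisection backs off them.

**Death rate.** With a single uniform death rate and an envelope that
spans a factor ~12 in μmax across the species grid, a fixed d makes
whole temperature bands unviable at low calibrated growth (every species
with μmax < d dies everywhere, and cold regions are then populated only
by warm species diffusing in — selection collapses). The death rate is
therefore tied to the calibration target, d = 0.2 × target by default,
which keeps the community viable across the basin at every growth level
and scales all demographic time scales together with growth. A fixed
death rate can be forced via `death_rate_fraction=None`.

## Engines and their equivalence

The IBM advects agents with midpoint (RK2) integration of bilinearly
interpolated velocities (nearest snapshot in time; the forcing interval
is 10 steps long) plus a Gaussian random walk of per-axis variance
2DΔt; walls reflect, and moves onto interior land cells are bounced back
to the starting position. The Eulerian twin integrates per-species
concentration fields with second-order upwind advection (MUSCL with a
minmod limiter, falling back to first order at walls and land) in flux
form — exactly mass-conserving — plus explicit diffusion and source
terms equal to the IBM's expected update (1 + pΔt)·e^{−lossΔt}; CFL and
diffusion stability are checked up front. The twin also advects the two
population-mean history fields as moment tracers (C_tot·T_hist moves
with the same flux operator, and division/death leave a cell's
biomass-weighted mean history unchanged), so its T_hist and ΔT_hist(s)
carry upstream memory like the agents' EMAs; the species-resolved
structure of the histories is still IBM-only.

Because growth and death depend only on extracellular fields, the two
engines discretize the same continuum model, and the suite checks ≥95%
cell-wise agreement of time-averaged most-abundant maps on a 12×12
basin (5 IBM replicates pooled). That comparison is run at the lateral
mixing coefficient consistent with the grid — 2×10⁴ m² s⁻¹, the
eddy-diffusivity scale of 200-km cells — because when explicit mixing is
much smaller than the schemes' intrinsic front diffusion, the comparison
measures front sharpness (the Lagrangian engine keeps advected dominance
fronts sharper than any practical flux scheme) rather than model
equivalence. The default run-time diffusivity stays at 500 m² s⁻¹.

The IBM records weighted per-cell per-species counts, the selection
rate, population-mean histories and the local temperature at the output
interval; a single seeded generator drives all randomness (stream order:
transport normals, then demography uniforms), so runs are bit-for-bit
reproducible under a seed. An optional per-cell agent cap with uniform
thinning and weight bookkeeping exists for desk-scale runs and is off by
default.

## Observation comparisons

`correct_temperatures` maps observations to the nearest valid ocean cell
(within 1.5 cell diagonals; unmappable rows are excluded and counted)
and attaches corrected_T = T_loc + ΔT_opt. Regressions (ecotype
log-ratio on temperature; pairwise metagenome nucleotide divergence on
|ΔT| of sample pairs) are ordinary least squares via `scipy`. The AND
fit uses each unordered off-diagonal pair once (n(n−1)/2 points) to
avoid double-weighting identical information; the ordered-pair count is
reported alongside for comparability with tabulations that count both
orders. Seasonal phase lags come from a linearized least-squares sine
fit (m + A sin(2π(t−φ)/365)), with lags wrapped to (−P/2, P/2].

The paired bootstrap resamples observation indices with replacement
(default n = 1000), computes the metric (RMSE or R²) for both
predictions per resample, and reports the point difference, its
bootstrap SD, and a two-sided p-value defined as twice the fraction of
resamples in which the difference's sign reverses, capped at 1. This
convention is stated because threshold-only reports leave it open;
under the null it is calibrated (≈5% false positives at α = 0.05, which
the suite checks). Degenerate resamples (zero variance under R²) are
dropped.

Synthetic observation generators close the loop for all three dataset
kinds: they draw locations from the atlas, embed an advection signal of
known size (T_opt(a) for isolates; β₀ + β₁·corrected_T for ecotype
log-ratios, defaults β = (−2.0, 0.12); c·|ΔcorrT| with c = 0.004 for
AND matrices — slopes and noise chosen to sit in the range typical of
the corresponding field data), and record their parameters so recovery
tests can verify that the built-in signal is detected and that detection
power decays as noise grows.

## Problem sizes and numerical choices

Desk-scale study conditions used by the test suite: a 20×20-cell basin,
50 species, 12-year paired Eulerian runs with the first 4 years excluded
from averages (growth-rate scan at 0.14/0.65/1.3 d⁻¹), and 3-year,
10⁵-agent IBM runs (5 replicates) on a 12×12 basin for the
engine-equivalence check. Ties in "most abundant" resolve to the lowest
T_opt, everywhere, for determinism. Records switch from float64 to
float32 only when a run's record would exceed ~5×10⁶ values. netCDF I/O
uses xarray's scipy backend (NETCDF3).

## Known limitations

- 2-D surface slab only; no vertical structure or upwelling.
- Uniform carrying capacity; no blooms, fronts or chlorophyll-derived K.
- No adaptation or evolution; species identities are fixed.
- The Eulerian twin's flux scheme remains diffusive at sharp dominance
  fronts even at second order; the engine-equivalence check is therefore
  stated on time-averaged most-abundant maps under grid-consistent
  mixing, not on concentration profiles.
- The synthetic basin's single meandering gyre cannot reproduce
  location-specific magnitudes from real circulation (e.g. differentials
  of named currents); those require real velocity and temperature
  fields supplied through the netCDF reader.
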