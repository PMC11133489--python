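# Methods

This note records the modelling choices behind `landes`: what each
component assumes, which knobs matter, what the synthetic landscapes do and
do not emulate, and where the design was genuinely open.

## Synthetic study areas

The generator (`synth`) produces internally consistent stand-ins for the
data structure of an arid, endorheic basin; it does not attempt a
calibrated climatology or hydrography.

- **Terrain.** A planar east-high/west-low ramp plus spectral (1/f^β)
  fractal noise, clamped to [0, 5000] m. Any autocorrelated surface with
  that gradient serves the purpose; spectral synthesis was chosen over
  midpoint displacement because it is exactly deterministic per seed and a
  few lines of FFT.
- **Climate.** Precipitation is affine in elevation (orographic) with
  smoothed multiplicative lognormal noise (non-negativity guaranteed),
  rescaled to a domain mean of 236 mm/yr — the arid-basin default.
  Temperature falls at 6 °C/km with Gaussian noise; PET follows temperature
  and is sized so PET ≥ P on most cells (the landscape is water-limited,
  with maxima near 1700 mm/yr). Monthly precipitation splits the annual
  total by a fixed continental profile with a winter/spring peak, so the
  monthly grids sum to the annual grid by construction.
- **Soils and drivers.** Erodibility, available water capacity and rooting
  depth are bounded fractal fields with weak elevation trends. Roads are a
  few random polylines; population decays with distance to road and with
  elevation.
- **Initial land use.** Per-class affinity fields (fixed linear functions
  of standardized drivers + smooth noise) are converted to a map by greedy
  ranked allocation under target class shares (barren-dominated: 32 %
  barren, 28 % grassland, 20 % cropland, 8 % each forest/water, 4 % urban).
  This guarantees all six classes at exact counts, water in the low west,
  and spatial autocorrelation well above a random labeling.
- **Known transition (t0 → t1).** Growing classes claim the best-scoring
  cells of shrinking classes under a logistic suitability in the drivers
  plus smooth noise (noise scale 0.35). This is deliberately the same
  *family* as the CA — so recovery is meaningful — but not the same
  process: it is ranked rather than roulette, has different noise, and no
  neighbourhood or inertia terms. Class counts match the recorded demand
  table exactly, and only flips occur (no cell creation).
- **Scenario presets.** Demand changes per scenario sit inside the
  reported scenario envelopes (urban +27..+135 %, cropland −0.6..−17 %,
  grassland −0.2..−15 %, barren +0.5..+15 %); water declines more under
  higher forcing (−5 % to −40 % across SSP126→SSP585). Climate deltas
  (precip multipliers 1.01–1.10, warming +0.8 to +4.8 °C) span the four
  future periods. These defaults *are* the study conditions for all tests.

What passing tests on these landscapes shows: the algorithms implement
their equations correctly, conserve what they must, and recover a known
driver-linked transition. What they do not show: skill on real basins,
where drivers are collinear, demand schedules uncertain, and land-cover
maps noisy.

## Land-use cellular automaton

- **Suitability.** One hidden layer of 12 logistic units on standardized
  drivers (scikit-learn MLP, fixed seed). The architecture is exposed;
  12 units is enough for the synthetic driver geometry while keeping the
  fit deterministic and fast. Probabilities for classes absent from the
  training sample are zero.
- **Neighbourhood effect.** Window count excludes the centre cell (the
  divisor N²−1 implies it). Edge windows are truncated over the same
  divisor, so Ω shrinks toward borders; renormalizing is a documented
  alternative, not the default. Default N = 3 and w_k = 1 for all classes
  (no published values exist to adopt).
- **Adaptive inertia.** The three-branch gap rule is not exhaustive as
  printed (sign-crossing gaps match no branch); unlisted cases leave the
  coefficient unchanged — the conservative choice, and the one that keeps
  the coefficient positive. Initial inertia is 1 for every class.
- **Allocation.** Each iteration recomputes Ω and inertia, then every cell
  of an over-allocated class draws a candidate under-demand class with
  probability ∝ TP (Gumbel-max), and flips are accepted in seeded random
  order with probability proportional to the cell's TP (normalized per
  class per iteration), while both classes' absolute gaps shrink. The
  TP-proportional acceptance is the substance of the roulette competition:
  without it, *which* cells change is uniform among candidates and the
  figure of merit collapses to the random baseline; with it, high-TP cells
  claim the demand first and change lands where the drivers say it should.
  A small Ω floor (1e-4) lets a class with no neighbours anywhere still be
  seeded by suitability alone. Demands must sum to the valid-cell count;
  convergence tolerance is max(5 cells, 0.5 % of demand) per class, and
  non-convergence raises with the residual gaps.
- **Costs.** Default conversion costs are 0.1 off-diagonal with
  water↔urban at 0.95 (near-forbidden); `sc = 1` forbids a transition
  outright. Water is otherwise an ordinary demand-driven class, since its
  area changes by scenario.
- **Validation.** κ uses Cohen's chance term (marginal products), not a
  fixed 1/6 expectation. FoM counts A (missed change), B (correct change),
  C (wrong-class change), D (false change); both metrics are verified
  against exhaustive confusion tallies on all 3-class 2×2 maps.

## Ecosystem services

- **Water yield.** Zhang/Fu–Budyko with ω = Z·AWC_eff/P + 1.25, Z default
  5 (seasonality constant, config-exposed). AWC_eff = min(root-restricting
  depth, class rooting cap) × volumetric AWC. PET is scaled per class by a
  crop coefficient Kc. Cells with P = 0 yield 0; the evaporative fraction
  is clipped to [0, 1] so 0 ≤ Y ≤ P holds exactly.
- **Erosivity.** Monthly Wischmeier-type form
  R = Σ_m 1.735·10^(1.5·log10(p_m²/P) − 0.8188), constants exposed so a
  locally calibrated formula can be substituted. Note the form is *not*
  strictly monotone in a single month's rainfall (raising a tiny month can
  shrink other months' p²/P terms); the guaranteed property, asserted in
  tests, is that scaling all months up strictly increases R.
- **LS.** Desmet–Govers length factor over D8 flow accumulation (steepest
  descent, high-to-low processing), McCool slope factor, slope floor 0.1 %,
  aspect-correction factor neutralized to 1 (a documented simplification
  appropriate at 1 km cells).
- **Soil conservation** is the literal per-cell product R·K·LS·(1 − C·P);
  absolute units follow the calibration of R and K.
- **Carbon** is stock accounting only — no flux over time.
- **Habitat quality.** Degradation averages the decay over *all* source
  cells of each threat (1/Y_r · Σ_y i_rxy), with linear or exponential
  (folding constant 2.99) decay, zero beyond the threat's reach, weights
  normalized across threats, and per-class sensitivities. Computed with
  chunked pairwise distances — exact, and affordable at the package's grid
  sizes (≤ ~200×200). The response exponent is configurable: default
  z = 2.5 (the stated constant), switchable to 2.0 (the printed form);
  k defaults to half the maximum degradation ("auto"), and if degradation
  is zero everywhere Q = H_j. Default threat set: urban, cropland, roads,
  with editable weights/sensitivities.

## Climate correction

Empirical quantile mapping with Weibull plotting positions i/(n+1), linear
interpolation between quantile knots, annual pooling. Outside the
calibrated range: constant offset for temperature, constant ratio for
precipitation (preserves non-negativity). The variant is the simplest
standard one; monthly pooling and parametric transfer functions are
deliberate non-goals. Ensemble means are cellwise, nodata only where all
members are nodata; period means cover exactly the four disjoint 20-year
windows 2021–2040, 2041–2060, 2061–2080, 2081–2100.

## Trade-off analysis

Points are sampled uniformly over valid cells *without replacement* —
coincident points would duplicate rows and inflate significance. Spearman
ρ uses midranks; p-values use the t-approximation on n−2 df. A constant
column gives undefined ρ, recorded as NaN and classified "none". Labels:
synergy iff ρ > 0 and p < α, trade-off iff ρ < 0 and p < α, default
α = 0.01. Zones split at the 1000 m and 100 m contours
(upper ≥ 1000 > middle ≥ 100 > lower); the point sample is basin-wide with
zone labels, and a zone with fewer than 10 points is omitted with a
warning.

## Pipeline and problem sizes

The orchestrated run is a pure function of (config, seed): every stage
seed derives from the master seed, manifests carry a config hash, and
identical configs produce byte-identical summary CSVs. Percent changes are
always relative to the configured baseline and stored unrounded. Default
demo sizes — 60×60 cells, two scenarios, two periods, 1500 training
samples, 2000 sample points — were chosen so a full run completes in a few
seconds on one core while every class and zone stays populated; the
recovery experiments use 100×100, the size at which the CA's skill margin
over the random baseline is comfortably resolved.

## Known limitations

- No reprojection, multi-band imagery or mosaicking; all rasters in a run
  must already be aligned (a strict guard, never silent resampling).
- No hydrological routing: water yield is per-cell, soil conservation is
  retention only (no sediment delivery ratio).
- The statistical downscaling of coarse model climate onto fine grids is
  represented by bilinear refinement of corrected anomalies — a stand-in,
  adequate for synthetic grids, not a downscaling method.
- The synthetic generator's realism claims end at structure: gradients,
  couplings, autocorrelation, class shares and demand envelopes. Absolute
  service totals on synthetic landscapes are not comparable to any real
  basin's.
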