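# Methods

This note records the models implemented in `benthosens`, the
assumptions and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the design decisions taken
where the methodology left room.

## Grids and rescaling

All spatial layers live on one regular lat-lon grid (default 0.03°
cells, cell-centre registration, north-up, row 0 = northernmost).
Layers arriving on other grids are resampled (bilinear for continuous
fields, nearest for categorical ones such as sediment class, which
therefore never acquires new category values). Missing data are
handled conservatively: any cellwise combination of layers masks a
cell if any operand is masked.

Min–max rescaling `(x − min)/(max − min)` is computed over the
unmasked cells of the analysis extent only — the rescaled indices are
therefore extent-relative by construction, and cropping the study area
changes them. A constant layer cannot be rescaled and raises a
degenerate-layer error rather than silently producing zeros.
Temporal percentiles (e.g. the 90th-percentile wave climate) use
linear interpolation between order statistics; the convention is fixed
so results are bit-stable.

## Disturbance

Near-bed wave orbital velocity follows linear (Airy) wave theory:
`u_b = π·Hs / (Tp·sinh(kh))`, with the wavenumber `k` solved per cell
from the dispersion relation `ω² = g·k·tanh(kh)` by a bracketed Brent
iteration (absolute tolerance 1e-10, ≤ 100 iterations; the deep-water
wavenumber `ω²/g` is a guaranteed lower bracket because
`g·k·tanh(kh) ≤ g·k`). For `kh > 700` the velocity is set to zero to
avoid `sinh` overflow — physically the deep-water limit. The
characteristic friction velocity is the plain scalar sum of the wave
orbital velocity and the tidal bottom current, i.e. the two are
assumed collinear; no drag-law conversion or wave–current boundary
layer interaction model (Grant–Madsen and kin) is applied.

The critical mobilisation velocity is the quartic-in-log₁₀ grain size
approximation of the Hjulström erosion curve, `u_crit = 10^Y` in cm/s
(the Hjulström-diagram convention; the friction velocity, computed in
m/s, is converted to cm/s before the ratio — the unit choice is
recorded in the layer metadata). The quartic keeps the classical
erosion-threshold minimum near 0.18 mm: the threshold *rises* again
for finer, cohesive sediment, so the disturbance ratio is strictly
decreasing in grain size only above ~0.2 mm. The disturbance index is
the ratio friction/critical, min–max rescaled to [0, 1] *after* the
ratio is formed.

Grain sizes come from a five-class sediment map through a class → mean
grain size (mm) lookup; the synthetic defaults are mud 0.05, fine sand
0.15, medium sand 0.35, coarse sand 1.0, gravel 8.0 mm.

## Scope for Growth

`SfG = (Fa + SST + S − Ta − Ti)/5` on layers individually rescaled to
[0, 1] (each parameter is rescaled separately; `Ta` and `Ti` are not
rescaled jointly). Food availability is particulate organic carbon,
`POC = 10^(2.27 + 0.35·log₁₀ Chla)` (valid shallower than 300 m),
rescaled *after* the transform because it is nonlinear. `Ta` is the
within-year SD of monthly means averaged over years; `Ti` is the
between-year SD of annual means; both use the sample (n−1) SD. Depth
is deliberately not an SfG input — the formula has exactly five terms;
surface temperature and chlorophyll stand in for bottom values on the
assumption of a well-mixed water column. The raw index lies in
[−0.4, 0.6] and is rescaled to [0, 1].

## Risk

`Risk = √((1−SfG)² + (1−Dist)²)` on the rescaled axes: the Euclidean
distance of a cell from the benign-disturbed (1, 1) corner of the
habitat template, in [0, √2]. The raw risk is carried through all
statistics; a rescaled `risk01` exists only for map rendering, because
rescaling would change GLM coefficients (rank correlations are
unaffected). No binning or classification is applied — the surface is
a continuum.

## Traits and TDI

The five-trait scoring scheme is hard-coded with its exact category
domains — Feeding has no score 2 and Size no score 1; the scheme's
ceiling (each trait at its maximum) is SI = 15. Label lookup is
case-insensitive and tolerates the verbose catalogue forms
("Sessile (attached)", "Large > 10 cm").

Aggregation: species collapse to genus; a taxon is retained at the
lowest lineage level (genus → family → order → class → division) whose
pooled records — all surveys together — span at least `min_years`
(default 6) distinct calendar years, pooling *all* taxa sharing that
lineage value; taxa whose division still fails are removed. The walk
is deterministic (sorted taxon order) and fully audited. Retained
groups take the per-trait **maximum** over members, so a single
vulnerable trait is never averaged away, and are removed as too
heterogeneous when both conditions hold: any trait's SD > 1.5 *and*
the SI SD > 2.5 (read conjunctively; an `or` mode exists for
sensitivity analysis). Sample SD is used, consistent with the rest of
the package; a single-member group always passes.

Station TDI is the biomass-weighted mean SI of the haul after
aggregation. Biomasses are transformed with log(1+B) before forming
proportions — this reconciles a plain biomass-proportion formula with
log-transformed relative biomasses while remaining finite at small
catches; `transform="none"` gives the raw-proportion variant.
Zero-biomass rows are treated as presence-only records (colonial or
encrusting organisms) and assigned the smallest positive biomass in
the haul (configurable). A haul with zero total transformed biomass
has an *undefined* TDI (NaN), never zero, since zero is a meaningful
indicator value.

## Coupling statistics

Community dissimilarity is Bray–Curtis on row-normalised log(1+B)
biomass compositions (the same transform as the TDI weights). BIO-ENV
z-scores the environmental variables, builds Euclidean distances for
every non-empty subset up to `max_subset_size`, and ranks subsets by
the Spearman correlation between the lower-triangle vectors of the two
matrices (plain, unweighted Spearman); ties go to the smaller subset,
then lexicographic order, so rankings are deterministic. An exhaustive
search over more than 20 candidates is refused. The permutation test
permutes station labels of the environmental table and re-runs the
whole search; this is implemented as a row/column permutation of each
subset's precomputed rank matrix, which is mathematically identical
and much faster. `p = (1 + #{permuted best ρ ≥ observed})/(1 + n_perm)`.

The TDI model is a Gaussian GLM with identity link on the
log-transformed response: `log TDI ~ Risk + Abrasion`. Stations with
undefined or zero TDI are excluded; a zero-variance predictor is
dropped with a warning; perfectly collinear predictors raise. The
predicted-TDI map is the bare exponential of the linear predictor —
no smearing correction, so it estimates the conditional median rather
than the mean on the TDI scale; this bias is accepted as the
documented back-transform of a log-scale Gaussian model. Spearman
matrices report raw two-sided p-values with no multiplicity
correction, with pairwise deletion of missing values and NaN for
constant variables.

## Synthetic data

The generator emulates the study conditions of a temperate shelf
survey system: an 8-year series (the aggregation rule needs ≥ 6
distinct years), ~38–63 hauls per year depending on the experiment,
120 taxa, physically plausible layer ranges (depth 5–100 m, Hs 0.5–4 m,
Tp 4–12 s, currents 0.05–1.5 m/s, SST 8–18 °C, salinity 30–35.5,
Chla 0.1–10 mg m⁻³), log-normal (multiplicative) biomass noise with
SD 1 on the log scale — survey catches of benthos are strongly
overdispersed — and 15% rare taxa seen in < 6 years so the removal
branch of the aggregation rule is always exercised.

Fields are Gaussian random fields: white noise smoothed with a
Gaussian kernel (default correlation length 4 cells, wrap-around
boundary), restandardised, and pushed through the normal CDF into each
layer's physical range. Environmental layers share two latent
gradients plus layer-specific noise, so they are mutually correlated
the way real shelf variables are. Abrasion (0–60% of cell area) has
its own latent and is statistically independent of the environment by
construction — note that with spatially autocorrelated fields the
*single-field* null spread of a Spearman correlation is wide (effective
sample size ≪ cell count), so independence shows up as a zero-centred
across-seed distribution rather than a tiny correlation in every
realisation.

Two generative mechanisms act on sensitive taxa (SI ≥ 10), with
strengths chosen once as study conditions: their expected log-biomass
rises by 1 per SD of the cell's modelled process-driven risk
(`risk_preference = 1`), and falls by
`suppression_rate × 4 × abrasion/100`
(`suppression_rate = 0.8` by default, i.e. a −3.2 log-biomass hit at
full abrasion) — trawling removes fragile sessile fauna where effort
concentrates. All other taxa respond to depth and current gradients
with random coefficients. The generator computes the risk field with
the same code path the analysis uses; that makes "sensitive fauna
prefer high-risk habitat" literally true in the simulation, which is
the point of a ground-truth generator, but it also means recovery
tests validate the pipeline's internal consistency, not the ecological
truth of the habitat-template model on real data. Likewise the
generator makes no attempt at real wave/current physics, coastline
geometry, gear selectivity or taxonomic realism.

Everything is driven by numpy's PCG64 generator under a mandatory
seed; identical seeds give bit-identical tables and fields.

## Problem sizes

The shipped experiments use sizes at which every statistical check is
stable: the demo run a 32×32 grid with 304 hauls; mechanism-direction
and sign-recovery experiments a 24×24 grid with ~504 hauls; the
permutation-null calibration 200 replicates of 30 stations × 4
candidate variables with 99 permutations; GLM recovery 100 seeds at
n = 500. The end-to-end sign-recovery property is exercised over 12
seeds in the test suite (all must recover both coefficient signs but
one).

## Known limitations

* Linear wave theory and scalar current addition understate bed shear
  in mixed wave–current boundary layers; the disturbance axis is a
  relative index, not a sediment-transport prediction.
* The cm/s convention for the Hjulström threshold is an informed
  choice; a different unit convention would rescale the ratio but not
  the rank order (and `Dist` is min–max rescaled anyway).
* The GLM back-transform is biased for the conditional mean (no
  smearing correction).
* BIO-ENV significance is for the *best* subset only; per-subset
  p-values are not corrected for the search.
* Reprojection is limited to lat-lon regridding; no CRS transforms.
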