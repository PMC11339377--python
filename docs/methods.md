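# Methods

This note documents the models implemented in `cfreserve`, the parameter
choices that matter, and the limits of what the synthetic experiments show.

## Synthetic landscapes

The generator replaces unavailable real inputs (an empirical forest-loss
risk surface, a pan-tropical biomass map, a protected-area database, a
land-cover classification) with seeded rasters reproducing the statistical
premises of the proactive-vs-expedient question. All layers share one grid
(default 64 × 64 cells of 500 m) and one master seed; a fixed config yields
a bit-identical landscape.

* **Elevation** — spectral (1/f^β) Gaussian noise, β = 2.2, scaled by a
  `roughness` factor (default 1) around a 400 m base with 600 m relief per
  roughness unit, clipped at sea level. Spectral synthesis was preferred to
  diamond-square: one parameter, trivially seeded, strong spatial
  autocorrelation.
* **Land cover** — forest/non-forest from a thresholded autocorrelated
  suitability field (realised forest share tracks the requested fraction,
  default 0.6, to within ties), with five forest classes stratified by
  elevation quantile (mangrove and peat-swamp lowest, upper montane
  highest) and four non-forest classes (water in the lowest terrain,
  plantation/regrowth, mosaic, scattered urban).
* **Protected areas** — grown from 6 seeds on the highest eligible
  (forest) cells by priority-queue region growing on elevation rank with a
  compactness penalty (0.35 rank units per cell of distance from the blob
  seed), until the target share of cells is reached. The compactness term
  matters: pure elevation-rank growth traces ridges and produces
  filamentous reserves whose planning-unit footprint is roughly twice
  their area share. Default protected share is 6% of land — an existing
  estate well below the 17% design target, the premise of the
  expand-the-network scenarios (strict-category reserves with mapped
  boundaries are a minority share of the land in the emulated system).
* **Loss risk** — `p = logistic(−1.0 − 1.5·z(elev) − 1.0·z(dist) −
  2.0·PA)` on forest cells, 0 elsewhere; `dist` is Euclidean distance to
  the nearest non-forest cell. The coefficients give landscape-mean forest
  risk near 0.2 per decade, concentrated low and at the frontier, and
  near-zero risk inside reserves. This is a deliberate three-covariate
  reduction of the machine-learnt risk models used on real data: only the
  output probability surface feeds the analysis.
* **Carbon** — class-mean above-ground biomass per 500 m cell (lowland
  forest 6,000 Mg ≈ 240 Mg/ha, montane and swamp classes less) with
  lognormal noise (σ = 0.3) parameterised to preserve the class mean; zero
  off forest.
* **Resistance** — pure table lookup on land-cover class; forest classes 1
  (mangrove/upper montane 2), mosaic 7, plantation/regrowth 10, water 20,
  urban 30. No published table exists for the source system, so these are
  configurable defaults ordered by habitat quality.

## Planning units and eligibility

Cell layers aggregate onto square planning units (desk default 8 × 8 cells
= 4 km; the island-scale convention is 10 km) by exact partition sums, with
truncated "coastal" edge units allowed. A unit is *available* iff its
forest area is at least 16% of a full unit (the 16 km²-of-100 km² rule — a
single female home range of ~16 km²), and *locked* (already protected) iff
its protected area strictly exceeds the same threshold; locked units are
force-available because retain-network scenarios lock them unconditionally.

## Reserve selection

The selector minimises `Σ cost + BLM·boundary + Σ_f SPF_f ·
(shortfall_f/target_f) · G_f` over unit sets. `G_f` — the cost of a greedy
best-amount-per-cost completion of feature f from the empty set, computed
once per problem — replaces MARXAN's unpublished internal penalty
bookkeeping; it has identical zeros (no penalty iff every target is met)
and the same SPF scaling. Boundary length counts edges against unselected
units *and* the landscape exterior (penalising stringy coastal designs).
Proactive problems use features (kernel, carbon, risk) with cost = unit
area; expedient problems use (kernel, carbon) with cost = mean risk × area
(floored at 1e−9 to keep amount-per-cost ratios defined). Targets are 30%
of each feature's total over available units; zero-total features drop out.

Annealing toggles one uniformly random non-locked unit per iteration,
accepting improvements always and deteriorations with probability
`exp(−Δ/T)`; T starts at the mean |Δ| of 100 presampled moves (unless set)
and decays geometrically (0.999/iteration). The best-seen solution is
returned; incremental bookkeeping is exact to recomputation. Desk defaults
(2,000 iterations × 20 runs in the pipeline; 10,000 × 100 standalone)
replace the published scale (10⁶ × 10⁴); on ≤ 12-unit problems best-of-20
runs matches exhaustive search in ≥ 95% of trials. The final design takes
the `round(0.17 × n_units)` most frequently selected units, locked first,
ties to lower id.

## Scenario updates

Protection masks: baseline S1 protects everything (it *is* the no-loss
reference state, not a zero-risk masking); S7 nothing; S6 the existing
network; redistribute scenarios (S2/S4) only the new design; retain
scenarios (S3/S5) the union. Outside protection, one decade of expected
loss is applied: `r' = r + p·r_plantation` (lost forest most plausibly
becomes plantation/regrowth) and `c' = c·(1 − p)`. The carbon update is
the *retained-fraction* reading of "reducing carbon by the product of
carbon and the inverse probability of deforestation"; the literal reading
(`c' = c·p`) would reward high-risk cells and invert every reported
ordering, but is exposed as `literal_inverse=True` for sensitivity
analysis rather than changed silently. No leakage: protecting a cell
displaces no loss elsewhere.

## Connectivity

Least-cost distances use Dijkstra on the 8-connected cell graph with edge
weight `step_factor × (r_a + r_b)/2 × cell_size` (step_factor √2 on
diagonals) — the standard cost-distance convention. Kernels decay linearly
to zero at the bandwidth (the common inverse-linear dispersal form), start
at 1 on a source's own cell, and superpose over a regular lattice of
forest source points (spacing 8 cells). Core habitat is density strictly
above the 10th percentile *of positive-density cells* (over the full
raster the percentile would be pinned to zero by the background);
percentile 0 keeps the whole support. Patch metrics follow FRAGSTATS
definitions with 8-connected patches; correlation length is the
area-weighted mean radius of gyration (mean cell-to-centroid distance).

**Bandwidth scaling.** The published analysis used 125,000 and 250,000
cost units (125/250 km of least-cost travel at forest resistance 1) on an
~1,100 km island. On the 32 km desk grid the pipeline defaults to 4,000
and 8,000 cost units (4/8 km), preserving the dispersal-to-landscape ratio
so that kernel support remains informative rather than saturating.

## Individual-based genetics

Fixed habitat points (lattice, one per 16 km² of core habitat — one home
range) each hold at most one individual. Per generation: each female draws
a father *per offspring* among males with weight `max(0, 1 −
cost/max_cost)` (mating with replacement — the design keeps male
reproductive variance Poisson-like, so the panmictic limit reproduces the
Wright–Fisher decay `H_t = H_0(1 − 1/(2N))^t`, the module's quantitative
anchor; a single mate per brood would depress Ne below N); broods are
Poisson(4); offspring inherit one uniform random allele per parent per
locus, draw sex fairly, and settle in random order at the nearest
unoccupied point within `max_cost` of the natal point (cost ties broken at
random), the rest dying. Parents die (non-overlapping generations). 30
loci × 10 initial alleles, no mutation or selection, so allelic richness
is non-increasing and its decline is a clean drift/fragmentation signal.
Because home-range spacing is at the published scale regardless of grid
size, the published dispersal budgets (125,000/250,000 cost units) are
used unchanged in the pipeline.

The pipeline's desk defaults run 50 generations × 3 replicates per
scenario × bandwidth; the calibration suite runs the full 200 generations
on a 50-point panmictic population and matches theory within 3 Monte-Carlo
standard errors over 30 replicates.

## What the synthetic experiments do and do not show

They show that the package's machinery produces the qualitative orderings
expected from first principles whenever the landscape has the high-and-far
reserve bias and frontier-concentrated risk: proactive designs retain more
connected landscape and carbon than expedient ones (matched-pair sign test
over 20 landscape seeds), every loss scenario sits at or below the
baseline, and redistribution yields fewer, larger patches than retention.
They do not reproduce the island-scale study's absolute numbers (29% vs
15.2% connected, 1.32 Gt carbon, ~1,100 simulated individuals), which
depend on real rasters at ~300× the desk cell count; the absolute desk
values (e.g. ~0.012 Gt carbon on 32 × 32 km) scale with landscape area and
biomass parameters. Synthetic landscapes also lack coastline geometry,
roads, rivers, land tenure and temporal risk dynamics (a single
decade-scale transition is modelled).

## Numerical choices and degenerate inputs

* Normalisation divides by the layer maximum and rejects non-positive
  maxima; aggregation excludes nodata cells from all statistics.
* The kappa-optimal cut-point scans a 0.01-step threshold grid (matching
  the reporting precision of the metrics), classifies positive at `pred ≥
  t`, and breaks ties toward the smaller threshold.
* Annealing with zero free units returns the locked set; an empty kernel
  support, an all-zero layer, a unit table with no available units, and a
  source on nodata are rejected with explicit errors.
* Percentile thresholds on constant-density support yield an empty core
  (strict inequality) — documented degenerate behaviour.
* Seeds: one master seed fans out to per-stage seeds through
  `numpy.random.SeedSequence`, so stages are independently rerunnable and
  every derived seed stays below 2³¹.
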