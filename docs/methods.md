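# Methods

This note documents the models, conventions and design choices behind
`habrange`, in the order the pipeline applies them.

## Grid geometry and rasterization

All analysis happens on regular, cell-edge-registered lat–lon grids (row 0
northernmost). Cell areas use the exact spherical-zone formula
R²·Δλ·(sin φ₂ − sin φ₁) with R = 6371 km, so any full-globe grid sums to
4πR² at machine precision and any sub-grid sums to its enclosing zone.

Extent-of-occurrence polygons are rasterized in two stages: cell centres of
a 6×-finer nested grid (e.g. 5 arc-minutes under a 0.5° analysis grid) are
tested against the polygon, and each coarse cell receives the flagged
count / 36. This count-based fraction is the default; an area-weighted
variant (`area_weighted=True`) weights flagged subcells by their spherical
area instead. A centre lying exactly on a polygon edge counts as inside —
a deterministic tie-break. Antimeridian-crossing rings must be pre-split by
the caller; no polygon repair is attempted beyond validity checking.
Fine-to-coarse aggregation of fraction fields is area-weighted and
conserves total class area exactly (tested to 1e−10 relative error).
Coastal cells are treated as fully terrestrial: any cell present in the
input masks participates with its whole area.

## Land use

Class fractions (cropland, pasture, urban) are clamped into [0, 1] on
ingest; cells whose class sum exceeds 1 are rescaled proportionally (class
ratios preserved) and counted in the log. Lower ≤ baseline ≤ upper variant
ordering is checked and violations warn rather than fail, since real-world
reconstructions occasionally violate it cell-wise.

Future projections are spliced onto the historical reconstruction by the
additive junction rule: the historical-minus-projected difference at 2010
is added to every projected time step, per class and cell, then clamped to
[0, 1] (with proportional rescaling if the clamp pushes a class sum above
1). The output therefore equals the historical series exactly at 2010.

"Converted area" summaries cap the per-cell class sum at 1 before
multiplying by cell area. The per-cell peak-conversion time is the end
year of the consecutive-time-step interval with the largest conversion
rate; ties go to the earliest interval, and cells with no positive rate
are flagged.

Default time grids: decadal 1700–2000 plus annual 2001–2016 (47 points)
historically; decadal 2020–2100 (9 points) for projections. Each analysis
year is paired with the temporally nearest decadal biome map, ties to the
earlier map.

## Climate preprocessing

Simulated climate is bias-corrected with the additive delta method:
out = sim(t) + (obs_ref − sim_ref), evaluated per cell and month on the
observational grid after nearest-neighbour regridding of the simulation
(which is also what downscales it). The additive form is used for all
three variables — temperature, precipitation, sunshine — with
precipitation and sunshine clamped to their physical ranges afterwards; a
ratio-based correction for precipitation would be a defensible
alternative, but the additive-with-clamp form is the simplest and is exact
for constant biases. Reference matching uses a 1900–1930 mean for
historical correction and the single year 2006 for future correction;
both are parameters. Biome-driving climatologies average the closed
window [t − 30, t] — 31 annual fields — and any missing year is an error
that names the gaps. Vegetation modelling itself is out of scope: biome
maps are inputs, and the bundled threshold classifier exists to close the
loop in tests.

## Range estimation

Potential range field: eoo_fraction × 1{biome suitable}. Actual range
field, per cell with class fractions f_k and natural remainder 1 − Σf_k:

* **extended** (default): eoo × [(1 − Σf_k)·1{biome suitable} +
  Σ_{k tolerated} f_k]. Tolerated artificial land counts anywhere in the
  EOO, so converting an *unsuitable* natural biome to, say, cropland can
  expand a cropland-tolerant species' range — the mechanism behind
  observed range expansions.
* **strict**: the artificial terms apply only where the natural biome is
  suitable, so the actual range is always a subset of the potential range
  at the same time.

Both semantics ship because the step-wise description of the procedure
("remove unsuitable anthropogenic land from the potential range") implies
strict, while the documented expansion mechanism requires extended; the
mode is a single switch and the analytic fixture pins both.

Range size is the area-weighted sum of the field. EOO fractions are
time-invariant. Species whose reference potential range (biomes of t₀ =
1850, no land use) is zero are flagged excluded; species whose EOO
overlaps no grid-cell centre are dropped with a logged count.

Sensitivity variants: **no_migration** zeroes EOO cells whose present-day
(2016) biome is unsuitable before computing future ranges — but the t₀
reference range is always the main analysis' unfiltered one, so only the
numerator of ΔA can shrink and no-migration losses dominate the main
analysis by construction. **static_biomes** freezes the biome distribution
at the present year for all later times.

## Statistics

ΔA percentiles use the linear-interpolation convention (pinned by a
sort-and-rank oracle test). Critical loss counts ΔA strictly below
−50%; a species at exactly −50% is not counted. A species' primary
mega-biome is the mega-biome whose member biomes contribute the largest
share of its reference potential range area, ties to the lexicographically
lowest label; per-group critical-loss shares are reported under both
normalisations (within group and of all species). The marginal-loss curve
pairs the across-species median loss with cumulative converted area and
takes successive finite differences. The local mean-range map averages,
per cell, the *global* reference range sizes of species locally present
(potential fraction > 0), unweighted. Bootstrap uncertainty resamples the
change vector with replacement (resample size = input size, default 10⁴
replicates) using NumPy's PCG64 generator under an explicit mandatory
seed; SD across resamples uses the population (ddof 0) formula, SD across
climate models the sample (n − 1) formula, flagged undefined for a single
model.

## Scenario bookkeeping

A historical scenario is a land-use variant; a future scenario is an
(RCP, SSP, climate model) triple; a run is a scenario at one time point.
With the default grids and registry: 47 × 3 = 141 historical and
9 × 16 × 3 = 432 future runs. The default registry takes all 20 RCP × SSP
pairs minus the four in which RCP 8.5 is combined with SSPs 1–4 (no
matching land-use projection), leaving 16 combinations; any other
combination list can be passed explicitly.

## Synthetic worlds

The generator emulates the statistical structure the analysis assumes, at
desk scale: a 4° grid over ±60° latitude and ±120° longitude (30 × 60
cells), 40 species per taxonomic group (mammals, birds, amphibians), the
47 + 9 point time grids above. Land conversion follows per-cell logistic
trajectories toward a 0.65 asymptote (rate 0.04 yr⁻¹, cell-wise texture in
[0.5, 1]) with midpoint 1880 outside the tropics and 1970 inside |lat| <
25° — a late-onset tropical band. Uncertainty variants scale the baseline
by ±10%. Species EOOs are random rectangles with log-uniform sizes,
tropical species drawn 3–12° wide and extratropical 8–50°, so the
late-converting region hosts the small-ranged species; artificial-class
tolerances are drawn with probabilities 0.35/0.45/0.05 for
cropland/pasture/urban. The toy climate is zonally banded with seasonal
cycle, 0.9 °C warming 1900–2016 and pathway-specific warming to 1.5–4.5 °C
by 2100 (±0.3 °C across three synthetic climate models); projected climate
carries a constant bias that the delta correction removes, exercising that
path end to end. The toy biome classifier crosses three annual-mean
temperature bands (edges 5 and 20 °C, threshold values to the lower band)
with two moisture bands (90 mm/month) into six biomes grouped into three
mega-biomes. SSP land-demand multipliers at 2100 range from 0.7 (SSP 1,
abandonment) to 1.6 (SSP 3, continued expansion).

What this emulates — and what it does not: the generator reproduces
bounded ordered uncertainty variants, monotone staggered conversion,
warming-driven poleward biome shifts, and the small-range/late-conversion
correlation that makes marginal losses accelerate. It does not reproduce
real species-richness geography, realistic EOO shapes, HYDE's
reconstruction logic, or any process-based vegetation model, so passing
tests demonstrate correctness of the pipeline's accounting and its order
relations, not real-world range-change magnitudes.

The analytic fixture is a 4×4-cell, 3-species, 3-time world whose species
occupy single latitude rows (areas cancel from every ratio); all expected
areas, changes, percentiles and critical-loss shares are computed by
independent closed-form arithmetic and stored in a ledger that end-to-end
runs must match exactly in both modes.

## Numerical choices and limitations

Float comparisons in aggregation guard against round-off just above 1 by
clipping; percentile and bootstrap conventions are fixed and versioned;
run enumeration order is deterministic; every pipeline output embeds a
config hash. Problem sizes in tests and the acceptance script (grid
resolution, species counts, bootstrap replicates) are the generator
defaults above, chosen so a full run completes in seconds while keeping
every structural feature active. Known limitations: one primary biome per
cell (no microclimates), no habitat connectivity or fragmentation effects,
no hunting/invasive/disease pressures, EOO bounds cap all range
expansion, and raster I/O is NetCDF-only (GeoTIFF is not supported).
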