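# Methods

This note documents the models implemented in `enforcement-lens`, the
synthetic data they are validated against, and the numerical and design
choices made where the underlying procedures leave room.

## Enforcement indicators

A sanction record is one administrative event — an infraction notice
(carrying a prospective fine in nominal BRL of its issue year), a land-use
embargo, or an equipment confiscation/destruction — keyed by a `record_id`
and a `process_id` shared across sanctions of one case. Ingest collapses
exact duplicate rows and repeated `record_id`s (a duplicate is either), then
filters to the nine Legal Amazon states (AC, AP, AM, MA, MT, PA, RO, RR,
TO) and the study window. The flora-theme filter applies to infraction
notices only: embargo and confiscation exports carry no key separating
deforestation sanctions from other flora crimes, so they are retained
regardless of theme. Rows with unparseable dates are rejected and counted,
never imputed; year assignment is by calendar year of the record date.

Derived series: per-year sanction counts, fine totals, the mean fine over
notices with a nonzero fine (so total = mean × nonzero-count holds exactly),
the geolocated share of notices (missing when a year has none), and the
count of prosecutions reaching the paid stage that year. The paid-fine
ratio is cohorted by *filing* year: of the processes filed in a window, the
share whose terminal stage is `paid`. Percent changes are signed,
`100·(comparison − reference)/reference`, with a half-away-from-zero
integer rounding helper for reporting. Note the antisymmetry identity is
`pc(a,b) = −pc(b,a)·b/a`. Period aggregation is element-wise; in sum mode
ratio-like columns are recomputed from their summed components rather than
summed.

## Spatial match

Both event layers are binned onto one analysis grid: points by cell count,
deforestation polygons by covered-area fraction (cell value × cell area
sums to the in-grid patch area). The binned raster is convolved (FFT) with
an analytic kernel sampled at cell centres:

- **quartic (biweight)**, the common GIS kernel-density convention:
  `K(r) = 3/(πh²)(1 − r²/h²)²` for `r ≤ h`, support radius = bandwidth `h`;
- **gaussian** option: `σ = h/3`, truncated at `h` and renormalised for the
  truncated mass.

Events are snapped to their cell centre before smoothing; with `h` an order
of magnitude above the cell size the discretization error is far below the
1% mass-conservation tolerance the tests enforce for interior events. No
edge correction is applied, so density is biased low within one bandwidth
of the region border — acceptable because both layers share the bias and
the statistic is a correlation.

Before correlating, the lowest quartile of each map's strictly positive
cells is set to nodata (linear-interpolation sample quantile; cells
strictly below the threshold are masked, ties at the threshold survive, and
zero cells are always masked), so the comparison covers hotspots only. The
quantile is computed per year per map. Pearson `r` is taken over the cells
valid in **both** maps (intersection rule). The annual series carries a
trailing 4-year moving average, defined only where the window is full.

Bandwidth scales with the study region: the biome-scale convention of 30 km
(the default in `SpatialMatchConfig`) corresponds to roughly 1/150 of the
region extent, so desk-scale analyses on the 50 km synthetic region use
2 km. The kernel family is recorded in output metadata via the config.

## Legality screening

- **APP zones**: union of flat-capped buffers (default half-width 30 m, the
  statutory minimum for narrow streams; configurable per stream class)
  around the stream polylines.
- **FC balance**: `native_fraction` is the share of native cells among
  raster cells whose centre falls in the holding;
  `deficit = max(0, 0.80 − native_fraction) × area`; compliant ⇔ zero
  deficit. The balance is computed on the pre-clearing native map — a
  patch's own clearing does not enter the deficit that judges it.
- **Classifier**, in precedence order for patches assigned to a holding by
  largest overlap (representative point as fallback): below the 6.25 ha
  minimum mapping unit → `below_mmu` (not assessed); intersects APP →
  `potentially_illegal`/`riparian_app`; holding non-compliant →
  `potentially_illegal`/`lr_deficit`; else `presumed_legal`. APP precedence
  means one reason is reported even when both apply.
- **Attribution**: a geolocated notice links to the holding containing its
  point; it is deforestation-related when the holding contains a patch with
  `patch.year ≤ notice year` — enforcement that *follows* clearing, at year
  granularity (record dates are not reliable below that).
- **Protected overlap**: fraction of the holding inside the union of
  protected areas; flagged when strictly above 25%. Invalid geometries are
  repaired by zero-buffer or rejected.
- **Land-category breakdown**: patch area apportioned with precedence
  indigenous land > conservation unit > settlement > landholding >
  undesignated, so per-year totals conserve total patch area.
- **Illegality-with-enforcement series**: per year, the share of
  potentially-illegal area whose holding was reached by a
  deforestation-related notice in that or a later year, and the share of
  that year's deforesting holdings (≥ 1 above-MMU patch) noticed that year;
  plus an all-years summary of deforesting holdings ever noticed.

## Synthetic landscape generator

The generator emulates the statistical structure of the real inputs, not
their geomorphology:

- **Cadastre**: Voronoi cells of uniform seed points (mirrored across the
  region edges so every cell is finite), clipped to the rectangle — a
  gapless, non-overlapping holding fabric. Default 60 holdings on 50 × 50 km.
- **Streams**: left-to-right random-walk polylines (default 5); protected
  areas are random rectangles covering ~12% of the region, alternating
  indigenous land / conservation unit.
- **Native map**: 100 m binary raster, fully native except in a designated
  deficit subset of holdings (default 25%), pre-cleared to 60% native —
  safely below the 80% requirement so raster sampling noise cannot flip
  compliance.
- **Patches**: `years × patches_per_year` axis-aligned rectangles (exact
  area bookkeeping), log-normal areas (median 30 ha, σ_log = 0.8; ~2% fall
  below the 6.25 ha MMU), aspect ratio uniform in [1, 3]. Each above-MMU
  patch draws an illegality intent (`illegal_fraction_target`, default 0.5;
  riparian vs deficit route split by `app_placement_share`). Placement is
  rejection-sampled to realize the intent — riparian patches centred on a
  stream point, deficit/legal patches fully inside a deficient/compliant
  holding and clear of the APP; if 60 tries fail, the patch is placed
  uniformly and its truth label derived from the realized geometry, so the
  ground truth is exact either way. Realized illegal fractions are binomial
  around the target.
- **Notices**: per year, each notice is coupled with probability
  `coupling_rho` (location = a same-year patch centroid + isotropic
  N(0, jitter_sigma) noise, default 1 km) else uniform; carries coordinates
  with probability `geolocation_prob` (default 0.6, a mid-study rate
  between the few-percent early years and the ~60% later ones). Configurable
  shares spawn embargo (0.35) and confiscation (0.20) records on the same
  process key. Years with no patches fall back to uniform with a warning.
- **Prosecutions**: one process per notice advancing filed→judged→paid with
  transition probabilities (0.5, 0.34), whose product matches the ~17%
  paid-fine ratio characteristic of the pre-2019 regime.
- **Budget**: a log-normal annual expenditure series split over budget
  items, plus a deterministic 4%/yr price index.

All randomness flows from one seed through named sub-streams (holdings,
protected, streams, patches, native, notices, prosecution, expenditure), so
components regenerate independently and a fixed seed reproduces everything
bit for bit.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: spatial contagion of deforestation,
realistic parcel shapes and river geomorphology, state-dependent reporting
artifacts, export-dialect heterogeneity, and any behavioural response of
offenders to enforcement. The tests establish that the *method* recovers
known structure, not that real Amazon series would show any particular
value.

## Efficiency

`deflate_convert` applies `real(y) = nominal(y) · index(base)/index(y) /
rate` with a default 5 BRL/USD; it is exactly invertible given the index
and rate. `operational_efficiency` divides the same annual expenditure by
each sanction type's count (missing where the count is zero). Period unit
costs are pooled (total expenditure / total sanctions) because multi-year
figures are totals; mean-of-ratios is available as an option. The
whole-agency budget is used as the expenditure proxy, without state
apportioning.

## Problem sizes and numerical notes

Validation runs use the 50 km region at 100 m cells (500 × 500), 2 km
bandwidth, 5–10 years × 40–50 patches, three seeds per coupling level, and
n = 2000 processes for funnel recovery — sizes at which every stochastic
check sits inside an exact binomial 99% interval while the whole suite runs
in well under a minute of arithmetic. FFT convolution can produce tiny
negative densities (~1e-18), clipped to zero. Correlation requires ≥ 2
jointly valid cells and non-constant surfaces; degenerate years are
reported missing rather than guessed. CSV floats are written at %.10g so
identical runs are byte-identical.

## Known limitations

- Only the two legality rules are implemented; full statutory accounting
  (hilltop/slope APPs, Legal Reserve compensation, pre/post-2008 amnesty)
  is out of scope.
- APP buffer widths are a single configurable default; the statutory
  width ladder (30–500 m by river width) is left to the `widths` hook.
- No significance testing of `r` under spatial autocorrelation; the
  statistic is descriptive.
- Notices are attributed at year granularity and by point-in-polygon only;
  process-level links between notices and specific patches are not
  modelled beyond the generator's ground truth.
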