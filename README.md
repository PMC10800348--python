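# enforcement-lens

Analytics for environmental-law-enforcement effectiveness in Amazon-like
settings: how well do fines, embargoes and confiscations track illegal
deforestation over space and time, and what does a sanction cost the state?

The package is written for conservation scientists and environmental-policy
analysts who work with administrative sanction records (IBAMA-style
exports), cadastral landholding boundaries (CAR-style), annual deforestation
polygons (PRODES-style) and budget series. Because those national datasets
are large and access-restricted, every stage can also be exercised on a
built-in synthetic landscape generator with exact ground truth, which is how
the test suite validates the method end to end.

## What it computes

**Enforcement indicators.** After deduplication and filtering (nine Legal
Amazon states; flora-theme infraction notices only, while embargoes and
confiscations are kept regardless of theme), annual series of sanction
counts, fine totals, geolocation shares and paid fines, plus period
aggregates, percent changes, the paid-fine ratio of the filed→judged→paid
prosecution funnel, and embargo/notice cross-referencing.

**Spatial match.** For each year, geolocated notices and deforestation
patches are rasterized and smoothed into kernel-density heatmaps
(quartic kernel, bandwidth *h*; 30 km at biome scale). The lowest quartile
of each positive surface is set to nodata so only hotspots are compared,
and the two maps are correlated pixel by pixel:

    r_y = corr( f̂_fines,y(x), f̂_defor,y(x) )   over cells valid in both,

with a trailing 4-year moving average. r → 1 means field operations
concentrate exactly where clearing concentrates.

**Legality screening.** Per holding, the Forest Code balance
`deficit = max(0, LR − native_fraction) × area` with LR = 80%; per patch
(≥ 6.25 ha, the minimum mapping unit) the label *potentially illegal* if it
intersects a riparian preservation buffer (APP, default 30 m) or sits in a
deficit holding, else *presumed legal*. Notices are attributed to holdings
by point-in-polygon and count as deforestation-related only when issued in
or after a clearing year. Protected-area overlap > 25% flags a holding as
potential public-land appropriation.

**Operational efficiency.** `OE_{i,y} = E_y / I_{i,y}` — inspection
expenditure of year *y* (IPCA-style deflation to a base year, converted at
5 BRL/USD) per sanction of type *i*. Period unit costs are pooled
(ratio of sums), since multi-year figures are totals.

## Worked example

```python
import pandas as pd
from enforcement_lens import *

cfg = LandscapeConfig(seed=11, years=(2012, 2016), patches_per_year=40,
                      coupling_rho=0.8, geolocation_prob=1.0)
land = generate_landscape(cfg)
bundle = generate_enforcement(land, cfg)

records, report = ingest_records(bundle.records, FilterConfig(study_window=cfg.years))
print(report)                 # {'duplicates': 0, 'bad_date': 0, 'out_of_window': 2,
                              #  'out_of_region': 0, 'non_flora': 12}

notices = records[(records.sanction_type == "infraction_notice") & records.x.notna()]
years = pd.to_datetime(notices.date).dt.year
fines = {int(y): notices.loc[years == y, ["x", "y"]].to_numpy(float) for y in years.unique()}
defor = {}
for p in land.patches:
    defor.setdefault(p.year, []).append(p.polygon)
series = match_series(fines, defor,
                      SpatialMatchConfig(bandwidth_m=2_000, cell_size_m=100), land.grid)
print(series.round(3))
#           r  n_cells     ma
# 2012  0.249    55732    NaN
# 2013  0.413    53765    NaN
# 2014  0.251    54788    NaN
# 2015  0.151    52981  0.266
# 2016  0.367    53229  0.296
```

The positive annual `r` (~0.15–0.41) reflects the configured
coupling of notices to same-year patches (`coupling_rho=0.8`); with
`coupling_rho=0` the same pipeline hovers around zero. Legality screening of
the same landscape labels 79 of the 200 patches potentially illegal (34
riparian, 45 Legal Reserve deficit), 5 fall below the 6.25 ha mapping unit,
and the prosecution funnel yields a paid-fine ratio of 0.21.

The same chain runs from the shell:

```bash
enforcement-lens run --config cfg.yaml --seed 11 --out out/
enforcement-lens simulate --out sim/ --seed 3
enforcement-lens spatial-match --landscape sim/ --out series.csv
```

writing annual indicator, spatial-match, legality, land-category and
efficiency tables as CSV plus a JSON run manifest (config hash, seed,
per-stage counts) that makes any run byte-for-byte reproducible.

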