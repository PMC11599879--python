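# mcpi — mangrove coastal protection analysis

Mangrove belts shield coasts from waves, storm surge and erosion, but
"how much mangrove" is usually tracked as *area* — which misses the
structure that actually does the protecting. This package implements a
process-based **Mangrove Coastal Protection Index (MCPI)** that combines,
per coastal grid cell,

```
MCPI = A · B · NDVI · 1000
A    = 1 − exp(−0.29 · W)        wave attenuation of a belt W km wide
B    = (h / 10)^2.55, capped at 1  biomass frontal barrier of canopy height h (m)
NDVI = (ρ_NIR − ρ_red) / (ρ_NIR + ρ_red)   greenness / condition
```

together with everything needed to compute and analyze it end to end:

- a **synthetic coastal scene generator** (rasters + coastline + storm
  tracks) with known ground truth, so every stage is testable without
  satellite data;
- **transect sampling**: outer-wrap coastline extraction, perpendicular
  transects at fixed spacing, per-region average mangrove width (AMW),
  average canopy height (ACH) and NDVI;
- the **index** itself plus distribution summaries;
- **trend statistics**: OLS width trends in m/yr with significance tests,
  and percent-per-year change-rate arithmetic;
- **cluster exchange network analysis (CENA)**: pooled two-epoch
  k-medoids clustering under a cosangle distance, bootstrap fuzzy
  memberships, and the k×k cross-epoch exchange matrix/network;
- **storm-response validation**: severe-storm filtering (> 64 kn, coast
  crossing), buffered impact zones, before/after NDVI change, and Spearman
  rank correlation against MCPI.

It is written for coastal-ecosystem researchers and method developers who
want a reproducible, fully tested desk-scale implementation of this
analysis chain. Geometry is planar (projected metres); all persisted
formats are text (ASCII grid, GeoJSON, CSV).

## Worked example

```python
from mcpi import (SceneConfig, generate_scene, extract_regions,
                  enrich_records, records_to_frame)

config = SceneConfig(
    n_cols=320, n_rows=100,                 # 9.6 km of coast at 30 m cells
    width_m=(900.0, 1500.0, 600.0, 1200.0), # true belt width per region
    height_m=(8.0, 11.0, 3.5, 6.0),         # true canopy height per region
    ndvi=(0.70, 0.80, 0.55, 0.65),
    n_regions=4,
)
scene = generate_scene(config, seed=42)
records = enrich_records(extract_regions(scene, spacing=250.0, length=2500.0))
print(records_to_frame(records).round(3).to_string(index=False))
```

prints

```
 region_id  epoch  amw_m  ach_m  ndvi  m  n     a     b    mcpi
         0   2019  900.0    8.0  0.70 10 10 0.230 0.566  91.028
         1   2019 1500.0   11.0  0.80 10 10 0.353 1.000 282.188
         2   2019  600.0    3.5  0.55  9  9 0.160 0.069   6.040
         3   2019 1200.0    6.0  0.65 10 10 0.294 0.272  51.928
```

Each row is one coastal region: the sampler recovered the configured
width/height/NDVI exactly on this noiseless scene (`amw_m`, `ach_m`,
`ndvi`), and `a`, `b`, `mcpi` are the attenuation factor, barrier factor
and composite index. Region 1's 11 m canopy saturates the 10 m barrier cap
(`b = 1.0`); region 2 scores a near-zero index despite a present band —
short, sparse-looking mangroves protect little.

The `examples/` directory has one short narrative script per capability
(scene generation, sampling + index, trends, cluster exchange, storm
validation, full pipeline); each prints the numbers it computes and what
they mean. A thin CLI wraps the same library:

```bash
mcpi run --config examples/demo_config.yaml     # full pipeline
mcpi simulate|sample|index|trend|cena|validate  # individual stages
```

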