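"""Transect-sample a scene and compute the protection index per region.

Transects are cast perpendicular to the wrapped coastline at fixed spacing;
each region's average mangrove width (AMW), canopy height (ACH) and NDVI
feed the index MCPI = A x B x NDVI x 1000, where A = 1 - exp(-0.29 W_km)
is wave attenuation and B = (h/10)^2.55 (capped at 1) the biomass barrier.
"""

from mcpi import (
    IndexConstants,
    SceneConfig,
    enrich_records,
    extract_regions,
    generate_scene,
    records_to_frame,
    summarize,
)

config = SceneConfig(
    n_cols=320, n_rows=100,
    width_m=(900.0, 1500.0, 600.0, 1200.0),
    height_m=(8.0, 11.0, 3.5, 6.0),
    ndvi=(0.70, 0.80, 0.55, 0.65),
    n_regions=4,
)
scene = generate_scene(config, seed=42)

records = extract_regions(scene, spacing=250.0, length=2500.0)
records = enrich_records(records, IndexConstants())

df = records_to_frame(records)
print(df.round(3).to_string(index=False))
# amw_m/ach_m/ndvi are the sampled factors (compare them with the truth of
# example 01); a and b are the attenuation and barrier factors in [0, 1];
# mcpi is their product scaled by 1000. Note region 1 (11 m canopy) hits the
# 10 m cap: its b is 1 despite the extra metre of height.

s = summarize(df["mcpi"])
print(f"\nMCPI distribution: median {s.median:.1f}, mean {s.mean:.1f}, "
      f"IQR [{s.q1:.1f}, {s.q3:.1f}], max {s.maximum:.1f}")
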