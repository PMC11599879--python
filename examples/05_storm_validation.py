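"""Storm-response validation of the protection index.

A synthetic world is built in which the index's hypothesis holds by
construction: storms damage the greenness of poorly protected (low-MCPI)
mangrove areas more than well-protected ones. The validation machinery —
severe-storm filter (wind > 64 kn, track crossing the coast), buffered
impact zones, before/after NDVI change, Spearman rank correlation against
MCPI — should then recover a positive, significant correlation.
"""

from mcpi import run_protection_experiment

out = run_protection_experiment(n_areas=53, seed=7, base_drop=0.30, noise_sd=0.03)

print(f"storm-impacted mangrove areas: n = {out['n']}")
print(f"Spearman rho(MCPI, dNDVI) = {out['rho']:.3f},  p = {out['p_value']:.2g}")
print("\nfive sample area-events (delta = NDVI after - before):")
for r in sorted(out["responses"], key=lambda r: r.mcpi)[:5]:
    print(f"  region {r.region_id:>2}  MCPI {r.mcpi:7.1f}  dNDVI {r.delta_ndvi:+.3f}")
# a positive rho with small p means greener outcomes in better-protected
# areas, i.e. the index ranks protective capacity as intended.
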