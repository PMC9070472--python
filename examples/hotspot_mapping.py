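"""Map facility hotspots with Getis-Ord Gi* on a fishnet grid.

Aggregates a clustered facility pattern to square cells, computes the Gi*
z-score per cell with a fixed-distance neighbourhood, adjusts the p-values
for multiple testing (Benjamini-Hochberg FDR) and bins the cells into
signed confidence classes: +3 is a hotspot at 99% confidence, -3 a cold
spot, 0 not significant.
"""

from geoaccess import SyntheticConfig, gen_facilities, hotspot_analysis

cfg = SyntheticConfig(seed=2, n_facilities=531, pattern="thomas", thomas_parents=5)
facilities = gen_facilities(cfg)

cells, params = hotspot_analysis(facilities, cfg.area, cell_size=4000.0, band=8000.0)

print(f"fishnet: {len(cells)} cells of {params.cell_size:.0f} m, "
      f"band {params.band:.0f} m")
for b in range(3, -4, -1):
    k = int((cells["bin"] == b).sum())
    if k:
        label = {3: "hot 99%", 2: "hot 95%", 1: "hot 90%", 0: "not significant",
                 -1: "cold 90%", -2: "cold 95%", -3: "cold 99%"}[b]
        print(f"  bin {b:+d} ({label:15s}): {k:4d} cells")
top = cells.loc[cells["gi_z"].idxmax()]
print(f"strongest hotspot cell: centre ({top['center_x']:.0f}, {top['center_y']:.0f}), "
      f"{int(top['count'])} facilities, Gi* z = {top['gi_z']:.2f}")
print("cells with bin = +3 are where facility density is significantly",
      "concentrated after FDR control - the 'urban core' of the simulation.")
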