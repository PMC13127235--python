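"""Map multi-year phenology trends with Theil-Sen + Mann-Kendall.

Generates 24 years with an imposed spring-advance trend in the west half
of the scene only, recovers per-pixel upturn-date trends from the full
pipeline, and summarizes them per region.
"""

import numpy as np

import lspheno as lp

years = tuple(range(2000, 2024))
west = lp.SceneConfig(ny=6, nx=3, years=years, seed=31,
                      base_truth=lp.TruthParams(sos_trend=-0.5))
east = lp.SceneConfig(ny=6, nx=3, years=years, seed=32)

ud_parts = []
for cfg in (west, east):
    scene = lp.generate_scene(cfg)
    comp = lp.compute_vi_composites(scene.reflectance, index_names=("ppi",))
    metrics = lp.extract_metrics_cube(comp)
    ud_parts.append(metrics["ppi"]["ud"])
ud = np.concatenate(ud_parts, axis=2)          # (24, 6, 6)
regions = np.zeros((6, 6), dtype=int)
regions[:, 3:] = 1                             # 0 = west, 1 = east

tm = lp.trend_map(ud, years=np.asarray(years, float))
table = lp.region_summary(ud, regions, years=np.asarray(years, float),
                          trends=tm)
print("upturn-date (UD) trends from PPI, 2000-2023:")
print(table.to_string(index=False, float_format=lambda v: f"{v:8.3f}"))
print()
print("Region 0 carries the imposed -0.5 d/yr spring advance (negative")
print("slope, significant); region 1 is trendless, so its regional slope")
print("is near zero and pixels clear |Z| >= 1.96 only at the ~5% false-")
print("positive rate (often none at all in a sample of 18 pixels).")
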