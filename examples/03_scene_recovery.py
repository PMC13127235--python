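"""Full-scene phenology recovery: reflectance cube -> Gu metric maps.

Generates a small synthetic scene (noise, clouds, winter snow, QA flags),
runs the complete chain for all three indices, and reports the median
absolute error of each recovered date against the per-pixel truth.
"""

import numpy as np

import lspheno as lp

cfg = lp.SceneConfig(ny=8, nx=8, years=(2012,), seed=11)
scene = lp.generate_scene(cfg)
print(f"scene: {cfg.ny}x{cfg.nx} pixels, year {cfg.years[0]}, "
      f"noise sd {cfg.contamination.noise_sd}, "
      f"cloud prob {cfg.contamination.cloud_prob}")

comp = lp.compute_vi_composites(scene.reflectance)
print(f"canopy-maximum DVI across the scene: "
      f"{np.nanmin(comp['m_grid']):.3f}-{np.nanmax(comp['m_grid']):.3f}")

metrics = lp.extract_metrics_cube(comp)
print(f"\n{'index':7s}" + "".join(f" {m.upper():>6s}" for m in
                                  ("ud", "sd", "dd0", "dd", "rd")))
for name, per_metric in metrics.items():
    errs = []
    for m in ("ud", "sd", "dd0", "dd", "rd"):
        truth = scene.true_metrics[m].values
        errs.append(np.nanmedian(np.abs(per_metric[m] - truth)))
    print(f"{name:7s}" + "".join(f" {e:6.2f}" for e in errs))

print("\nValues are scene-median |error| in days versus the generator's")
print("closed-form truth. DD compares against the flat-plateau truth, so")
print("part of its offset is the geometric greendown adjustment itself.")
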