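"""Compute EVI, kNDVI, and PPI for a handful of reflectance samples.

Builds three typical surface-reflectance situations (bare soil, mid
green-up, closed canopy) and prints each index. EVI and kNDVI come
straight from band arithmetic; PPI additionally needs the canopy-maximum
DVI `M`, the bare-soil DVI, and the solar-geometry gain K.
"""

import numpy as np

import lspheno as lp

samples = {
    "bare soil  ": dict(blue=0.06, red=0.12, nir=0.21),
    "green-up   ": dict(blue=0.05, red=0.10, nir=0.38),
    "peak canopy": dict(blue=0.04, red=0.07, nir=0.52),
}

# PPI geometry: record-maximum DVI for this (synthetic) site, overhead sun
theta = lp.solar_zenith_noon(36.0, 180)  # latitude 36 N, late June
params = lp.PPIParams(M=0.46, DVIs=0.09, G=0.5, dc=0.0, theta=theta)
K = lp.ppi_gain_k(theta, params.dc, params.G, params.M)
print(f"solar zenith at noon: {np.degrees(theta):.1f} deg, gain K = {K:.3f}")
print(f"{'sample':12s}  {'DVI':>6s} {'EVI':>6s} {'kNDVI':>6s} {'PPI':>6s}")
for name, s in samples.items():
    dvi = lp.compute_dvi(s["nir"], s["red"])
    evi = lp.compute_evi(s["nir"], s["red"], s["blue"])
    kndvi = lp.compute_kndvi(s["nir"], s["red"])
    ppi = lp.compute_ppi(dvi, params)
    print(f"{name:12s}  {dvi:6.3f} {evi:6.3f} {kndvi:6.3f} {ppi:6.3f}")

print()
print("DVI/EVI/kNDVI are dimensionless greenness measures; PPI is in")
print("m2/m2 (near-linear in leaf area index). Bare soil sits at the")
print("index floors (PPI = 0 exactly at the bare-soil DVI); the closed")
print("canopy approaches the PPI saturation cap as DVI nears M.")
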