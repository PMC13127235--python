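# Methods

This note documents the models implemented in `lspheno`, the defaults and
their units, the synthetic-data generator that serves as the package's
test bed, and the numerical choices made where the design was open.

## 1. Vegetation indices

All indices operate on surface reflectance in [0, 1] (NBAR-like: already
atmosphere- and view-angle-corrected), with NaN as the missing marker.
Index functions propagate missingness and never raise on data values.

**EVI** uses the standard MODIS coefficient set (gain 2.5, background
adjustment L = 1, aerosol coefficients C1 = 6, C2 = 7.5). A denominator at
or below 1e-9 — near-singular or negative, possible for bright-blue
(cloud/snow) samples — returns missing rather than an unstable ratio.

**kNDVI** is tanh(((NIR − red)/2σ)²). The default length scale
σ = 0.5(NIR + red) makes it identically tanh(NDVI²), bounded in [0, 1);
σ is an argument for applications that calibrate it otherwise.

**PPI** inverts a Beer's-law canopy model: with DVI = NIR − red,
PPI = −K·ln((M − DVI)/(M − DVI_s)), in m²/m² (near-linear in LAI).

- DVI_s = 0.09 (bare-soil DVI) and G = 0.5 (spherical leaf-angle
  distribution) follow common practice for this index family.
- M, the canopy-maximum DVI, is estimated per pixel as the record maximum
  of the composited DVI series (`per_pixel_max_dvi`). Pixels whose record
  maximum does not exceed DVI_s carry no vegetation signal and are masked
  from PPI and all downstream phenology.
- K = [0.25·cosθ / ((1 − d_c)·G + d_c·cosθ)]·(1 + M)/(1 − M). θ is
  evaluated per pixel row at local solar noon for each composite mid-date
  from the classical declination approximation (23.45°·sin(2π(284+DOY)/365));
  a fixed-θ override exists. The diffuse fraction d_c has no standard
  published value for this use; the default d_c = 0 (pure direct beam) is a
  documented choice, configurable per run.
- **Saturation clamp.** Because M is the in-record maximum, the record's
  peak composite touches M and the logarithm diverges there; near-peak
  composites sit within noise of M and would produce large spurious spikes.
  DVI is therefore clamped to [DVI_s, M − eps] with eps = 0.04 DVI units by
  default — roughly three times the noise scale of an 8-day composite DVI
  (per-band noise ~0.02 → composite DVI noise ~0.012), so the cap engages
  exactly where the gap to the canopy maximum is statistically
  indistinguishable from zero. The cap value is K·ln((M − DVI_s)/eps)
  (≈ 2·K for typical scenes), safely above seasonal peak PPI. A much
  smaller eps re-introduces order-10·K spikes at the record peak that
  destroy the seasonal fine fit; eps is exposed for sensitivity analysis.

**Compositing** follows the fixed MODIS-style 8-day grid, windows starting
DOY 1, 9, …, 361 (46 per year; the last window holds 5 days in the 365-day
calendar used throughout). A composite is the mean of good-QA daily values
in its window; its weight is n_good / window_length; an all-poor window is
missing with weight 0. Window anchoring is a convention, not a derived
quantity. `fill_leading_gap` substitutes missing *leading* composites of
the first year with the multi-year mean of the same composite position
(the standard treatment when a sensor record begins mid-winter); filled
values are flagged.

## 2. Seasonal curve fitting

**Rough fit (wHANTS-style).** Weighted least-squares harmonic regression
with base period 365 days and `n_harmonics = 3` by default — enough to
track one asymmetric season without chasing noise. After each of
`n_outer_iter = 3` fits, weights are updated by the upper-envelope rule
below. Both counts are conventions of TIMESAT-style processing chains,
exposed in configuration.

**Upper-envelope weight update (wTSM-style).** Residual r = value − fit;
points at or above the curve keep their weight; points below are
down-weighted to `original · max(0.05, 1 − |r|/(3·SD(r)))`, where SD(r) is
taken over positive-weight points. A point 3 SDs below the curve hits the
floor (5 % of its original weight); weights never increase above their
original and zero stays zero. The exact TIMESAT decay formula varies
between implementations; what the package guarantees (and tests) is the
contract: envelope-sided, monotone, bounded below, floor-limited.

**Season division.** One growing season per calendar year (temperate
regime; multi-season phenology is unsupported by design). The rough curve
is evaluated daily over the year ± 90 days; the peak is the in-year
maximum (ties to the earliest day) and the window bounds are the curve
minima either side of the peak. A rough amplitude under `min_amplitude`
(default 0.05 VI units) marks the pixel-year "no seasonality" and skips it.

**Fine fit (Beck double logistic).**
v(t) = mn + (mx − mn)[σ(rsp(t − sos)) + σ(−rau(t − eos)) − 1], fitted by
bounded weighted least squares (scipy `least_squares`, trf) with an
analytic Jacobian; bounds: mn/mx within the data range widened by 20 % of
the amplitude, sos/eos within the season window ± 30 days, rates in
(0.001, 2] day⁻¹; tolerances 1e-8 on parameters, max 200 evaluations.
Initialization: mn/mx from the 5th/95th percentiles, sos/eos from the
half-amplitude crossings either side of the peak (window quartiles as
fallback), rates 16/(eos − sos) clipped to [0.01, 1]. After convergence one
envelope reweight/refit cycle is applied (count configurable).
Non-convergence returns the best parameters with a flag rather than
raising; fewer than 7 usable points is an error the pipeline converts to a
missing pixel-season. All fits are deterministic.

## 3. Gu metric extraction

From the fitted daily curve (integer-day sampling) and its exact
derivative: baseline/maxline are the in-window curve minimum/maximum; the
recovery line is the tangent at the maximum derivative at or before the
curve peak, the senescence line the tangent at the minimum derivative at
or after it (ties to the earliest day). UD/SD/DD0/RD are the analytic
intersections of these tangents with baseline and maxline; DD is the
senescence ∩ plateau-line intersection, the plateau line being the OLS fit
of the curve between SD and DD0 (greendown adjustment). A single
baseline is used for both season ends. Metrics are real-valued days,
equivariant under time shifts and invariant under positive affine
transforms of the VI axis; a monotone window, a parallel plateau, or an
ordering violation flags the affected metrics invalid instead of raising.

For a pure Beck curve with decoupled flanks the closed forms are
UD = sos − 2/rsp, SD = sos + 2/rsp, DD0 = eos − 2/rau, RD = eos + 2/rau
(`gu_closed_form`, the tests' independent oracle). Two geometric facts
worth recording: (i) the closed form is only accurate when each logistic
is saturated at the season midpoint — rate·(eos − sos)/2 ≳ 6 keeps the
numerical extraction within a fraction of a day, and the test samplers
enforce this; (ii) the pure Beck curve's SD→DD0 segment sags σ(−2) ≈ 12 %
of amplitude below the maxline at both endpoints by construction, so its
OLS plateau is *not* flat and the adjusted DD lands within a couple of
days of DD0 on either side of it, depending on the plateau tilt. The
identity DD = DD0 holds exactly for a genuinely flat plateau, and that is
how it is tested.

## 4. Consistency statistics

Pearson correlations are computed with pairwise missing removal (≥ 3
complete pairs, nonzero variance, else missing with a warning); per-pixel
maps are summarized by median, IQR, and a fixed histogram on [−1, 1] with
step 0.05. Tower comparisons use the missing-ignoring mean of the 3×3
pixel window around the site (edge sites are rejected — pad or relocate).
Daily references are averaged onto the same 8-day grid; `shift_days`
uniformly shifts the reference time axis before binning, for products
whose calendar is offset from the composite grid (sign: positive = later;
the parameter is signed precisely because offset conventions differ
between products). Cross-validated regression shuffles once (seeded),
splits into k near-equal contiguous folds, fits y = a + bx per training
set, and pools out-of-fold predictions into R² = 1 − SS_res/SS_tot, RMSE,
and bias_median = median(observed − estimated) — so *negative* bias means
overestimation by the VI model. Residual seasonality uses half-open DOY
bins [1,60), [60,150), [150,240), [240,330), [330,366): dormant, green-up,
peak season, senescence, dormant; the last bin closes at 366 to cover leap
days in external data.

## 5. Trend analysis

Theil–Sen: median of all pairwise slopes, missing years dropped pairwise,
≥ 2 points. Mann–Kendall: S = Σ_{i<j} sign(v_j − v_i) with tie-corrected
variance [n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18 and continuity-corrected
Z; ties are rare for real-valued dates but filled or rounded data can
produce them. Significance classes use |Z| ≥ 1.96 (95 %) and |Z| > 2.56
(99 %); 2.56 — rather than the exact normal quantile 2.576 — is kept
deliberately as the threshold conventional in this literature, and makes
a difference only for |Z| in (2.56, 2.576]. Per-pixel maps require ≥ 4
valid years. Regional summaries compute the trend of the region-mean
annual series (series-first, the right analogue of basin-mean trend
reporting); pixel-level significant/advancing/delaying fractions are
reported alongside from the per-pixel grid, since the two aggregation
orders answer different questions. No autocorrelation pre-whitening and
no cross-pixel multiple-testing correction are applied — both are
documented limitations of the plain MK map.

## 6. Synthetic scenes: what they emulate, and what not

The generator (`lspheno.synthetic`) produces daily 3-band reflectance
cubes with QA flags, SIF/GPP proxy series, and closed-form true metrics.
Per pixel and year, LAI follows the Beck form (plus an optional linear
greendown ≤ 0 across the plateau, clipped at the baseline); reflectance
follows DVI = M_true − (M_true − DVI_s,true)·exp(−c·LAI) with constant
soil red/blue and NIR = red + DVI; clouds depress DVI (60 % NIR drop,
40 % red rise of a draw around |cloud_vi_bias|) and are QA-flagged with
probability 0.9 — the unflagged remainder is exactly what upper-envelope
fitting must absorb; snow brightens the visible bands toward 0.7 and
collapses DVI to ~0 inside the winter window, occasionally escaping QA.
GPP = lue·(1 − exp(−0.5·LAI))·S(t), where the saturating term is an fPAR
proxy (any monotone saturating function would serve) and
S = min(1, 2σ(−rau(t − (eos − lead)))) starts the photosynthetic decline
`autumn_lead_days` before the structural inflection; SIF is proportional
to GPP plus noise. Scenes are bit-reproducible from one seed (independent
child streams for truth, band noise, contamination, proxies).

Default study conditions (chosen once, at design time, as a semi-arid
temperate grassland; all configurable):

| parameter | default | unit | note |
|---|---|---|---|
| mn_lai / mx_lai | 0.2 / 1.2 | m²/m² | sparse grassland amplitude |
| sos / eos | 130 / 280 | DOY | mid-latitude season |
| rsp / rau | 0.2 / 0.2 | day⁻¹ | ~20-day transitions |
| jitter_sd | 2 | days | interannual sos/eos jitter |
| sos/eos gradient | 6 | days | edge-to-edge spatial range |
| M_true / DVI_s,true | 0.7 / 0.09 | – | canopy/soil DVI endpoints |
| c_lai2dvi | 0.6 | (m²/m²)⁻¹ | extinction, erectophile grass |
| red_base / blue_base | 0.12 / 0.06 | – | bright loess-type soil |
| noise_sd | 0.02 | – | per-band Gaussian |
| cloud_prob / qa_detect | 0.2 / 0.9 | – | 2 % of days escape QA |
| cloud_vi_bias | −0.15 | DVI | mean depression |
| snow window/prob | [335, 60] / 0.08 | – | winter episodes |
| lue | 6 | g C m⁻² d⁻¹ | peak GPP scale |
| autumn_lead_days | 20 | days | photosynthesis leads structure |

The amplitude matters: each index is a *different nonlinear transform* of
LAI, so tangent-line dates carry an index-specific structural bias that
grows with canopy density — at peak LAI 3 the kNDVI recession date is
biased late by more than 10 days on noise-free data, and no pipeline can
remove that; at the default amplitude the biases stay within ~3 days for
all three indices. This is the same mechanism that makes real
structural-greenness indices lag PPI and GPP in autumn, and it is why the
recovery tests are run at grassland-like amplitude rather than
dense-forest amplitude.

What the generator does **not** emulate: BRDF and view-angle effects,
atmospheric variability, mixed pixels and land-cover change, leap days,
multi-modal (double-cropping) seasons, spatially correlated weather, and
autocorrelated interannual variability. Passing recovery tests therefore
demonstrates the correctness and calibration of the retrieval chain under
controlled conditions — not retrieval accuracy on any specific satellite
product.

## 7. Pipeline, formats, conventions

Time runs on 365-day (no-leap) years with 1-based DOY; cubes are NetCDF
(xarray, NetCDF3-classic backend) with an integer day index plus
`doy`/`cal_year` coordinates, per-row latitude, and int8 QA (1 = good);
grids are row-major, row 0 = north. Tables are CSV (missing = empty
field); the tidy metric table is (row, col, year, index, metric, value,
valid) with full-precision values — rounding is a display concern. Each
pipeline run writes a manifest (config hash, software version, seed,
per-stage timings, warnings, failure point) last, so a complete manifest
certifies a complete run; stage outputs are written atomically
(temp-file + rename). YAML configs are validated strictly: unknown keys
and a missing scene seed are errors before any computation. The library
is the interface — `examples/` holds runnable narrative scripts and the
reference config `scene_demo.yaml`; there is no shell entry point, as the
intended use is from Python.

Problem sizes in the shipped verification runs (`scripts/acceptance.py`,
`tests/test_acceptance.py`) are chosen to exercise the full chain at
statistical power appropriate for their tolerances on a single CPU:
a 20×20 single-year scene for date recovery, 10×10 and 20×20 24-year
scenes for trend recovery and false-positive calibration, 50-seed
envelope comparisons, and 10 000-replicate Mann–Kendall calibration.

## 8. Known limitations

- PPI's record-maximum M estimator makes peak-season PPI noise-sensitive
  (heavy-tailed upward spikes near saturation); the clamp bounds but does
  not remove this, and peak-adjacent dates (SD, DD0) inherit a few days of
  index-specific bias.
- The plateau-adjusted DD is defined purely geometrically; under weak
  greendown its sign relative to DD0 depends on the plateau tilt.
- Single season per year; no pre-whitening in MK; no field-significance
  control across pixels; GeoTIFF ingestion is not implemented (NetCDF and
  CSV only).
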