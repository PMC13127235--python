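# Reference pipeline configuration (all values shown are the defaults
# unless commented otherwise; units and rationale in docs/methods.md).
scene:
  ny: 8
  nx: 8
  years: [2000, 2001, 2002, 2003]
  seed: 7                    # required: every run states its seed
  jitter_sd: 2.0             # interannual sos/eos jitter, days
  sos_gradient: 6.0          # edge-to-edge spatial range, days
  eos_gradient: 6.0
  mx_gradient: 0.2           # edge-to-edge range of peak LAI
  lat_range: [38.0, 34.0]    # north row first, degrees
  base_truth:
    mn_lai: 0.2              # m2/m2
    mx_lai: 1.2
    sos: 130.0               # day of year
    rsp: 0.2                 # 1/day
    eos: 280.0
    rau: 0.2
    plateau_slope: 0.0       # LAI/day greendown (<= 0)
    sos_trend: 0.0           # days/year
    eos_trend: 0.0
  optics:
    M_true: 0.7              # closed-canopy DVI asymptote
    DVIs_true: 0.09          # bare-soil DVI
    c_lai2dvi: 0.6           # extinction coefficient, 1/LAI
    red_base: 0.12
    blue_base: 0.06
  contamination:
    noise_sd: 0.02           # per-band Gaussian sd
    cloud_prob: 0.2
    cloud_vi_bias: -0.15     # mean DVI depression on cloudy days
    cloud_qa_detect: 0.9     # fraction of cloudy days the QA catches
    snow_window: [335, 60]   # DOY range, wraps over new year
    snow_prob: 0.08
    snow_qa_miss_prob: 0.1
  sif_gpp:
    lue: 6.0                 # peak GPP scale, g C m-2 day-1
    autumn_lead_days: 20.0   # photosynthetic decline leads structural
    sif_scale: 0.02
    noise_sd: 0.05           # fraction of peak SIF
indices: [evi, kndvi, ppi]
vi_options:
  dc: 0.0                    # diffuse fraction (no published value; 0 =
                             # pure direct beam, see docs/methods.md)
  theta_mode: noon           # per-row latitude at local solar noon
  eps: 0.04                  # PPI saturation clamp, DVI units
fit_options:
  n_harmonics: 3             # rough-fit harmonics (convention, not a
                             # published figure)
  n_outer_iter: 3            # envelope iterations of the rough fit
  envelope_iters: 1          # Beck post-convergence reweight cycles
  min_amplitude: 0.05        # "no seasonality" floor, VI units
write_scene_nc: false
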