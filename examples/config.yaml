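# mobint pipeline configuration template.
# Every key is optional; omitted keys take the defaults shown here.
# Unknown keys are rejected.

# master seed: fans out to simulation, imputation and the down-sampling
# replicates (replicate i uses seed + i)
seed: 0

# seconds per frame (10 ms = 100 Hz stroboscopic imaging)
frame_interval_s: 0.01

# multiplicative factor applied to x/y on read; set to the pixel size in
# micrometres when the track table is in pixel units
coord_scale: 1.0

classify:
  # anomalous-exponent bands: alpha <= 0.7 Confined,
  # 0.7 < alpha < 1 Brownian, alpha >= 1 Directed
  alpha_confined_max: 0.7
  alpha_directed_min: 1.0
  # butterfly (mixed-behaviour) detection: 'relative' flags steps larger
  # than (1 + threshold) x the track mean jump; alternatives:
  # 'additive_sd' (mean + threshold * sd), 'absolute' (threshold in um)
  butterfly_rule: relative
  butterfly_threshold: 1.5
  # tracks (and butterfly segments) shorter than this are discarded
  min_duration: 5
  # Confined rows with mean frame-to-frame jump above this are removed
  confined_jump_max_um: 0.1
  # randomized down-sampling of the final table
  downsample_n: 20000
  downsample_reps: 3

features:
  # TA-MSD lags computed per track (capped at duration - 1)
  max_lag: 50
  # inclusive lag window of the log-log alpha fit
  alpha_lag_min: 1
  alpha_lag_max: 4

mobility:
  # H2B marginal percentiles defining the LoMC (<= lo_pct on both axes)
  # and HiMC (>= hi_pct on both axes) gates
  lo_pct: 75
  hi_pct: 95

interactome:
  # interactor call: fold > fold_min and BH-adjusted p < adj_p_max
  # against BOTH controls
  fold_min: 2.0
  adj_p_max: 0.05
  # left-shifted imputation: Normal(mean - downshift*sd, (width*sd)^2)
  # per sample column
  impute_width: 0.3
  impute_downshift: 1.8
  # differential label outside cohort mean +/- sd_cutoff * sd
  sd_cutoff: 3.0
  # Student (true) or Welch (false) two-sample t-test
  equal_var: true
  # cohort for the differential mean/sd: 'all' or 'significant'
  differential_cohort: all
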