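# Published base-case inputs for the ALK test-and-treat cost-effectiveness
# model (advanced NSCLC in China; costs in 2016 US dollars).
#
# Every scalar parameter is {base, low, high, distribution}:
#   * base       — deterministic base-case value
#   * low/high   — one-way sensitivity range
#   * distribution — PSA family: triangular (mode at base), beta
#                    (method-of-moments, mean at base, sd = range/4),
#                    or fixed (never sampled)
# Omitting any entry (or the whole file) falls back to these same built-in
# defaults, so this file doubles as the documented schema.

clinical:
  # Weibull PFS curves, S(t) = exp(-scale * t^shape).  The two published
  # (scale, shape) pairs are mutually inconsistent under a shared time unit,
  # so each curve carries its own calibrated unit (see docs/calibration.md):
  # months for crizotinib (median 9.8 months), weeks for chemotherapy.
  pfs_crizotinib: {scale: 0.0211, shape: 1.5326, time_unit: month, fit_r2: 0.972}
  pfs_chemo: {scale: 0.0663, shape: 0.8604, time_unit: week, fit_r2: 0.991}
  # overall-survival hazard ratio, chemotherapy vs supportive care; used to
  # derive the supportive-care PFS curve followed by false positives
  hr_chemo_vs_supportive: {base: 0.77, low: 0.71, high: 0.83, distribution: triangular}
  # per-cycle death probability in the progressed state, from the 5.4-month
  # median post-progression overall survival
  p_death_progressed_per_cycle: {base: 0.086, low: 0.08, high: 0.093, distribution: beta}
  alk_prevalence: {base: 0.065, low: 0.014, high: 0.116, distribution: beta}
  body_surface_area: {base: 1.72, low: 1.5, high: 1.9, distribution: triangular}  # m^2
  # proportion of progressed patients receiving salvage chemotherapy
  salvage_uptake: {base: 0.566, low: 0.26, high: 0.72, distribution: beta}
  post_progression_median_os: {base: 5.4, distribution: fixed}  # months

tests:
  # sensitivity/specificity base 1 admits no proper beta; PSA samples
  # uniform on the printed range instead (logged)
  ngs_sensitivity: {base: 1.0, low: 0.95, high: 1.0, distribution: beta}
  ngs_specificity: {base: 1.0, low: 0.95, high: 1.0, distribution: beta}
  pcr_sensitivity: {base: 1.0, low: 0.95, high: 1.0, distribution: beta}
  pcr_specificity: {base: 1.0, low: 0.95, high: 1.0, distribution: beta}
  ngs_test_cost: {base: 1014.49, low: 869.57, high: 1159.42, distribution: triangular}
  pcr_test_cost: {base: 660.75, low: 440.50, high: 881.01, distribution: triangular}

costs:
  pemetrexed_per_500mg: {base: 2083.97, low: 857.14, high: 2126.51, distribution: triangular}
  chemo_other_per_cycle: {base: 518.4, low: 388.8, high: 648.0, distribution: triangular}
  # fixed in PSA; the low end (half price) feeds the one-way analysis only
  crizotinib_per_day: {base: 238.1, low: 119.05, high: 238.1, distribution: fixed}
  followup_per_cycle: {base: 55.6, low: 41.7, high: 69.4, distribution: triangular}
  salvage_per_cycle: {base: 2352.7, low: 1921.1, high: 4383.3, distribution: triangular}
  palliative_terminal: {base: 2042.91, low: 793.65, high: 5456.19, distribution: triangular}
  supportive_per_cycle: {base: 337.5, low: 158.7, high: 793.7, distribution: triangular}
  sae_initial_chemo_per_cycle: {base: 507.4, low: 189.7, high: 825.0, distribution: triangular}

utilities:
  # +/-25% of the mean; the progression-free upper end is capped at 1
  u_pfs: {base: 0.804, low: 0.603, high: 1.0, distribution: beta}
  u_progressed: {base: 0.321, low: 0.24075, high: 0.40125, distribution: beta}
  # adverse-event disutility during initial chemotherapy cycles; the source
  # publishes no numeric values, so the default decrement is zero
  sae_disutility_per_chemo_cycle: {base: 0.0, low: 0.0, high: 0.0, distribution: fixed}

run:
  horizon_years: 10.0
  # calibrated conventions — see docs/calibration.md
  cycle_days: 30.0
  days_per_month: 30.0
  # fixed in PSA; the 0-8% one-way range is an assumption (none published)
  annual_discount: {base: 0.05, low: 0.0, high: 0.08, distribution: fixed}
  wtp_per_qaly: 32000.0
  chemo_max_cycles: 4
  salvage_max_cycles: 12
  half_cycle_correction: false
  pemetrexed_whole_vials: true
  # patient assistance program: payer funds the first paid_days of
  # crizotinib, free supply thereafter; paid_days calibrated
  pap: {enabled: true, paid_days: 19}
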