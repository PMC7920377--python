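# Model inputs for the EGFR mutation-guided TKI vs empirical chemotherapy
# cost-effectiveness model (Hong Kong public healthcare provider perspective).
#
# Conventions: all currency in USD (2020 unit costs), all times in months.
# Each uncertain input carries {base, low, high, distribution}; the
# distribution is the family used by the probabilistic sensitivity analysis
# (beta for probabilities/prevalences, triangular for odds ratios, utilities
# and costs, fixed for quantities not varied). Cost ranges are medians with
# IQR stored verbatim (low = Q1, base = median, high = Q3).

prevalence_egfr_pos: {base: 0.501, low: 0.427, high: 0.588, distribution: beta}

# Weibull parameters fitted to cisplatin-pemetrexed Kaplan-Meier curves;
# S(t) = exp(-scale * t^shape), t in months. Held fixed in sensitivity analyses.
weibull:
  chemo_pfs: {scale: 0.0572, shape: 1.2883}
  chemo_os: {scale: 0.0057, shape: 1.4499}

# Odds ratios versus first-line chemotherapy (network meta-analysis, 95% CI
# as triangular bounds). OR > 1 favours the TKI: the odds of remaining
# event-free each month are multiplied by the OR.
treatments:
  afatinib:
    or_pfs: {base: 8.31, low: 3.19, high: 23.21, distribution: triangular}
    or_os: {base: 1.11, low: 0.62, high: 1.96, distribution: triangular}
    monthly_cost: {base: 1870, low: 1741, high: 2749, distribution: triangular}
    sae_incidence:
      nausea_vomiting: {base: 0.008, low: 0.0064, high: 0.0096, distribution: beta}
      diarrhea: {base: 0.054, low: 0.043, high: 0.065, distribution: beta}
      rash: {base: 0.142, low: 0.114, high: 0.170, distribution: beta}
      anemia: {base: 0.004, low: 0.003, high: 0.005, distribution: beta}
      neutropenic_fever: {base: 0.004, low: 0.003, high: 0.005, distribution: beta}
  erlotinib:
    or_pfs: {base: 6.57, low: 2.74, high: 15.1, distribution: triangular}
    or_os: {base: 1.08, low: 0.67, high: 1.76, distribution: triangular}
    monthly_cost: {base: 447, low: 318, high: 1326, distribution: triangular}
    sae_incidence:
      nausea_vomiting: {base: 0.0, low: 0.0, high: 0.0001, distribution: beta}
      diarrhea: {base: 0.010, low: 0.008, high: 0.012, distribution: beta}
      rash: {base: 0.020, low: 0.016, high: 0.024, distribution: beta}
      anemia: {base: 0.0, low: 0.0, high: 0.0001, distribution: beta}
      neutropenic_fever: {base: 0.0, low: 0.0, high: 0.0001, distribution: beta}
  gefitinib:
    or_pfs: {base: 6.12, low: 2.87, high: 13.5, distribution: triangular}
    or_os: {base: 0.80, low: 0.50, high: 1.27, distribution: triangular}
    monthly_cost: {base: 1341, low: 1212, high: 2220, distribution: triangular}
    sae_incidence:
      nausea_vomiting: {base: 0.003, low: 0.002, high: 0.004, distribution: beta}
      diarrhea: {base: 0.038, low: 0.030, high: 0.046, distribution: beta}
      rash: {base: 0.031, low: 0.025, high: 0.037, distribution: beta}
      anemia: {base: 0.022, low: 0.018, high: 0.026, distribution: beta}
      neutropenic_fever: {base: 0.002, low: 0.001, high: 0.0024, distribution: beta}
  cisplatin_pemetrexed:
    monthly_cost: {base: 2374, low: 1159, high: 4410, distribution: triangular}
    sae_incidence:
      nausea_vomiting: {base: 0.036, low: 0.029, high: 0.043, distribution: beta}
      diarrhea: {base: 0.0, low: 0.0, high: 0.0001, distribution: beta}
      rash: {base: 0.0, low: 0.0, high: 0.0001, distribution: beta}
      anemia: {base: 0.063, low: 0.050, high: 0.076, distribution: beta}
      neutropenic_fever: {base: 0.180, low: 0.144, high: 0.216, distribution: beta}

utilities:
  pfs: {base: 0.80, low: 0.77, high: 0.84, distribution: triangular}
  pd: {base: 0.56, low: 0.47, high: 0.66, distribution: triangular}

# Disutility decrements (negative) applied per serious adverse event episode,
# assumed to last sae_duration_months. The nausea/vomiting range is stored as
# -(0.016-0.080) by analogy with the diarrhea row (the printed range contains
# an evident typographical error).
disutilities:
  nausea_vomiting: {base: -0.048, low: -0.080, high: -0.016, distribution: triangular}
  diarrhea: {base: -0.047, low: -0.077, high: -0.016, distribution: triangular}
  rash: {base: -0.032, low: -0.050, high: -0.010, distribution: triangular}
  anemia: {base: -0.070, low: -0.100, high: -0.040, distribution: triangular}
  neutropenic_fever: {base: -0.090, low: -0.120, high: -0.060, distribution: triangular}

costs:
  egfr_test: {base: 324, low: 284, high: 432, distribution: triangular}
  followup_month: {base: 152, low: 122, high: 183, distribution: triangular}
  palliative_month: {base: 493, low: 233, high: 1013, distribution: triangular}
  sae_episode:
    nausea_vomiting: {base: 160, low: 159, high: 177, distribution: triangular}
    diarrhea: {base: 153, low: 152, high: 153, distribution: triangular}
    rash: {base: 155, low: 154, high: 155, distribution: triangular}
    anemia: {base: 654, low: 653, high: 693, distribution: triangular}
    neutropenic_fever: {base: 4479, low: 2267, high: 4729, distribution: triangular}

# Compliance with TKI therapy among mutation-positive patients; varied in
# one-way sensitivity analysis only (held fixed in the PSA).
tki_compliance: {base: 1.0, low: 0.5, high: 1.0, distribution: fixed}

settings:
  discount_rate_annual: 0.03
  horizon_months: 120
  # "Up to six 21-day cycles" of cisplatin-pemetrexed = 126 days ~ 4.2 months,
  # prorated within the fifth monthly cycle.
  chemo_duration_months: 4.2
  # Assumed duration of one serious-adverse-event episode for disutility.
  sae_duration_months: 1.0
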