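# Baseline parameter set for first-line pembrolizumab (arm P) vs
# chemotherapy (arm C) in dMMR/MSI-H metastatic colorectal cancer,
# Chinese health-care system perspective, 2022 USD.
#
# Row schema: {base, low, high, dist, alpha/beta | shape/scale, mean, se}.
# `low`/`high` are the one-way (DSA) bounds; `dist` rows are sampled in
# the PSA (beta for probabilities/utilities, gamma for costs, fixed =
# never sampled).  Where both explicit distribution parameters and
# (mean, se) are given, the explicit parameters are used and any
# moment mismatch is logged.

model:
  cycle_days: 42
  discount_rate: {base: 0.05, low: 0.0, high: 0.08}
  wtp: 38142.56
  horizon_threshold: 0.01
  horizon_cap_years: 40
  bsa: {base: 1.80, low: 1.50, high: 1.90}
  weight_kg: 65

utilities:
  u_pfs: {base: 0.7825, low: 0.75, high: 0.84, dist: beta, alpha: 245.001, beta: 63.176, mean: 0.795, se: 0.023}
  u_pd: {base: 0.64, low: 0.576, high: 0.704, dist: beta, alpha: 137.658, beta: 77.432, mean: 0.640, se: 0.033}

# grade >= 3 adverse events; incidence per arm, management cost and
# disutility shared; the one-off burden applies in cycle 1 only
ae_incidence:
  P:
    diarrhoea: {base: 0.060, low: 0.048, high: 0.072, dist: beta, alpha: 90.218, beta: 1413.409, mean: 0.060, se: 0.006}
    anaemia: {base: 0.050, low: 0.040, high: 0.060, dist: beta, alpha: 91.188, beta: 1732.572, mean: 0.050, se: 0.005}
    hypokalaemia: {base: 0.010, low: 0.008, high: 0.012, dist: beta, alpha: 95.070, beta: 9411.890, mean: 0.010, se: 0.001}
    neutropenia: {base: 0.0, low: 0.0, high: 0.0, dist: fixed}
  C:
    diarrhoea: {base: 0.110, low: 0.088, high: 0.132, dist: beta, alpha: 85.366, beta: 690.685, mean: 0.110, se: 0.011}
    anaemia: {base: 0.100, low: 0.080, high: 0.120, dist: beta, alpha: 86.336, beta: 777.024, mean: 0.100, se: 0.010}
    hypokalaemia: {base: 0.060, low: 0.048, high: 0.072, dist: beta, alpha: 90.218, beta: 1413.409, mean: 0.060, se: 0.006}
    neutropenia: {base: 0.235, low: 0.188, high: 0.282, dist: beta, alpha: 73.236, beta: 238.405, mean: 0.235, se: 0.024}

ae_cost:  # USD per episode
  diarrhoea: {base: 392.44, low: 313.95, high: 470.93, dist: gamma, shape: 16.000, scale: 24.527, mean: 392.439, se: 98.110}
  anaemia: {base: 724.64, low: 579.71, high: 869.57, dist: gamma, shape: 16.000, scale: 45.290, mean: 724.638, se: 181.160}
  hypokalaemia: {base: 157.28, low: 125.82, high: 188.73, dist: gamma, shape: 16.000, scale: 9.830, mean: 157.275, se: 39.319}
  neutropenia: {base: 628.96, low: 503.17, high: 754.76, dist: gamma, shape: 16.000, scale: 39.310, mean: 628.965, se: 157.241}

ae_disutility:  # negative decrements; sampled as beta magnitudes, negated
  diarrhoea: {base: -0.090, low: -0.108, high: -0.072, dist: beta, alpha: 14.470, beta: 146.308, mean: 0.090, se: 0.023, negate: true}
  anaemia: {base: -0.085, low: -0.102, high: -0.068, dist: beta, alpha: 14.555, beta: 156.680, mean: 0.085, se: 0.021, negate: true}
  hypokalaemia: {base: -0.080, low: -0.096, high: -0.064, dist: beta, alpha: 14.640, beta: 168.360, mean: 0.080, se: 0.020, negate: true}
  neutropenia: {base: -0.0607, low: -0.073, high: -0.049, dist: beta, alpha: 14.968, beta: 231.623, mean: 0.061, se: 0.015, negate: true}

prices:  # USD per mg, 2022 local bid-winning prices
  pembrolizumab: {base: 179.18, dist: fixed}
  oxaliplatin: {base: 3.4, low: 2.72, high: 4.08, dist: gamma, shape: 16.000, scale: 0.213, mean: 3.400, se: 0.850}
  leucovorin: {base: 0.25, low: 0.20, high: 0.30, dist: gamma, shape: 16.000, scale: 0.016, mean: 0.250, se: 0.063}
  fluorouracil: {base: 0.29, low: 0.232, high: 0.348, dist: gamma, shape: 16.000, scale: 0.018, mean: 0.290, se: 0.073}
  bevacizumab: {base: 15.0, low: 11.88, high: 15.0, dist: gamma, shape: 16.000, scale: 0.840, mean: 13.440, se: 3.360}
  cetuximab: {base: 12.04, dist: fixed}
  irinotecan: {base: 17.73, low: 14.05, high: 24.90, dist: gamma, shape: 16.000, scale: 1.217, mean: 19.475, se: 4.869}
  nivolumab: {base: 96.2, dist: fixed}
  capecitabine: {base: 0.04, low: 0.01, high: 0.04, dist: gamma, shape: 16.000, scale: 0.002, mean: 0.025, se: 0.006}

costs:
  admin_cost: {base: 310.16, low: 248.13, high: 372.19, dist: gamma, shape: 16.000, scale: 19.385, mean: 310.160, se: 77.540}   # USD/attendance
  followup_cost: {base: 31.33, low: 25.06, high: 37.60, dist: gamma, shape: 16.000, scale: 1.958, mean: 31.330, se: 7.833}      # USD/cycle alive
  bsc_cost: {base: 0.0, dist: fixed}  # best supportive care assumed free

# first-line chemotherapy regimen shares in arm C
firstline_mix_C:
  mFOLFOX: 0.0769
  mFOLFOX_bev: 0.4476
  mFOLFOX_cet: 0.0350
  FOLFIRI: 0.1119
  FOLFIRI_bev: 0.2517
  FOLFIRI_cet: 0.0769

# post-progression (second-line) treatment-class shares per arm
subsequent_mix:
  P:
    pembrolizumab: {base: 0.100, low: 0.080, high: 0.120, dist: beta, alpha: 86.336, beta: 777.024, mean: 0.100, se: 0.010}
    other_ici: {base: 0.075, low: 0.060, high: 0.090, dist: beta, alpha: 88.762, beta: 1094.731, mean: 0.075, se: 0.008}
    chemotherapy: {base: 0.438, low: 0.350, high: 0.525, dist: beta, alpha: 53.585, beta: 68.895, mean: 0.438, se: 0.045}
    vegf: {base: 0.275, low: 0.220, high: 0.330, dist: beta, alpha: 69.354, beta: 182.842, mean: 0.275, se: 0.028}
    egfr: {base: 0.113, low: 0.090, high: 0.135, dist: beta, alpha: 85.123, beta: 671.526, mean: 0.113, se: 0.011}
  C:
    pembrolizumab: {base: 0.427, low: 0.342, high: 0.513, dist: beta, alpha: 54.557, beta: 73.068, mean: 0.427, se: 0.044}
    other_ici: {base: 0.282, low: 0.226, high: 0.339, dist: beta, alpha: 68.632, beta: 174.362, mean: 0.282, se: 0.029}
    chemotherapy: {base: 0.153, low: 0.122, high: 0.183, dist: beta, alpha: 81.225, beta: 450.797, mean: 0.153, se: 0.016}
    vegf: {base: 0.099, low: 0.079, high: 0.119, dist: beta, alpha: 86.410, beta: 784.338, mean: 0.099, se: 0.010}
    egfr: {base: 0.038, low: 0.031, high: 0.046, dist: beta, alpha: 92.336, beta: 2326.872, mean: 0.038, se: 0.004}

pap:  # patient assistance program price scheme for first-line pembrolizumab
  enabled: false
  annual_cost: 11200.0
  cap: 22400.0
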