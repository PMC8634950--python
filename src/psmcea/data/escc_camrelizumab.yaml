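# Base-case inputs: second-line camrelizumab vs blended docetaxel/irinotecan
# chemotherapy for advanced/metastatic oesophageal squamous cell carcinoma.
# Time unit: months. Money: USD (2020, 6.8974 CNY/USD), except that
# costs.non_drug_unit_scale rescales follow-up/BSC/SAE unit costs to the
# magnitudes the source analysis actually used -- see docs/methods.md.
description: >
  Replication configuration for the published second-line camrelizumab
  cost-effectiveness analysis (ESCORT-based partitioned survival model).
model:
  cycle_length_months: 1.0
  horizon_months: 120.0
  annual_discount_rate: 0.05
  body_surface_area_m2: 1.72
  days_per_month: 30.4375
  half_cycle_correction: true
  discount_timing: midpoint
  drug_population: pfd
  wtp_per_capita_gdp: 10503.52
  wtp_thresholds: [10503.52, 21007.04, 31510.56]
survival:
  loglogistic:
    camrelizumab:
      pfs: {shape: 2.0011, scale: 0.1471}
      os: {shape: 1.2879, scale: 0.04461}
    chemotherapy:
      pfs: {shape: 3.1368, scale: 0.08394}
      os: {shape: 2.1592, scale: 0.01946}
  weibull:
    camrelizumab:
      pfs: {shape: 1.1296, scale: 0.1965}
      # published scale is -0.04380, impossible under S = exp(-lam t^gam);
      # the loader takes |scale| and records a warning (override this key to
      # supply a corrected value)
      os: {shape: 1.3018, scale: -0.04380}
    chemotherapy:
      pfs: {shape: 1.9527, scale: 0.1282}
      os: {shape: 1.4487, scale: 0.04345}
arms:
  camrelizumab:
    regimens:
      camrelizumab:
        dose_per_admin: 200.0       # mg, flat
        dose_basis: flat
        admin_interval_days: 14
        price_per_mg: 2.16
        price_range: [1.08, 2.16]   # negotiated price varied 50% downward only
        course_cap: 6
        weight: 1.0
    sae_incidence:
      anemia: 0.03
  chemotherapy:
    regimens:
      docetaxel:
        dose_per_admin: 75.0        # mg/m^2
        dose_basis: bsa
        admin_interval_days: 21
        price_per_mg: 1.77
        price_range: [0.26, 14.95]
        course_cap: 3
        weight: 0.5
      irinotecan:
        dose_per_admin: 180.0       # mg/m^2
        dose_basis: bsa
        admin_interval_days: 14
        price_per_mg: 1.64
        price_range: [0.88, 4.65]
        course_cap: 4
        weight: 0.5
    sae_incidence:
      anemia: 0.05
      neutropenia: 0.15
      vomiting: 0.05
costs:
  currency: USD
  # Follow-up/BSC/SAE unit costs enter the model multiplied by this factor.
  # The published outcome table is reproducible only with these costs at
  # their yuan magnitudes (6.8974 CNY/USD); set to 1.0 for a strict all-USD
  # reanalysis.
  non_drug_unit_scale: 6.8974
  followup_per_cycle: {base: 7.47, range: [6.52, 8.47]}
  bsc_per_cycle: {base: 16.98, range: [4.68, 46.77]}
  sae:
    anemia: {base: 73.68, range: [55.27, 92.11]}
    # published bounds printed swapped (lower 200.66 > base); stored sorted
    neutropenia: {base: 67.56, range: [55.27, 200.66]}
    vomiting: {base: 98.33, range: [63.64, 140.46]}
utilities:
  pfd: {base: 0.741, range: [0.593, 0.889]}
  pd: {base: 0.581, range: [0.465, 0.697]}
  disutilities:
    anemia: {base: -0.074, range: [-0.110, -0.037]}
    neutropenia: {base: -0.090, range: [-0.120, -0.059]}
    vomiting: {base: -0.048, range: [-0.080, -0.016]}
sensitivity:
  discount_rate_range: [0.0, 0.08]
  bsa_range: [1.50, 1.90]
  psa_default_se_fraction: 0.25   # se when no range is published
  vary_survival: false            # no ranges are published for survival rows
  survival_log_se: 0.10           # used only when vary_survival is true
  n_iterations: 10000
  ceac_wtp_grid: [0.0, 1050.35, 2100.70, 3151.06, 4201.41, 5251.76, 6302.11,
                  7352.46, 8402.82, 9453.17, 10503.52, 12604.22, 15755.28,
                  21007.04, 31510.56]
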