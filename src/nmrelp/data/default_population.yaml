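# Default synthetic serum population.
#
# Nine lipoprotein subclasses (large->small VLDL, LDL, HDL) with log-normally
# distributed concentrations, a 15% hypertriglyceridemic stratum (TG >= 250
# mg/dL), and Lorentzian rendering of the lipid methyl/methylene region.
# All renderer constants (line positions, widths, amplitudes, composition
# coefficients) are artifact choices: no public spectral reference exists for
# this assay, so they were calibrated once against the published population
# analyte ranges (TC 64-476, TG 24-886, HDL-C 14-167, apoB 35-305 mg/dL;
# means 181/127/54/94).

seed: 42
noise_sd: 0.005        # Gaussian noise SD as a fraction of the median rendered line height
ppm_jitter_sd: 0.002   # per-line center jitter SD, ppm
stratum_fraction: 0.15 # probability a sample belongs to the high-TG stratum
tg_threshold: 250.0    # mg/dL boundary defining the stratum

render_grid:
  ppm_max: 1.66
  ppm_min: 0.44
  n_points: 4096       # ~2.3x the canonical 1600-point region resolution

# Baseline polynomial in ppm, low order first: b0 + b1*ppm + b2*ppm^2
baseline_coeffs: [4.0, -2.0, 0.6]

# Composition coefficients are mg/dL of cholesterol / triglyceride / apoB per
# concentration unit; amplitudes are signal height per mg/dL of (chol + tg)
# carried. Line centers are size-graded within the methyl (~0.80-0.87 ppm)
# and methylene (~1.21-1.30 ppm) envelopes; linewidth is Lorentzian HWHM.
subclasses:
  V1: {ch3_center: 0.870, ch2_center: 1.295, linewidth: 0.016, chol_coeff: 0.10, tg_coeff: 0.75, apob_coeff: 0.04, ch3_amp: 0.9, ch2_amp: 3.2}
  V2: {ch3_center: 0.862, ch2_center: 1.285, linewidth: 0.015, chol_coeff: 0.12, tg_coeff: 0.65, apob_coeff: 0.06, ch3_amp: 0.9, ch2_amp: 3.0}
  V3: {ch3_center: 0.854, ch2_center: 1.275, linewidth: 0.014, chol_coeff: 0.15, tg_coeff: 0.55, apob_coeff: 0.09, ch3_amp: 1.0, ch2_amp: 2.8}
  L1: {ch3_center: 0.846, ch2_center: 1.263, linewidth: 0.013, chol_coeff: 0.45, tg_coeff: 0.08, apob_coeff: 0.28, ch3_amp: 1.0, ch2_amp: 1.7}
  L2: {ch3_center: 0.838, ch2_center: 1.252, linewidth: 0.012, chol_coeff: 0.42, tg_coeff: 0.06, apob_coeff: 0.33, ch3_amp: 1.0, ch2_amp: 1.6}
  L3: {ch3_center: 0.830, ch2_center: 1.241, linewidth: 0.012, chol_coeff: 0.38, tg_coeff: 0.05, apob_coeff: 0.40, ch3_amp: 1.1, ch2_amp: 1.5}
  H1: {ch3_center: 0.820, ch2_center: 1.230, linewidth: 0.011, chol_coeff: 0.30, tg_coeff: 0.04, apob_coeff: 0.0, ch3_amp: 1.2, ch2_amp: 1.5}
  H2: {ch3_center: 0.810, ch2_center: 1.218, linewidth: 0.010, chol_coeff: 0.25, tg_coeff: 0.03, apob_coeff: 0.0, ch3_amp: 1.2, ch2_amp: 1.4}
  H3: {ch3_center: 0.800, ch2_center: 1.206, linewidth: 0.010, chol_coeff: 0.20, tg_coeff: 0.03, apob_coeff: 0.0, ch3_amp: 1.3, ch2_amp: 1.4}

population:
  # Natural-scale medians of subclass concentration (units); the log-mean of
  # each log-normal is ln(median).
  median:        {V1: 40.0, V2: 35.0, V3: 30.0, L1: 90.0, L2: 100.0, L3: 70.0, H1: 45.0, H2: 85.0, H3: 85.0}
  log_sd:        {V1: 0.42, V2: 0.42, V3: 0.42, L1: 0.30, L2: 0.30, L3: 0.30, H1: 0.25, H2: 0.25, H3: 0.25}
  # Median multipliers applied in the high-TG stratum (VLDL up, HDL down).
  hyper_median_factor: {V1: 4.2, V2: 3.8, V3: 3.4, L1: 1.0, L2: 1.0, L3: 1.0, H1: 0.75, H2: 0.75, H3: 0.75}
  # Correlation of log-concentrations, order V1 V2 V3 L1 L2 L3 H1 H2 H3.
  # Within-class 0.8/0.7/0.6; VLDL-LDL 0.15; VLDL-HDL -0.4 (the TG-HDL
  # inverse relation); LDL-HDL 0.
  correlation:
    - [ 1.00,  0.80,  0.80,  0.15,  0.15,  0.15, -0.40, -0.40, -0.40]
    - [ 0.80,  1.00,  0.80,  0.15,  0.15,  0.15, -0.40, -0.40, -0.40]
    - [ 0.80,  0.80,  1.00,  0.15,  0.15,  0.15, -0.40, -0.40, -0.40]
    - [ 0.15,  0.15,  0.15,  1.00,  0.70,  0.70,  0.00,  0.00,  0.00]
    - [ 0.15,  0.15,  0.15,  0.70,  1.00,  0.70,  0.00,  0.00,  0.00]
    - [ 0.15,  0.15,  0.15,  0.70,  0.70,  1.00,  0.00,  0.00,  0.00]
    - [-0.40, -0.40, -0.40,  0.00,  0.00,  0.00,  1.00,  0.60,  0.60]
    - [-0.40, -0.40, -0.40,  0.00,  0.00,  0.00,  0.60,  1.00,  0.60]
    - [-0.40, -0.40, -0.40,  0.00,  0.00,  0.00,  0.60,  0.60,  1.00]

# Sharp non-lipoprotein signals inside/near the analysis region. Amplitudes
# are log-normally randomized per sample (median `amplitude`, log-SD
# `amp_log_sd`); widths are Lorentzian HWHM in ppm.
nuisance:
  - {name: lactate, centers: [1.321, 1.339], amplitude: 30.0, amp_log_sd: 0.5, width: 0.004}
  - {name: alanine, centers: [1.471, 1.489], amplitude: 12.0, amp_log_sd: 0.5, width: 0.004}
  - {name: bcaa, centers: [0.900, 0.925, 0.950, 0.975, 1.005, 1.035], amplitude: 8.0, amp_log_sd: 0.4, width: 0.005}
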