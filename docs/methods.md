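# Methods

This note documents the models, defaults and numerical choices behind
`nmrelp`, and what the synthetic-data tests do and do not demonstrate.

## Spectral model and analysis region

The assay input is a uniformly sampled 1D ¹H trace. Internally every
spectrum is stored with a descending ppm axis (the NMR display convention);
ascending files are reversed on read so only one orientation ever exists in
memory. The analysis region is the lipid methyl/methylene window,
0.494–1.592 ppm at 1600 points; the canonical grid takes both endpoints as
inclusive with spacing (1.592 − 0.494)/1599 ppm, which is the unique uniform
grid consistent with that region and point count. Off-grid input is
resampled by linear interpolation, chosen over spline or Fourier resampling
because it is deterministic, local and exactly linear — the linearity of
region extraction is load-bearing for several oracle tests. No apodization,
phasing, baseline correction or intensity normalization is applied: the
extractor assumes upstream acquisition/processing is fixed, and the
calibration operates on raw region intensities.

## Synthetic population generator

The generator exists so that every downstream stage — calibration,
routing, censoring, validation statistics — can be tested end to end
without patient data. It models serum as nine lipoprotein subclasses
(V1–V3, L1–L3, H1–H3: large→small VLDL, LDL, HDL). Each subclass carries
fixed cholesterol/triglyceride/apoB composition coefficients (mg/dL per
concentration unit; apoB exactly zero for HDL subclasses), so the four
analyte truths are exact linear functionals of the 9-vector of
concentrations. This linearity is deliberate: it gives closed-form oracles
(truth conservation, parameter recovery with R = 1 on noiseless spectra,
full-rank PLS ≡ least squares).

Concentrations are drawn from a correlated log-normal: log-medians and
log-SDs per subclass with a 9×9 correlation matrix (within-class 0.6–0.8,
VLDL–HDL −0.4 to encode the inverse TG/HDL-C relation). The population is a
two-component mixture: with probability 0.15 a sample comes from a
hypertriglyceridemic stratum whose VLDL medians are raised ~3.4–4.2× and
HDL medians lowered to 0.75×. Each component is rejection-conditioned on
its own side of TG = 250 mg/dL, so the high-TG fraction is exactly
Binomial(n, 0.15) and the TG ≥ 250 subset that trains HDL-C model 2 always
has support. A mixture is a mathematical necessity, not a convenience: a
single log-normal with mean ≈127 mg/dL cannot place 15% of its mass above
250 mg/dL (the maximum over all variances is ≈12%) without blowing through
the upper population range. With the shipped defaults the n = 5000
population lands 1st–99th percentiles inside TC 64–476, TG 24–886, HDL-C
14–167, apoB 35–305 mg/dL with means within 15% of 181/127/54/94 — the
published population characteristics the generator is meant to emulate.

Spectra are rendered as sums of Lorentzian lines (methyl and methylene line
per subclass, centers size-graded across 0.80–0.87 and 1.21–1.30 ppm, HWHM
0.010–0.016 ppm), plus sharp nuisance multiplets (lactate doublet at 1.33
ppm, alanine doublet at 1.48 ppm, a branched-chain amino-acid cluster at
0.90–1.05 ppm) with per-sample log-normal amplitudes, a fixed low-order
baseline polynomial, per-line ppm jitter N(0, 0.002 ppm), and white
Gaussian noise with SD = 0.5% of the sample's median rendered line height.
Lorentzians were chosen over Gauss/Voigt because their area πah is closed
form, enabling exact area oracles. The render grid (0.44–1.66 ppm, 4096
points) covers the analysis region at ~2.3× its resolution. All renderer
constants are artifact choices shipped in
`src/nmrelp/data/default_population.yaml`; no public spectral reference
exists for this assay, so they were set once to reproduce the published
analyte distributions while keeping calibration non-trivial (jitter and
noise are the two knobs that prevent an exact linear inverse).

What the generator does *not* emulate: real lineshape dispersion
(field/temperature effects), baseline drift correlated with composition,
particle-size heterogeneity within a subclass, matrix differences between
serum and plasma, and chemical-reference measurement error (truths are
exact). Passing calibration tests on this population therefore demonstrates
the correctness and stability of the calibration machinery — not that a
clinical assay trained on real sera would achieve the same figures.

## PLS1 engine

Wold's PLS1 via NIPALS with mean centering only; spectral variables share
units, so no autoscaling (none is conventional for full-spectrum
calibration). For a single response NIPALS needs no iteration per
component: w ∝ Xᵀy, t = Xw, loading p = Xᵀt/tᵀt, q = yᵀt/tᵀt, then X and y
deflation. The regression vector is b = W(PᵀW)⁻¹q. Components stop early if
the residual covariance underflows (relative tolerance 1e-12); requesting
more components than the data's rank logs a warning and keeps the extracted
ones.

RMSE_CV is implemented as √((1/n)Σ(e−p)²) — the standard quantity the name
"root mean square error" denotes (a published rendering that typesets the
root over 1/n alone is read as typographic).

LOOCV fits one nested NIPALS decomposition per fold and reads predictions
for every component count A ≤ A_max from it; nestedness makes this exactly
equal to refitting per A, and a property-based test enforces equality with
brute-force refitting to 1e-10 for n ≤ 25. A is chosen as the global
RMSE_CV argmin, ties toward fewer components; a minimum at the search bound
logs a warning that A_max may be too small. A_max defaults to 40
(configurable); desk-scale runs in the tests and acceptance script use
A_max = 15–20, which this synthetic population does not exhaust — the
RMSE_CV curve is already in its flat sub-mg/dL regime there, so the choice
trades a cosmetic bound warning for runtime.

DFFITS is computed in the fixed score space of the selected model:
leverage h = 1/n + tᵢ(TᵀT)⁻¹tᵢᵀ (TᵀT is diagonal by score orthogonality),
externally studentized deletion scale via the standard one-pass identity,
and DFFITS = (ŷᵢ − ŷ₍ᵢ₎,ᵢ)/(s₍ᵢ₎√h). The cutoff defaults to the
conventional size-adjusted 2√((A+1)/n). Removal is a single pass — flagged
samples are dropped once, then LOOCV selection is re-run on the reduced set
and the final model fit; there is no re-screening after the refit. When a
fit interpolates to numerical precision (SSE below (1e-8·scale)²·n) all
DFFITS are defined as zero: deletion influence there is pure roundoff.
Note the DFFITS scores treat the PLS score basis as fixed regressors;
the brute-force oracle in the tests deletes rows within that basis rather
than re-running the decomposition, which has no closed-form target.

Models serialize to versioned JSON with explicit arrays (x_mean, b, y_mean,
A, diagnostics) for diffability and cross-language portability; training
scores/weights are reconstructible artifacts and are not serialized.

## Assay engine

Routing to HDL-C model 2 uses ≥ 250 mg/dL on the *uncensored* PLS-predicted
TG (the predicted value is the routing signal even when outside the
reportable range). Predictions within ±2 mg/dL of the threshold trigger a
logged audit comparing both HDL-C models — diagnostic only. LDL-C uses the
NIH equation constants 0.948 / 0.971 / 8.56 / 2140 / 16100 / 9.44 on
unrounded inputs; TG > 800 mg/dL logs an extrapolation warning but is not
cut off. Display values round half-away-from-zero to one decimal, performed
on the shortest decimal representation so values that read as exact halves
round upward. Measured analytes are censored at TC 66–868, TG 35–950,
HDL-C 14–152, apoB 35–366 mg/dL (`<low` / `>high`); negative predictions
are below-range. LDL-C and non-HDL-C have no published ranges, so they are
reported uncensored but suppressed whenever an input analyte is censored —
suppression was chosen over inventing bounds.

## Validation statistics

CV% = 100·SD/mean with sample SD (n−1). Within-lab precision reports the
total SD over all results of a pool (e.g. 80 from a 20-day duplicate
design) rather than a variance-components decomposition, matching how such
tables are conventionally summarized. LOB = blank mean + 1.645·SD_blank and
LOD = LOB + 1.645·pooled low-level SD (one-sided 95% normal quantile); LOQ
is the lowest dilution level with replicate CV ≤ 20% and mean ≥ LOD — the
20% criterion is an explicit artifact choice where the source convention is
unstated. Deming regression is non-weighted with error-variance ratio fixed
at 1 (closed form; symmetric, so reverse fitting gives the reciprocal
slope). Interference flags a strictly >10% change in means; stability
accepts differences within ±10% inclusive — the asymmetry follows the
respective verb phrasing of the acceptance rules being modeled. Tube
comparison is OLS of test on reference with 95% CIs, flagged for slope
deviating from 1 by >0.10 or mean proportional difference >10%.

## Problem sizes and determinism

The acceptance script and the calibration-recovery test use 1000 samples
(800 train / 200 held out) with A_max = 20 — sizes at which the full
pipeline (two LOOCV passes plus screening) completes in about two minutes
on one CPU while leaving the conclusion unchanged from larger runs.
Property tests run at n ≤ 25 where brute-force refitting is exact and
cheap. All randomness flows through numpy `SeedSequence` spawning: a
population is bitwise reproducible from its config seed, and each sample
carries its own render seed so spectra can be rendered lazily, cached, and
re-rendered identically.

## Known limitations

* The calibration figures reported by the tests quantify recovery on
  synthetic spectra with exact reference values; they are upper bounds on
  what chemically referenced real spectra would give.
* DFFITS screening at the default cutoff removes a few percent of clean
  training samples at large n (the conventional 2√((A+1)/n) shrinks with
  n); this is the standard behavior of the cutoff, and removal is capped in
  effect by the single-pass design.
* JCAMP-DX support covers uncompressed AFFN `(X++(Y..Y))` tables only.
* The score-space DFFITS ignores the dependence of the PLS basis on the
  deleted sample, as is usual when applying linear-model influence
  diagnostics to latent-variable regressions.
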