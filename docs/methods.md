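# Methods

## The problem

Early-phase trials of tumor-targeted fluorescent tracers (here modelled
on an anti-VEGF-A antibody conjugated to an 800 nm dye, given in
escalating doses before breast-conserving surgery) need a standard way
to decide whether the tracer actually accumulates in tumor, which dose
is worth expanding, and whether intraoperative cavity fluorescence
predicts a tumor-involved margin. `tracereval` implements that
evaluation pipeline as reusable, tested code, and pairs it with a
synthetic specimen/cohort generator so every stage can be exercised
end-to-end without clinical data.

## Quantification model

**MFI.** The mean fluorescence intensity of a region is total detector
counts divided by the region's pixel area. It is computed from the
exact integer pixel sum at double precision and matches a two-loop
sum/count oracle bit for bit.

**Macro-segmentation and TBR.** Per fresh tissue slice, tumor and
background ROIs are measured; the patient-level MFI per tissue type is
the *unweighted mean of per-slice MFIs* over slices containing that
type, and TBR = MFI_tumor / MFI_background. Background at the macro
level is all surrounding healthy tissue — parenchyma+collagen plus fat;
carcinoma in situ enters neither the numerator nor the denominator.
Averaging per-slice MFIs (rather than pooling pixels) follows the
"measured per ROI and averaged per tissue type per patient" reading;
the pooled-pixel alternative is available behind `pooled=True` because
the two differ whenever slice ROI areas differ.

**Micro-segmentation.** Per 10-µm section, each delineated tissue
component (tumor, carcinoma in situ, parenchyma+collagen, fat) is
measured; patient means are taken per component over the slides
containing it. "Normal tissue" is the pixel-area-weighted combination
of parenchyma+collagen and fat, and the tumor-to-parenchyma ratio
divides tumor MFI by parenchyma+collagen MFI (flagged when < 1 — a real
phenomenon: collagen-rich parenchyma can out-fluoresce tumor on
sections). The whole-section MFI satisfies an exact partition identity:
it equals the area-weighted combination of component MFIs, because both
sides reduce to the same integer pixel sum.

Saturated pixels (65535) are included in MFIs by default; the clinical
protocol handled saturation by lowering camera gain, not by masking.
Gain rescaling to 300-equivalents is never applied implicitly.

## Spectroscopy model

Multi-diameter single-fiber reflectance / single-fiber fluorescence
(MDSFR/SFF) probes recover the intrinsic fluorescence Q·µ_a,x^f
(mm⁻¹) — quantum yield times tracer absorption at excitation — by
correcting the raw fluorescence spectrum for tissue scattering and
absorption. The published instrument's inversion mathematics is
proprietary to its calibration chain, so this package uses a
self-consistent semi-empirical single-fiber model:

    R(λ)  = η · x/(c + x) · exp(−k·µ_a·d),   x = (µ_s′(λ)·d)^p
    C(λ)  = R(λ) · d                         (effective path length, mm)
    F(λ)  = Q·µ_a,x^f · C(λ) · S(λ),         ∫S dλ = 1 on 800–900 nm

with µ_s′(λ) = a·(λ/800 nm)^(−b) and constants η = 0.5, p = c = k = 1
(configurable). Per wavelength, the two fiber diameters pin down
(µ_s′, µ_a) by a bracketed monotone root find (the feasibility
boundary has a closed form, so bracketing never guesses); the power-law
pair (a, b) then follows from an exact log-log regression. The claim
made — and tested across a ∈ [0.5, 3], b ∈ [0.5, 2], µ_a ∈ [0, 0.1]
mm⁻¹ — is *self-consistency*: noise-free forward spectra invert to the
generating parameters to < 10⁻⁶ relative error and the recovered
Q·µ_a,x^f is exact and linear in the raw spectrum. No numerical
fidelity to the published instrument model is claimed, and the trial
printed no spectroscopy values to anchor to.

Aggregation mirrors the clinical protocol: three spots per tissue,
three replicate measurements per spot; replicate means within spot,
then spot means per tissue; fit-failed replicates are excluded and
counted, and a tissue with no valid replicate is reported missing (the
trial lost one patient to a device malfunction this way).

## Dose-escalation engine

Group comparisons are nonparametric throughout, because none of the
trial's endpoints passed normality testing: Kruskal–Wallis
(tie-corrected H, asymptotic χ² p) across dose groups with Dunn's
post-hoc z-tests, Mann–Whitney U within groups, Spearman for
clinicopathological correlations, all two-sided with α = 0.05. Two
choices the trial's report leaves open:

- **Dunn's multiplicity scheme** defaults to Bonferroni over all pairs
  (the most conservative common reading of "Dunn's multiple comparison
  test").
- **Mann–Whitney** uses the exact enumeration distribution when both
  samples have n ≤ 8 (ties handled through midranks) and the
  tie-corrected normal approximation otherwise.

The χ² approximation for Kruskal–Wallis is coarse at tiny n: against
the full permutation distribution on n = 8 datasets its deviation is
typically below 0.05 (mid-p convention) but can reach ≈0.06–0.1 for
unlucky datasets. The tests document this by bounding the median
deviation at 0.05 with a 0.1 pointwise cap rather than claiming a
uniform 0.05.

**Expansion rule.** After the 4×3 step-up part (three patients per
dose), the best dose by median TBR and one de-escalating dose are
expanded to ten patients each; ties break toward the lower dose, and a
best-at-lowest-dose corner is flagged and paired with the next dose up.

**Plateau rule.** Scanning ascending consecutive doses, the first dose
whose step to the next gains less than `rel_threshold` (default 0.10)
in relative TBR is the optimal dose. The trial never quantified
"plateau"; 10% is this package's operationalization, exposed as a
parameter, and the rule is provably monotone: raising the threshold
never selects a higher dose.

**Sample-size arithmetic.** `required_sample_size(rate, needed)` is
ceil(needed/rate): 15 required tumor-involved margins at a 20% rate
give 75 patients. Note the formula gives 50 at a 30% rate, whereas the
trial's discussion prints "45–75" for the 20–30% range; the arithmetic
behind the printed 45 is unstated, so the formula is implemented as
defined and the discrepancy recorded here.

## Margin diagnostics

The intraoperative cavity call is qualitative in the clinic ("clear
signal, easily delineated from background"). The operational rule here:
a signal is *present* iff some 8-connected component of pixels at or
above k× the patient's background MFI spans at least A_min pixels
(defaults k = 2, A_min = 25); both knobs are exposed, and the call is
monotone in k. Cross-tabulating calls against histopathological margin
status (positive = ink on invasive cancer or carcinoma in situ) gives
the 2×2 table; sensitivity (= intraoperative detection rate),
specificity and margin rates are carried as exact rationals plus
integer percents rounded half-up — the rounding is explicit because no
single convention reproduces every percentage a clinical report prints.

The packaged `table2.csv` encodes the 26 margin calls of the reference
trial (7 true positives, 2 false positives, 1 false negative, 16 true
negatives), giving 7/8 = 88% sensitivity and 16/18 = 89% specificity.

**CalibrationDisk QC.** The camera phantom holds 8 tubes: one blank
plus seven two-fold tracer dilutions (1:6400 → 1:100) in 2% intralipid.
QC passes iff the readings increase strictly from the blank upward and
the top tube reads ≥ 5× the blank; the report carries the
log2-linearity R² of the seven dilutions (exactly 1 for an ideal
two-fold ladder) and the first offending index on failure.

## Synthetic cohort generator

The generator encodes the study conditions the analysis assumes; its
defaults are not tuning knobs.

- **Trial layout:** doses (4.5, 10, 25, 50) mg with group sizes
  (3, 10, 10, 3) — 26 patients.
- **Dose response:** tumor mean counts anchored at the printed group
  medians (5368, 6014, 14390, 18472 counts/pixel), interpolated
  piecewise-linearly in log-dose. Background anchors are not printed
  anywhere; they are derived from the printed TBRs (14390/3.07 at
  25 mg, 6014/1.79 at 10 mg) and held flat outside 10–25 mg, encoding
  the reported absence of a background dose trend. Per-component macro
  means: parenchyma+collagen 1.3× and fat 0.7× the background anchor
  (parenchyma share of background area drawn in [0.45, 0.55], keeping
  the pooled background within ~3% of its anchor), carcinoma in situ
  0.8× tumor. These component splits make the micro-level
  tumor-to-parenchyma ratio smaller than the macro TBR, as observed
  clinically.
- **Patient variability:** a log-normal uptake multiplier with median 1
  (so group medians stay anchored), CV 0.15 at 4.5/10 mg and 0.35 at
  25/50 mg — the trial reports larger between-patient variation at the
  two highest doses only qualitatively.
- **Geometry:** per slice, one connected elliptical tumor blob with
  low-frequency radial boundary noise, area fraction uniform in
  [0.05, 0.30], inside an elliptical tissue region over a smoothed-noise
  parenchyma/fat mosaic; tumor sizes are printed (0.5–3.2 cm) but
  shapes are not, so the blob model is this package's choice.
- **Noise:** Poisson shot noise on expected counts plus additive
  Gaussian read noise (σ = 25 counts), clipped to 16 bits — generic
  EMCCD/CMOS behaviour; the clinical report is silent on noise.
- **Margins:** margin-positive probability 0.30, cavity-signal
  conditionals P(signal|positive) = 7/8 and P(signal|negative) = 2/18,
  matching the reference contingency table; cavity images implant one
  ~100 px focus at 3× background for signal-positive patients.
- **Determinism:** every stream (patient draw, slice geometry, image
  noise, spectroscopy spot) is seeded by SHA-256 of (master seed,
  stream identity), so outputs are pure functions of (config, seed) and
  adding patients never perturbs existing ones.

What the generator does **not** emulate: 3-D specimen structure and
slice registration, camera optics (vignetting, PSF, light transport),
stain appearance, spatially correlated uptake heterogeneity within a
component, and any correlation between margin status and image content
beyond the implanted cavity focus. Passing tests therefore demonstrate
that the *analysis* recovers the structure the generator puts in — not
that real specimens satisfy that structure.

## Problem sizes and numerical choices

Default synthetic images are 192×192 px (0.1 mm pixels) with 3 slices
per patient; recovery tests use 10-patient single-dose cohorts and
cohort-statistics checks use 2500 simulated patients (record-level
only, no images). Counts are uint16 end to end; MFIs divide exact
integer sums. The spectroscopy root find uses Brent's method at
xtol 1e-14 inside an analytically derived bracket and flags (rather
than raises through) per-replicate failures so aggregation can count
them. Rasterization assigns a pixel to a polygon iff its center lies
inside under the even-odd rule, 0-based row/col coordinates, later ROIs
overwriting earlier ones; degenerate polygons warn and produce empty
regions.

## Known limitations

- The spectroscopy module guarantees self-consistency, not fidelity to
  the published MDSFR/SFF instrument inversion.
- Printed clinical P-values and per-patient MFIs are not reproducible
  without the patient-level data, which was never deposited; the
  pipeline reproduces the printed *derived* quantities (contingency
  metrics, TBR medians via the anchored generator, sample-size bounds).
- The cavity-call rule and the plateau threshold are explicit
  operationalizations of qualitative clinical definitions.
- FITS support covers exactly the dialect this pipeline writes (2-D
  primary HDU, unsigned 16-bit); it is not a general FITS library.
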