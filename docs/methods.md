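# Methods

## Problem and scope

Locally advanced breast cancer is commonly treated with neoadjuvant
chemotherapy (NAC) before surgery, but only a minority of tumors respond
completely; identifying likely nonresponders from the baseline MRI would
spare futile toxicity and surgical delay. This package re-implements, as a
tested pipeline over synthetic data, a volumetric first-order texture
analysis of baseline multiparametric breast MRI: semi-quantitative kinetic
and diffusion maps are computed voxelwise, pooled into histogram statistics
over the tumor volume of interest (VOI), and screened univariately for
discrimination of nonresponders with ROC analysis and permutation
inference. No patient images are distributed or downloaded: a synthetic
cohort generator with known ground truth stands in for the acquisition, and
the clinical study's printed summary table is used only as input to an
internal-consistency check.

Out of scope by design: pharmacokinetic (Tofts) modelling and k-trans,
arterial input functions, registration/motion correction, BI-RADS and
histopathology workflows, multi-lesion RECIST sums, second-order (GLCM)
texture, and any DICOM handling.

## Synthetic multiparametric MRI

Each patient is a digital phantom on a small voxel grid: an ellipsoidal
tumor (semi-axes 0.38 of the grid, ≥ 5% of the volume) in a uniform
background. The tumor is partitioned into concentric shells — hypervascular
rim (50%), fibrotic band (30%), necrotic core (20%) by default — assigned
by descending ellipsoidal radius with largest-remainder apportionment of
the voxel counts and a seeded tie-break. Every tumor voxel carries six
noiseless parameters:

| parameter | meaning | units | rim / band / core default mean |
|---|---|---|---|
| amplitude | peak relative enhancement | – | 2.0 / 0.9 / 0.4 |
| tme | time to maximal enhancement | s | 180 / 270 / 360 |
| washout_slope | post-peak enhancement decline | 1/s | 1.5e-3 / 5e-4 / 8e-4 |
| adc | apparent diffusion coefficient | mm²/s | 0.9e-3 / 1.2e-3 / 2.2e-3 |
| t2si | T2 signal intensity | a.u. | 300 / 250 / 600 |
| s0 | pre-contrast baseline signal | a.u. | 500 / 450 / 420 |

Voxel values are normal draws around the compartment mean (spreads of
roughly 10–40% of the mean), clipped to physical ranges. The enhancement
curve is piecewise linear — rise from 0 to `amplitude` at `tme`, then
decline at `washout_slope`, floored at zero — sampled at the acquisition
grid 0, 90, …, 450 s (one pre-contrast plus five post-contrast volumes,
90 s apart). The DCE signal is `s0 · (1 + E(t))`; DWI signals are
`s0 · exp(−b · adc)` at b = 0 and 900 s/mm², acquired as the average of
three magnitude samples (`dwi_averages=3`, mirroring diffusion gradients
applied along x, y and z); the T2 volume is `t2si`. Noise is Rician:
magnitude of the complex signal with i.i.d. Gaussian perturbations of
scale `noise_sigma` (default 0 for exact unit tests; 10 a.u. ≈ 2% of the
rim baseline for "realistic" cohort runs; 25 a.u. = 5% for the noisy
recovery experiment).

Two identifiability choices make the noiseless ground truth exactly
recoverable from the sampled curve, which the round-trip tests rely on:
`tme` draws are snapped to the post-contrast acquisition grid (a peak
between samples is not observable at 90 s resolution), and
`washout_slope` is capped so the curve is still nonnegative at the last
acquisition (beyond that cap the floor at zero hides the true slope; when
the peak falls on the last acquisition the slope is unobservable and truth
records 0). Amplitudes are floored at 0.05 so every tumor voxel has a
unique sampled peak.

Cohorts draw response labels CR/PR/NR with proportions (0.478, 0.377,
0.145) — largest-remainder apportionment reproduces the emulated study's
33/26/10 split at n = 69. NR is simulated as stable disease by default
(the emulated study reports no progressions). Baseline diameters are
lognormal (median 3.4 cm) clipped to 1.1–10.0 cm; post-NAC diameters are
drawn inside the RECIST band of the assigned label (CR: 0; PR: −90…−35%;
SD: −25…+15%; PD: +25…+60%), so labels always re-classify from the
diameters. Nonresponder kinetics are shifted at the compartment-mean
level, in units of the compartment spread: higher hypervascular amplitude
(raising the enhancement-AUC maximum), longer TME, lower necrotic washout
(the compartment that dominates the low washout percentiles). The default
`EffectSpec(1.5, 1.0, 1.0)` was chosen once as a plausibly strong effect;
the effect sizes are free parameters of the generator, not reported
clinical values. `EffectSpec.null()` gives label-independent kinetics for
calibration runs.

What the generator does **not** emulate: breast anatomy, coil/bias fields,
motion, fat suppression, partial-volume effects, spatial noise
correlation, VOI delineation error, or any real covariance structure
between kinetic parameters. Passing tests therefore demonstrate
correctness and calibration of the analysis code under the stated model,
not clinical performance on real data.

## Parameter maps

Relative enhancement is E(t) = (S(t) − S(0)) / S(0); voxels whose baseline
is at or below 1e-6 of the volume's 99th-percentile signal are invalid for
all kinetic maps. From E(t): `PEAK` = max over post-contrast samples;
`TME` = time of that maximum, first occurrence on ties; `AUC_ENH` =
trapezoidal integral over the full window (exact for the piecewise-linear
model, which a fine-Riemann-sum oracle test confirms); `WASHIN` =
PEAK/TME (mean uptake slope — a maximum instantaneous slope is not
distinguishable at this temporal resolution); `WASHOUT` =
(PEAK − E(t_last)) / (t_last − TME), defined 0 when the peak falls on the
last sample. Negative enhancement is allowed, so PEAK and WASHIN may be
negative for de-enhancing voxels. ADC is the two-point mono-exponential
`ln(S_b0 / S_b900) / b`; voxels with a non-positive signal are invalid and
negative ADCs (noise floor) are retained but counted in the log. The T2
map is a raw-intensity pass-through. All conventions are explicit function
parameters or config fields.

## First-order histogram features

Statistics are computed over the multiset of valid masked voxel values; no
spatial information enters. Per map: percentiles {5, 10, 20, 25, 30, 40,
50, 60, 70, 75, 80, 90, 95} (linear interpolation at zero-based rank
(n−1)p/100), max, min, range, SD (n−1), mean, median (= p50), mode,
skewness (Fisher–Pearson g1, biased moments), kurtosis (excess by default;
a flag switches to non-excess since vendor conventions vary), and the
valid-voxel count — 23 columns per map, 161 per patient. The mode of a
continuous map uses 64 equal-width bins over [min, max] (lowest bin on
ties); when the VOI holds at most 64 distinct values the exact multiset
mode is returned instead (binning would only smear exact repeats — this
also covers discrete maps such as TME, whose support is the acquisition
grid). Constant VOIs report sd = 0 and undefined (NaN) skewness/kurtosis
rather than 0.

## Response classification

RECIST 1.1 on the longest diameter of the single largest lesion: CR iff
the post-NAC diameter is 0 (tolerance 1e-9 cm), PR iff the change is
≤ −30%, PD iff ≥ +20%, SD otherwise; boundaries inclusive. Endpoints:
`CR_vs_rest` (complete responders positive) and `NR_vs_rest` (SD/PD
positive, the primary endpoint of the analysis stage).

## ROC, cutoff and permutation inference

The AUC is the Mann–Whitney probability P(score_pos > score_neg) +
½ P(tie), computed via midranks (identical to all-pairs counting). A raw
AUC below 0.5 is reflected and the direction (`less_is_positive`)
reported explicitly, since both higher-in-NR and lower-in-NR features are
meaningful. A second, independent route — trapezoidal area under the
empirical ROC curve, with operating points sorted by (FPR, TPR) so tie
segments connect correctly — is kept in the codebase and pinned to the
first route at 1e-12 by tests.

The optimal cutoff minimizes (1 − sens)² + (1 − spec)², the squared
distance to the top-left corner of the ROC plane. The rule is sometimes
(mis)stated as *maximizing* that quantity, which would select the worst
operating point; `literal_maximize=True` preserves that literal reading
for auditability, but the default follows the corner rule the name
implies. Ties break toward higher specificity, then the lower numeric
cutoff; the returned cutoff is the midpoint between the adjacent distinct
scores straddling the operating point, so strict-vs-non-strict comparison
is immaterial.

Permutation p-values use the two-sided statistic |AUC − 0.5| under uniform
label relabelings: exhaustive enumeration when C(n, n_pos) ≤ n_perm
(exact tail fraction), else n_perm Monte-Carlo draws with the add-one
estimator (1 + hits)/(n_perm + 1), which is never 0 and has minimum
1/(n_perm + 1). Equal statistics count as hits (≥ with a 1e-12 float
guard), making the test conservative under heavy ties. Significance is
flagged at p < 0.05 with no multiple-testing correction by default,
matching the emulated analysis; Benjamini–Hochberg q-values are an opt-in
extension. `reconstruct_confusion` inverts printed sensitivity/specificity
into an integer 2×2 table (round-half-up) for consistency checking of
published summary rows.

## Problem sizes and numerical choices

The test suite and acceptance script choose problem sizes that exercise
the full pipeline while staying small: unit phantoms 10–16 voxels per
axis (lesion ≈ 100–900 voxels), null calibration 200 zero-effect cohorts
of 40 patients on 10×10×8 grids with 499 permutations per feature, the
power experiment 60 patients on 12×12×10 grids with 2000 permutations,
and the demo analysis the same 60-patient cohort. Determinism is
end-to-end: one integer seed feeds a `SeedSequence` tree covering cohort
metadata, each phantom's noise and every feature's permutation stream, and
a repeated run reproduces the report CSV byte-for-byte.

## Known limitations

* With Rician noise at 5% of the baseline signal, the two-point ADC at
  b = 900 s/mm² has a per-voxel median absolute relative error of ≈ 6%
  even with three averaged acquisitions (error propagation of the log
  ratio gives a floor of ≈ 5.6% at the optimal b·ADC ≈ 1.1); two-point
  ADC mapping at this noise level is simply not a 5%-accurate estimator,
  and no smoothing is applied to pretend otherwise.
* Wash-in/washout are mean slopes; at 90 s temporal resolution
  instantaneous rates are unidentifiable, and the 10 s injection delay is
  ignored (a constant offset that cannot change any ranking-based
  statistic).
* The effect-size parameters of the cohort generator are free knobs: the
  pipeline demonstrates recoverability of a planted effect and calibration
  under the null, not the magnitude of any real clinical effect.
* Features within a patient are strongly correlated (161 statistics of 7
  maps of one lesion), so the expected count of false positives at
  p < 0.05 has larger variance than independent tests would suggest; the
  null-calibration experiment measures the aggregate rate directly.
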