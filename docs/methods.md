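# Methods

## Pipeline model

`ctcquant` treats a CTC sample as a set of imaging fields, each a
five-channel fluorescence stack: nuclear stain, CAXII, pan-CK, a pooled
exclusion channel (CD34/CD45/CD66b on one dye), and one biomarker
channel (PD-L1 or HLA-I). The analysis assumes cells are compact,
nucleated objects whose marker signal lives in a peri-nuclear
membrane/cytoplasm compartment, that background is smooth on scales
much larger than a cell, and that pixel noise is approximately
independent and Gaussian at the camera.

### Image stage

1. **Rolling-ball subtraction** — the background is the grey-scale
   morphological opening with a disk footprint; default radius 50 px,
   much larger than a cell (nucleus radius 8–12 px at 10×
   magnification). An exact disk is used up to radius 16 and a sequence
   decomposition beyond that; the shape approximation is far below
   noise. Output is clipped at zero.
2. **Segmentation** — binary threshold on the subtracted nuclear
   channel; Otsu by default, fixed-value and quantile methods in
   config. The channel is Gaussian-denoised (`smooth_sigma`, default
   2 px) before thresholding only — measurements always use the
   unsmoothed data. Without denoising, speckle at low SNR fragments
   masks and the solidity filter rejects real nuclei. Connected
   components are kept when they look like intact nuclei: area within
   [80, 2000] px and solidity ≥ 0.8 (an automatable proxy for manual
   "intact nucleus" review). Rejected objects go to a discard log.
3. **Measurement regions** — each nucleus dilated by `ring_width`
   (default 4 px) to capture membrane/cytoplasmic signal; pixels
   claimed by two cells go to the nearer centroid, so regions always
   partition the field.
4. **Quantification** — per cell and channel, the raw mean over the
   region and the background-subtracted mean (raw − average intensity
   of non-cell pixels, cells dilated by `exclusion_dilation` = 8 px
   before masking). Subtracted means are *not* clipped at zero: cutoff
   fitting needs the negative tail. Rolling-ball subtraction is applied
   before thresholding but, by default, not to the measured channels: a
   morphological background taken on a noisy image carries spatially
   correlated error of several intensity units that would dominate the
   shot-noise error of a region mean, while the per-field scalar
   background keeps per-cell errors at the `noise_sd/sqrt(area)` level
   and still cancels any additive offset exactly. The
   `measure_on_subtracted` flag restores per-pixel subtraction when
   within-field gradients matter more than per-cell noise.
5. **QC flags** — saturation (≥ 0.5% of region pixels at or above
   `saturation_level`, any channel), border-touching, size. Flagged
   cells are classified but never enumerated.

### Gating

Positivity cutoffs come from a 1-D analogue of flow-cytometry cluster
gating: the two-cluster partition of the sorted background-subtracted
intensities minimising within-cluster variance (computed exactly with
prefix sums; identical to the brute-force scan over all split points),
with the cutoff at the midpoint of the two cluster means. When the
best split does not separate two real populations — Ashman-style
separation `|m₂−m₁| / sqrt((s₁²+s₂²)/2)` below 3 (an unimodal normal
yields ≈ 2.7, a mixture 4 SD apart ≈ 4) — the method falls back to
negative-population mean + 3 SD, treating the whole sample as negative.
Cutoffs are fitted per sample by default (washing efficiency varies
between samples); a cohort-pooled scope is available and recorded in
the config snapshot. Per-sample fitting presumes each sample contains
both positive and negative cells on every gated channel, which holds
whenever white blood cells are present; a sample consisting of a single
phenotype sends the unaffected channels down the fallback path.

Classification is a pure function of three boolean gates (value ≥
cutoff): exclusion-positive ⇒ EXCLUDED with absolute precedence
(specificity first); otherwise CAXII/CK define CAXII_S, DP, CK_S or
TRIPLE_NEG. TRIPLE_NEG and EXCLUDED cells are never counted as CTCs.
Biomarker positivity (strictly above the cutoff) and mean expression
are reported per subpopulation — ALL_CTC, CAXII_S, DP, CK_S and pooled
CK_PLUS = CK_S ∪ DP — with empty subpopulations reported as missing,
not zero. The mean is reported independently of the cutoff. Whether
"average expression" should be a mean or median is a genuine choice;
the arithmetic mean is used.

### Cohort statistics

Densities are counts of countable cells divided by blood volume (mL);
pooled densities are computed from summed counts so that equal counts
stay exactly tied after the division. Group comparisons: Welch's t, or
Mann–Whitney U with the p-value obtained by full enumeration of all
C(n, n₁) group assignments (midranks, so ties are handled exactly) when
the combined n ≤ 12, and by the tie-corrected normal approximation
otherwise. The `alternative` follows the scipy convention (it refers to
the first group).

ROC curves take progressing as the positive class with higher density
meaning more positive. Candidate cutoffs are midpoints between
consecutive distinct scores plus ±∞ sentinels, so a reported cutoff
always falls between observed sample values — the form in which a
threshold would be applied prospectively. The AUC is the trapezoidal
area walked in cutoff order (tied scores produce diagonal segments) and
equals the midrank `U/(n₁n₂)` exactly; the p-value against AUC = 0.5
uses the normal approximation of the U test. The optimal operating
point maximises LR = sensitivity/(1−specificity) over cutoffs with
sensitivity > 0; points with specificity 1 have infinite LR and win
whenever present, flagged `lr_infinite` rather than silently dropped —
with small control groups this is the typical outcome. Ties break
toward higher sensitivity, then the lower cutoff.

Longitudinal reports flag each crossing of a supplied density cutoff
between consecutive timepoints; a value exactly at the cutoff counts as
below it, so at-cutoff → above is one upward crossing.

## Synthetic data: what it emulates and what it does not

The generator stands in for patient samples, for which no per-sample
data are public. Design choices, made once:

- **Cells** are uniform-intensity disks with Gaussian edge smoothing
  (σ = 1 px) — the simplest geometry that exercises segmentation and
  ring quantification. Nucleus radius uniform in 8–12 px; marker signal
  fills a concentric disk extending `cytoplasm_extent` = 10 px beyond
  the nucleus, so the measured ring sits well inside the full-signal
  zone and small segmentation-boundary errors do not bias means.
- **Intensity laws** are log-normal, parameterised by arithmetic mean
  and SD (fluorescence is non-negative and right-skewed): nuclear
  600 ± 60, positive markers 500 ± 150, exclusion signal on WBCs
  600 ± 180, all on a configurable background plane (level + linear
  gradient) with i.i.d. Gaussian noise, clipped at zero like a camera.
  For validation fields at low SNR the background level is set high
  enough (≈ 2 noise SD) that zero-clipping stays negligible, as a real
  camera offset does.
- **Biomarker** values follow a two-component normal mixture on the
  background-subtracted scale (negative 0 ± 30, positive 300 ± 60;
  separation is a named parameter). Default positive fractions per
  subtype follow the reported representative sample: CK S+ 0.84,
  DP 0.50, CAXII S+ 0.33.
- **Cohorts**: per-sample density log-normal with arithmetic group
  means 19.8 (progressing) and 2.3 (responding) CTCs/mL — the published
  group averages — and log-SD 1.2, implying a ~0.9–100 CTCs/mL central
  95% range for progressing samples, consistent with the published
  0.5–163 range; n = 11 vs 9, matching the printed sensitivity (6/11)
  and specificity (8/9) granularity. Counts are Poisson(density ×
  volume); volume defaults to 1 mL (not stated per sample). Subtype
  mixing defaults to CAXII_S 0.5 / DP 0.3 / CK_S 0.2 (CAXII-dominant,
  as in the longitudinal cases). No per-sample empirical distribution
  exists to calibrate against; only group means/ranges are anchored.
- **Ground truth** per cell records the phenotype, the law draws, and
  the noiseless rendered mean signal over the ideal measurement
  footprint (nucleus mask dilated exactly as the measurement stage
  dilates) — the quantity the pipeline estimates.

Not emulated: optics/PSF, cell doublets and debris (beyond an optional
saturated-artifact injector for QC tests), uneven illumination beyond a
linear gradient, autofluorescence structure, or staining batch effects.
Passing tests therefore demonstrate correctness of the analytics under
the stated noise model, not robustness to every real-world artifact.

## Validation problem sizes

The test suite and `scripts/acceptance.py` validate at sizes chosen to
give tight statistical bands while remaining desk-scale: 20 fields of
384×384 px with 12 cells each at SNR 5 for the image stage (recall and
precision ≥ 95%; ≥ 99% of per-cell channel means within 3 noise-SEs of
truth — with ~10³ independent measurements, demanding *every* value
inside a 3 SE band would fail by chance alone); 200 seeds for cutoff
recovery (components 4 SD apart, 500 draws per side) and for the
cohort simulation (one-sided Mann–Whitney power and median AUC); 1000
random instances for the AUC/U identity and the exhaustive-search
agreement of the LR-optimal cutoff; full permutation enumeration up to
combined n = 10.

## Numerical choices and edge cases

- Cutoff fitting requires ≥ 2 finite values; all-identical values take
  the fallback path with a warning. The fitted cutoff is exactly
  translation-equivariant.
- Exact Mann–Whitney enumeration compares U values with a 1e-9 slack so
  midrank ties are not split by float error; two-sided p is twice the
  smaller one-sided p, capped at 1.
- Background estimates fall back to a flagged "unreliable" result
  (rather than an error) when fewer than 1% of pixels remain after
  masking.
- Empty segmentations return an empty table, not an error; a missing
  channel role or cutoff raises with the role named.
- Scale equivariance (volumes ×c ⇒ densities ÷c with AUC, p-values and
  cutoff classifications unchanged) holds exactly when the division is
  exact in floating point; otherwise ties between equal counts can
  split at the 1e-16 level and move tie-corrected p-values slightly.

## Known limitations

- The published headline numbers (19.8 vs 2.3 CTCs/mL means; the
  4.8 CTCs/mL total-CTC cutoff with 55% sensitivity, 89% specificity,
  LR 4.9; the 2.6 CK+/mL cutoff; the therapy-stratified biomarker AUCs)
  derive from patient samples whose per-sample values were never
  published. They anchor the generator's scales and the worked
  examples but cannot be reproduced numerically, and nothing in the
  package hard-codes them as outputs.
- Per-sample cutoff fitting needs both populations present per channel;
  cohort-pooled fitting or explicit cutoffs are the escape hatches.
- The exclusion channel is pooled (one dye), so individual exclusion
  markers cannot be distinguished in the imaging path; the
  five-marker flow panel appears only in the composition analysis.
- PD-L1/HLA-I co-expression on the same cell is out of scope (one
  biomarker channel per stack), as are survival analysis, RECIST
  scoring and multi-site batch harmonisation.
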