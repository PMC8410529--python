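# ctcquant

Analytics for multiplexed circulating-tumor-cell (CTC) immunofluorescence
assays in clear cell renal cell carcinoma (ccRCC), from raw multichannel
fields to clinical-correlation statistics.

Classical CTC assays identify tumor cells by EpCAM capture and
cytokeratin (CK) staining, which are frequently downregulated in ccRCC.
Assays built around the renal markers carbonic anhydrase IX/XII recover
these missed cells but need careful analytics: a rigorous
white-blood-cell/endothelial exclusion gate, phenotype subtyping
(CAXII single-positive, CAXII/CK double-positive, CK single-positive),
per-cell biomarker quantification (PD-L1, HLA-I), per-mL enumeration,
and response-discrimination statistics. `ctcquant` implements that
pipeline as a tested Python library for assay developers and
translational researchers, together with a ground-truthed synthetic-data
generator so every stage can be validated without patient material.

## What it computes

**Image stage** (`ctcquant.imaging`). Rolling-ball (grey-opening)
background subtraction, binary thresholding of the nuclear channel,
connected-component segmentation with intact-nucleus filters (area,
solidity), ring-inclusive per-cell measurement regions, and per-channel
mean intensities with the average background fluorescence of non-cell
pixels subtracted. Manual artifact review is replaced by QC flags
(saturation, border-touching); flagged cells are kept in the table but
never enumerated.

**Gating** (`ctcquant.gating`). Positivity cutoffs per channel by the
principles of clustering used in flow cytometry: the 1-D two-cluster
partition minimising within-cluster variance, with the cutoff at the
midpoint of the cluster means

```
cutoff = (m_neg + m_pos) / 2,   (m_neg, m_pos) = argmin within-cluster SSE,
```

falling back to `mean + 3·SD` when the channel is unimodal. Cells are
then classified by the assay's rule set — exclusion-positive ⇒ EXCLUDED
(always, regardless of other channels); otherwise CAXII/CK positivity
defines CAXII S+, Double+, CK S+ or triple-negative (never counted as a
CTC) — and PD-L1/HLA-I is scored per subpopulation as %positive and
mean background-subtracted expression. A marker co-expression
(Euler-style) composition table covers the flow-cytometry panel
(CK, EpCAM, CAIX, CAXII).

**Cohort statistics** (`ctcquant.stats`). Per-mL densities by phenotype
(including pooled CK+ = CK S+ ∪ Double+), Welch t and Mann–Whitney U
tests (exact by full enumeration for combined n ≤ 12), ROC analysis
with progressing samples as the positive class, candidate cutoffs at
midpoints between observed densities, trapezoidal AUC (identical to the
Mann–Whitney `U/(n₁n₂)` statistic, ties included), and the operating
point maximising the positive likelihood ratio

```
LR = sensitivity / (1 − specificity),
```

with perfect-specificity points reported as LR = ∞ and flagged.
Longitudinal series are screened for cutoff crossings (a value exactly
at the cutoff counts as below it).

**Synthetic data** (`ctcquant.synthetic`). Renders multichannel fields
of disk-shaped cells with per-phenotype log-normal intensity laws,
linear background gradients and Gaussian noise; draws per-cell tables,
progressing/responding cohorts (log-normal density laws with arithmetic
means 19.8 and 2.3 CTCs/mL, n = 11 vs 9) and longitudinal series. Every
generator is deterministic given a seed and returns ground truth for
validation.

## Worked example

```python
from ctcquant import CohortSpec, generate_cohort, compare_groups, roc, optimal_cutoff
from ctcquant.stats import density_table

samples, cells = generate_cohort(CohortSpec(seed=22))
table = density_table(samples)
prog = table.loc[table.group == "progressing", "density_all_ctc"]
resp = table.loc[table.group == "responding", "density_all_ctc"]

test = compare_groups(prog, resp, alternative="greater")
res = roc(table["density_all_ctc"], table["group"])
opt = optimal_cutoff(res)
```

which prints (via the obvious f-strings):

```
progressing: n=11, mean 8.8 CTCs/mL (range 0.0-29.0)
responding:  n=9, mean 5.0 CTCs/mL (range 0.0-37.0)
one-sided Mann-Whitney: U=76, p=0.0230
ROC AUC 0.768 (p vs chance 0.0461)
LR-optimal cutoff 3.5 CTCs/mL: sensitivity 64%, specificity 89%, LR 5.73
```

The cohort generator drew 20 samples at the two clinical density
scales; despite one high-burden responder the progressing group ranks
higher (one-sided Mann–Whitney p = 0.023), the total-CTC density
discriminates response with AUC 0.77, and the likelihood-ratio-optimal
threshold lands at 3.5 CTCs/mL between observed sample values — an
operating point (64% sensitivity at 89% specificity) that would flag a
sample above the cutoff as roughly 5.7× more likely to come from a
progressing patient. With only nine negatives, many seeds instead
produce a perfect-specificity cutoff, which is reported with LR = ∞ and
an explicit flag.

A command-line interface mirrors the library:

```
ctcquant simulate field --seed 1 --out sim/
ctcquant quantify --stack sim/field.tiff --out quant/
ctcquant gate --cells quant/cells.csv --out gated/
ctcquant roc --samples samples.csv --score ALL_CTC --out roc/
ctcquant longitudinal --series series.csv --cutoff 2.6 --out events/
```

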