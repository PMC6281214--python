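# niptcall

Trisomy 13/18/21 screening from low-coverage cell-free DNA sequencing,
with machine-learning correction of the calls a single Z score cannot
make.

Non-invasive prenatal testing (NIPT) counts sequencing reads from
maternal plasma in fixed genomic bins. A trisomic fetal chromosome
raises that chromosome's read share by half the fetal fraction *ff* (only
the fetal portion of plasma DNA carries the third copy), so the classic
caller standardizes the chromosome's mean binned depth against a panel
of confirmed negatives,

```
Z = (mean_i − mean(ref_i)) / s.d.(ref_i)
```

and calls a trisomy when Z exceeds a cutoff (traditionally Z = 3). At
low fetal fraction the expected shift `ref_i · ff/2 / s.d.(ref_i)` is
only 2–4 standard deviations, leaving a **grey zone** (run Z in
[1.96, 4]) where positives and noisy negatives overlap and laboratories
fall back to retesting.

`niptcall` implements the full pipeline around a better decision rule:

* **Normalization** — per-sample mean scaling, winsorization within
  contiguous 15-bin windows, LOESS correction of the depth-vs-GC trend,
  mean scaling again, then summation of every 15 bins into merged
  windows.
* **Six Z statistics per chromosome** — the panel baseline (D1), the
  within-sample autosome-median baseline (D3) and a robust
  MAD-standard-error baseline (D5), each paired with a
  *predicted-positive* variant (D2/D4/D6) that subtracts the baseline
  uplifted by `1 + ff/2`. A true trisomy scores high on D1/D3/D5 and
  near zero on D2/D4/D6; a negative does the reverse — jointly the pair
  separates cases a single Z cannot.
* **QC and triage** — samples under 3,000,000 unique reads or 5% fetal
  fraction are QC-filtered; the rest are grouped N (Z < 1.96),
  P (Z > 4) or Unclassified (grey zone).
* **Per-chromosome SVM correction** — a ten-feature vector (the six Z
  statistics plus fetal fraction, read-length peak, maternal age,
  gestational week, the last four min-max scaled to [0, 3] with saved
  training ranges) feeds a class-weighted SVM (linear or RBF kernel,
  C and γ chosen by coarse-then-0.1-step grid search with stratified
  5-fold CV). Models train on groups N and P and predict the grey zone
  and the QC failures. Closed-form LDA/QDA baselines are included for
  comparison.
* **Cohort simulator** — synthetic cohorts on a scaled-down autosome
  grid with GC bias, negative-binomial overdispersion, per-chromosome
  variance and the exact `1 + ff/2` trisomy uplift, so every stage is
  testable without patient data; plus a bootstrap study of Z
  separability versus fetal fraction.

## Worked example

```python
from niptcall import SimConfig, SvmConfig, screen_cohort, simulate_cohort

cfg = SimConfig(n_ref=100, n_train_neg=150, n_train_pos_per_chrom=10,
                n_grey_pos_per_chrom=4, n_grey_neg=12, n_qcfail=4)
cohort = simulate_cohort(cfg, seed=7)
screen = screen_cohort(cohort, SvmConfig(seed=7))
print(f"internal: {100*screen.internal_accuracy:.1f}% of {screen.n_internal}")
print(f"grey-zone holdout: {100*screen.holdout_accuracy:.1f}% "
      f"of {screen.n_holdout}")
```

prints (seed 7)

```
internal: 100.0% of 480
grey-zone holdout: 100.0% of 72
```

Internal accuracy is measured on the triage-N/P rows the models trained
on (three chromosomes × the QC-pass training samples each model could
use); the held-out number is the clinically interesting one — all 72
sample×chromosome calls in the low-fetal-fraction holdout arm are
correct here, including trisomies whose run Z sat inside the grey zone.
More examples live in `examples/` (screening-burden arithmetic, Z-score
triage, the fetal-fraction bootstrap study, the on-disk formats), and a
thin CLI (`niptcall simulate|reference|normalize|zscores|triage|train|
predict|report|burden`) drives the same library from the shell.

## Supplementary per-sample data

`read_supplementary_table` ingests a published per-sample workbook (one
sheet per chromosome: six Z scores, upstream run Z, confirmed state,
grouping). Such workbooks are third-party clinical data and are not
bundled; place one at `data/supplementary/per_sample_table.xlsx` to run
the corresponding reproduction test.
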