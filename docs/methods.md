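# Methods

## The statistical model

Low-coverage whole-genome sequencing of maternal plasma yields, per
sample, read counts over a fixed grid of 20 kb autosomal bins
(coordinates 0-based half-open; only autosomes 1–22 are analysed, since
the internal reference is a median over autosomes and the screening
targets are chromosomes 13, 18 and 21). Plasma DNA is a mixture of
maternal and fetal fragments; the fetal share is the fetal fraction
*ff*. A fetus with three copies of chromosome *i* raises that
chromosome's expected share of reads by a factor **1 + ff/2**: the extra
copy exists only in the fetal compartment, so only half of *ff* worth of
extra material appears.

### Normalization

Raw bin counts are distorted by data volume, outlier bins and GC bias.
The pipeline removes these in a fixed order, each step motivated by the
bias it targets and deliberately run before the next:

1. **Mean scaling** — each sample is divided by its own mean over usable
   bins, removing the between-sample data-volume difference. (The run
   identifier is carried in the metadata; a run-stratified variant would
   slot in here, but per-sample scaling is the default because the
   quantity being removed is per-sample data volume.)
2. **Winsorization** — within each contiguous window of 15 bins on one
   chromosome, values outside the window's [0.05, 0.95] fractile band
   are moved to the band edge. Quantiles interpolate linearly between
   order statistics (numpy's default, type 7). The fractiles are not
   dictated by the underlying method description and are exposed as
   parameters. Note a mathematical subtlety: clamping to *interpolated*
   fractiles is not exactly idempotent — re-clamped data has a strictly
   tighter 0.95-quantile whenever clamping occurred — so the invariant
   tested is the clamp property (in-band values untouched, range never
   grows, no-op inputs are fixed points), not literal idempotence.
3. **LOESS GC correction** — per sample, a locally weighted regression
   of bin depth on bin GC (span 0.75 by default); the fitted deviation
   from the sample's overall mean is subtracted, so the correction is
   additive and mean-preserving to first order, and negative corrected
   depths are clipped at zero. A grid whose usable bins share one GC
   value makes the fit undefined; the correction then logs and passes
   through.
4. **Mean scaling again** — steps 2–3 perturb the effective data size.

Finally every 15 consecutive usable bins are summed into **merged
windows** (trailing remainders of fewer than 15 bins are dropped at the
merge, and left untouched by winsorization), and per chromosome the
mean, n−1 s.d., unscaled median absolute deviation (MAD) and window
count of the merged depths are recorded, along with the median over
autosomes of the chromosome means. Bins with zero depth across the
reference panel are flagged unusable before any normalization: they
carry no information and destabilize both the LOESS fit and the Z
denominators.

### The six Z statistics

With `mean_i` the sample's merged-depth mean on chromosome *i*,
`mean(ref_i)`/`s.d.(ref_i)` the mean and n−1 s.d. of that quantity over
a reference panel of confirmed negatives, `med` the sample's autosome
median, `MAD_i` its unscaled MAD and `w_i` its window count:

| | versus negative baseline | versus predicted positive |
|---|---|---|
| panel | D1 = (mean_i − mean(ref_i)) / s.d.(ref_i) | D2: ref uplifted by 1+ff/2 |
| internal | D3 = (mean_i − med) / s.d.(ref_i) | D4: med uplifted by 1+ff/2 |
| within-sample | D5 = (mean_i − mean(ref_i)) / (Sm·MAD_i/√w_i) | D6: ref uplifted by 1+ff/2 |

`Sm = 1.4826 = 1/Φ⁻¹(0.75)` rescales the MAD of normal data to a
standard deviation; dividing by √w_i turns it into a standard error of
the chromosome mean. The source typography for the D5/D6 denominator
does not show the operator between MAD and window count; √w is the
implemented default and a `sem_denominator="linear"` option preserves
the alternative reading. The fetal fraction is a fraction in [0, 1]
throughout (a 5% fetal fraction gives an uplift factor 1.025).

The *_vs_p* statistics are what make low-ff cases tractable: a true
trisomy at fetal fraction ff has E[D2] = 0 while a negative with the
same recorded ff has E[D2] = −(ref·ff/2)/s.d.(ref) — strongly negative —
so the (D1, D2) pair separates classes that overlap in D1 alone.

### QC, triage and features

Samples with fewer than 3,000,000 unique reads **or** fetal fraction
below 5% are QC-filtered (strict comparisons; equality passes). QC-pass
samples are triaged on the run Z (D1 by default; an upstream caller's
reported Z takes precedence when ingesting supplementary-style tables):
N below 1.96, P above 4, Unclassified in the closed grey zone
[1.96, 4] — the bounds belong to the grey zone because the confident
groups are defined by strict inequalities.

The classifier input is (D1..D6, ff, read-length peak, maternal age,
gestational week). The Z features are already standardized and pass
through unscaled; the four metadata features are min-max scaled to
[0, 3] with the training ranges saved and restored verbatim on test data
(a constant training feature maps to 0; out-of-range test values
extrapolate linearly and may leave [0, 3]; a missing test value is
imputed with the training median, with a warning — training refuses
missing values outright).

### Classification

Per target chromosome, a soft-margin SVM is trained on the triage-N/P
samples with labels P→+1, N→−1 (an option substitutes confirmed states,
the feedback loop a laboratory would run after diagnostic confirmation).
Class imbalance is handled with per-class penalties w_k = n/(2·n_k), so
the effective penalty for class k is C·w_k. Hyper-parameters maximize
stratified 5-fold CV accuracy over a coarse grid (log₂C ∈ [−5, 15],
log₂γ ∈ [−15, 3], step 1) followed by a 0.1-step refinement ±1 around
the best cell; accuracy ties break toward smaller C, then smaller γ,
which guards against needlessly hard margins. The final model refits on
all training data with Platt-style probability calibration; prediction
is the sign of the decision value with an exact 0 assigned to −1 and
flagged. The dual solution is exposed (support vectors, α_i·y_i, offset)
and its feasibility — Σα_i y_i = 0 and the weighted box constraints — is
asserted in tests. The quadratic-programming itself is delegated to
libsvm via scikit-learn; re-deriving an SMO solver is explicitly a
non-goal.

LDA and QDA baselines are implemented in closed form (class means,
empirical priors, pooled or per-class covariance with an automatic 1e−8
ridge when singular; the QDA discriminant uses the standard −½ log|Σ_k|
term) and cross-checked against scikit-learn's implementations in tests.
Further comparison models (trees, boosting) plug in through a hook that
accepts any fit/predict estimator and makes no correctness claims.

## The simulator

The generator is the package's study-conditions definition, not a
convenience fixture. Defaults:

* **Grid** — ~15,000 bins of 20 kb allocated to autosomes 1–22 in
  proportion to their physical lengths (so chromosome 21 gets ~250 bins
  and per-chromosome read totals match a real ~3.5M-read NIPT run);
  bin GC ~ Beta(39.5, 56.8) (mean 0.41, s.d. 0.05).
* **Depth** — a sample's binned read total ~ Normal(3.5M, 0.3M); the
  expected bin weight is a quadratic GC-bias curve
  (1 + 1.0·(gc−0.41) − 8·(gc−0.41)², clipped positive) times a
  per-sample, per-chromosome lognormal effect (σ = 0.008) times the
  1 + ff/2 uplift on an affected chromosome; counts are negative
  binomial with size 100 (Poisson is the size→∞ limit). The
  per-chromosome effect models the residual between-sample variation in
  chromosome representation that widens real reference panels beyond
  counting noise; together with the counting term it puts a 5%-ff
  trisomy's expected D1 near the bottom of the grey zone, which is the
  regime the grey-zone study design describes.
* **Arms** — 200 reference negatives; 500 negative and 3×30 trisomic
  training samples (trisomy ff ~ U(0.08, 0.15)); 60 held-out
  "grey-zone-like" samples at ff ~ U(0.05, 0.08), half trisomic; 10 QC
  failures (alternating low-reads and low-ff causes, three of them
  trisomic). Negative ff ~ Normal(0.11, 0.035) clipped to [0.05, 0.25].
* **Metadata** — maternal age ~ Normal(31.8, 4.5) (integer-rounded,
  clipped 18–46), gestational week ~ U{12..27}, read-length peak ~
  Normal(145, 10): realistic ranges, deliberately class-uninformative.

What the simulator does **not** emulate: run/batch effects and
flow-cell structure, mappability and blacklist regions, maternal copy
number variants, fetal mosaicism, GC-bias shapes that vary by sample,
and fetal-fraction estimation error (ff is an input to the method, and
the simulator records the true value). Passing tests therefore
demonstrate the pipeline's correctness and its behaviour under the
assumed statistical structure, not clinical performance.

The bootstrap separability study draws a reference panel plus a pool of
simulated samples per arm (negatives, trisomies fixed at ff = 5% and
10%), computes each pool sample's D1 and bootstraps the arm's Z
distribution by resampling those per-sample scores. An alternative —
resampling merged windows of a single base sample — was considered and
rejected: it reproduces only within-sample counting noise and
understates the between-sample variance that defines the panel s.d.,
compressing the bootstrap Z spread to ~0.5 instead of ~1.

## An intrinsic accuracy limit

D1 is standardized to unit variance by construction, so a trisomy at
fetal fraction ff sits u = (ref·ff/2)/s.d.(ref) standard deviations
above the negatives. A negative *at the same recorded ff* whose
chromosome fluctuates more than u/2 above baseline is likelier under the
positive model than the negative one (symmetrically for positives
fluctuating low): the Bayes error per such at-risk sample is Φ(−u/2) —
about 10% at u = 2.5 (ff = 5% under the default noise), still ~0.3% in
the Poisson-only limit. Any cohort whose negatives' fetal fractions
reach the 5% QC floor therefore contains a few unavoidable grey-zone
errors; the default 860-sample cohort yields about five, all carrying
the ambiguity signature |D2| < |D1| < u. This is why the end-to-end
recovery test that demands *zero* errors over three seeds fails by
design, while the headline accuracy lands at 99–100%. Perfect grey-zone
separation on a real cohort is a finite-sample outcome under a
favourable fetal-fraction distribution, not a property the statistics
can guarantee — consistent with the observation that QC filtering (the
5% ff floor) remains necessary no matter the classifier.

## Numerical and design choices

* Quantiles: linear interpolation everywhere (numpy default).
* Panel s.d. uses the n−1 estimator; a panel needs ≥2 samples and
  positive spread on every analysed chromosome, else it is rejected as
  degenerate.
* MAD is computed on the sample's own merged windows, unscaled; the
  1.4826 factor is applied only in the D5/D6 denominator.
* Screening-burden expectations round half away from zero
  (2970/250 = 11.88 → 12).
* Grid-search fold assignment is stratified by class and seeded; if the
  minority class has fewer members than the fold count, the fold count
  drops to the class size (minimum 2).
* Decision ties (f = 0) go to the negative class and are logged — the
  choice that sends the sample toward retest rather than invasive
  confirmation — and never silently.
* Model persistence is a format-versioned joblib archive carrying the
  support vectors, dual weights, offset, kernel parameters, scaler
  ranges, seed and training-group counts.
* Test problem sizes: the full default cohort (~860 samples × 15,000
  bins) anchors the headline checks; distributional null checks use a
  4,000-bin flat-GC grid with 1,000 test samples and a 400-sample
  panel, where panel-estimation error is shared out by pooling the
  three target chromosomes.

## Known limitations

* Fetal fraction is consumed, not estimated; garbage ff in, garbage
  D2/D4/D6 out.
* The triage-label training scheme inherits the one-Z-test's mistakes
  near the group boundaries (a trisomy with run Z < 1.96 trains as a
  negative), and because the P group only contains Z > 4 positives, the
  grey-zone region itself is unrepresented in training — the boundary
  there is RBF interpolation, systematically more conservative than the
  likelihood-ratio rule for positives at D1 just above u/2. The
  confirmed-state option exists for laboratories with diagnostic
  follow-up.
* Platt probabilities from small positive classes are crude (a
  handful of support vectors on the positive side); they order samples
  sensibly but should not be read as calibrated risks.
* The LOESS span and winsorization fractiles are defaults, not claims
  of fidelity to any particular laboratory pipeline.
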