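# Methods

This note documents the statistical procedures `somatoref` implements,
the modelling assumptions behind them, the defaults that matter, and the
choices made where the underlying publications are silent.

## Pooling published healthy summaries

Study summaries carry a group size, a mean (ms) and one of three
dispersion forms.  Standard errors become SDs as `SD = SE·√n`.
Confidence intervals become SDs as `SD = √n·(upper − lower)/(2·t*)`,
where `t*` is the two-sided critical value at the interval's level on
n−1 degrees of freedom — the small-sample refinement of the fixed 3.92
divisor, appropriate because one contributing study has n = 20.  Groups
are then pooled *by concatenation*: the pooled mean is the
sample-size-weighted mean, and the pooled SD is

    SD² = [ Σ(nᵢ−1)sᵢ² + Σnᵢ(mᵢ−M)² ] / (Σnᵢ − 1)

which equals, exactly, the (n−1)-denominator SD of the concatenated raw
samples (property-tested against that oracle).  The generalised form is
used rather than iterated pairwise combination because it is order-free;
the two are algebraically identical.  No inverse-variance or
random-effects weighting is applied — the target of inference is the
concatenated healthy sample, not a meta-analytic mean.

**Known discrepancy.** From the published per-study values, the pooled
means (34.0, 92.6, 61.5 ms for TOJ, TOJc, DUR) and the TOJc pooled SD
(40.4 ms) reproduce exactly to the printed precision.  The printed TOJ
and DUR pooled SDs (17.0 and 27.9 ms) do not: the combination formula
gives 19.40 and 28.37 ms, and no obvious alternative (SE-weighted,
n-weighted RMS, pairwise iteration) recovers the printed numbers.  The
package reports its own values alongside and feeds the *published*
mean/SD pairs to every downstream stage, so that reference
distributions, adjusted medians and comparison results remain
comparable with the published analysis.

The one CI-reporting study ships in the packaged table with its
already-transformed SDs (10.1, 19.1 ms) because the interval bounds and
level were not published; the CI transform itself is fully implemented
and oracle-tested.

## Gamma reference simulation

Healthy somatosensory scores are strictly positive and positively
skewed, so the healthy reference is modelled as a gamma distribution
parameterised by method of moments:

    shape = mean²/SD²,    rate = mean/SD²

(TOJ: shape 4.00, rate 0.1176 — mean 34, SD 17; TOJc: shape 5.25, rate
0.0567; DUR: shape 4.86, rate 0.0790.)  Reference samples are drawn with
numpy's Generator; sample size always matches the patient sample being
compared (79 at initial assessment, 45 at discharge).

Because medians and IQRs describe skewed distributions better than
moments, "adjusted" healthy summaries are obtained by simulating 100
samples of 45 observations per measure.  The **pooled median** is the
median of all 4 500 draws concatenated (the lower-variance reading; the
median of per-sample medians is available behind
`median_pooling="median_of_medians"`, and the two agree within
Monte-Carlo error).  The **average IQR** is the per-sample (Q1, Q3)
averaged over the 100 samples.  Quartiles use linear interpolation
between order statistics (numpy's default convention).  The Monte-Carlo
standard error of the pooled median is ≈ 1.2533·SD/√4500 (0.32, 0.75,
0.52 ms per measure), which is what the tolerance bands in the tests are
derived from; at that precision the simulated medians agree with both
the analytic gamma medians (31.21, 86.80, 57.34 ms) and the published
adjusted values (31.3, 87.4, 56.9 ms).

Seed handling: one master seed spawns named, statistically independent
substreams (`substream(seed, stage, measure, ...)`), so each measure and
stage is reproducible in isolation and reruns are bit-identical.

## Synthetic cohort generator

The generator emulates the *published statistical shape* of a 79-patient
SR-mTBI clinic cohort: trajectory groups of 22 (symptom resolution ≤ 14
days), 41 (> 14 days) and 16 (lost to referral/follow-up); a 45-patient
discharge subset split 15/30 across the two resolution groups; per-group
sex and sport frequencies; and per-group median [Q1; Q3] targets for
age, days to initial assessment, days to asymptomatic, PST, SSS, TOJ,
TOJc and DUR.

* **Continuous skewed variables** use gamma marginals fitted by quantile
  matching: two parameters are solved numerically (log-space root
  finding on scipy's gamma quantile function) so the analytic median and
  IQR *width* hit the targets to 10⁻⁸; the residual mismatch in Q1 and
  Q3 individually (a two-parameter family cannot match three quantiles)
  is reported on request and is ≈ 0.1 ms for the typical targets.
* **Days to asymptomatic** is rejection-sampled to respect the group
  definition (≤ 14 vs > 14 days).
* **SCAT-5 scores** are built structurally: PST (number of endorsed
  symptoms, 1–22) comes from a quantile-fitted gamma rounded to integer;
  SSS is the sum of PST per-symptom severities drawn uniform on
  {1..cap}, with the per-group cap = round(2·SSS_med/PST_med − 1)
  clipped to [1, 6] so the mean severity matches the group's target
  SSS/PST ratio (caps 2/3/4 for the three groups).  This guarantees
  PST ≤ SSS ≤ 6·PST and SSS = 0 ⇔ PST = 0 by construction, at the cost
  of matching SSS medians only approximately (within order-statistic
  noise at the group sizes).
* **Discharge somatosensory scores** share a gamma frailty with the
  initial scores.  If the initial score is X₁ ~ Gamma(k, rate), the
  shared component is recovered conditionally as A = X₁·Beta(ρk, (1−ρ)k)
  — the exact conditional law of a Gamma(ρk) summand given the total —
  and the discharge score is X₂ = A + Gamma((1−ρ)k, rate).  This
  preserves the marginal exactly and gives corr(X₁, X₂) = ρ.  The
  within-subject correlation is not published; ρ = 0.5 is a documented
  config knob.  The default discharge shift is zero, encoding the
  published finding of no within-subject change in the somatosensory
  scores between initial assessment and recovery; with that default the
  paired Wilcoxon test is non-significant in ≥ 90% of seeds per measure.
* **Discharge symptom scores** are drawn low (Poisson PST, severities
  mostly 1) and always satisfy the sex-specific recovery criterion
  SSS ≤ 5 (males) / ≤ 6 (females).
* **Effect switches**: `healthy_reference_scores=True` draws every ms
  score from the pooled healthy reference (the exchangeable null used
  for type-I calibration); a set such as `{"toj", "dur"}` switches only
  those measures, leaving TOJc patient-calibrated — the configuration
  under which the qualitative published pattern (TOJc flagged ~100% at
  both timepoints, highest AUC; TOJ/DUR quiet) is reproduced.

What passing tests on this generator do **not** show: the synthetic
cohort has gamma marginals and independent-by-construction covariates
within groups, no missing data beyond the lost group's absent discharge,
and no measurement floor/ceiling effects or repeat-administration
learning; agreement of downstream stages on synthetic data demonstrates
the *machinery*, not the clinical effect sizes, which require the real
cohort.

## Nonparametric comparisons

Mann-Whitney U uses exact enumeration when the combined sample is ≤ 20
and tie-free, otherwise the tie-corrected normal approximation with
continuity correction (scipy backend).  At the cutoff boundary the two
agree within 0.01.  Wilcoxon signed-rank drops zero differences before
ranking (the classic convention; an all-zero difference vector raises a
degenerate-input error rather than fabricating a p-value) and is exact
for ≤ 15 tie-free non-zero pairs; the corrected normal approximation at
that boundary is within ~0.011 of enumeration.  Kruskal-Wallis is
tie-corrected with a chi-square reference; an all-identical pooled
sample returns H = 0, p = 1.  Dunn's post hoc z statistics use pooled
midranks with the tie term Σ(t³−t)/(12(N−1)); p-values are unadjusted by
default (no adjustment was used in the motivating analysis), with
Bonferroni/Holm available by flag.

The repeated-comparison experiment draws a fresh reference sample per
repetition (size matched to the patient sample), runs the two-sided
Mann-Whitney test, and reports the percentage of p < α over 100
repetitions.  Note a single experiment conditions on the one observed
patient sample, so its flag percentage is *not* binomial around α under
the null; the procedure's unconditional type-I rate — estimated by
pooling many single-repetition experiments with fresh null patient
samples — is ~5% at α = 0.05.

## LOOCV logistic discrimination

One healthy reference sample of the patient-sample size is drawn once
and frozen per run (matching the single simulated comparison group of
the motivating analysis).  Each of the 2n cases is held out in turn; the
univariable logistic model is refit by Newton-Raphson (log-likelihood
change < 10⁻¹²) on the remaining 2n−1 and the held-out case classified
at probability threshold 0.5 (the threshold is a documented choice).
Complete separation in a fold — detectable exactly for a univariable
model as a class-dividing threshold — is handled by refitting with a
ridge penalty of 10⁻⁴ on the slope, with a logged warning, so every fold
emits a prediction.  AUC is the tied-rank (trapezoidal) AUC of the
held-out probabilities and satisfies AUC = U/(n₁n₀) against the
Mann-Whitney statistic to machine precision.

A caveat worth knowing: held-out LOOCV probabilities are *pessimistically
biased* under the null.  Removing a case tilts the training class
balance against its class by one, so when the slope is near zero the
intercept alone anti-ranks the held-out cases and the null AUC falls
below 0.5 (≈ 0.40 on average in our calibration runs, occasionally 0).
The estimator never fabricates discrimination — which is the property
the tests assert — but its null expectation is not 0.5.

## Classification trees

Growth: greedy binary splits by Gini impurity decrease; candidate
thresholds are midpoints between sorted distinct values; a node splits
only with ≥ `min_split` cases (default 20), children ≥ `min_leaf`
(default 7), and strictly positive impurity decrease.  Defaults follow
the recursive-partitioning tradition's conventions and are configurable.

Pruning: weakest-link cost-complexity pruning with the penalty expressed
as a complexity parameter **cp relative to the root cost**: the internal
node with the smallest impurity improvement per split is collapsed while
that value is ≤ cp × root Gini.  cp = 0 leaves the tree unchanged,
cp ≥ 1 collapses to the root, and the pruned trees are nested, so split
counts are monotone non-increasing in cp.

Model selection: ten cp values, log-spaced from 0.001 to the root's
relative cost (1.0) by default, each evaluated by leave-one-out
accuracy; the winning cp maximises accuracy with ties broken toward the
tree with fewest partitions on the full-data refit (then toward larger
cp).  The final tree is refit on all data at the selected cp.  Reported:
per-class one-vs-rest sensitivity, specificity and balanced accuracy
((sens+spec)/2), and overall accuracy with an exact Clopper-Pearson 95%
binomial interval (47/79 correct gives 47.8–70.4%, i.e. the printed-style
48–70%).  A fold whose training set loses an entire class predicts the
training majority with a logged warning.

Two feature sets are evaluated: the somatosensory block
{TOJ, TOJc, DUR, TOJc−TOJ} and that block plus {PST, SSS}.  The
TOJc−TOJ difference is computed row-wise per participant.

One published inconsistency is deliberately not forced: a balanced
accuracy of 45% was printed for the lost-to-follow-up class alongside
sensitivity 0 and specificity 1, which the identity makes 50%; the
implementation always reports the identity-consistent value.

## Problem sizes and runtime

Defaults mirror the study conditions: 100 repetitions × 45 draws for the
adjusted summaries, 79/45-patient cohorts, 100-repetition comparison
experiments, 10-value cp grids.  Calibration tests use 100 seeds
(cohort-level) or 1000 pooled null experiments (type-I rate).  The full
pipeline runs in a few seconds on one CPU; the complete test suite in
well under a minute.
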