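# Methods

## The analysis model

`readerbench` treats a multi-reader multi-case study as a paired comparison
of two "classifiers" on one labelled case set: the consensus of a group of
human readers and the consensus of an ensemble of AI models. The case label
is binary (1 = with target pathology). All analysis is case-level; reader
identity enters only through the consensus construction, and no
reader-level variance components are modelled (no Obuchowski–Rockette or
Dorfman–Berbaum–Metz decomposition). P-values therefore describe the
case-sampling variability of the consensus scores, not between-reader
variability.

### Reader consensus

Ratings are on a 5-point ordinal scale mapped to probabilities by
p = (s − 1)/4, so 1 → 0.0, 3 ("undefined") → 0.5, 5 → 1.0. Per case:

1. **Undefined majority.** If strictly more than 50 % of the ratings equal
   3, the case is excluded. Exactly 50 % is not a majority and the case
   survives.
2. **Minimum responses.** If the case has fewer than `min_responses`
   (default 5) ratings it is excluded — except in the
   breast-imaging-specialist subgroup analysis, where the filter is off.
   Rule 1 is evaluated first; the order matters only for the reported
   exclusion reason.
3. **Upper median.** The consensus score is the ⌈(n+1)/2⌉-th order
   statistic of the ratings. For odd n this is the ordinary median; for
   even n the ambiguity resolves to the *higher* of the two central scores.
   "Median with ties resolved upward" is one of two defensible readings of
   a median-with-tie-breaking rule; the alternative — the most frequent
   score, ties to the higher score — is available as
   `consensus_rule="mode_high"` for sensitivity analysis, and the default
   is the upper median because it keeps the aggregate a proper median.

### AI consensus

Each model's scores are calibrated with the label-free midrank transform
(rank − ½)/m over the model's own m scores, ties sharing their mean rank.
This is a pure monotone rescaling: every model's ROC curve, and hence AUC,
is unchanged, while all models land on a common uniform-(0, 1) scale so that
averaging is meaningful. Supervised recalibration (Platt, isotonic) is
deliberately out of scope: it would use the ground-truth labels that the
evaluation is about. The per-case AI consensus is the arithmetic mean of
the calibrated scores of the models that scored the case; no exclusion
rules apply on the AI side.

### ROC inference

* **AUROC** is the empirical Mann–Whitney estimator with ties
  half-weighted. Inference always uses this estimator; the smoothed curve
  is display-only.
* **DeLong interval.** With placement values V10ᵢ (fraction of negatives
  below positive i, ties half) and V01ⱼ, the variance is
  var(V10)/m + var(V01)/n using the plug-in (ddof = 0) variance of the
  placements, and the CI is Â ± z·√var truncated to [0, 1]. Under perfect
  separation the variance is 0 and a degenerate [Â, Â] interval is returned
  with a warning. The plug-in variance differs from the (m−1)-denominator
  form by O(1/m); the coverage study in the acceptance suite (1000
  replicates at AUC 0.85, 100+100) lands at the nominal 95 % either way.
* **Smoothing.** Binormal probit smoothing: least-squares fit of
  Φ⁻¹(TPR) = a + b·Φ⁻¹(FPR) through the interior empirical ROC points,
  giving the smooth curve and closed-form area Φ(a/√(1+b²)). With fewer
  than two interior points (e.g. perfect separation) the empirical curve is
  returned with a warning. The exact smoother used for the published
  figures is not identifiable from a methods section that says only that
  smoothing was applied; the binormal fit is this package's documented
  stand-in, and it never feeds inference.
* **Operating point.** Thresholds range over the distinct observed scores
  with predicted-positive defined as score ≥ t (so a cut-off of "3" on the
  Likert scale counts score 3 as positive). The Youden index
  J(t) = Se(t) + Sp(t) − 1 is maximized; ties are broken toward the highest
  sensitivity, i.e. the lowest threshold, which is the screening-friendly
  convention. Se, Sp and accuracy carry exact Clopper–Pearson intervals
  from the beta-quantile closed form — chosen because reported cells of the
  form 1.00 (0.63–1.00) equal the exact interval's (α/2)^(1/n) bound at
  x = n = 8 and no other standard interval reproduces it.
* **Permutation test.** The two arms are mapped to per-arm rank scales
  (making the test scale-free), and the null of equal AUROC is simulated by
  swapping the per-case pair (aᵢ, bᵢ) independently with probability ½ —
  the reflection group of the paired design. The statistic is |ΔAUC|,
  two-sided; the Monte-Carlo p uses the add-one estimator
  (1 + #{≥ obs})/(B + 1), so p ≥ 1/(B+1) and the test is exact-level. For
  n ≤ 20 an exhaustive 2ⁿ enumeration is available (and used automatically
  when cheaper than the requested B). An unpaired variant (reassigning the
  pooled score–label observations to arms) is provided behind
  `paired=False`; paired is the default because both arms score the same
  cases. Default B = 10 000.

### Pipeline

Per modality, the pipeline builds the AI consensus, then for each reader
group (all readers, the four experience bands 0–1 / 1–5 / 5–10 / 10+ years
and, for mammography, the specialist subgroups) computes the group's
consensus, drops excluded cases, intersects with the AI consensus cases,
and runs ROC inference plus the paired comparison on exactly that shared
set. Each row's n is its own paired count; small groups lose more cases to
the <5-response filter, which is why per-band n varies. The AI row itself
is evaluated on the cases it shares with the all-readers group (the
head-to-head set). Comparisons are AI-vs-group only. No multiplicity
correction is applied by default, matching per-row reporting practice; a
Holm step-down adjustment is available via `BenchmarkConfig(holm=True)`.
Display rounding is 2 decimals, half-up; all internal values are kept at
full precision, and the identity J = Se + Sp − 1 holds exactly
pre-rounding (checked by `youden_identity_check`).

## The synthetic-study generator

The generator emulates an enriched retrospective reader study:

* **Cases.** Exactly round(n·prevalence) positives (fixed-margin design,
  matching a curated test set, not Bernoulli sampling). Default
  compositions: 140 (47) X-ray, 184 (84) fluorography, 269 (167)
  mammography; demographic columns follow the corresponding age/sex
  profiles.
* **Readers.** Four experience bands with configurable counts (defaults
  mirror the emulated study's roster, including the mammography specialist
  subgroup). Each reader rates a subset of `set_size` cases — one of
  20/50/80, default 50 (the middle choice offered to study participants).
  Assignment is independent uniform per reader by default; a balanced
  round-robin dealing (`assignment="balanced"`) keeps per-case response
  counts even while each reader's set is still marginally a uniform random
  subset.
* **Ratings.** Equal-variance binormal latent z ~ N(y·d, 1), discretized
  by four cut-points symmetric about d/2 with inner spacing 0.75 latent SD
  (a fixed convention — only the ordering matters for ROC; this choice
  populates all five categories at realistic rates). The separation d is
  calibrated numerically so that the *ordinal ratings themselves* have AUC
  equal to `reader_auc` — the continuous-score closed form
  d = √2·Φ⁻¹(AUC) would leave the ratings about 0.01 short at AUC ≈ 0.9
  because discretization ties are half-weighted. Independently, with
  probability `undefined_rate` (default 0.05; the emulated study does not
  report its rate) a rating is replaced by 3.
* **AI scores.** z ~ N(y·d, 1) with the closed-form d, reported as
  logistic(α·z + β) — a strictly increasing per-model distortion that
  changes the score scale but not the ROC — rounded to 0.01.
* **Reproducibility.** Every table is a pure function of (config, seed);
  streams are split by (modality, purpose) via seed sequences, so adding
  readers does not perturb the case table.

### What the generator does not emulate

Readers are conditionally independent given the case label. Real reader
panels share error modes — genuinely ambiguous images are missed by many
readers at once — which caps the benefit of aggregating many opinions. With
dozens of independent simulated readers per case, the median consensus is
therefore nearly noiseless and consensus AUROCs saturate near 1.0, visibly
above the 0.94–0.98 consensus values typical of real panels. Passing
pipeline tests on synthetic data consequently validate the *machinery*
(rules, estimators, pairing, determinism), not the field realism of
consensus accuracy levels. Learning curves, fatigue, case-difficulty
structure and inter-modality reader overlap are likewise not modelled.

### The parameter-recovery experiment

Recovering a band's configured AUC from its *consensus* scores is
structurally confounded: upper-median aggregation of k ≥ 2 independent
ratings inflates AUC well above the individual level (≈ +0.04 at k = 2 for
AUC 0.87), while at k = 1 the undefined-majority rule excludes every
singleton "3" rating, censoring the hardest cases and inflating the
survivor AUC by ≈ +0.03. The acceptance experiment therefore estimates each
band's AUROC at the rating level — all of a band's Likert-mapped ratings
against their case labels — which is the estimator that identifies the
generator parameter. The design is an X-ray-like composition scaled to
2000 cases (prevalence 47/140), 100 readers per band rating 80 cases each
under balanced assignment (4 ratings per case per band), no undefined
noise, and a single AI model, so that every estimate carries a Monte-Carlo
standard error below 0.007 and sits within ±0.02 of its configured value
with large margin. A 40-seed design pilot measured bias < 0.001 per band
before the experiment was frozen.

## Numerical choices and degenerate inputs

* Ordinal-AUC calibration solves a closed-form category-probability
  expression by Brent's method to 1e−10.
* AUC computations use midranks throughout (exact with ties); row-wise
  permutation statistics compare with a 1e−12 slack so enumerated and
  Monte-Carlo paths agree bit-for-bit with brute-force references.
* Single-class inputs raise typed inference errors; empty rating sets and
  out-of-range scores raise validation errors naming the offending row.
* A model whose scores are all identical calibrates to a constant 0.5 with
  a logged warning.
* All stochastic entry points take explicit integer seeds; benchmark rows
  derive independent child seeds from (seed, row index), so reports are
  byte-identical across runs.

## Known limitations

* No reader-level variance components (see above): CIs and p-values are
  conditional on the realized reader panel.
* The binormal smoother can be a poor fit for strongly non-binormal
  empirical curves; it is never used for inference.
* The upper-median reading of the consensus tie rule and the label-free
  calibration are documented interpretations of under-specified procedures;
  both alternatives considered are discussed above and one
  (`mode_high`) is implemented.
* Clopper–Pearson intervals are conservative, as exact intervals are.
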