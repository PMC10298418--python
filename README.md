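# readerbench

Statistical benchmarking of human readers against AI classifiers in
multi-reader multi-case (MRMC) diagnostic accuracy studies — the setting of
enriched retrospective reader studies in chest radiography, fluorography and
screening mammography, where many radiologists rate overlapping case subsets
on a 5-point Likert scale and several commercial AI models score the same
cases with a probability of pathology.

`readerbench` is aimed at researchers running observer-performance studies
who need the full analysis chain behind a per-group table of diagnostic
performance metrics:

* **Consensus scoring.** Per case, reader ratings (1 = definitely without
  pathology … 5 = definitely with pathology, 3 = undefined) are aggregated
  by the *upper median* (the ⌈(n+1)/2⌉-th order statistic, so an ambiguous
  even-n median resolves to the higher score) after two exclusion rules:
  cases whose ratings are >50 % "undefined" are dropped, and cases with
  fewer than 5 responses are dropped except in the breast-imaging-specialist
  subgroup analysis. AI models are combined by calibrating each model's
  scores to a common (0, 1) scale with the label-free midrank transform
  (rank − ½)/m — which leaves every model's ROC curve unchanged — and
  averaging per case.
* **ROC inference.** The empirical Mann–Whitney AUROC
  Â = (mn)⁻¹ ΣᵢΣⱼ [1(xᵢ > yⱼ) + ½·1(xᵢ = yⱼ)] with the DeLong
  placement-value variance and normal-theory 95 % CI; binormal probit
  smoothing Φ⁻¹(TPR) = a + b·Φ⁻¹(FPR) for display; the Youden-optimal
  operating point (max J = Se + Sp − 1, predicted-positive at score ≥ t)
  with exact Clopper–Pearson intervals on Se/Sp/Acc; and a paired per-case
  swap permutation test for the difference of two AUROCs on the same cases.
* **Synthetic studies.** An equal-variance binormal latent-variable
  generator reproduces the statistical structure of such a study — fixed
  case mixes (e.g. 140 cases / 47 positive), four reader experience bands
  with calibrated rating-level AUCs, per-reader case subsets of 20/50/80,
  an "undefined" rating rate, and AI scores at 0.01 precision — so the whole
  pipeline is testable without access to any clinical data.

## Worked example

```python
import readerbench as rb

study = rb.simulate_study(rb.default_study_config(seed=3))
model = rb.ReaderStudyBenchmark(**study,
                                config=rb.BenchmarkConfig(n_permutations=500))
results = model.fit(seed=3)
print(results.summary())
```

```
modality group                 n  AUROC(CI95)      Se(CI95)         Sp(CI95)           thr     J        p
XRAY     AI                  140  1.00(0.99–1.00)  0.98(0.89–1.00)  0.98(0.92–1.00)   0.61  0.96        -
XRAY     ALL_READERS         140  1.00(1.00–1.00)  1.00(0.92–1.00)  1.00(0.96–1.00)   0.75  1.00    0.002
...
FLG      AI                  159  0.93(0.89–0.97)  0.89(0.79–0.95)  0.85(0.76–0.92)   0.50  0.74        -
FLG      ALL_READERS         159  1.00(1.00–1.00)  0.97(0.90–1.00)  1.00(0.96–1.00)   0.75  0.97    0.002
FLG      E0_1                  2  insufficient data
```

Reading the output: each row is one reader group (or the AI ensemble) in one
modality, evaluated on its surviving cases paired with the AI consensus —
`n` is that paired count, which legitimately differs between rows because
the <5-response filter binds harder in small groups (the two-reader FLG
band above loses almost every case). `AUROC` carries its DeLong 95 % CI,
`Se`/`Sp` the Clopper–Pearson intervals at the Youden-optimal threshold
`thr`, `J` the Youden index, and `p` the paired permutation p-value against
the AI ensemble. With many conditionally independent simulated readers per
case, consensus AUROCs saturate near 1.0 — see `docs/methods.md` for why
real reader panels do not.

The same run from a shell:

```bash
readerbench simulate --out study/ --seed 3
readerbench run --cases study/cases.csv --readers study/readers.csv \
    --ratings study/ratings.csv --ai study/model_scores.csv \
    --out report.csv --seed 3
```

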