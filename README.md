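# aldpanel

Plasma/liver proteomics biomarker-panel discovery and evaluation for
alcohol-related liver disease (ALD).

Liver biopsy is the reference standard for staging fibrosis, inflammatory
activity and steatosis, but it is invasive and unsuitable for screening.
`aldpanel` implements, as a tested and reusable pipeline, the workflow by
which a plasma proteome matrix (DIA mass spectrometry, proteins × samples,
linear intensities with missing values) is turned into small protein marker
panels that classify histology-defined disease stages, benchmarked against
established clinical tests and evaluated prognostically. Because real
patient-level cohorts of this kind are access-restricted, the package ships
a synthetic-cohort generator with known ground truth that reproduces the
statistical structure the analysis assumes, so every step is exercised and
validated end to end.

## The method

1. **Preprocessing** — samples with < 200 quantified proteins are dropped;
   proteins observed in < 60% of samples are removed; intensities are log2
   transformed; proteins with CV > 30% across analytical QC replicates are
   removed; remaining missing values are imputed per sample from a
   downshifted normal, x ~ N(m_s − 1.8·d_s, (0.3·d_s)²), where m_s, d_s are
   the mean and SD of the sample's observed log2 intensities — the standard
   treatment for abundance-dependent (MNAR) dropout.
2. **Differential screens** — per protein: ANCOVA (partial F-test of the
   histology factor as a categorical variable, adjusting for age, BMI, sex,
   abstinence and the complementary lesion score) and Spearman partial
   correlation with the ordinal score; Benjamini–Hochberg FDR across
   proteins; a protein passes at q < 0.05 (and |r| ≥ 0.3 for the
   correlation screen).
3. **Liver–plasma integration** — Pearson correlation per protein across
   paired biopsied patients; proteins co-dysregulated in both compartments
   annotated concordant/discordant; annotation-category direction fractions.
4. **Panel selection** — minimum-redundancy–maximum-relevance (mRMR)
   ranking (ANOVA-F relevance divided by mean |Pearson r| redundancy),
   five-fold cross-validation repeated ten times with stratification on
   (class × missingness pattern), panel size chosen as the smallest k with
   the maximal mean F1, and a final L2-logistic model frozen from a
   stratified 80/20 split (classification cutoff 0.5).
5. **Benchmarking** — comparator tests (elastography, ELF, FIB-4, APRI, …)
   at fixed clinical cutoffs; DeLong's test for paired ROC-AUCs; class-based
   net reclassification improvement
   NRI = P(up|event) − P(down|event) + P(down|nonevent) − P(up|nonevent);
   rule-out accuracy in presumed disease-free populations.
6. **Prognosis** — the frozen diagnostic model's probability is evaluated
   against right-censored outcomes (composite liver-related events,
   all-cause mortality) by Harrell's C-index and fixed-horizon ROC-AUC.

## Worked example

```python
from aldpanel import (CohortConfig, generate_cohort, run_preprocess,
                      ImputeParams, label_endpoint)
from aldpanel.diffabund import ancova_stagewise, spearman_partial_scores
from aldpanel.panel import cv_evaluate, final_fit

cfg = CohortConfig(n_patients=360, seed=42)     # biopsied ALD-like cohort
plasma, liver, meta, truth = generate_cohort(cfg)
mat = run_preprocess(plasma, impute=ImputeParams(seed=42))

anc = ancova_stagewise(mat, meta, "fibrosis")
cor = spearman_partial_scores(mat, meta, "fibrosis")

labels = label_endpoint(meta, "F2")             # significant fibrosis
idx = labels.dropna().index
X, y = mat.data.T.loc[idx], labels[idx].astype(int).to_numpy()
report = cv_evaluate(X, y, k=9, folds=5, repeats=10, seed=42)
model, metrics = final_fit(X, y, k_star=9, seed=42, endpoint="F2")
```

With this seed the run prints (via the objects above):

```
plasma matrix: (500, 360)  missing fraction: 0.094
after preprocessing: (449, 360)
fibrosis screen hits: 18 — all 9 planted fibrosis markers recovered
CV ROC-AUC: 0.980 ± 0.010
held-out ROC-AUC: 0.985, F1: 0.914
```

The screen finds 18 proteins (the 9 planted fibrosis markers plus
inflammation markers that track fibrosis through the correlated histology
scores); the 9-protein logistic panel separates F0–1 from F2–4 with a
cross-validated ROC-AUC of 0.98 on this synthetic cohort, where the planted
effect (0.5 log2 units per stage against 0.5 log2 noise) makes the classes
nearly separable by construction.

The same flow is available from the shell:

```bash
aldpanel simulate --seed 7 --outdir cohort/
aldpanel run --config config.yaml            # preprocess … prognosis
```

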