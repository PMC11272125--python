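# tilquant

Automated quantification of tumor-infiltrating lymphocytes (TILs) from
H&E-stained tumor-section images, with the downstream cohort statistics and
survival analyses used to establish TIL proportion as a prognostic
biomarker in esophagogastric cancers (AEGJ, GAC, ESCC).

Manual TIL scoring needs expert pathologists, suffers inter-observer
variability, and does not scale. This package implements the automated
alternative as a tested, reusable pipeline:

1. **Segmentation** — LAB colour transform, projection onto a nucleus-signal
   grayscale, Otsu thresholding (maximising between-class variance),
   morphological opening, and seeded watershed to split touching nuclei;
   whole sections are processed as a 10×10 grid of tiles.
2. **Feature extraction** — a fixed, versioned registry of 43 per-nucleus
   features: shape (12), intensity (12), grey-level co-occurrence texture
   (13), neighbourhood (3), and boundary gradient (3).
3. **Classification** — an RBF-kernel SVM over standardised features
   assigns each nucleus to {cancer cell, lymphocyte, stromal cell}, trained
   per cancer type; validated by stratified 10-fold cross-validation,
   concordance with manual counts, and a Jonckheere–Terpstra trend test
   against ordered manual grades.
4. **TIL quantification** — π = 100 · L / (C + L + S) per section, and a
   cohort-median split into high/low TIL groups.
5. **Cohort statistics** — Kruskal–Wallis, Wilcoxon rank-sum, Pearson
   chi-square, Bonferroni correction, Spearman, and multivariable linear
   regression with standardised coefficients.
6. **Survival** — Kaplan–Meier curves, log-rank tests, and Cox
   proportional-hazards models with TIL % entering per percentage point
   (hazard ratio HR = exp(β) per TIL point; Efron ties).

Because the original cohorts and sections are not distributable, the
package ships a first-class synthetic-data module: H&E-like images with
three nucleus morphologies (large irregular cancer nuclei, small round
dark lymphocytes, elongated stroma) and known ground truth, plus cohorts
drawn from an exponential proportional-hazards model in which the
log-hazard is linear in TIL %. Every pipeline stage is validated against
this ground truth.

## Worked example

```python
from tilquant import SlideSpec, generate_slide, quantify_slide, train_classifier
from tilquant.pipeline import build_training_set

ts = build_training_set("AEGJ", n_per_class=80, seed=1)   # labelled cells
model = train_classifier(ts, seed=0)

spec = SlideSpec(width_px=1000, height_px=1000, n_nuclei=200,
                 class_fractions=(0.5, 0.2, 0.3), seed=7)
img, truth = generate_slide(spec)
res = quantify_slide(img, model)
print(res.counts, res.til_proportion, truth.true_til_proportion)
```

prints

```
{'cancer': 94, 'lymphocyte': 49, 'stroma': 57} 24.5 24.5
```

— the classifier found 49 lymphocytes among 200 detected cells, an
estimated TIL proportion of 24.5%, equal here to the generator's ground
truth. The analysis is driven end to end by the numbered scripts:

```bash
python analysis/01_simulate_data.py 1      # slides + cohort
python analysis/02_train_and_validate.py 1 # per-cancer training sets + CV
python analysis/03_quantify_slides.py 1    # TIL estimates vs truth
python analysis/04_cohort_statistics.py 1  # Kruskal–Wallis, regression
python analysis/05_survival_analysis.py 1  # KM, log-rank, Cox
```

each writing its tables under `results/`. A typical step-05 line:

```
[multivariable] til_pct: HR=0.962 (95% CI 0.947, 0.976) p=3.33e-07
```

i.e. each additional TIL percentage point multiplies the hazard of death
by ≈0.96 — higher lymphocyte infiltration, better prognosis. The same
pipeline is exposed as a CLI (`tilquant --help`) with subcommands
`simulate-slide`, `simulate-cohort`, `segment`, `train`, `cross-validate`,
`quantify`, `stats`, `survival`, and `run-all`.

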