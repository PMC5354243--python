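# focm-screen

Multivariate screening of folate-dependent one-carbon metabolism /
transsulfuration (FOCM/TS) metabolite panels:

- **Cross-validated Fisher Discriminant Analysis (FDA)** for two-cohort
  classification (ASD vs. neurotypical), with per-fold z-scoring,
  leave-one-out scoring, and projection of an external sibling cohort
  through the frozen model.
- **Gaussian kernel density estimation** of cohort score distributions with
  least-squares cross-validation (LSCV) bandwidth selection.
- **PDF-based ROC curves and C-statistics**, an equal-density decision
  threshold, confusion summaries (TPR/FPR/PPV/NPV) and Type I/II error
  curves.
- **Metabolite subset selection**: exhaustive search of all combinations up
  to a size cap by cross-validated C-statistic, greedy extension beyond it,
  and a sibling-separability criterion for augmenting a chosen panel.
- **Gaussian-kernel partial least squares (KPLS)** regression of Vineland
  adaptive-behavior scores, dual NIPALS form, with leave-one-out Q² and an
  exhaustive regression subset search.
- **Synthetic data**: a three-cohort generator with correlated lognormal
  metabolite profiles, planted discriminative shifts, an intermediate
  sibling cohort, exactly recomputed ratio columns, and a noisy nonlinear
  metabolite → behavior link — every pipeline stage is testable without the
  study data.

## Input data

The pipeline reads a CSV with one row per participant: the 24 panel
metabolite columns (header matching is case/punctuation-insensitive, with
an optional alias map), a cohort column (ASD/SIB/NEU, common aliases
accepted), and an optional Vineland score column. The study's own
supplementary table is **not** redistributed here; place it at
`data/s1_dataset.csv` to run the real-data analyses (acceptance tests 1–5
and all targets of `scripts/acceptance.py` need it). Synthetic stand-ins
with the same layout come from `focm-screen simulate`.

## Command line

```bash
focm-screen simulate --seed 1 --out synthetic.csv   # synthetic dataset + ground truth
focm-screen validate synthetic.csv                  # ratio/positivity consistency report
focm-screen classify synthetic.csv --variables "8-OHG,GSSG"
focm-screen search synthetic.csv --k-max 3 --jobs 4
focm-screen regress synthetic.csv --k-max 3 --hyper-policy nested
focm-screen run --config cfg.yaml                   # full staged pipeline
```

`focm-screen run` executes, from one YAML config: load/validate →
full-panel classification → sibling projection → exhaustive + greedy
subset search → final-panel classifier with confusion and error curves →
KPLS regression search, writing each stage's tables (CSV/JSON) to the
output directory. Reruns with the same config are byte-identical.

## Layout

```
src/focm_screen/
  panel.py          canonical 24-metabolite panel, ratio metadata, aliases
  data_io.py        CSV reading/writing, validation report
  fda.py            scatter matrices, discriminant fitting, LOO scoring
  density.py        Gaussian KDE, LSCV bandwidth selection
  roc_classify.py   ROC/C-statistic from PDFs, threshold, confusion
  subset_search.py  exhaustive + greedy combination search
  kpls.py           dual-form Gaussian-kernel PLS, LOO Q², search
  synthetic.py      planted-structure cohort generator
  pipeline.py       staged orchestration
  cli.py            click entry points
```
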