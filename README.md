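# ceusomics

Texture-feature ("ultrasomics") pipeline for classifying focal liver lesions
from three-phase contrast-enhanced ultrasound (CEUS) image triplets —
baseline, arterial phase, portal phase.

The package implements the full analysis chain:

1. **synthetic_data** — a seeded generator of two-class cohorts (benign
   FNH-like vs. malignant HCC-like): elliptical lesions with class-dependent
   texture and enhancement, ordinal reader scores (grades 1–3) stochastically
   concordant with the class, and clinical covariates drawn from per-class
   marginals. Everything downstream is testable without any external data.
2. **imaging** — PNG/TIFF/DICOM reading (single-frame DICOM via a minimal
   built-in parser), ROI polygon rasterization (even-odd rule at pixel
   centers with a documented half-open "top-left in" tie rule), and
   ROI-relative equal-width grey-level quantization.
3. **features** — a 1,044-feature-per-image catalogue: 42 histogram
   statistics, 12 form-factor (shape) descriptors, 18 Sobel
   gradient-magnitude statistics, 780 grey-level co-occurrence (GLCM)
   features (13 features × 5 distances × {4 angles, angular mean, angular
   range} × {32, 64} grey levels) and 192 run-length (GLRLM) features (16 ×
   6 directional slots × 2 level settings). A patient triplet yields
   3 × 1,044 = 3,132 values with `BL_`/`AP_`/`PP_` prefixes.
4. **selection** — correlation filter (|r| > 0.95, keep the higher-AUC
   member), univariate folded-AUC filter (≥ 0.6), z-normalization (training
   mean / population SD), and L1-penalized logistic regression over a
   log-spaced λ path chosen by repeated 10-fold CV with the 1-SE rule; plus
   an events-per-variable (≥ 10× ) warning.
5. **modeling** — RBF-SVM (C = 1, kernel width σ = 0.012 in the
   kernlab convention k(u,v) = exp(−σ‖u−v‖²)) over three predictor sets:
   texture features, reader score, and both combined; repeated stratified
   80/20 hold-out (10 repeats), 10-fold CV diagnostics, best-repeat
   selection; all selection/normalization is fitted inside each training
   split (no leakage).
6. **evaluation** — ROC/AUC (Mann–Whitney, ties ½), Youden operating point,
   sensitivity/specificity/PPV/NPV/±LR with Clopper–Pearson and bootstrap
   CIs, paired DeLong test, Wilcoxon signed-rank, linear-weighted kappa,
   ICC(2,1), decision-curve analysis (net benefit), normal-AFP subgroup
   re-evaluation, and baseline-table group tests.
7. **pipeline / CLI** — a reproducible end-to-end run driven by one master
   seed; rerunning with the same configuration is byte-identical for all
   numeric artifacts, and every report table can be regenerated from the
   persisted `features.csv` + `clinical.csv` alone.

## CLI

```bash
ceusomics run --out runs/demo --seed 1 --repeats 10        # full pipeline
ceusomics run --out runs/tiny --seed 1 --n-fnh 4 --n-hcc 4 --repeats 1 \
    --lasso-repeats 2                                      # fast smoke run
ceusomics simulate --out cohort/ --seed 1                  # cohort only
ceusomics extract  --cohort cohort/ --out features.csv
ceusomics select   --features features.csv --clinical cohort/clinical.csv \
    --out selection.json
ceusomics train    --features features.csv --clinical cohort/clinical.csv \
    --out runs/models
ceusomics evaluate --scores runs/models/scores_combined.csv --out eval.json
```

A run directory contains the feature matrix, selection result, model report
(per-repeat train/validation AUCs, best repeat, selected features),
validation diagnostics and subgroup tables, ROC/DCA curves as CSV, the
baseline covariate table, and a log of every seed, count, and warning.

## Conventions

- Images are `[row, col]` arrays; polygons are `(x, y)` = (col, row),
  0-based, origin at the top-left pixel corner; pixel `(r, c)` has center
  `(c + 0.5, r + 0.5)`.
- The malignant class is coded 1 and a test is positive when the model
  output is at or above the operating threshold.
- Quantization is ROI-relative (min–max of in-mask intensities), making all
  GLCM/GLRLM features invariant to intensity shift and positive scaling.
- Entropies use log base 2 with 0·log 0 ≡ 0; moments are population moments;
  percentiles interpolate linearly between order statistics.
- ROIs must contain at least 16 pixels; smaller masks raise an error rather
  than emit unstable texture values.
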