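# ewsbench

Validation benchmark for five early warning scores (NEWS, NEWS2, MEWS, REMS,
IEWS) as predictors of 24-hour clinical deterioration (death or ICU
admission) in emergency-department patients aged 80 years or older.

The package provides, as reusable tested components:

- **`score_engine`** — a generic, validated band-table scoring engine with the
  five score definitions shipped as editable JSON fixtures
  (`src/ewsbench/definitions/`), including the NEWS2 alternate SpO2 scale for
  patients at risk of hypercapnic respiratory failure.
- **`synthetic`** — a synthetic ED cohort generator matched to the study
  population's class-conditional vital-sign medians/IQRs, 2.4% event
  prevalence, age distribution (median 85, IQR 82–88, minimum 80) and
  per-variable MCAR missingness below 5%.
- **`imputation`** — the exclusion rule (records with more than 2 missing
  score parameters are dropped) and chained-equations multiple imputation
  with Monte-Carlo posterior draws collapsed to one completed dataset.
- **`discrimination`** — tie-corrected AUROC with DeLong variance and paired
  DeLong comparisons; sliding 5-year / 1-year-step AUROC-by-age windows with
  a restricted-cubic-spline OLS fit (3 df) and an F test against the
  intercept-only model.
- **`calibration`** — single-predictor logistic risk models, Brier scores
  with seeded bootstrap CIs and paired comparison p values, logit
  recalibration slopes, equal-count calibration bins, PPV-margin threshold
  classification metrics with Wilson CIs, and precision–recall curves.
- **`contribution`** — gradient-boosted tree model over the union of all
  score inputs with an exact path-dependent TreeSHAP implementation (raw and
  max-normalised mean |SHAP|), and a bootstrap contrast of normalised
  contributions between the 80–86 and ≥87 age strata.
- **`pipeline` / `cli`** — a fully deterministic end-to-end run emitting CSV
  tables plus JSON metrics and a manifest.

## CLI

```bash
ewsbench simulate --n 20000 --seed 1 --out cohort.csv
ewsbench impute   --input cohort.csv --seed 1 --m 20 --out completed.csv
ewsbench score    --input completed.csv --out scores.csv
ewsbench evaluate --input completed.csv --seed 1 --out report/
ewsbench contribution --input completed.csv --seed 1 --age-cut 87 --out contrib.csv
ewsbench run-all  --seed 1 --out report/          # full simulated pipeline
```

`ewsbench run-all` accepts `--config config.json` with any `RunConfig` field
(n, prevalence, bootstrap B, PPV margins, window width/step, spline df, age
cut, model hyperparameters, …).  Re-running an identical config reproduces
every artifact byte for byte; the global seed fans out to per-stage seeds via
`numpy.random.SeedSequence` with fixed per-stage spawn keys.

## Notes

- Score definitions are data, not code: the IEWS age/sex point table is a
  provisional transcription and can be corrected by editing
  `src/ewsbench/definitions/iews.json` alone.
- The contribution model uses scikit-learn gradient boosting with a
  first-principles exact TreeSHAP (validated in the test suite against a
  brute-force Shapley oracle), so no external xgboost/shap dependency is
  needed.
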