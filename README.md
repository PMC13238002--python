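# sustkit

Subtype-and-stage inference for regional brain atrophy, exercised end-to-end
on synthetic multi-site longitudinal cohorts.

The package implements a z-score event-based subtype-and-stage model over
regional deformation-based-morphometry (DBM) values:

1. **synthetic** — generates multi-site longitudinal cohorts (healthy
   controls + patients) with planted subtype-specific atrophy sequences,
   stage-linked clinical decline, subtype-linked survival hazards and
   attrition.
2. **wscore** — fits per-ROI healthy-control reference models (linear mixed
   effects: age + sex fixed, site + subject random intercepts) and converts
   observed values to w-scores (negative = atrophy).
3. **events / sustain** — builds the (biomarker, z-threshold) event catalogue
   (14 ROIs × thresholds {1, 2} → 28 events, per-region z_max ∈ {2, 3}),
   fits mixtures of event orderings by greedy ascent + EM with hierarchical
   cluster splitting, quantifies uncertainty by Metropolis MCMC, selects the
   number of subtypes by 8-fold cross-validated information criterion
   (CVIC, lower is better), and assigns each observation a MAP
   (subtype, stage) with the stage-0 → Normal Appearing (S0) rule.
4. **longitudinal** — applies the baseline-trained model to follow-up visits,
   classifies between-visit subtype/stage consistency, compares assignment
   confidence between consistent and inconsistent cases (t-test or
   Mann-Whitney by a Shapiro-Wilk gate), and resolves one most-confident
   non-S0 subtype per subject while retaining all per-visit stages.
5. **association** — longitudinal group contrasts
   (`feature ~ Dx * ΔTime (+ Age_bl + Sex) + (1 | subject)`), baseline
   regressions dispatched on variable type (OLS / logistic / ordinal
   logistic), stage associations with ΔTime adjustment, and
   Benjamini-Hochberg FDR within declared families.
6. **survival** — composite-endpoint records with censoring rules,
   Kaplan-Meier curves with medians, and omnibus/pairwise log-rank tests.
7. **pipeline** — YAML-configured orchestration of all stages with a
   run manifest and deterministic per-stage seed fan-out.

## Test

```sh
python -m pytest tests/
```

The suite includes unit tests per module, property tests (trajectory
monotonicity, likelihood-vs-enumeration equivalence, greedy-vs-exhaustive
oracles, BH equivalence against statsmodels, type-I calibration of the mixed
models and the log-rank test) and `tests/test_acceptance.py`. The full run
takes roughly 15–20 minutes on one CPU; the model-order-selection test
dominates.

## CLI

```sh
sustkit simulate --seed 1 --n-hc 144 --n-patients 198 --out cohort/
sustkit wscore --hc-csv cohort/hc.csv --table-csv cohort/patients.csv \
               --out wscores.csv --model-out reference.json
sustkit fit --wscores-csv wscores.csv --max-k 3 --iters 10000 --seed 1 --out model.json
sustkit cv  --wscores-csv wscores.csv --max-k 4 --folds 8 --seed 1 --out cvic.json
sustkit run-all --config config.yaml --seed 1 --out run/
```

`run-all` executes the whole analysis (simulate or ingest CSVs → w-scores →
fit/CVIC → longitudinal consistency → statistics → survival) and writes all
stage outputs plus `manifest.json` into the output directory. See
`sustkit.pipeline.DEFAULT_CONFIG` for the configuration schema; any subset
may be overridden in the YAML file.

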