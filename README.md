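# ssirs

Derivation, integer point-score conversion, and validation of a surgical
site infection (SSI) risk model, exercised end to end on synthetic
registry-like cohorts with a known ground-truth risk model.

The pipeline mirrors a classic two-stage clinical risk-score construction:

1. **Synthetic cohorts** (`ssirs.synthetic`) — one row per operation
   (demographics, comorbidities, surgical factors, a 5-character procedure
   code whose 3-digit prefix defines a procedure group, binary 30-day SSI
   outcome), drawn from a configurable inverse-logit model with seeded
   per-group log-odds offsets. Every downstream stage is testable by
   parameter/score recovery.
2. **Derivation** (`ssirs.derivation`) — random half split; stage-1 forward
   selection logistic regression (categorical covariates as whole indicator
   blocks, continuous covariates through closed-test fractional-polynomial
   forms from `ssirs.fracpoly`); an observed/expected SSI ratio per 3-digit
   procedure prefix (the *CPT3 score*, with 0/1 defaults for zero-event
   groups); stage-2 forward selection at p < 0.0001 with the CPT3 score in
   the candidate pool plus likelihood-ratio tests of configured a-priori
   interactions.
3. **Scoring** (`ssirs.scoring`) — Sullivan-style conversion of the final
   model into an integer point table (one point = the log-odds change of a
   5-unit BMI increase by default), a score-to-risk logistic map, and an NNT
   utility.
4. **Evaluation** (`ssirs.evaluation`) — c-statistic with DeLong confidence
   intervals, Hosmer–Lemeshow goodness of fit, Clopper–Pearson exact
   binomial intervals, per-score-level calibration, and the legacy 0–3
   NNIS-style basic risk index as a comparator.
5. **I/O + CLI** (`ssirs.io`, `ssirs.pipeline`, `ssirs.cli`) — documented
   cohort CSV schema, YAML pipeline configs, JSON artifacts with a run
   manifest, deterministic reruns.

## Command line

```sh
ssirs simulate --n 20000 --seed 0 --out cohort.csv
ssirs split cohort.csv --seed 0 --derivation-out d.csv --validation-out v.csv
ssirs derive d.csv --outdir artifacts/
ssirs score d.csv --model artifacts/final_model.json \
    --cpt3 artifacts/cpt3_table.json --out points.json
ssirs evaluate v.csv --model artifacts/final_model.json \
    --cpt3 artifacts/cpt3_table.json --points points.json --out report.json
ssirs run --outdir run1/ --n 20000 --seed 0    # full pipeline in one step
ssirs nnt 0.10 0.5                             # -> 20
```

`ssirs run --config cfg.yaml` takes a YAML config; see
`ssirs.io.PipelineConfig` for the fields (split seed, stage-1/stage-2 entry
thresholds, interaction candidates, categorization preset or explicit
boundaries, evaluation options, and a simulate block).

Exit codes: 0 success, 1 validation error, 2 runtime error.

## Notes

- Cohort CSVs use the fixed header documented in `ssirs.io.COHORT_COLUMNS`;
  generated cohorts never contain missing values. On read, covariates with
  ≥1% missingness are dropped as columns, then remaining incomplete rows
  are dropped complete-case (both logged).
- All randomness flows from explicit seeds; identical config + seed
  reproduces byte-identical JSON artifacts.
- The default synthetic marginals are plausibility choices (the emulated
  registry is only described qualitatively in public sources); they live in
  `ssirs.synthetic.default_config`, not in code paths.
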