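# postpipe

Scoring, outcome classification and validation pipeline for headache after
flow-diverter treatment of unruptured intracranial aneurysms.

The package implements:

- **`postpipe.cohort_model`** — domain types (headache phenotype profiles,
  patient records, expert ratings, rater labels), validation, and a lossless
  CSV schema (`cohort.csv`, `panel.csv`, `raters.csv`). Missing values are
  empty cells; `0` is never "missing".
- **`postpipe.score`** — the composite post-procedural headache score: a
  diagnostic pathway for headache-naive patients and a six-criterion change
  score (intensity, lateralization relative to the aneurysm side, attack
  duration category, associated symptoms, frequency, subjective
  dissimilarity) for patients with a pre-existing headache disorder, plus
  the five-way outcome classification (never / new-onset / improvement /
  no-change / worsening) including the "minimal worsening counts as no
  change" rule. All band edges, point values and the diagnostic threshold
  (default >= 9) live in `postpipe.config.ScoringConfig`.
- **`postpipe.validity`** — item- and scale-level content validity indices
  (I-CVI, S-CVI/Ave), per-rater cut-off validation (confusion counts,
  sensitivity/specificity, single-threshold trapezoidal AUC =
  (sens + spec)/2), and binormal ROC fitting.
- **`postpipe.cohort_stats`** — Shapiro–Wilk, probability-mass two-sided
  Fisher exact test (2×2), seeded Monte-Carlo conditional exact test for
  r×c tables, Mann–Whitney U (exact null distribution when feasible,
  tie-corrected normal approximation with continuity correction otherwise),
  and a group-comparison table builder.
- **`postpipe.regression`** — logistic regression by IRLS with step-halving,
  Wald 95% intervals, odds-ratio tables, perfect-separation diagnostics,
  complete-case handling, and named model specifications (`model0`: age +
  sex; `full`: eight covariates).
- **`postpipe.synthdata`** — a stochastic cohort generator (`SimConfig`,
  `simulate_cohort`) with moment-matched lognormal aneurysm dimensions and a
  logistic neck-size outcome model; a deterministic 137-record fixture
  cohort (`make_fixture_cohort`) whose derived categorical marginals
  reproduce the published counts exactly when run through the real scoring
  code; simulated noisy raters and Likert expert panels.
- **`postpipe.cli_reports`** — the `postpipe` command-line interface.

## CLI

```bash
postpipe fixture  --out cohort.csv --truth truth.csv
postpipe simulate --n 500 --seed 7 --out sim.csv --truth sim_truth.csv
postpipe score    --cohort cohort.csv [--config scoring.yaml] --out scores.csv
postpipe compare  --cohort cohort.csv --scores scores.csv --out table2.csv
postpipe regress  --cohort cohort.csv --scores scores.csv --model full --out table3.csv
postpipe validate --scores scores.csv --raters raters.csv --cutoffs 8,9,10 --out validation.csv
postpipe cvi      --panel panel.csv --out cvi.csv
postpipe run      --cohort cohort.csv --out-dir report/   # full bundle + manifest
```

Exit codes: 0 ok, 1 validation/configuration error, 2 internal error.
`scoring.yaml` may override any `ScoringConfig` field, e.g.:

```yaml
threshold: 9
c3_multi_jump_points: 4
lenient_lateralization: false
```

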