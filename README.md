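# teamdx

Analysis pipeline for paired-session optical-diagnosis trials in which raters
judge the same lesions twice — once unassisted (S1) and once alongside an AI
advisor (S2). The package builds the four pre-registered endpoint odds
ratios (influence, diagnostic accuracy, effectiveness, safety) with a
crossed rater/lesion random-intercepts logistic model, runs
confidence-calibration and agreement analyses, and ships a latent-evidence
synthetic-cohort generator so the whole pipeline is testable without any
download.

## Components

| module | what it does |
|---|---|
| `teamdx.data_model` | trial-record types, label vocabularies, variable transforms (5-to-3 judgment map, 1–9 belief score, correctness, agreement), cohort validation |
| `teamdx.synthetic` | latent-evidence cohort generator with confidence-weighted belief integration, plus simulation-based power |
| `teamdx.glmm` | logistic regression with crossed random intercepts, Laplace maximum likelihood (inner PIRLS, outer bounded search), Wald intervals, one-sided tests |
| `teamdx.quadrature` | brute-force Gauss–Hermite marginal likelihood, the small-instance oracle for the GLMM engine |
| `teamdx.endpoints` | endpoint row construction (with exclusion logs) and odds-ratio estimation, overall and per expertise subgroup |
| `teamdx.calibration` | accuracy-by-confidence tables, switch rates on disagreement trials, AI accuracy conventions, agreement proportions |
| `teamdx.io` / `teamdx.report` / `teamdx.cli` | cohort CSV I/O, the end-to-end report bundle, and the command line |

## CLI

```sh
teamdx simulate --config gen.yaml --seed 7 --out cohort.csv
teamdx estimate --cohort cohort.csv --ai-basis perceived --out estimates.json
teamdx calibrate --cohort cohort.csv --out tables.json
teamdx power --config gen.yaml --reps 200 --out power.json
teamdx run --config gen.yaml --seed 7 --out bundle_dir   # all-in-one report
```

`gen.yaml` holds `GeneratorConfig` fields (all optional), e.g.

```yaml
n_raters: 21
n_expert: 10
n_lesions: 504
adenoma_prevalence: 0.6
misread_prob: 0.06
```

The cohort CSV is long format, one row per rater × lesion × session, with
columns `rater_id, lesion_id, session, raw_choice, diagnosis, confidence,
perceived_ai_dx, perceived_ai_conf, algorithmic_ai_dx, histology, expertise`
(empty string for structurally absent fields).

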