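# pcrt — Pancreatic Cancer Risk Tool

A tested library and CLI for questionnaire-based pancreatic-cancer risk
triage in a GI outpatient setting. It combines two independent pathways:

1. **Familial risk scoring** — a configurable point table over personal and
   first-degree-relative cancer events (with an at-or-before-50 diagnosis
   modifier and an Ashkenazi-ancestry bonus). A total of **3 or more**
   indicates referral to genetic counseling.
2. **New-onset-diabetes (NOD) triage** — an ENDPAC-criteria flag from
   self-reported weight change and fasting-glucose change: any weight loss
   plus elevated glucose around age 50 or later, excluding respondents with
   a pre-existing pancreatic-cancer diagnosis. A full three-component
   ENDPAC point model is structurally supported via JSON config (no
   parameterization is shipped).

The package also provides a questionnaire data model with lossless
JSON/CSV round trips, a seeded synthetic-cohort generator, a
deterministic 453-record reference cohort reproducing a published
deployment funnel (117 high-risk, 348 NOD completers, 220 assessable,
4 criteria-met), and two-group summary tables with chi-square, Fisher's
exact (including an exact r×c enumeration) and Mann-Whitney tests.

## CLI

A single `pcrt` entry point with four subcommands:

```sh
# deterministic reference cohort, then triage it
pcrt simulate --fixture --out cohort.csv
pcrt triage cohort.csv --out outcomes.csv --flow-out flow.json

# random cohort from configurable prevalences
pcrt simulate --n 500 --seed 7 --config cohort_config.json --out sim.json

# familial scores only, with an optional custom point table
pcrt score cohort.csv --point-table table.json --threshold 3

# two-group summary table (markdown or CSV)
pcrt report cohort.csv --format markdown
```

Exit codes: 0 success, 1 data/validation/configuration error, 2 usage
error. Identical arguments and `--seed` give byte-identical outputs.

## Data formats

- **JSON**: one document per cohort, `{"respondents": [...]}`. A JSON
  Schema ships as `src/pcrt/cohort.schema.json`.
- **CSV**: one row per respondent; repeated family-history groups use
  columns `mother_cancer1_type`, `mother_cancer1_le50`,
  `sibling2_cancer1_type`, …; empty cells always mean *unknown*, never
  *no*.
- **Point table / ENDPAC model / cohort config**: flat JSON files; see
  `pcrt.scoring.load_point_table`, `pcrt.endpac.load_endpac_model`,
  `pcrt.simulate.load_cohort_config`.

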