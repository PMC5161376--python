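# cdburden

A reusable, tested pipeline for self-report burden-of-disease analysis in
Crohn's disease cohorts:

- **Scoring** — patient-completed Harvey-Bradshaw disease-activity index
  (with or without the abdominal-mass item; activity > 4 points = active
  disease) and EQ-5D-3L utilities against a pluggable additive value set,
  with age/sex-matched population-norm lookup.
- **Cost engine** — human-capital valuation of absenteeism, presenteeism
  and registered early departure from the labour market (prevalence method,
  optional friction period); opportunity-cost valuation of replaced unpaid
  work and informal care; public-payer direct costs (consultations,
  hospitalisations, DDD-based drug costing); out-of-pocket range valuation;
  GDP-share normalisation and PLN→EUR conversion.
- **Statistics** — descriptives, Spearman correlation, rank tests,
  percentage agreement + Cohen's kappa, fractional-logit adjusted utility
  means, two-part (logit + gamma) cost models with delta-method CIs,
  modified Park diagnostics, and the design-stage sample-size formula.
- **Synthetic cohorts** — a seeded generator producing questionnaire
  records with a two-stratum severity structure, zero-inflated right-skewed
  cost outcomes and severity-correlated utility/impairment, so the whole
  pipeline is testable without study data.

## CLI

```bash
cdburden generate --n 200 --seed 1 --out cohort.csv     # synthetic cohort + config YAML
cdburden score cohort.csv --out scores.csv
cdburden cost cohort.csv --out costs.csv --friction-days 90
cdburden analyze cohort.csv --out stats.csv --covariates full
cdburden report --n 200 --seed 1 --out-dir out/          # full bundle
cdburden all --seed 1                                    # end-to-end smoke
```

`report`/`all` write a bundle: the validated cohort, per-respondent scores
and cost breakdowns, characteristics / cost summary tables, box-whisker
summaries, the statistics table and a JSON manifest. Identical config and
seed give byte-identical numeric outputs.

## Data files and configuration

- **Cohort files**: CSV or XLSX, one row per respondent, using the
  canonical headers in `cdburden.io.COLUMN_DICTIONARY`. Foreign layouts are
  adapted with a `CohortDialect` column mapping (`{foreign: canonical}`);
  monetary columns may be declared PLN and are converted to EUR on read.
  Cross-field inconsistencies (diagnosis after current age, more days
  missed than worked, more private than total consultations, …) are blanked
  per field and logged — records are never dropped.
- **Unit costs**: `src/cdburden/data/unit_costs.yaml` holds all monetary
  constants (hourly productivity-loss cost, care wage, consultation /
  hospitalisation tariffs, per-dose drug prices with dosing metadata,
  exchange rate, GDP figures). Override with a YAML of the same schema.
- **Value set / norms**: `value_set_pl.csv` (additive 3L tariff:
  any-problem constant, any-level-3 term, per-dimension level decrements)
  and `norms_pl.csv` (mean utility by half-open age band and sex). Any
  tariff or norms table with the same schema can be loaded in their place;
  the scoring engine is value-set-agnostic.

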