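# Input file schemas

All tables are UTF-8 CSV with a required header row, comma delimiter
and lowercase snake_case category labels. Unknown labels, malformed
numbers and out-of-range values are rejected with the offending
column, value and line number. Category vocabularies (age bands,
chapters, sexes, locations) come from `config.yaml`.

| file | columns | notes |
|---|---|---|
| `stock.csv` | `year,sex,age_band,location,status,headcount` | base-year rows are selected by `supply.base_year` |
| `hours.csv` | `sex,age_band,status,weekly_hours` | active statuses only; part-time < 35 ≤ full-time |
| `transitions.csv` | `sex,age_band,from_location,from_status,to_location,to_status,probability` | only allowed move kinds; probability ∈ [0,1] |
| `multipliers.csv` | id columns + `multiplier` | annual change per transition |
| `priors.csv` | id columns + `alpha,beta,mult_low,mult_high` | beta shapes > 0; `mult_low ≤ mult_high` |
| `entries.csv` | `year,type,count` | `type` ∈ {graduate, migrant} |
| `allocation.csv` | `type,sex,age_band,location,status,fraction` | fractions sum to 1 per type over active states |
| `targets.csv` | `year,sex,age_band,location,status,headcount` | calibration targets, ≥ 2 years per stratum |
| `population.csv` | `year,sex,age_band,persons` | projection for every scenario year |
| `burden.csv` | `chapter,sex,age_band,incident_cases,prevalent_cases` | chapter labels may be source categories when `mapping.csv` is given |
| `mix.csv` | `chapter,sex,age_band,proportion` | include `prevent_admin` pseudo-chapter rows per cell |
| `lengths.csv` | `sex,age_band,mean_minutes` | mean consultation length |
| `attendances.csv` | `year,sex,age_band,consultations` | base-year rows are used for fitting |
| `mapping.csv` | `source_category,icpc2_chapter` | optional burden-category crosswalk |

`config.yaml` keys: `sexes`, `locations`, `chapters`, `age_bands`
(list of `{label, lower, upper}`, `upper: null` for the open band),
`supply.{base_year, horizon, aging, temp_return_prob}`,
`need.{base_year, horizon}`,
`calibration.{n_samples, tolerance, seed}`,
`hours.{standard_week, working_weeks}`, and `files.*` (paths relative
to the config file).

Stable CLI flags across subcommands: `--seed`, `--tolerance`,
`--n-samples`, `--scenario`, `--out`. Every run writes a
`manifest.json` (config hash, seed, versions) beside its outputs.
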