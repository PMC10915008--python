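# fieldpipe

Data collection and management for plant science experiments: generate
standardized CSV collection templates from an experimental design, harmonize
the heterogeneous measurement files a field season produces, and load the
result into a relational database — all driven by human-readable YAML
configuration, no programming required of the domain scientist.

## The problem

A field or growth-chamber experiment produces data from many sources at once:
hand measurements entered into spreadsheets, the Field Book Android app on a
tablet, and instruments with their own storage (chlorophyll meters, canopy
analyzers, infrared thermometers). Each source exports CSVs with its own
column names and layout — `LAI`, `Leaf Area Index`, `lai`, and
`leaf area index` may all name the same trait across four files. Before any
analysis, someone has to merge dozens of such files, unify their columns,
attach design metadata (genotype, replication, treatment), and store the
result where the whole lab can query it.

fieldpipe covers that path in three stages:

1. **Template creation** — expand a design table (one row per experimental
   unit: plot or pot, replication, genotype, treatment) into a
   data-collection template with one row per *observation* (unit × sample)
   and a unique observation identifier per row, built by concatenating
   configured design-column values and the sample label
   (`plot_treatment_sample`, e.g. `101_WW_1`). The identifier column comes
   first, so the template is directly usable as a Field Book *field file*.
2. **Extract–Transform** — read every CSV in a directory, report shared vs.
   file-specific column names, concatenate, left-join auxiliary metadata,
   unify column spellings via a rename map, drop bookkeeping columns, and
   move the measurement into a standardized long format
   (`value` / `variable` / `units`), keyed by the observation identifier.
3. **Load** — create the database table if needed (`CREATE TABLE IF NOT
   EXISTS`), extend it if needed (`ADD COLUMN IF NOT EXISTS`), and *upsert*
   every row (`INSERT ... ON CONFLICT (pk) DO UPDATE`), so re-loading a
   corrected file updates records in place. SQL is emitted in the PostgreSQL
   dialect with fully parameterized values; an embedded SQLite engine with
   identical upsert semantics runs the same plans locally and in tests.

Every stage is configured by a YAML document made of uppercase *block
collections* (`TEMPLATE_INPUT`, `FILES_TO_PROCESS`, `DATABASE_CREDENTIALS`,
…); validation is total and reports every violation at once. Cell values are
opaque text end to end — plot `007` never becomes the number 7.

## Worked example

Generate a synthetic wheat trial (14 genotypes × 3 replications × 3
environments), run the ETL over the filled templates, and load twice to see
the upsert:

```sh
fieldpipe fixtures make --case wheat --out fixtures --seed 11
head -3 fixtures/templates/wheat_canopy_temperature_C1.csv
```

```
observation_id,plot,rep,genotype,treatment,crop,trait,units,campaign,sample,value
101_WW_1,101,1,G001,WW,wheat,canopy_temperature,C,C1,1,28.09
102_WW_1,102,1,G002,WW,wheat,canopy_temperature,C,C1,1,31.40
```

With an `etl.yml` naming `fixtures/templates` under `FILES_TO_PROCESS`, the
observation id as `PRIMARY_KEY_COLUMN`, and a `MEASUREMENT` block
(`source_column: value`, `variable_name: canopy_temperature`, `units: C`):

```sh
fieldpipe etl run --config etl.yml --out out
# -> out/wheat_canopy_temperature_2022.csv   (126 rows, one per observation)
```

With a `load.yml` pointing at that file (`dialect: sqlite` credentials for a
local database file):

```sh
fieldpipe db load --config load.yml
fieldpipe db load --config load.yml
fieldpipe db sql --config load.yml --statement \
    "SELECT count(*), round(avg(value),2) FROM observations"
```

```
{"inserted": 126, "updated": 0}
{"inserted": 0, "updated": 126}
[[126, 28.1]]
```

The first load inserts all 126 observations; the second hits every primary
key and updates in place — the table still holds exactly 126 rows, whose mean
canopy temperature (28.1 °C) matches the generator's distribution. `fieldpipe
etl inspect` prints the shared/unique column report as JSON before you decide
on transformations, and `fieldpipe db load --dry-run` prints the SQL plan
without touching anything.

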