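# Methods

## Pipeline model

fieldpipe treats an experiment's data flow as three stages with explicit
contracts between them.

**Templates.** The experimental design is a rectangular CSV with one unique
row per experimental unit (plot or pot). A template expands it to one row per
observation — the cross product of design rows and *sample labels*, where a
sample is one repeated measurement on the same unit within a campaign. Each
row receives an observation identifier: the values of the configured
identifier columns joined by `_`, with the sample label always appended as
the final component. The sample suffix guarantees per-sample distinctness;
the identifier columns must jointly distinguish design rows, and the builder
verifies this with a duplicate scan, refusing to emit a template with
colliding identifiers rather than warning. The identifier doubles as the
downstream primary key and as the image filename when the template is used
in a data-collection app, which is why the written CSV puts it first.

**Extract–Transform.** All `*.csv` files in the input directory are read
with all-text cells (empty cell = missing, `pd.NA` in memory) and
concatenated with an outer union of columns; a `_source_file` provenance
column records each row's origin and is dropped at finalization unless
explicitly kept. Transform order is fixed:

1. left-join each auxiliary metadata file on the configured key columns
   (duplicate keys in the auxiliary file are an error — they would multiply
   rows; unmatched working rows keep missing markers and are counted in a
   warning);
2. rename columns (`UPDATE_COLUMN_NAMES`), then drop, then add constants;
3. standardize the measurement: move the single source column into `value`
   and tag constant `variable` and `units` columns;
4. rewrite primary-key substrings and whole-cell row values;
5. assert the output invariants and write one CSV.

Renames run *before* measurement standardization, a deliberate ordering:
when four files spell the same trait four ways, the rename map must first
unify them into the one column the measurement block names. Every column
name in a later block therefore refers to the post-rename name. When several
old names map to one new name, the columns merge cell-wise with
`combine_first`; in well-formed inputs (each file uses one spelling) the
cells never overlap.

Key rewriting is literal substring replacement applied in document order —
not regex — because the use case is fixing label conventions
(`PLT` → `PLOT`), and a replacement that makes two keys equal aborts with
the colliding keys listed. Row-value rules match whole cells only, so a
genotype named `EP-12` survives a `EP → early_planting` treatment recode.

The finalized table must have a present, non-missing, duplicate-free primary
key, and every row carrying a value must carry variable and units. One
measurement variable per run is a contract, not an accident: multivariable
files need one pass per variable because the observation identifier is
per-measurement-event.

**Load.** Three statement generators produce the SQL surface:
`build_create_table_statement` (CREATE TABLE IF NOT EXISTS with a
primary-key constraint), `build_add_column_statements` (one ADD COLUMN IF
NOT EXISTS per entry), and `build_upsert_plan` (per-row
`INSERT ... ON CONFLICT (pk) DO UPDATE SET col = EXCLUDED.col`). Plans are
PostgreSQL-dialect text with `%s` placeholders; data values are always bound
parameters, never interpolated, which is what makes hostile cell contents
(quotes, semicolons, SQL keywords) round-trip verbatim. One file loads in
one transaction: any failure — an uncoercible cell, a constraint violation —
rolls back the entire file, since a half-loaded table is worse for
downstream dashboards than a failed load.

The engine seam has two implementations. `PostgresEngine` wraps psycopg2 (an
optional extra). `SqliteEngine` executes the same plans against stdlib
SQLite: `%s` becomes `?`, `ADD COLUMN IF NOT EXISTS` (absent from SQLite) is
emulated with a catalog check, and the primary-key column is declared
NOT NULL explicitly because SQLite — unlike PostgreSQL — does not imply it,
which would otherwise weaken the constraint behaviour the tests rely on.
SQLite's `ON CONFLICT ... DO UPDATE` already has the PostgreSQL semantics.
The load summary counts a conflicting key as *updated* whether or not the
row actually changed; change detection would require a read-back per row for
little benefit.

## Configuration

Documents are parsed with a YAML loader that keeps every scalar a string;
only the sample count and the port are coerced to integers. This is a data
integrity choice: plot `007`, genotype `2022-A`, and date-like strings must
survive untouched. Unknown block names are hard errors with a
nearest-known-name hint, because a silently ignored typo in an uppercase
block name is the dominant user error. Validation collects all violations
before failing, and a validated config serializes back to YAML and
re-validates to an equal object.

`SAMPLES_PER_PLOT` accepts either an integer count *n* (labels `"1"`..`"n"`,
unpadded) or an explicit label sequence. `OUTPUT_FILE_NAME` and
`TEMPLATE_OUTPUT` are optional; when empty, outputs get a timestamped
default name from an injectable clock, which keeps file emission
deterministic under test.

The optional `MEASUREMENT` block (`source_column`, `variable_name`,
`units`) is this package's own addition to the Extract-Transform schema: it
makes the long-format standardization configurable instead of hard-coded.
The canonical output column names `value`, `variable`, `units` are likewise
this package's convention.

## Synthetic data

The fixtures module generates three preset experiments: a soybean trial
(25 genotypes × 4 replications × 2 planting treatments, 200 plots), a wheat
trial (14 × 3 × 3 environments, 126 plots), and a rice chamber experiment
(6 genotypes × 2 CO₂ × 2 drought × 2 replications, 48 pots). Trait values
are draws from per-variable normal distributions (e.g. canopy temperature
28 ± 2.5 °C) — generic by design, since the pipeline's correctness depends
on table structure, keys and headers, not on trait biology. Device exports
reproduce the structural pathologies of real instrument files — divergent
measurement spellings cycling across files, bookkeeping columns, optionally
no identifier column — without being byte-faithful to any vendor format.
All generators are seeded (`numpy.random.default_rng`); one seed gives
byte-identical files.

Consequently, passing tests demonstrate the data-handling contracts
(identifier uniqueness, row conservation, header unification, upsert and
rollback semantics), not robustness to the full messiness of field data:
encodings other than UTF-8, embedded newlines from spreadsheet exports,
or semi-structured instrument preambles are out of scope.

## Problem sizes and numerical choices

Tests and the acceptance script run the scenarios at their natural scale —
the 42-file merge covers 1 764 observation rows, the upsert oracle replays
about 1 000 random single-row operations in batches against a plain
`dict` reference — which completes in seconds on one core. Type coercion at
load time is strict: integers must match `^[+-]?[0-9]+$`, empty cells become
SQL NULL, and failures name the row and column instead of truncating.
Identifiers are sanitized to lowercase snake_case with a collision check,
avoiding dialect case-folding surprises. File discovery sorts
lexicographically so a run is independent of directory enumeration order.

## Known limitations

- One measurement variable per Extract–Transform run (by contract).
- No Excel ingestion, no unit conversion, no QA/QC analytics — quality
  control happens between Transform and Load, outside the tool.
- The join with auxiliary files is a left join; rows without metadata pass
  through with missing markers rather than being dropped.
- No schema-migration framework: `NEW_COLUMNS_IF_TABLE_EXISTS` adds columns,
  nothing renames or retypes them.
- The PostgreSQL path requires psycopg2 and a reachable server; it shares
  all plan-construction code with the embedded engine but is not exercised
  by the test suite.
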