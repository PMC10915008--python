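"""Extract and Transform: harmonize heterogeneous measurement CSVs into one long table.

The stage reads every CSV in a directory (filled collection templates,
lab spreadsheets, instrument exports), reports which header names are
shared and which are file-specific, concatenates everything into one
working table, optionally joins auxiliary metadata (e.g. genotype names
keyed by plot), moves the measurement values into a canonical
``value``/``variable``/``units`` triple, and applies the configured
column and row transformations.  The result is a single standardized
CSV whose primary-key column is duplicate-free — ready for quality
control and for the Load stage.

Missing data are empty cells on disk and ``pd.NA`` in memory.  Header
matching is exact after trimming surrounding whitespace; case variants
("LAI" vs "lai") are unified only through the explicit
``UPDATE_COLUMN_NAMES`` rename map.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from fieldpipe.config_schema import EtlConfig
from fieldpipe.errors import DataError

logger = logging.getLogger(__name__)

#: Provenance column recording the source filename of each row.
SOURCE_COLUMN = "_source_file"

#: Canonical long-format columns.
VALUE_COLUMN = "value"
VARIABLE_COLUMN = "variable"
UNITS_COLUMN = "units"

Clock = Callable[[], datetime.datetime]


@dataclass
class ColumnReport:
    """Shared vs. file-specific header names across an input file set."""

    shared: set[str]
    per_file_unique: dict[str, set[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "shared": sorted(self.shared),
                "per_file_unique": {f: sorted(s) for f, s in sorted(self.per_file_unique.items())},
            },
            indent=2,
        )


def discover_input_files(directory: str | Path) -> list[Path]:
    """All ``*.csv`` files in the directory, sorted lexicographically for determinism."""
    directory = Path(directory)
    if not directory.is_dir():
        raise DataError(f"input directory not found: {directory}")
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".csv" and p.is_file())
    if not files:
        raise DataError(f"no CSV files to extract in {directory}")
    return files


def _read_csv(path: Path, delimiter: str = ",") -> pd.DataFrame:
    """Read one CSV with all-text cells; empty cells become pd.NA."""
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, sep=delimiter, encoding="utf-8-sig")
    except Exception as exc:
        raise DataError(f"cannot read {path}: {exc}") from exc
    frame.columns = [str(c).strip() for c in frame.columns]
    return frame.mask(frame == "", pd.NA)


def column_report(files: Sequence[str | Path], delimiter: str = ",") -> ColumnReport:
    """Compare header names across files: which are shared by all, which are not.

    ``shared`` holds names present in every file; ``per_file_unique``
    maps each filename to its names that are absent from at least one
    other file.  The two partitions cover the union of all headers.
    """
    headers: dict[str, set[str]] = {}
    for path in files:
        path = Path(path)
        frame = _read_csv(path, delimiter=delimiter)
        headers[path.name] = set(frame.columns)
    shared = set.intersection(*headers.values()) if headers else set()
    per_file_unique = {name: cols - shared for name, cols in headers.items()}
    return ColumnReport(shared=shared, per_file_unique=per_file_unique)


def concatenate_files(files: Sequence[str | Path], delimiter: str = ",") -> pd.DataFrame:
    """Concatenate all files into one working table.

    Columns with shared names are combined; file-specific columns are
    retained with missing markers where a source lacks them.  A
    provenance column records each row's source filename.
    """
    parts = []
    for path in files:
        path = Path(path)
        frame = _read_csv(path, delimiter=delimiter)
        frame[SOURCE_COLUMN] = path.name
        parts.append(frame)
    work = pd.concat(parts, ignore_index=True, sort=False)
    return work


def join_additional_info(
    work: pd.DataFrame,
    extra: str | Path,
    keys: Sequence[str],
    delimiter: str = ",",
) -> pd.DataFrame:
    """Left-join an auxiliary metadata file (e.g. a genotype lookup) onto the working table.

    The row count never changes; unmatched working rows keep missing
    markers (a warning counts them).  Duplicate key combinations in the
    auxiliary file would multiply rows and are an error.
    """
    extra = Path(extra)
    lookup = _read_csv(extra, delimiter=delimiter)
    keys = [str(k).strip() for k in keys]
    if not keys:
        raise DataError("JOIN_FILES_COMMON_COLUMNS is empty; cannot join additional information")
    for k in keys:
        if k not in work.columns:
            raise DataError(f"join column {k!r} not present in the working table")
        if k not in lookup.columns:
            raise DataError(f"join column {k!r} not present in {extra.name}")
    dup = lookup.duplicated(subset=keys, keep=False)
    if dup.any():
        offending = lookup.loc[dup, keys].astype(str).agg("/".join, axis=1).unique()
        raise DataError(
            f"duplicate key combination(s) in {extra.name}: {', '.join(sorted(offending)[:5])}"
        )
    before = len(work)
    joined = work.merge(lookup, how="left", on=keys, suffixes=("", "_extra"))
    assert len(joined) == before  # unique-key left join preserves row count
    new_cols = [c for c in lookup.columns if c not in keys]
    if new_cols:
        unmatched = int(joined[new_cols].isna().all(axis=1).sum())
        if unmatched:
            logger.warning("%d row(s) had no match in %s", unmatched, extra.name)
    return joined


def standardize_measurement(work: pd.DataFrame, measurement: Mapping[str, str]) -> pd.DataFrame:
    """Move the measurement values into the canonical value column and tag variable/units.

    One variable per run: files holding several measurement columns
    must be processed in separate runs (the observation identifier would
    otherwise stop being unique per row).  An empty measurement mapping
    is a no-op.
    """
    if not measurement:
        return work
    source = measurement.get("source_column", "")
    if isinstance(source, (list, tuple)):
        raise DataError(
            "only one measurement column may be standardized per run; "
            "process multivariable files as separate steps"
        )
    if source not in work.columns:
        raise DataError(f"measurement source column {source!r} not present in the working table")
    out = work.copy()
    if VALUE_COLUMN in out.columns and source != VALUE_COLUMN:
        if out[VALUE_COLUMN].notna().any():
            raise DataError(
                f"column {VALUE_COLUMN!r} already present with data; cannot standardize {source!r} into it"
            )
        out = out.drop(columns=[VALUE_COLUMN])
    if source != VALUE_COLUMN:
        out = out.rename(columns={source: VALUE_COLUMN})
    out[VARIABLE_COLUMN] = measurement["variable_name"]
    out[UNITS_COLUMN] = measurement["units"]
    return out


def apply_column_transforms(work: pd.DataFrame, config: EtlConfig) -> pd.DataFrame:
    """Apply the column-level transforms in fixed order: rename, drop, add constants.

    Untouched columns keep their values byte-identical.  Renaming onto a
    name that already exists (and is not itself renamed away) merges the
    columns cell-wise only when that name is a rename target from
    several sources — the header-unification case; a collision with an
    untouched existing column is an error.
    """
    out = work.copy()
    renames = {old: new for old, new in config.update_column_names.items() if old in out.columns}
    untouched = set(out.columns) - set(renames)
    merge_groups: dict[str, list[str]] = {}
    for old, new in renames.items():
        merge_groups.setdefault(new, []).append(old)
    for new, olds in merge_groups.items():
        if new in untouched and new not in olds:
            raise DataError(
                f"rename target {new!r} collides with an existing column; rename or drop it first"
            )
    for new, olds in merge_groups.items():
        # several divergent spellings unify into one column; cells never overlap
        # across well-formed inputs, later sources fill gaps left by earlier ones
        merged = out[olds[0]]
        for other in olds[1:]:
            merged = merged.combine_first(out[other])
        out = out.drop(columns=[c for c in olds if c != new])
        out[new] = merged
    for col in config.columns_to_drop:
        if col in out.columns:
            out = out.drop(columns=[col])
        else:
            logger.warning("COLUMNS_TO_DROP names %r, not present; skipped", col)
    for name, value in config.new_columns.items():
        out[name] = value
    return out


def update_keys_and_rows(work: pd.DataFrame, config: EtlConfig) -> pd.DataFrame:
    """Rewrite primary-key substrings and whole-cell row values.

    Key replacements are literal substrings applied in document order;
    a replacement that makes two keys equal is an error.  Row-value
    replacements match whole cells only, so genotype names are never
    partially corrupted.
    """
    out = work.copy()
    if config.update_primary_key_values:
        pk = config.primary_key_column
        if not pk or pk not in out.columns:
            raise DataError(
                f"UPDATE_PRIMARY_KEY_VALUES requires PRIMARY_KEY_COLUMN naming a present column (got {pk!r})"
            )
        keys = out[pk].astype("string")
        for old, new in config.update_primary_key_values.items():
            keys = keys.str.replace(old, new, regex=False)
        collisions = keys[keys.duplicated(keep=False) & keys.notna()]
        if not collisions.empty:
            raise DataError(
                "primary-key replacement creates duplicate keys: "
                + ", ".join(sorted(set(collisions))[:5])
            )
        out[pk] = keys
    for col, rules in config.update_row_values.items():
        if col not in out.columns:
            logger.warning("UPDATE_ROW_VALUES names %r, not present; skipped", col)
            continue
        out[col] = out[col].map(lambda cell: rules.get(cell, cell) if pd.notna(cell) else cell)
    return out


def finalize_standard_table(
    work: pd.DataFrame,
    config: EtlConfig,
    out_dir: str | Path,
    keep_source: bool = False,
    clock: Clock | None = None,
) -> Path:
    """Assert the standardized-table invariants and write the output CSV.

    The primary-key column must be present, non-missing and
    duplicate-free; rows carrying a value must carry variable and units.
    The filename joins the ``OUTPUT_FILE_NAME`` components, or falls
    back to a timestamped default.
    """
    pk = config.primary_key_column
    if not pk:
        raise DataError("PRIMARY_KEY_COLUMN is required to finalize the standardized table")
    if pk not in work.columns:
        raise DataError(f"primary-key column {pk!r} not present in the working table")
    keys = work[pk]
    if keys.isna().any():
        raise DataError(f"primary-key column {pk!r} has {int(keys.isna().sum())} missing value(s)")
    dup = keys[keys.duplicated()]
    if not dup.empty:
        raise DataError("duplicate primary-key values: " + ", ".join(sorted(set(dup.astype(str)))[:5]))
    if VALUE_COLUMN in work.columns:
        has_value = work[VALUE_COLUMN].notna()
        for col in (VARIABLE_COLUMN, UNITS_COLUMN):
            if col not in work.columns:
                raise DataError(f"value column present but {col!r} column missing; configure MEASUREMENT")
            bad = int((has_value & work[col].isna()).sum())
            if bad:
                raise DataError(f"{bad} row(s) carry a value but no {col}")

    out = work if keep_source else work.drop(columns=[SOURCE_COLUMN], errors="ignore")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.output_file_name:
        name = "_".join(config.output_file_name) + ".csv"
    else:
        now = (clock or datetime.datetime.now)()
        name = f"standardized_{now.strftime('%Y%m%d-%H%M%S')}.csv"
    path = out_dir / name
    out.to_csv(path, index=False, na_rep="", lineterminator="\n")
    return path


def run_etl(
    config: EtlConfig,
    out_dir: str | Path,
    keep_source: bool = False,
    delimiter: str = ",",
    clock: Clock | None = None,
) -> Path:
    """Run the whole Extract-Transform sequence and return the written output path.

    Order: discover files, concatenate, join auxiliary metadata,
    rename/drop/add columns, standardize the measurement, rewrite keys
    and row values, finalize.  Renames run before standardization so a
    rename map can first unify divergent measurement spellings into the
    single source column the measurement block names; every name in
    later blocks refers to the post-rename name.
    """
    files = discover_input_files(config.files_to_process)
    work = concatenate_files(files, delimiter=delimiter)
    for label, extra in config.additional_information_files.items():
        logger.info("joining additional information %r from %s", label, extra)
        work = join_additional_info(work, extra, config.join_common_columns, delimiter=delimiter)
    work = apply_column_transforms(work, config)
    work = standardize_measurement(work, config.measurement)
    work = update_keys_and_rows(work, config)
    return finalize_standard_table(work, config, out_dir, keep_source=keep_source, clock=clock)
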