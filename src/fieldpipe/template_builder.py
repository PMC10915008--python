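"""Generate per-observation data-collection templates from an experimental design.

The design table holds one row per experimental unit (a field plot or a
pot): plot number, replication, genotype, treatment, and any other
design metadata.  The builder expands it into a collection template with
one row per (experimental unit x sample), where a *sample* is one of
several repeated measurements on the same unit within a campaign.  Each
row carries a unique observation identifier built by concatenating
configured design-column values and the sample label; that identifier is
the primary-key candidate for everything downstream, and doubles as the
image filename when the template is used as a Field Book field file.

Cell values are opaque text end to end: nothing is coerced to numbers,
so plot "007" and genotype names with leading zeros survive verbatim.
"""

from __future__ import annotations

import csv
import datetime
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from fieldpipe.config_schema import TemplateConfig
from fieldpipe.errors import DataError

logger = logging.getLogger(__name__)

#: Delimiter joining observation-identifier components.
ID_DELIMITER = "_"

#: Default column names added by the builder.
SAMPLE_COLUMN = "sample"
ID_COLUMN = "observation_id"
VALUE_COLUMN = "value"

Clock = Callable[[], datetime.datetime]


@dataclass
class DesignTable:
    """The experimental-design input: unique header, one unique row per unit."""

    columns: list[str]
    frame: pd.DataFrame  # all-string cells, in file order

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class TemplateTable:
    """A generated data-collection sheet (design columns + metadata + id + empty value)."""

    frame: pd.DataFrame
    id_column: str = ID_COLUMN
    sample_column: str = SAMPLE_COLUMN
    value_column: str = VALUE_COLUMN
    broadcast_columns: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)


def read_design_table(path: str | Path) -> DesignTable:
    """Parse a design CSV: header row first, values kept verbatim as text.

    Raises :class:`DataError` on an empty file, duplicate header names
    (after whitespace trimming) or ragged rows, naming the offender.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8-sig") as fh:
        reader = csv.reader(fh)
        try:
            raw_header = next(reader)
        except StopIteration:
            raise DataError(f"design file {path} is empty") from None
        header = [h.strip() for h in raw_header]
        seen: set[str] = set()
        for name in header:
            if name in seen:
                raise DataError(f"duplicate column name {name!r} in design file {path}")
            seen.add(name)
        rows: list[list[str]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:  # blank line
                continue
            if len(row) != len(header):
                raise DataError(
                    f"ragged row at line {lineno} of {path}: expected {len(header)} cells, found {len(row)}"
                )
            rows.append([c for c in row])
    frame = pd.DataFrame(rows, columns=header, dtype=str)
    return DesignTable(columns=header, frame=frame)


def make_observation_id(
    row: Mapping[str, str],
    id_columns: Sequence[str],
    sample_label: str,
    delimiter: str = ID_DELIMITER,
) -> str:
    """Build one observation identifier: id-column values then the sample label, joined.

    Pure function of its inputs; the sample label is always the final
    component, which guarantees per-sample distinctness.
    """
    parts = []
    for col in id_columns:
        if col not in row:
            raise DataError(f"identifier column {col!r} not found in row")
        parts.append(str(row[col]))
    parts.append(str(sample_label))
    return delimiter.join(parts)


def build_template(design: DesignTable, config: TemplateConfig) -> TemplateTable:
    """Expand a design into a collection template, one row per (unit x sample).

    Column order: the retained design columns, then the broadcast
    constants from ``NEW_COLUMNS``, the sample-label column, the
    observation-id column, and one empty value column.  Rows follow
    design-file order with the sample label cycling fastest.
    """
    for col in config.columns_template:
        if col not in design.columns:
            raise DataError(f"COLUMNS_TEMPLATE names {col!r}, not a design column")

    keep = list(config.columns_template) if config.columns_template else list(design.columns)
    available = set(keep) | set(config.new_columns) | {SAMPLE_COLUMN}
    for col in config.sample_identifier:
        if col not in available and col not in design.columns:
            raise DataError(f"SAMPLE_IDENTIFIER names {col!r}, not a design, new, or sample column")

    records: list[dict[str, str]] = []
    for _, design_row in design.frame.iterrows():
        base = {col: design_row[col] for col in keep}
        full = {**{c: design_row[c] for c in design.columns}, **config.new_columns}
        for label in config.sample_labels:
            rec = dict(base)
            rec.update(config.new_columns)
            rec[SAMPLE_COLUMN] = label
            id_source = {**full, SAMPLE_COLUMN: label}
            id_cols = [c for c in config.sample_identifier if c != SAMPLE_COLUMN]
            rec[ID_COLUMN] = make_observation_id(id_source, id_cols, label)
            rec[VALUE_COLUMN] = ""
            records.append(rec)

    columns = keep + list(config.new_columns) + [SAMPLE_COLUMN, ID_COLUMN, VALUE_COLUMN]
    frame = pd.DataFrame(records, columns=columns, dtype=str) if records else pd.DataFrame(columns=columns, dtype=str)

    ids = frame[ID_COLUMN]
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise DataError(
            "observation-id collision: "
            + ", ".join(sorted(set(dup))[:5])
            + "; add more columns to SAMPLE_IDENTIFIER"
        )
    return TemplateTable(frame=frame, broadcast_columns=list(config.new_columns))


_SAFE = re.compile(r"[^A-Za-z0-9_-]")


def render_output_name(
    template: TemplateTable,
    config: TemplateConfig,
    clock: Clock | None = None,
) -> str:
    """Compose the output filename from first-row values of the TEMPLATE_OUTPUT columns.

    Characters outside ``[A-Za-z0-9_-]`` become ``-``.  An empty
    TEMPLATE_OUTPUT falls back to a timestamped default (deterministic
    under an injected ``clock``).
    """
    if not config.template_output:
        now = (clock or datetime.datetime.now)()
        return f"template_{now.strftime('%Y%m%d-%H%M%S')}.csv"
    parts = []
    for col in config.template_output:
        if col not in template.frame.columns:
            raise DataError(f"TEMPLATE_OUTPUT names {col!r}, not a template column")
        values = template.frame[col]
        if values.nunique(dropna=False) > 1:
            logger.warning("TEMPLATE_OUTPUT column %r is not constant; using first-row value", col)
        parts.append(_SAFE.sub("-", str(values.iloc[0])))
    return ID_DELIMITER.join(parts) + ".csv"


def write_template(
    template: TemplateTable,
    directory: str | Path,
    config: TemplateConfig,
    overwrite: bool = False,
    clock: Clock | None = None,
) -> Path:
    """Write the template CSV with the observation-id column first.

    The id-first layout satisfies the Field Book field-file requirement
    of a leading unique-identifier column.  Refuses to clobber an
    existing file unless ``overwrite`` is set.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = render_output_name(template, config, clock=clock)
    out = directory / name
    if out.exists() and not overwrite:
        raise DataError(f"refusing to overwrite existing file {out}; pass overwrite to replace it")
    ordered = [template.id_column] + [c for c in template.frame.columns if c != template.id_column]
    template.frame[ordered].to_csv(out, index=False, lineterminator="\n")
    return out
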