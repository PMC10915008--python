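"""Parse and validate the YAML configuration documents driving the pipeline.

Every configuration document is a collection of *blocks*: top-level
sections named in uppercase (``TEMPLATE_INPUT``, ``FILES_TO_PROCESS``,
...), each holding a mapping of key/value pairs, a sequence of scalars,
or nothing.  Three document kinds exist:

``template``
    drives the template builder (6 blocks),
``etl``
    drives the Extract-Transform stage (10 blocks, plus the optional
    ``MEASUREMENT`` block for long-format standardization),
``load``
    drives the database Load stage (6 blocks, 4 of them required).

Scalars are kept as *text* throughout — a plot labelled ``007`` must not
come back as the integer 7 — except where the schema itself demands an
integer (a sample count, a port number).  Validation is total: a document
either yields exactly one config object or a :class:`ConfigError`
carrying every violation found; never a partially populated config.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from fieldpipe.errors import ConfigError, ValidationIssue

# Canonical block names, in document order.
TEMPLATE_BLOCKS: tuple[str, ...] = (
    "TEMPLATE_INPUT",
    "COLUMNS_TEMPLATE",
    "NEW_COLUMNS",
    "SAMPLES_PER_PLOT",
    "SAMPLE_IDENTIFIER",
    "TEMPLATE_OUTPUT",
)

ETL_EXTRACT_TRANSFORM_BLOCKS: tuple[str, ...] = (
    "FILES_TO_PROCESS",
    "ADDITIONAL_INFORMATION_FILES",
    "JOIN_FILES_COMMON_COLUMNS",
    "COLUMNS_TO_DROP",
    "UPDATE_COLUMN_NAMES",
    "NEW_COLUMNS",
    "PRIMARY_KEY_COLUMN",
    "UPDATE_PRIMARY_KEY_VALUES",
    "UPDATE_ROW_VALUES",
    "OUTPUT_FILE_NAME",
)

LOAD_BLOCKS: tuple[str, ...] = (
    "DATABASE_CREDENTIALS",
    "TABLE_NAME",
    "NEW_TABLE_COLUMNS",
    "NEW_COLUMNS_IF_TABLE_EXISTS",
    "FILE_TO_UPLOAD",
    "PRIMARY_KEY_COLUMN",
)

# Optional block introduced by this package: makes the variable/units
# standardization of the long format configurable.
MEASUREMENT_BLOCK = "MEASUREMENT"

_KINDS = {
    "template": TEMPLATE_BLOCKS,
    "etl_extract_transform": ETL_EXTRACT_TRANSFORM_BLOCKS,
    "load": LOAD_BLOCKS,
}


def list_schema_blocks(kind: str) -> tuple[str, ...]:
    """Return the canonical ordered block names for a schema group.

    ``kind`` is one of ``template``, ``etl_extract_transform``, ``load``.
    """
    try:
        return _KINDS[kind]
    except KeyError:
        raise ConfigError(
            [ValidationIssue("-", "kind", f"unknown schema kind {kind!r}; expected one of {sorted(_KINDS)}")]
        ) from None


@dataclass
class TemplateConfig:
    """Validated template-builder configuration."""

    template_input: str
    columns_template: list[str] = field(default_factory=list)
    new_columns: dict[str, str] = field(default_factory=dict)
    sample_labels: list[str] = field(default_factory=lambda: ["1"])
    sample_identifier: list[str] = field(default_factory=list)
    template_output: list[str] = field(default_factory=list)

    def to_yaml(self) -> str:
        doc: dict[str, Any] = {
            "TEMPLATE_INPUT": self.template_input,
            "COLUMNS_TEMPLATE": list(self.columns_template),
            "NEW_COLUMNS": dict(self.new_columns),
            "SAMPLES_PER_PLOT": list(self.sample_labels),
            "SAMPLE_IDENTIFIER": list(self.sample_identifier),
            "TEMPLATE_OUTPUT": list(self.template_output),
        }
        return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)


@dataclass
class EtlConfig:
    """Validated Extract-Transform configuration."""

    files_to_process: str
    additional_information_files: dict[str, str] = field(default_factory=dict)
    join_common_columns: list[str] = field(default_factory=list)
    columns_to_drop: list[str] = field(default_factory=list)
    update_column_names: dict[str, str] = field(default_factory=dict)
    new_columns: dict[str, str] = field(default_factory=dict)
    primary_key_column: str = ""
    update_primary_key_values: dict[str, str] = field(default_factory=dict)
    update_row_values: dict[str, dict[str, str]] = field(default_factory=dict)
    output_file_name: list[str] = field(default_factory=list)
    measurement: dict[str, str] = field(default_factory=dict)

    def to_yaml(self) -> str:
        doc: dict[str, Any] = {
            "FILES_TO_PROCESS": self.files_to_process,
            "ADDITIONAL_INFORMATION_FILES": dict(self.additional_information_files),
            "JOIN_FILES_COMMON_COLUMNS": list(self.join_common_columns),
            "COLUMNS_TO_DROP": list(self.columns_to_drop),
            "UPDATE_COLUMN_NAMES": dict(self.update_column_names),
            "NEW_COLUMNS": dict(self.new_columns),
            "PRIMARY_KEY_COLUMN": [self.primary_key_column] if self.primary_key_column else [],
            "UPDATE_PRIMARY_KEY_VALUES": dict(self.update_primary_key_values),
            "UPDATE_ROW_VALUES": {k: dict(v) for k, v in self.update_row_values.items()},
            "OUTPUT_FILE_NAME": list(self.output_file_name),
        }
        if self.measurement:
            doc[MEASUREMENT_BLOCK] = dict(self.measurement)
        return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)


@dataclass
class LoadConfig:
    """Validated database Load configuration."""

    credentials: dict[str, str]
    table_name: str
    file_to_upload: str
    primary_key_column: str
    new_table_columns: dict[str, str] = field(default_factory=dict)
    new_columns_if_table_exists: dict[str, str] = field(default_factory=dict)

    def to_yaml(self) -> str:
        doc: dict[str, Any] = {
            "DATABASE_CREDENTIALS": dict(self.credentials),
            "TABLE_NAME": [self.table_name],
            "NEW_TABLE_COLUMNS": dict(self.new_table_columns),
            "NEW_COLUMNS_IF_TABLE_EXISTS": dict(self.new_columns_if_table_exists),
            "FILE_TO_UPLOAD": self.file_to_upload,
            "PRIMARY_KEY_COLUMN": [self.primary_key_column],
        }
        return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)


# ---------------------------------------------------------------------------
# payload coercion helpers — all operate on yaml.BaseLoader output, where
# every scalar is already a string.

def _as_scalar(value: Any, block: str, issues: list[ValidationIssue], key: str = "") -> str:
    if value is None:
        return ""
    if isinstance(value, str):
        return value.strip()
    if isinstance(value, Mapping):
        # single-entry mappings like {path: x} / {path: d, file_name: f}
        parts = [str(v).strip() for v in value.values() if v is not None and str(v).strip()]
        if "path" in value and "file_name" in value:
            return str(Path(str(value["path"]).strip()) / str(value["file_name"]).strip())
        if len(parts) == 1:
            return parts[0]
    if isinstance(value, Sequence) and not isinstance(value, str):
        items = [str(v).strip() for v in value if v is not None]
        if len(items) <= 1:
            return items[0] if items else ""
    issues.append(ValidationIssue(block, key, "expected a single scalar value"))
    return ""


def _as_sequence(value: Any, block: str, issues: list[ValidationIssue]) -> list[str]:
    if value is None:
        return []
    if isinstance(value, str):
        return [value.strip()] if value.strip() else []
    if isinstance(value, Mapping):
        issues.append(ValidationIssue(block, "", "expected a sequence of scalars, got a mapping"))
        return []
    out: list[str] = []
    for i, item in enumerate(value):
        if item is None or isinstance(item, (Mapping, list)):
            issues.append(ValidationIssue(block, str(i), "sequence items must be scalars"))
        else:
            out.append(str(item).strip())
    return out


def _as_mapping(value: Any, block: str, issues: list[ValidationIssue]) -> dict[str, str]:
    if value is None:
        return {}
    if not isinstance(value, Mapping):
        issues.append(ValidationIssue(block, "", "expected a mapping of key: value pairs"))
        return {}
    out: dict[str, str] = {}
    for k, v in value.items():
        if isinstance(v, (Mapping, list)):
            issues.append(ValidationIssue(block, str(k), "values must be scalars"))
        else:
            out[str(k).strip()] = "" if v is None else str(v).strip()
    return out


def _as_nested_mapping(value: Any, block: str, issues: list[ValidationIssue]) -> dict[str, dict[str, str]]:
    if value is None:
        return {}
    if not isinstance(value, Mapping):
        issues.append(ValidationIssue(block, "", "expected a mapping of column: {old: new} pairs"))
        return {}
    out: dict[str, dict[str, str]] = {}
    for col, rules in value.items():
        if not isinstance(rules, Mapping):
            issues.append(ValidationIssue(block, str(col), "expected a mapping of old: new replacements"))
            continue
        out[str(col).strip()] = {str(a).strip(): ("" if b is None else str(b).strip()) for a, b in rules.items()}
    return out


def _as_int(value: str, block: str, key: str, issues: list[ValidationIssue]) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        issues.append(ValidationIssue(block, key, f"expected an integer, got {value!r}"))
        return 0


def _check_block_names(doc: Mapping[str, Any], known: Sequence[str], issues: list[ValidationIssue]) -> None:
    for name in doc:
        if not isinstance(name, str) or not name or not all(c.isupper() or c == "_" for c in name) or name[0] == "_":
            issues.append(ValidationIssue(str(name), "", "block names must be uppercase tokens matching ^[A-Z][A-Z_]*$"))
            continue
        if name not in known:
            hint = difflib.get_close_matches(name, known, n=1)
            msg = f"unknown block {name!r}"
            if hint:
                msg += f"; did you mean {hint[0]!r}?"
            issues.append(ValidationIssue(name, "", msg))


def _read_yaml(path: str | Path) -> dict[str, Any]:
    p = Path(path)
    if not p.exists():
        raise ConfigError([ValidationIssue("-", "path", f"configuration file not found: {p}")])
    try:
        # BaseLoader keeps every scalar a string: plot "007" survives.
        doc = yaml.load(p.read_text(encoding="utf-8"), Loader=yaml.BaseLoader)
    except yaml.YAMLError as exc:
        raise ConfigError([ValidationIssue("-", "yaml", f"malformed YAML: {exc}")]) from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise ConfigError([ValidationIssue("-", "yaml", "top level must be a mapping of BLOCK_NAME: payload")])
    return dict(doc)


# ---------------------------------------------------------------------------
# per-kind validators

def _validate_template(doc: Mapping[str, Any]) -> TemplateConfig:
    issues: list[ValidationIssue] = []
    _check_block_names(doc, TEMPLATE_BLOCKS, issues)

    if "TEMPLATE_INPUT" not in doc:
        issues.append(ValidationIssue("TEMPLATE_INPUT", "", "required block is missing"))
    template_input = _as_scalar(doc.get("TEMPLATE_INPUT"), "TEMPLATE_INPUT", issues)
    if "TEMPLATE_INPUT" in doc and not template_input:
        issues.append(ValidationIssue("TEMPLATE_INPUT", "", "must name the design CSV file"))

    columns_template = _as_sequence(doc.get("COLUMNS_TEMPLATE"), "COLUMNS_TEMPLATE", issues)
    new_columns = _as_mapping(doc.get("NEW_COLUMNS"), "NEW_COLUMNS", issues)
    sample_labels = _parse_samples(doc.get("SAMPLES_PER_PLOT"), issues)
    sample_identifier = _as_sequence(doc.get("SAMPLE_IDENTIFIER"), "SAMPLE_IDENTIFIER", issues)
    template_output = _as_sequence(doc.get("TEMPLATE_OUTPUT"), "TEMPLATE_OUTPUT", issues)

    if not sample_identifier:
        issues.append(ValidationIssue("SAMPLE_IDENTIFIER", "", "at least one identifier column is required"))
    if not sample_labels:
        issues.append(ValidationIssue("SAMPLES_PER_PLOT", "", "effective sample count must be >= 1"))

    if issues:
        raise ConfigError(issues)
    return TemplateConfig(
        template_input=template_input,
        columns_template=columns_template,
        new_columns=new_columns,
        sample_labels=sample_labels,
        sample_identifier=sample_identifier,
        template_output=template_output,
    )


def _parse_samples(value: Any, issues: list[ValidationIssue]) -> list[str]:
    """SAMPLES_PER_PLOT: an integer count n (labels "1".."n") or an explicit label sequence."""
    block = "SAMPLES_PER_PLOT"
    if value is None:
        return ["1"]
    if isinstance(value, str):
        n = _as_int(value, block, "", issues)
        return [str(i) for i in range(1, n + 1)] if n >= 1 else []
    if isinstance(value, Mapping):
        if len(value) == 1:
            n = _as_int(_as_scalar(value, block, issues), block, next(iter(value)), issues)
            return [str(i) for i in range(1, n + 1)] if n >= 1 else []
        issues.append(ValidationIssue(block, "", "expected a single count key or a sequence of labels"))
        return []
    labels = _as_sequence(value, block, issues)
    if len(set(labels)) != len(labels):
        issues.append(ValidationIssue(block, "", "sample labels must be distinct"))
    return labels


def _validate_etl(doc: Mapping[str, Any]) -> EtlConfig:
    issues: list[ValidationIssue] = []
    known = ETL_EXTRACT_TRANSFORM_BLOCKS + (MEASUREMENT_BLOCK,)
    _check_block_names(doc, known, issues)

    if "FILES_TO_PROCESS" not in doc:
        issues.append(ValidationIssue("FILES_TO_PROCESS", "", "required block is missing"))
    files_to_process = _as_scalar(doc.get("FILES_TO_PROCESS"), "FILES_TO_PROCESS", issues)
    if "FILES_TO_PROCESS" in doc and not files_to_process:
        issues.append(ValidationIssue("FILES_TO_PROCESS", "", "must name the input directory"))

    update_column_names = _as_mapping(doc.get("UPDATE_COLUMN_NAMES"), "UPDATE_COLUMN_NAMES", issues)
    measurement = _as_mapping(doc.get(MEASUREMENT_BLOCK), MEASUREMENT_BLOCK, issues)
    if measurement:
        extra = set(measurement) - {"source_column", "variable_name", "units"}
        for key in sorted(extra):
            issues.append(ValidationIssue(MEASUREMENT_BLOCK, key, "unknown key; expected source_column, variable_name, units"))
        for key in ("source_column", "variable_name", "units"):
            if not measurement.get(key):
                issues.append(ValidationIssue(MEASUREMENT_BLOCK, key, "required when MEASUREMENT is given"))

    cfg = EtlConfig(
        files_to_process=files_to_process,
        additional_information_files=_as_mapping(
            doc.get("ADDITIONAL_INFORMATION_FILES"), "ADDITIONAL_INFORMATION_FILES", issues
        ),
        join_common_columns=_as_sequence(doc.get("JOIN_FILES_COMMON_COLUMNS"), "JOIN_FILES_COMMON_COLUMNS", issues),
        columns_to_drop=_as_sequence(doc.get("COLUMNS_TO_DROP"), "COLUMNS_TO_DROP", issues),
        update_column_names=update_column_names,
        new_columns=_as_mapping(doc.get("NEW_COLUMNS"), "NEW_COLUMNS", issues),
        primary_key_column=_as_scalar(doc.get("PRIMARY_KEY_COLUMN"), "PRIMARY_KEY_COLUMN", issues)
        if doc.get("PRIMARY_KEY_COLUMN") is not None
        else "",
        update_primary_key_values=_as_mapping(
            doc.get("UPDATE_PRIMARY_KEY_VALUES"), "UPDATE_PRIMARY_KEY_VALUES", issues
        ),
        update_row_values=_as_nested_mapping(doc.get("UPDATE_ROW_VALUES"), "UPDATE_ROW_VALUES", issues),
        output_file_name=_as_sequence(doc.get("OUTPUT_FILE_NAME"), "OUTPUT_FILE_NAME", issues),
        measurement=measurement,
    )

    # a rename target must not collide with an existing name it does not itself rename
    targets = list(cfg.update_column_names.values())
    sources = set(cfg.update_column_names)
    for old, new in cfg.update_column_names.items():
        if targets.count(new) > 1 and new in sources and new != old:
            issues.append(
                ValidationIssue("UPDATE_COLUMN_NAMES", old, f"target {new!r} collides with a column that is itself renamed")
            )

    if issues:
        raise ConfigError(issues)
    return cfg


def _validate_load(doc: Mapping[str, Any]) -> LoadConfig:
    issues: list[ValidationIssue] = []
    _check_block_names(doc, LOAD_BLOCKS, issues)

    required = ("DATABASE_CREDENTIALS", "TABLE_NAME", "FILE_TO_UPLOAD", "PRIMARY_KEY_COLUMN")
    for block in required:
        if block not in doc or doc[block] is None:
            issues.append(ValidationIssue(block, "", "required block is missing"))

    credentials = _as_mapping(doc.get("DATABASE_CREDENTIALS"), "DATABASE_CREDENTIALS", issues)
    table_name = _as_scalar(doc.get("TABLE_NAME"), "TABLE_NAME", issues) if doc.get("TABLE_NAME") is not None else ""
    file_to_upload = _as_scalar(doc.get("FILE_TO_UPLOAD"), "FILE_TO_UPLOAD", issues) if doc.get("FILE_TO_UPLOAD") is not None else ""
    pk = _as_scalar(doc.get("PRIMARY_KEY_COLUMN"), "PRIMARY_KEY_COLUMN", issues) if doc.get("PRIMARY_KEY_COLUMN") is not None else ""
    new_table_columns = _as_mapping(doc.get("NEW_TABLE_COLUMNS"), "NEW_TABLE_COLUMNS", issues)
    new_columns_if_exists = _as_mapping(doc.get("NEW_COLUMNS_IF_TABLE_EXISTS"), "NEW_COLUMNS_IF_TABLE_EXISTS", issues)

    if "DATABASE_CREDENTIALS" in doc and not credentials:
        issues.append(ValidationIssue("DATABASE_CREDENTIALS", "", "must map connection parameters (host, port, database, user, password)"))
    if "TABLE_NAME" in doc and not table_name:
        issues.append(ValidationIssue("TABLE_NAME", "", "must name the target table"))
    if "FILE_TO_UPLOAD" in doc and not file_to_upload:
        issues.append(ValidationIssue("FILE_TO_UPLOAD", "", "must name the standardized CSV to load"))
    if "PRIMARY_KEY_COLUMN" in doc and not pk:
        issues.append(ValidationIssue("PRIMARY_KEY_COLUMN", "", "must name the primary-key column"))
    if new_table_columns and pk and pk not in new_table_columns:
        issues.append(
            ValidationIssue("NEW_TABLE_COLUMNS", pk, "primary-key column must appear among the declared columns")
        )
    if "port" in credentials:
        _as_int(credentials["port"], "DATABASE_CREDENTIALS", "port", issues)

    if issues:
        raise ConfigError(issues)
    return LoadConfig(
        credentials=credentials,
        table_name=table_name,
        file_to_upload=file_to_upload,
        primary_key_column=pk,
        new_table_columns=new_table_columns,
        new_columns_if_table_exists=new_columns_if_exists,
    )


def load_and_validate(path: str | Path, kind: str) -> TemplateConfig | EtlConfig | LoadConfig:
    """Read a YAML configuration document and validate it against one schema kind.

    Parameters
    ----------
    path:
        Filesystem path of the YAML document.
    kind:
        ``template``, ``etl`` or ``load``.

    Raises
    ------
    ConfigError
        With the full list of violations: unknown blocks (with a
        nearest-name hint), missing required blocks, payload kind
        mismatches.
    """
    doc = _read_yaml(path)
    if kind == "template":
        return _validate_template(doc)
    if kind == "etl":
        return _validate_etl(doc)
    if kind == "load":
        return _validate_load(doc)
    raise ConfigError([ValidationIssue("-", "kind", f"unknown config kind {kind!r}; expected template, etl or load")])


def validate_document(doc: Mapping[str, Any], kind: str) -> TemplateConfig | EtlConfig | LoadConfig:
    """Validate an already-parsed document (scalars must be strings)."""
    if kind == "template":
        return _validate_template(doc)
    if kind == "etl":
        return _validate_etl(doc)
    if kind == "load":
        return _validate_load(doc)
    raise ConfigError([ValidationIssue("-", "kind", f"unknown config kind {kind!r}")])
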