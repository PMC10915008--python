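"""Load the standardized table into a relational database with upsert semantics.

Three statement builders mirror the Load workflow: create the table if
it does not exist, add columns if the table already exists, and upsert
the rows of the standardized CSV keyed on the primary-key constraint
(insert, or update in place when the key already exists).  Plans are
emitted in the PostgreSQL dialect with parameterized values — cell
contents are never interpolated into SQL text — and executed through an
engine seam: a PostgreSQL engine (psycopg2, optional dependency) for
real servers, and an embedded SQLite engine with equivalent upsert
semantics for local work and tests.

Each file loads inside one transaction: a failing row anywhere rolls
the whole load back, so the table is never left half-updated.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

from fieldpipe.config_schema import LoadConfig
from fieldpipe.errors import DataError, DatabaseError

logger = logging.getLogger(__name__)

#: PostgreSQL native type names accepted in column declarations.
ALLOWED_SQL_TYPES = frozenset(
    {
        "text",
        "integer",
        "bigint",
        "real",
        "double precision",
        "numeric",
        "date",
        "timestamp",
        "boolean",
    }
)

_INT_RE = re.compile(r"^[+-]?[0-9]+$")
_IDENT_RE = re.compile(r"[^a-z0-9_]+")


def sanitize_identifier(name: str) -> str:
    """Lowercase an identifier and replace runs of non-alphanumerics with ``_``."""
    ident = _IDENT_RE.sub("_", str(name).strip().lower()).strip("_")
    if not ident:
        raise DataError(f"cannot derive a valid identifier from {name!r}")
    if ident[0].isdigit():
        ident = "_" + ident
    return ident


def _quote(ident: str) -> str:
    return '"' + ident.replace('"', '""') + '"'


@dataclass(frozen=True)
class ColumnSpec:
    """A declared table column: sanitized name plus an allow-listed SQL type."""

    name: str
    sql_type: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", sanitize_identifier(self.name))
        sql_type = str(self.sql_type).strip().lower()
        if sql_type not in ALLOWED_SQL_TYPES:
            raise DataError(
                f"SQL type {self.sql_type!r} for column {self.name!r} is not allowed; "
                f"use one of: {', '.join(sorted(ALLOWED_SQL_TYPES))}"
            )
        object.__setattr__(self, "sql_type", sql_type)


@dataclass(frozen=True)
class SqlStatement:
    """One parameterized statement: kind, SQL text, bound values."""

    kind: str  # create_table | add_column | upsert | maintenance
    sql: str
    params: tuple[Any, ...] = ()


@dataclass
class SqlPlan:
    """An ordered sequence of statements; DDL always precedes DML."""

    statements: list[SqlStatement] = field(default_factory=list)

    def __iter__(self):
        return iter(self.statements)

    def __len__(self) -> int:
        return len(self.statements)

    def describe(self) -> str:
        lines = []
        for st in self.statements:
            lines.append(f"-- [{st.kind}] params={list(st.params)!r}" if st.params else f"-- [{st.kind}]")
            lines.append(st.sql + ";")
        return "\n".join(lines)


@dataclass
class LoadSummary:
    """Outcome of one file load."""

    inserted: int = 0
    updated: int = 0


def _column_specs(mapping: Mapping[str, str]) -> list[ColumnSpec]:
    specs = [ColumnSpec(name, sql_type) for name, sql_type in mapping.items()]
    seen: set[str] = set()
    for spec in specs:
        if spec.name in seen:
            raise DataError(f"column name {spec.name!r} duplicated after sanitization")
        seen.add(spec.name)
    return specs


def build_create_table_statement(config: LoadConfig) -> SqlStatement:
    """CREATE TABLE IF NOT EXISTS with all declared columns and the primary-key constraint."""
    if not config.new_table_columns:
        raise DataError("NEW_TABLE_COLUMNS is empty; nothing to create")
    specs = _column_specs(config.new_table_columns)
    pk = sanitize_identifier(config.primary_key_column)
    if pk not in {s.name for s in specs}:
        raise DataError(f"primary-key column {pk!r} is not among the declared columns")
    table = sanitize_identifier(config.table_name)
    # NOT NULL is implied by PRIMARY KEY in PostgreSQL but not in SQLite;
    # declaring it keeps the two engines' constraint behaviour identical.
    cols = ", ".join(
        f"{_quote(s.name)} {s.sql_type} NOT NULL" if s.name == pk else f"{_quote(s.name)} {s.sql_type}"
        for s in specs
    )
    sql = f"CREATE TABLE IF NOT EXISTS {_quote(table)} ({cols}, PRIMARY KEY ({_quote(pk)}))"
    return SqlStatement(kind="create_table", sql=sql)


def build_add_column_statements(config: LoadConfig) -> list[SqlStatement]:
    """One ADD COLUMN IF NOT EXISTS statement per configured new column."""
    if not config.new_columns_if_table_exists:
        return []
    table = sanitize_identifier(config.table_name)
    return [
        SqlStatement(
            kind="add_column",
            sql=f"ALTER TABLE {_quote(table)} ADD COLUMN IF NOT EXISTS {_quote(spec.name)} {spec.sql_type}",
        )
        for spec in _column_specs(config.new_columns_if_table_exists)
    ]


def coerce_value(value: Any, sql_type: str, row: int, column: str) -> Any:
    """Coerce one text cell to the declared type; empty cells become NULL.

    Failures name the offending row and column rather than truncating
    silently.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)) or value is pd.NA:
        return None
    text = str(value)
    if text == "":
        return None
    if sql_type in ("integer", "bigint"):
        if not _INT_RE.match(text):
            raise DataError(f"row {row}, column {column!r}: {text!r} is not an integer")
        return int(text)
    if sql_type in ("real", "double precision", "numeric"):
        try:
            return float(text)
        except ValueError:
            raise DataError(f"row {row}, column {column!r}: {text!r} is not numeric") from None
    if sql_type == "boolean":
        low = text.strip().lower()
        if low in ("true", "t", "yes", "1"):
            return True
        if low in ("false", "f", "no", "0"):
            return False
        raise DataError(f"row {row}, column {column!r}: {text!r} is not a boolean")
    return text  # text, date, timestamp travel as strings


def build_upsert_plan(frame: pd.DataFrame, config: LoadConfig) -> SqlPlan:
    """Per-row insert-on-conflict-update statements for the standardized table.

    Column names are sanitized; when column types are declared in the
    config, file columns must be a subset of them and values are coerced
    accordingly.
    """
    table = sanitize_identifier(config.table_name)
    pk = sanitize_identifier(config.primary_key_column)
    columns = [sanitize_identifier(c) for c in frame.columns]
    if len(set(columns)) != len(columns):
        raise DataError("file column names collide after sanitization")
    if pk not in columns:
        raise DataError(f"primary-key column {pk!r} not present in the file to upload")

    declared = {}
    for mapping in (config.new_table_columns, config.new_columns_if_table_exists):
        for spec in _column_specs(mapping):
            declared[spec.name] = spec.sql_type
    if declared:
        missing = [c for c in columns if c not in declared]
        if missing:
            raise DataError(
                f"file column(s) {missing} absent from the table schema; "
                "declare them under NEW_COLUMNS_IF_TABLE_EXISTS"
            )

    col_list = ", ".join(_quote(c) for c in columns)
    placeholders = ", ".join(["%s"] * len(columns))
    non_pk = [c for c in columns if c != pk]
    if non_pk:
        update = ", ".join(f"{_quote(c)} = EXCLUDED.{_quote(c)}" for c in non_pk)
        conflict = f"ON CONFLICT ({_quote(pk)}) DO UPDATE SET {update}"
    else:
        conflict = f"ON CONFLICT ({_quote(pk)}) DO NOTHING"
    sql = f"INSERT INTO {_quote(table)} ({col_list}) VALUES ({placeholders}) {conflict}"

    plan = SqlPlan()
    for i, (_, row) in enumerate(frame.iterrows()):
        params = tuple(
            coerce_value(cell, declared.get(col, "text"), i + 1, col)
            for col, cell in zip(columns, row)
        )
        plan.statements.append(SqlStatement(kind="upsert", sql=sql, params=params))
    return plan


# ---------------------------------------------------------------------------
# engines


class Engine:
    """Minimal database-engine interface the loader relies on."""

    dialect: str = "?"

    def execute(self, sql: str, params: Sequence[Any] = ()) -> int:  # affected rows
        raise NotImplementedError

    def fetchall(self, sql: str, params: Sequence[Any] = ()) -> list[tuple]:
        raise NotImplementedError

    def begin(self) -> None:
        raise NotImplementedError

    def commit(self) -> None:
        raise NotImplementedError

    def rollback(self) -> None:
        raise NotImplementedError

    def close(self) -> None:
        raise NotImplementedError

    def table_exists(self, table: str) -> bool:
        raise NotImplementedError

    def table_columns(self, table: str) -> list[str]:
        raise NotImplementedError


class SqliteEngine(Engine):
    """Embedded engine executing PostgreSQL-dialect plans against SQLite.

    Translation: ``%s`` placeholders become ``?``, and ``ADD COLUMN IF
    NOT EXISTS`` (which SQLite lacks) is emulated with a catalog check.
    SQLite's ``ON CONFLICT ... DO UPDATE`` has the PostgreSQL semantics,
    so upsert plans run unchanged.
    """

    dialect = "sqlite"

    _ADD_COLUMN_RE = re.compile(
        r'^ALTER TABLE\s+"(?P<table>(?:[^"]|"")+)"\s+ADD COLUMN IF NOT EXISTS\s+"(?P<column>(?:[^"]|"")+)"\s+(?P<type>.+)$',
        re.IGNORECASE,
    )

    def __init__(self, database: str = ":memory:"):
        import sqlite3

        self._conn = sqlite3.connect(database)
        self._conn.isolation_level = None  # explicit transaction control

    def _translate(self, sql: str) -> str | None:
        match = self._ADD_COLUMN_RE.match(sql.strip())
        if match:
            table = match.group("table").replace('""', '"')
            column = match.group("column").replace('""', '"')
            if column in self.table_columns(table):
                return None  # already there; IF NOT EXISTS semantics
            return f'ALTER TABLE "{match.group("table")}" ADD COLUMN "{match.group("column")}" {match.group("type")}'
        return sql.replace("%s", "?")

    def execute(self, sql: str, params: Sequence[Any] = ()) -> int:
        translated = self._translate(sql)
        if translated is None:
            return 0
        try:
            cur = self._conn.execute(translated, tuple(params))
        except Exception as exc:
            raise DatabaseError(f"{exc} (while executing: {sql[:120]})") from exc
        return max(cur.rowcount, 0)

    def fetchall(self, sql: str, params: Sequence[Any] = ()) -> list[tuple]:
        translated = self._translate(sql)
        if translated is None:
            return []
        try:
            cur = self._conn.execute(translated, tuple(params))
        except Exception as exc:
            raise DatabaseError(f"{exc} (while executing: {sql[:120]})") from exc
        return cur.fetchall()

    def begin(self) -> None:
        self._conn.execute("BEGIN")

    def commit(self) -> None:
        self._conn.execute("COMMIT")

    def rollback(self) -> None:
        try:
            self._conn.execute("ROLLBACK")
        except Exception:
            pass

    def close(self) -> None:
        self._conn.close()

    def table_exists(self, table: str) -> bool:
        rows = self._conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' AND name=?", (table,)
        ).fetchall()
        return bool(rows)

    def table_columns(self, table: str) -> list[str]:
        return [r[1] for r in self._conn.execute(f'PRAGMA table_info("{table}")').fetchall()]


class PostgresEngine(Engine):
    """Engine backed by a real PostgreSQL server via psycopg2 (optional dependency)."""

    dialect = "postgresql"

    def __init__(self, credentials: Mapping[str, str]):
        try:
            import psycopg2
        except ImportError as exc:
            raise DatabaseError(
                "psycopg2 is not installed; install the 'postgres' extra or use the sqlite dialect"
            ) from exc
        kwargs = {
            key: credentials[key]
            for key in ("host", "port", "database", "user", "password")
            if credentials.get(key)
        }
        try:
            self._conn = psycopg2.connect(**kwargs)
        except Exception as exc:
            raise DatabaseError(f"cannot connect to PostgreSQL: {exc}") from exc
        self._conn.autocommit = False

    def execute(self, sql: str, params: Sequence[Any] = ()) -> int:
        try:
            with self._conn.cursor() as cur:
                cur.execute(sql, tuple(params))
                return max(cur.rowcount, 0)
        except Exception as exc:
            raise DatabaseError(f"{exc} (while executing: {sql[:120]})") from exc

    def fetchall(self, sql: str, params: Sequence[Any] = ()) -> list[tuple]:
        try:
            with self._conn.cursor() as cur:
                cur.execute(sql, tuple(params))
                return cur.fetchall()
        except Exception as exc:
            raise DatabaseError(f"{exc} (while executing: {sql[:120]})") from exc

    def begin(self) -> None:  # psycopg2 opens transactions implicitly
        pass

    def commit(self) -> None:
        self._conn.commit()

    def rollback(self) -> None:
        self._conn.rollback()

    def close(self) -> None:
        self._conn.close()

    def table_exists(self, table: str) -> bool:
        rows = self.fetchall("SELECT to_regclass(%s)", (table,))
        return bool(rows and rows[0][0])

    def table_columns(self, table: str) -> list[str]:
        rows = self.fetchall(
            "SELECT column_name FROM information_schema.columns WHERE table_name = %s ORDER BY ordinal_position",
            (table,),
        )
        return [r[0] for r in rows]


_ENV_PREFIX = "FIELDPIPE_DB_"


def connect(credentials: Mapping[str, str]) -> Engine:
    """Open an engine from a credentials mapping.

    Environment variables ``FIELDPIPE_DB_HOST/PORT/DATABASE/USER/PASSWORD``
    override the configured values (credentials are never logged).  A
    ``dialect: sqlite`` key selects the embedded engine, with
    ``database`` as the file path (default in-memory).
    """
    merged = dict(credentials)
    for key in ("host", "port", "database", "user", "password", "dialect"):
        env = os.environ.get(_ENV_PREFIX + key.upper())
        if env:
            merged[key] = env
    if merged.get("dialect", "postgresql").lower() == "sqlite":
        return SqliteEngine(merged.get("database", ":memory:"))
    return PostgresEngine(merged)


def compose_load_plan(config: LoadConfig, frame: pd.DataFrame) -> SqlPlan:
    """Full plan for one load: optional create-table, optional add-columns, upserts."""
    plan = SqlPlan()
    if config.new_table_columns:
        plan.statements.append(build_create_table_statement(config))
    plan.statements.extend(build_add_column_statements(config))
    plan.statements.extend(build_upsert_plan(frame, config))
    return plan


def _read_standard_file(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"file to upload not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8-sig")
    frame.columns = [str(c).strip() for c in frame.columns]
    return frame.mask(frame == "", pd.NA)


def load_standard_file(config: LoadConfig, engine: Engine | None = None) -> LoadSummary:
    """Execute the full Load sequence for one file inside a single transaction.

    Create-table and add-column statements run first when configured,
    then the per-row upserts.  Any failure rolls back the whole file.
    Returns how many rows were newly inserted and how many hit an
    existing key (counted as updated).
    """
    own_engine = engine is None
    if engine is None:
        engine = connect(config.credentials)
    frame = _read_standard_file(config.file_to_upload)
    plan = compose_load_plan(config, frame)
    table = sanitize_identifier(config.table_name)
    pk = sanitize_identifier(config.primary_key_column)
    try:
        engine.begin()
        for st in plan:
            if st.kind != "upsert":
                engine.execute(st.sql, st.params)
        existing: set[str] = set()
        if engine.table_exists(table):
            existing = {str(r[0]) for r in engine.fetchall(f'SELECT {_quote(pk)} FROM {_quote(table)}')}
        inserted = updated = 0
        pk_index = [sanitize_identifier(c) for c in frame.columns].index(pk)
        for st in plan:
            if st.kind != "upsert":
                continue
            engine.execute(st.sql, st.params)
            if str(st.params[pk_index]) in existing:
                updated += 1
            else:
                inserted += 1
        engine.commit()
    except Exception:
        engine.rollback()
        raise
    finally:
        if own_engine:
            engine.close()
    return LoadSummary(inserted=inserted, updated=updated)


_ROW_RETURNING = ("select", "with", "values", "show", "explain", "pragma", "table")


def run_sql(engine: Engine, statement: str) -> list[tuple] | int:
    """Execute one user-supplied SQL statement.

    Row-returning statements (SELECT and friends) return their rows;
    everything else returns the affected-row count.  Server-side errors
    surface as :class:`DatabaseError` with a statement excerpt, and the
    connection stays usable.
    """
    statement = statement.strip()
    if not statement:
        raise DataError("empty SQL statement")
    first = statement.split(None, 1)[0].lower()
    try:
        if first in _ROW_RETURNING:
            return engine.fetchall(statement)
        engine.begin()
        affected = engine.execute(statement)
        engine.commit()
        return affected
    except DatabaseError:
        engine.rollback()
        raise


def drop_column(engine: Engine, table: str, column: str) -> None:
    """Maintenance helper: remove one column from a table."""
    sql = f"ALTER TABLE {_quote(sanitize_identifier(table))} DROP COLUMN {_quote(sanitize_identifier(column))}"
    engine.begin()
    try:
        engine.execute(sql)
        engine.commit()
    except DatabaseError:
        engine.rollback()
        raise


def drop_table(engine: Engine, table: str) -> None:
    """Maintenance helper: remove a table entirely."""
    sql = f"DROP TABLE IF EXISTS {_quote(sanitize_identifier(table))}"
    engine.begin()
    try:
        engine.execute(sql)
        engine.commit()
    except DatabaseError:
        engine.rollback()
        raise
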