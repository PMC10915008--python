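"""Exception hierarchy shared across the pipeline stages.

The split mirrors the CLI exit codes: configuration problems (exit 2),
data problems (exit 3), database problems (exit 4).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass


@dataclass(frozen=True)
class ValidationIssue:
    """One structured validation violation: which block, which key, what went wrong."""

    block: str
    key: str
    message: str


class FieldpipeError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(FieldpipeError):
    """A configuration document failed validation.

    Carries the full list of violations so callers can render a
    machine-readable report instead of fixing errors one at a time.
    """

    def __init__(self, issues: list[ValidationIssue] | None = None, message: str | None = None):
        self.issues = list(issues or [])
        if message is None:
            message = "; ".join(f"[{i.block}] {i.key}: {i.message}" for i in self.issues)
        super().__init__(message or "invalid configuration")

    def as_json(self) -> str:
        return json.dumps([asdict(i) for i in self.issues], indent=2)


class DataError(FieldpipeError):
    """An input table violated a contract (duplicate keys, ragged rows, missing columns)."""


class DatabaseError(FieldpipeError):
    """A database statement or connection failed."""
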