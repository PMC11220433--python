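"""Exception hierarchy shared across the toolkit."""

from __future__ import annotations


class PhvError(Exception):
    """Base class for all toolkit errors."""


class MissingColumnsError(PhvError):
    """The CSV header lacks required columns."""

    def __init__(self, missing: list[str]) -> None:
        self.missing = sorted(missing)
        super().__init__(f"missing required columns: {', '.join(self.missing)}")


class DateParseError(PhvError):
    """A date cell could not be parsed."""

    def __init__(self, row: int, raw: str) -> None:
        self.row = row
        self.raw = raw
        super().__init__(f"row {row}: unparseable date {raw!r}")


class VocabularyError(PhvError):
    """A selector term does not resolve through the vocabulary."""


class EmptyContingencyError(PhvError):
    """No normalized couple events available to build a contingency table."""


class DegenerateDesignError(PhvError):
    """The regression design has no case posts or no non-case posts."""


class UndefinedMetricError(PhvError):
    """A metric is undefined for the given inputs (e.g. F1 at P=R=0)."""


class ConfigError(PhvError):
    """Invalid run or simulation configuration."""
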