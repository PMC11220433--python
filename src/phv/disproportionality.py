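"""Disproportionality signal detection: PRR and ROR on 2x2 event tables.

In spontaneous-report style data the number of exposed patients is unknown, so
association is assessed by comparing how often an adverse event is reported
with the drug of interest against how often it is reported with every other
drug.  The 2x2 table cells are *couple events*:

================  ================  ==========
cell              ADE of interest   other ADEs
================  ================  ==========
Drug of interest  a                 b
Other drugs       c                 d
================  ================  ==========

Counting is event-level: a drug-ADE pair annotated k times (including several
times within one post) contributes k events.  PRR = [a/(a+b)] / [c/(c+d)] and
ROR = ad/bc, both 1 under independence; 95% confidence intervals are Wald
intervals on the log scale and a signal is declared when the lower bound of
the 95% CI of the log measure exceeds 0.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .annotation_store import (
    AnnotationCorpus,
    AnnotationLine,
    Vocabulary,
    atc_matches,
    resolve_meddra_selector,
)
from .errors import EmptyContingencyError, PhvError

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """Event counts for one drug/ADE selector pair."""

    a: float
    b: float
    c: float
    d: float

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d

    def with_haldane(self) -> "ContingencyTable":
        """Haldane-Anscombe continuity correction: +0.5 to every cell."""
        return ContingencyTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)

    def swapped_rows(self) -> "ContingencyTable":
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class SignalEstimate:
    """A PRR or ROR point estimate with its log-scale 95% Wald interval.

    ``computable`` is False when the requested measure is undefined for the
    table under the chosen zero-cell policy; the numeric fields are then NaN
    and ``is_signal`` is False — an explicit marker, never a silent infinity.
    """

    measure: str
    point: float
    log_point: float
    log_ci_low: float
    log_ci_high: float
    is_signal: bool
    table: ContingencyTable
    computable: bool = True

    @classmethod
    def not_computable(cls, measure: str, table: ContingencyTable) -> "SignalEstimate":
        nan = float("nan")
        return cls(measure, nan, nan, nan, nan, False, table, computable=False)

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "a": self.table.a,
            "b": self.table.b,
            "c": self.table.c,
            "d": self.table.d,
            "point": self.point,
            "ci_low": self.log_ci_low,
            "ci_high": self.log_ci_high,
            "signal": self.is_signal,
            "computable": self.computable,
        }


# ---------------------------------------------------------------------------
# Contingency construction
# ---------------------------------------------------------------------------


def build_contingency(
    corpus: AnnotationCorpus,
    drug_selector: str | Iterable[str],
    ade_selector: str | Iterable[str],
    *,
    vocabulary: Vocabulary | None = None,
    by: str = "events",
) -> ContingencyTable:
    """Classify every normalized couple event into one cell of the 2x2 table.

    Multi-code selectors are pooled: all selected drugs act as one
    drug-of-interest entity, and likewise for ADEs.  ``by='events'`` (the
    default and the analysis mode) counts every couple line; ``by='posts'`` is
    a sensitivity mode counting each post once, classified by the presence of
    the drug and ADE of interest among its couples.
    """
    if by not in ("events", "posts"):
        raise PhvError(f"unknown counting mode {by!r}")
    pt_set = resolve_meddra_selector(ade_selector, vocabulary)
    couples = corpus.couple_lines()
    if not couples:
        raise EmptyContingencyError("corpus contains no normalized couple lines")

    def classify(line: AnnotationLine) -> tuple[bool, bool]:
        return (
            atc_matches(line.drug_atc_code, drug_selector),
            line.ade_pt_code in pt_set,
        )

    a = b = c = d = 0
    if by == "events":
        for ln in couples:
            drug_hit, ade_hit = classify(ln)
            if drug_hit and ade_hit:
                a += 1
            elif drug_hit:
                b += 1
            elif ade_hit:
                c += 1
            else:
                d += 1
    else:
        per_post: dict[str, list[bool]] = {}
        for ln in couples:
            drug_hit, ade_hit = classify(ln)
            flags = per_post.setdefault(ln.post_id, [False, False])
            flags[0] |= drug_hit
            flags[1] |= ade_hit
        for drug_hit, ade_hit in per_post.values():
            if drug_hit and ade_hit:
                a += 1
            elif drug_hit:
                b += 1
            elif ade_hit:
                c += 1
            else:
                d += 1
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# PRR / ROR
# ---------------------------------------------------------------------------


def _apply_zero_cell(table: ContingencyTable, zero_cell: str) -> ContingencyTable:
    if zero_cell == "strict":
        return table
    if zero_cell == "haldane":
        return table.with_haldane()
    raise PhvError(f"unknown zero-cell policy {zero_cell!r}")


def _estimate(
    measure: str,
    raw: ContingencyTable,
    point: float,
    se_log: float,
) -> SignalEstimate:
    log_point = math.log(point)
    low = log_point - Z_95 * se_log
    high = log_point + Z_95 * se_log
    return SignalEstimate(
        measure=measure,
        point=point,
        log_point=log_point,
        log_ci_low=low,
        log_ci_high=high,
        is_signal=low > 0.0,
        table=raw,
    )


def prr(table: ContingencyTable, *, zero_cell: str = "strict") -> SignalEstimate:
    """Proportional reporting ratio with its log-scale 95% Wald interval.

    Requires a>0, c>0 and both row totals positive (after the optional
    Haldane-Anscombe correction); otherwise the result is marked
    not-computable.
    """
    t = _apply_zero_cell(table, zero_cell)
    if t.a <= 0 or t.c <= 0 or t.a + t.b <= 0 or t.c + t.d <= 0:
        return SignalEstimate.not_computable("PRR", table)
    point = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    var = 1.0 / t.a - 1.0 / (t.a + t.b) + 1.0 / t.c - 1.0 / (t.c + t.d)
    return _estimate("PRR", table, point, math.sqrt(max(var, 0.0)))


def ror(table: ContingencyTable, *, zero_cell: str = "strict") -> SignalEstimate:
    """Reporting odds ratio ad/bc with its log-scale 95% Wald interval."""
    t = _apply_zero_cell(table, zero_cell)
    if t.a <= 0 or t.b <= 0 or t.c <= 0 or t.d <= 0:
        return SignalEstimate.not_computable("ROR", table)
    point = (t.a * t.d) / (t.b * t.c)
    var = 1.0 / t.a + 1.0 / t.b + 1.0 / t.c + 1.0 / t.d
    return _estimate("ROR", table, point, math.sqrt(var))


# ---------------------------------------------------------------------------
# Cumulative monthly PRR
# ---------------------------------------------------------------------------


def cumulative_prr_series(
    corpus: AnnotationCorpus,
    drug_selector: str | Iterable[str],
    ade_selector: str | Iterable[str],
    *,
    vocabulary: Vocabulary | None = None,
    zero_cell: str = "strict",
    measure: str = "PRR",
) -> list[tuple[pd.Period, SignalEstimate]]:
    """PRR (or ROR) on data cumulated from the corpus start up to each month.

    The series runs from the first month with an event of the selected pair to
    the last month with any couple event.  Months where the measure is
    undefined carry a not-computable estimate rather than being dropped.
    """
    pt_set = resolve_meddra_selector(ade_selector, vocabulary)
    couples = corpus.couple_lines()
    if not couples:
        raise EmptyContingencyError("corpus contains no normalized couple lines")
    pair_months = [
        pd.Period(ln.post_date, freq="M")
        for ln in couples
        if atc_matches(ln.drug_atc_code, drug_selector) and ln.ade_pt_code in pt_set
    ]
    if not pair_months:
        raise EmptyContingencyError("no couple events match the selected pair")
    start = min(pair_months)
    end = max(pd.Period(ln.post_date, freq="M") for ln in couples)
    fn = prr if measure.upper() == "PRR" else ror
    out: list[tuple[pd.Period, SignalEstimate]] = []
    for month in pd.period_range(start, end, freq="M"):
        cutoff = month.to_timestamp(how="end").date()
        sub = AnnotationCorpus(
            lines=[ln for ln in corpus.lines if ln.post_date <= cutoff]
        )
        table = build_contingency(
            sub, drug_selector, ade_selector, vocabulary=vocabulary
        )
        out.append((month, fn(table, zero_cell=zero_cell)))
    return out
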