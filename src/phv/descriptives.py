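"""Descriptive statistics over annotation corpora.

Reproduces the "forum statistics" family of outputs: corpus-level summaries,
ranked distributions with cumulative frequencies, monthly time series, and the
precision/recall/F1 helper used to score annotation quality.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_store import AnnotationCorpus, Vocabulary, filter_corpus
from .errors import PhvError, UndefinedMetricError, VocabularyError


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the convention of printed percentage tables)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Corpus summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorpusSummary:
    n_posts: int
    n_annotation_lines: int
    n_drug_annotations: int
    n_ade_annotations: int
    n_normalized_couples: int
    n_posts_with_couple: int
    pct_posts_with_couple: float

    def to_dict(self) -> dict[str, float | int]:
        return {
            "n_posts": self.n_posts,
            "n_annotation_lines": self.n_annotation_lines,
            "n_drug_annotations": self.n_drug_annotations,
            "n_ade_annotations": self.n_ade_annotations,
            "n_normalized_couples": self.n_normalized_couples,
            "n_posts_with_couple": self.n_posts_with_couple,
            "pct_posts_with_couple": self.pct_posts_with_couple,
        }


def pct_of(numerator: int, denominator: int) -> float:
    """Percentage ``100*numerator/denominator`` rounded half-up to 2 decimals."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, 2)


def summarize(corpus: AnnotationCorpus) -> CorpusSummary:
    """Post- and line-level counts for a corpus.

    Drug/ADE annotation counts are at verbatim level (any annotated mention);
    couples are counted only when both normalized codes are present on the
    line.  Post-level fields count distinct post identifiers.
    """
    posts_with_couple = {ln.post_id for ln in corpus.lines if ln.is_normalized_couple}
    return CorpusSummary(
        n_posts=corpus.n_posts,
        n_annotation_lines=corpus.n_lines,
        n_drug_annotations=sum(1 for ln in corpus.lines if ln.has_drug_annotation),
        n_ade_annotations=sum(1 for ln in corpus.lines if ln.has_ade_annotation),
        n_normalized_couples=corpus.n_couples,
        n_posts_with_couple=len(posts_with_couple),
        pct_posts_with_couple=pct_of(len(posts_with_couple), corpus.n_posts),
    )


# ---------------------------------------------------------------------------
# Ranked distributions with cumulative frequencies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankedRow:
    label: str
    count: int
    cumulative_pct: float


@dataclass(frozen=True)
class RankedDistribution:
    rows: tuple[RankedRow, ...]
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.label, r.count, r.cumulative_pct) for r in self.rows],
            columns=["label", "count", "cumulative_pct"],
        )


def ranked_distribution(
    counts: Mapping[str, int], top_n: int | None = None
) -> RankedDistribution:
    """Sort label counts descending (ties lexicographic) and attach the
    cumulative frequency column.

    Cumulative percentages are computed on the full total *before* any top-n
    truncation, so a truncated table still reports shares of the whole.
    """
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(counts.values())
    rows = []
    running = 0
    for label, count in items:
        if count < 0:
            raise PhvError(f"negative count for label {label!r}")
        running += count
        rows.append(RankedRow(label, count, pct_of(running, total)))
    if top_n is not None:
        rows = rows[:top_n]
    return RankedDistribution(rows=tuple(rows), total=total)


_RANK_KEYS = ("forum_name", "ade_pt_code", "soc", "drug_atc_code")


def rank_by(
    corpus: AnnotationCorpus,
    key: str,
    *,
    vocabulary: Vocabulary | None = None,
    top_n: int | None = None,
) -> RankedDistribution:
    """Ranked annotation counts by forum, PT code, SOC, or ATC code.

    ``forum_name`` counts every annotation line; the code keys count only
    lines carrying that normalized code.  The SOC key maps PT codes through
    the vocabulary, so it requires one, and an annotation whose PT is outside
    the vocabulary is an error rather than a silent drop.
    """
    if key not in _RANK_KEYS:
        raise PhvError(f"unknown ranking key {key!r}; expected one of {_RANK_KEYS}")
    counts: dict[str, int] = {}
    for ln in corpus.lines:
        if key == "forum_name":
            label = ln.forum_name
        elif key == "ade_pt_code":
            label = ln.ade_pt_code
        elif key == "drug_atc_code":
            label = ln.drug_atc_code
        else:  # soc
            if vocabulary is None:
                raise VocabularyError("ranking by SOC requires a Vocabulary")
            label = vocabulary.soc_of(ln.ade_pt_code) if ln.ade_pt_code else None
        if label is None:
            continue
        counts[label] = counts.get(label, 0) + 1
    return ranked_distribution(counts, top_n=top_n)


# ---------------------------------------------------------------------------
# Monthly time series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MonthlyCounts:
    """Contiguous monthly event counts; months with no events are zeros."""

    start_month: pd.Period | None
    values: tuple[int, ...]

    @property
    def is_empty(self) -> bool:
        return len(self.values) == 0

    def months(self) -> pd.PeriodIndex:
        if self.start_month is None:
            return pd.PeriodIndex([], freq="M")
        return pd.period_range(self.start_month, periods=len(self.values), freq="M")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.months(), dtype=int)


_SERIES_UNITS = ("posts", "annotation_lines", "couples")


def monthly_series(
    corpus: AnnotationCorpus,
    *,
    unit: str = "couples",
    forums: Iterable[str] | None = None,
    date_range: tuple[dt.date, dt.date] | None = None,
    atc_selector: str | Iterable[str] | None = None,
    meddra_selector: str | Iterable[str] | None = None,
    vocabulary: Vocabulary | None = None,
) -> MonthlyCounts:
    """Monthly counts of posts, annotation lines or normalized couples after
    filtering; one bucket per calendar month from first to last matching date,
    with explicit zeros for empty months.  ``unit='posts'`` counts each post
    once per month regardless of how many lines it contributes."""
    if unit not in _SERIES_UNITS:
        raise PhvError(f"unknown unit {unit!r}; expected one of {_SERIES_UNITS}")
    sub = filter_corpus(
        corpus,
        forums=forums,
        date_range=date_range,
        atc_selector=atc_selector,
        meddra_selector=meddra_selector,
        vocabulary=vocabulary,
    )
    if unit == "couples":
        lines = sub.couple_lines()
    else:
        lines = sub.lines
    if not lines:
        return MonthlyCounts(start_month=None, values=())
    periods = pd.PeriodIndex(
        [pd.Period(ln.post_date, freq="M") for ln in lines], freq="M"
    )
    if unit == "posts":
        frame = pd.DataFrame({"month": periods, "post": [ln.post_id for ln in lines]})
        per_month = frame.drop_duplicates().groupby("month").size()
    else:
        per_month = pd.Series(1, index=periods).groupby(level=0).sum()
    full = pd.period_range(periods.min(), periods.max(), freq="M")
    per_month = per_month.reindex(full, fill_value=0)
    return MonthlyCounts(
        start_month=full[0], values=tuple(int(v) for v in per_month.to_numpy())
    )


# ---------------------------------------------------------------------------
# Precision / recall / F1
# ---------------------------------------------------------------------------


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R) of a precision/recall pair in [0, 1]."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise UndefinedMetricError("precision and recall must lie in [0, 1]")
    if precision == 0.0 and recall == 0.0:
        raise UndefinedMetricError("F1 is undefined when precision = recall = 0")
    return 2.0 * precision * recall / (precision + recall)
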