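"""Data model, validation and CSV I/O for normalized drug/ADE annotation corpora.

An annotation corpus is a flat table in which each row records, for one forum
post, a drug annotation, an adverse-drug-event (ADE) annotation, or both.  When
both are present on the same row the annotator has asserted a causality
relationship and the row is a *couple*.  Drugs are normalized to ATC level-5
codes and ADEs to MedDRA preferred-term (PT) codes; a couple is *normalized*
only when both codes are present.  Couples are never inferred by joining
separate rows of the same post.
"""

from __future__ import annotations

import csv
import datetime as dt
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import DateParseError, MissingColumnsError, PhvError, VocabularyError

# ---------------------------------------------------------------------------
# Code patterns
# ---------------------------------------------------------------------------

CUI_RE = re.compile(r"^C\d{7}$")
PT_CODE_RE = re.compile(r"^\d{8}$")
ATC5_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")
#: Valid ATC prefix lengths for levels 1-5.
ATC_PREFIX_LENGTHS = (1, 3, 4, 5, 7)
_ATC_PREFIX_RES = {
    1: re.compile(r"^[A-Z]$"),
    3: re.compile(r"^[A-Z]\d{2}$"),
    4: re.compile(r"^[A-Z]\d{2}[A-Z]$"),
    5: re.compile(r"^[A-Z]\d{2}[A-Z]{2}$"),
    7: ATC5_RE,
}

#: Canonical CSV header (order used on write; reads are order-insensitive).
CSV_COLUMNS = (
    "forum_name",
    "post_id",
    "date",
    "time",
    "ade_verbatim",
    "ade_normalized",
    "cui",
    "meddra_code",
    "drug_verbatim",
    "drug_normalized",
    "active_ingredient",
    "atc_code",
)

#: Cell values treated as absent on read (the em dash mirrors printed tables).
_ABSENT = {"", "—", "-", "–"}


def parse_post_date(raw: str) -> dt.date:
    """Parse an ISO ``YYYY-MM-DD`` or locale ``October 8, 2018`` date."""
    raw = raw.strip()
    try:
        return dt.date.fromisoformat(raw)
    except ValueError:
        pass
    try:
        return dt.datetime.strptime(raw, "%B %d, %Y").date()
    except ValueError:
        raise ValueError(f"not a recognised date: {raw!r}") from None


def is_atc_prefix(text: str) -> bool:
    pat = _ATC_PREFIX_RES.get(len(text))
    return bool(pat and pat.match(text))


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class AnnotationLine:
    """One CSV row: post metadata plus optional drug and/or ADE annotation."""

    forum_name: str
    post_id: str
    post_date: dt.date
    post_time: dt.time | None = None
    ade_verbatim: str | None = None
    ade_normalized: str | None = None
    ade_cui: str | None = None
    ade_pt_code: str | None = None
    drug_verbatim: str | None = None
    drug_normalized: str | None = None
    active_ingredient: str | None = None
    drug_atc_code: str | None = None

    @property
    def is_normalized_couple(self) -> bool:
        """True iff the row links a coded drug and a coded ADE."""
        return self.ade_pt_code is not None and self.drug_atc_code is not None

    @property
    def has_drug_annotation(self) -> bool:
        return self.drug_verbatim is not None

    @property
    def has_ade_annotation(self) -> bool:
        return self.ade_verbatim is not None

    def validate(self) -> None:
        """Raise ``ValueError`` if any structural invariant is violated."""
        if self.ade_verbatim is None and self.drug_verbatim is None:
            raise ValueError("line carries neither an ADE nor a drug annotation")
        if self.ade_cui is not None and not CUI_RE.match(self.ade_cui):
            raise ValueError(f"malformed UMLS CUI: {self.ade_cui!r}")
        if self.ade_pt_code is not None and not PT_CODE_RE.match(self.ade_pt_code):
            raise ValueError(f"malformed MedDRA PT code: {self.ade_pt_code!r}")
        if self.drug_atc_code is not None and not ATC5_RE.match(self.drug_atc_code):
            raise ValueError(f"malformed ATC level-5 code: {self.drug_atc_code!r}")


@dataclass(frozen=True, slots=True)
class RejectedRow:
    """A data row refused on read, with its 1-based row number and reason."""

    row: int
    reason: str


@dataclass
class AnnotationCorpus:
    """An ordered collection of annotation lines with a post index."""

    lines: list[AnnotationLine] = field(default_factory=list)
    rejected: list[RejectedRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._post_index: dict[str, list[AnnotationLine]] | None = None

    @property
    def post_index(self) -> dict[str, list[AnnotationLine]]:
        if self._post_index is None:
            index: dict[str, list[AnnotationLine]] = {}
            for line in self.lines:
                index.setdefault(line.post_id, []).append(line)
            self._post_index = index
        return self._post_index

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_posts(self) -> int:
        return len(self.post_index)

    @property
    def n_couples(self) -> int:
        return sum(1 for ln in self.lines if ln.is_normalized_couple)

    def couple_lines(self) -> list[AnnotationLine]:
        return [ln for ln in self.lines if ln.is_normalized_couple]

    def __iter__(self) -> Iterator[AnnotationLine]:
        return iter(self.lines)

    def __len__(self) -> int:
        return len(self.lines)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationCorpus):
            return NotImplemented
        return self.lines == other.lines


# ---------------------------------------------------------------------------
# Vocabulary (toy MedDRA / ATC tables bundled with the package)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PtEntry:
    pt_code: str
    pt_label: str
    hlt: str
    hlgt: str
    soc: str


class Vocabulary:
    """MedDRA PT hierarchy (PT -> HLT -> HLGT -> SOC) and ATC code labels.

    The bundled tables are a small synthetic subset sufficient for tests and
    simulations; the licensed MedDRA and WHO ATC dictionaries are not
    distributed.
    """

    def __init__(
        self,
        pt_entries: Iterable[PtEntry],
        atc_to_label: Mapping[str, str],
    ) -> None:
        self.pt_to_hierarchy: dict[str, PtEntry] = {}
        for entry in pt_entries:
            if not PT_CODE_RE.match(entry.pt_code):
                raise VocabularyError(f"malformed PT code: {entry.pt_code!r}")
            self.pt_to_hierarchy[entry.pt_code] = entry
        self.atc_to_label: dict[str, str] = {}
        for code, label in atc_to_label.items():
            if not ATC5_RE.match(code):
                raise VocabularyError(f"malformed ATC code: {code!r}")
            self.atc_to_label[code] = label
        # reverse indexes for higher-level MedDRA terms (case-insensitive)
        self._level_index: dict[str, set[str]] = {}
        for entry in self.pt_to_hierarchy.values():
            for term in (entry.pt_label, entry.hlt, entry.hlgt, entry.soc):
                self._level_index.setdefault(term.casefold(), set()).add(entry.pt_code)

    @classmethod
    def load_toy(cls) -> "Vocabulary":
        """Load the bundled toy MedDRA/ATC tables."""
        pkg = resources.files("phv") / "data"
        with (pkg / "meddra_toy.csv").open(encoding="utf-8") as fh:
            pts = [
                PtEntry(r["pt_code"], r["pt_label"], r["hlt"], r["hlgt"], r["soc"])
                for r in csv.DictReader(fh)
            ]
        with (pkg / "atc_toy.csv").open(encoding="utf-8") as fh:
            atc = {r["atc_code"]: r["label"] for r in csv.DictReader(fh)}
        return cls(pts, atc)

    def soc_of(self, pt_code: str) -> str:
        try:
            return self.pt_to_hierarchy[pt_code].soc
        except KeyError:
            raise VocabularyError(f"unknown PT code: {pt_code!r}") from None

    def resolve_meddra(self, selector: str | Iterable[str]) -> set[str]:
        """Resolve PT codes and/or higher-level terms to a set of PT codes.

        A selector item that looks like an 8-digit code is taken verbatim;
        anything else is matched (case-insensitively) against PT, HLT, HLGT
        and SOC labels.  An unknown term raises :class:`VocabularyError`.
        """
        items = [selector] if isinstance(selector, str) else list(selector)
        out: set[str] = set()
        for item in items:
            item = item.strip()
            if PT_CODE_RE.match(item):
                out.add(item)
                continue
            codes = self._level_index.get(item.casefold())
            if not codes:
                raise VocabularyError(f"unknown MedDRA term: {item!r}")
            out |= codes
        return out


def resolve_meddra_selector(
    selector: str | Iterable[str], vocabulary: Vocabulary | None
) -> set[str]:
    """Resolve a MedDRA selector, requiring a vocabulary for non-code terms."""
    items = [selector] if isinstance(selector, str) else list(selector)
    if all(PT_CODE_RE.match(i.strip()) for i in items):
        return {i.strip() for i in items}
    if vocabulary is None:
        raise VocabularyError(
            "a Vocabulary is required to resolve non-PT-code MedDRA selectors"
        )
    return vocabulary.resolve_meddra(items)


def atc_matches(code: str | None, selector: str | Iterable[str]) -> bool:
    """True iff an ATC level-5 code matches any selected code or prefix."""
    if code is None:
        return False
    items = [selector] if isinstance(selector, str) else list(selector)
    for item in items:
        item = item.strip()
        if not is_atc_prefix(item):
            raise VocabularyError(f"malformed ATC code or prefix: {item!r}")
        if code.startswith(item):
            return True
    return False


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _cell(row: Mapping[str, str], key: str) -> str | None:
    value = (row.get(key) or "").strip()
    return None if value in _ABSENT else value


def read_annotations(path: str | Path, *, dialect: str = "excel") -> AnnotationCorpus:
    """Read an annotation CSV into a corpus.

    Rows violating the line invariants are rejected, not fatal: they are
    reported with their 1-based data-row numbers on ``corpus.rejected`` so
    that ``len(corpus.lines) + len(corpus.rejected)`` equals the raw data-row
    count.  A missing required column or a syntactically broken file is an
    error.
    """
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, dialect=dialect)
        if reader.fieldnames is None:
            raise MissingColumnsError(list(CSV_COLUMNS))
        missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise MissingColumnsError(missing)
        corpus = AnnotationCorpus()
        for rownum, row in enumerate(reader, start=1):
            try:
                date_raw = (row.get("date") or "").strip()
                try:
                    post_date = parse_post_date(date_raw)
                except ValueError:
                    raise DateParseError(rownum, date_raw)
                time_cell = _cell(row, "time")
                post_time = dt.time.fromisoformat(time_cell) if time_cell else None
                line = AnnotationLine(
                    forum_name=_cell(row, "forum_name") or "",
                    post_id=_cell(row, "post_id") or "",
                    post_date=post_date,
                    post_time=post_time,
                    ade_verbatim=_cell(row, "ade_verbatim"),
                    ade_normalized=_cell(row, "ade_normalized"),
                    ade_cui=_cell(row, "cui"),
                    ade_pt_code=_cell(row, "meddra_code"),
                    drug_verbatim=_cell(row, "drug_verbatim"),
                    drug_normalized=_cell(row, "drug_normalized"),
                    active_ingredient=_cell(row, "active_ingredient"),
                    drug_atc_code=_cell(row, "atc_code"),
                )
                if not line.forum_name or not line.post_id:
                    raise ValueError("forum_name and post_id must be non-empty")
                line.validate()
            except (ValueError, DateParseError) as exc:
                corpus.rejected.append(RejectedRow(rownum, str(exc)))
                continue
            corpus.lines.append(line)
    return corpus


def write_annotations(corpus: AnnotationCorpus, path: str | Path) -> Path:
    """Write a corpus as canonical CSV (ISO dates, empty cells for absents)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for ln in corpus.lines:
            writer.writerow(
                [
                    ln.forum_name,
                    ln.post_id,
                    ln.post_date.isoformat(),
                    ln.post_time.isoformat() if ln.post_time is not None else "",
                    ln.ade_verbatim or "",
                    ln.ade_normalized or "",
                    ln.ade_cui or "",
                    ln.ade_pt_code or "",
                    ln.drug_verbatim or "",
                    ln.drug_normalized or "",
                    ln.active_ingredient or "",
                    ln.drug_atc_code or "",
                ]
            )
    return path


# ---------------------------------------------------------------------------
# Filtering (mirrors the query sidebar: forum, period, drugs, ADEs)
# ---------------------------------------------------------------------------


def filter_corpus(
    corpus: AnnotationCorpus,
    *,
    forums: Iterable[str] | None = None,
    date_range: tuple[dt.date, dt.date] | None = None,
    atc_selector: str | Iterable[str] | None = None,
    meddra_selector: str | Iterable[str] | None = None,
    vocabulary: Vocabulary | None = None,
) -> AnnotationCorpus:
    """Keep lines satisfying all provided criteria; absent criteria are no-ops.

    Drug and ADE selectors match on normalized codes only: when an
    ``atc_selector`` is given, lines without an ATC code are dropped, and
    likewise for ``meddra_selector`` and PT codes.  ``date_range`` is a closed
    interval.  Higher-level MedDRA terms resolve through the vocabulary; an
    unknown term is an error, never an empty result.
    """
    forum_set = set(forums) if forums is not None else None
    pt_set = (
        resolve_meddra_selector(meddra_selector, vocabulary)
        if meddra_selector is not None
        else None
    )
    if date_range is not None and date_range[0] > date_range[1]:
        raise PhvError(f"empty date range: {date_range[0]} > {date_range[1]}")

    kept: list[AnnotationLine] = []
    for ln in corpus.lines:
        if forum_set is not None and ln.forum_name not in forum_set:
            continue
        if date_range is not None and not (
            date_range[0] <= ln.post_date <= date_range[1]
        ):
            continue
        if atc_selector is not None and not atc_matches(ln.drug_atc_code, atc_selector):
            continue
        if pt_set is not None and ln.ade_pt_code not in pt_set:
            continue
        kept.append(ln)
    return AnnotationCorpus(lines=kept)
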