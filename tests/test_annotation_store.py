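"""Corpus data model, CSV round-trips, and query filtering."""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import given
from hypothesis import strategies as st

from phv import (
    AnnotationCorpus,
    AnnotationLine,
    filter_corpus,
    read_annotations,
    write_annotations,
)
from phv.annotation_store import parse_post_date
from phv.errors import MissingColumnsError, VocabularyError


class TestRead:
    def test_sample_corpus_counts(self, sample_corpus):
        """8 annotation rows in one post; only the two rows with both codes
        are normalized couples."""
        assert sample_corpus.n_lines == 8
        assert sample_corpus.n_posts == 1
        assert sample_corpus.n_couples == 2
        assert not sample_corpus.rejected

    def test_em_dash_cells_are_absent(self, sample_corpus):
        calcium = sample_corpus.lines[1]
        assert calcium.drug_verbatim == "Calcium"
        assert calcium.drug_normalized is None
        assert calcium.drug_atc_code is None

    def test_french_diacritics_preserved(self, sample_corpus):
        assert sample_corpus.lines[0].ade_verbatim == "Maux de tête"
        assert sample_corpus.lines[0].ade_normalized == "Céphalée"

    def test_header_only_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(
            "forum_name,post_id,date,time,ade_verbatim,ade_normalized,cui,"
            "meddra_code,drug_verbatim,drug_normalized,active_ingredient,atc_code\n"
        )
        corpus = read_annotations(path)
        assert corpus.n_lines == 0 and corpus.n_posts == 0

    def test_drug_only_row_is_not_a_couple(self):
        line = AnnotationLine(
            forum_name="f",
            post_id="p",
            post_date=dt.date(2018, 1, 1),
            drug_verbatim="levothyrox",
            drug_atc_code="H03AA01",
        )
        line.validate()
        assert not line.is_normalized_couple

    def test_missing_columns_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("forum_name,post_id,date\n")
        with pytest.raises(MissingColumnsError) as exc:
            read_annotations(path)
        assert "atc_code" in str(exc.value) and "meddra_code" in str(exc.value)

    def test_bad_date_rejected_with_row_number(self, tmp_path, sample_csv_path):
        text = sample_csv_path.read_text(encoding="utf-8")
        text += "Atoute,7354,not-a-date,,fatigue,Fatigue,C0015672,10016256,,,,\n"
        path = tmp_path / "withbad.csv"
        path.write_text(text, encoding="utf-8")
        corpus = read_annotations(path)
        assert corpus.n_lines == 8
        assert len(corpus.rejected) == 1
        assert corpus.rejected[0].row == 9
        assert "not-a-date" in corpus.rejected[0].reason

    def test_accepted_plus_rejected_equals_raw(self, tmp_path, sample_csv_path):
        text = sample_csv_path.read_text(encoding="utf-8")
        text += "Atoute,7354,2018-01-01,,,,,,,,,\n"  # no drug and no ADE
        text += "Atoute,7354,2018-01-01,,fatigue,,,badcode,,,,\n"  # bad PT code
        path = tmp_path / "mixed.csv"
        path.write_text(text, encoding="utf-8")
        corpus = read_annotations(path)
        assert corpus.n_lines + len(corpus.rejected) == 10


class TestDates:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("2018-10-08", dt.date(2018, 10, 8)),
            ("October 8, 2018", dt.date(2018, 10, 8)),
            ("January 1, 2017", dt.date(2017, 1, 1)),
        ],
    )
    def test_both_dialects_parse(self, raw, expected):
        assert parse_post_date(raw) == expected

    def test_garbage_raises(self):
        with pytest.raises(ValueError):
            parse_post_date("8/10/2018")


class TestRoundTrip:
    def test_sample_round_trips(self, sample_corpus, tmp_path):
        path = write_annotations(sample_corpus, tmp_path / "out.csv")
        again = read_annotations(path)
        assert again == sample_corpus

    def test_empty_corpus_round_trips(self, tmp_path):
        empty = AnnotationCorpus()
        path = write_annotations(empty, tmp_path / "empty.csv")
        assert read_annotations(path) == empty

    def test_absent_fields_written_as_empty_cells(self, tmp_path):
        corpus = AnnotationCorpus(
            lines=[
                AnnotationLine(
                    forum_name="f",
                    post_id="p",
                    post_date=dt.date(2020, 2, 29),
                    ade_verbatim="fatigue",
                )
            ]
        )
        path = write_annotations(corpus, tmp_path / "sparse.csv")
        raw = path.read_text(encoding="utf-8").splitlines()[1]
        assert "None" not in raw and "—" not in raw
        assert read_annotations(path) == corpus


class TestFilter:
    def test_atc_prefix_selects_levothyrox_rows(self, sample_corpus):
        sub = filter_corpus(sample_corpus, atc_selector="H03AA")
        assert sub.n_lines == 4
        assert all(ln.drug_atc_code == "H03AA01" for ln in sub.lines)

    def test_no_criteria_is_identity(self, sample_corpus):
        assert filter_corpus(sample_corpus) == sample_corpus

    def test_excluding_date_range_empties(self, sample_corpus):
        sub = filter_corpus(
            sample_corpus, date_range=(dt.date(2001, 1, 1), dt.date(2001, 12, 31))
        )
        assert sub.n_lines == 0

    def test_meddra_higher_level_term(self, sample_corpus, vocab):
        sub = filter_corpus(
            sample_corpus,
            meddra_selector="General disorders and administration site conditions",
            vocabulary=vocab,
        )
        # tiredness rows only; weight-decreased rows belong to Investigations
        assert {ln.ade_pt_code for ln in sub.lines} == {"10016256"}

    def test_unknown_meddra_term_is_error(self, sample_corpus, vocab):
        with pytest.raises(VocabularyError):
            filter_corpus(
                sample_corpus, meddra_selector="No such organ class", vocabulary=vocab
            )

    def test_filters_commute_and_conjoin(self, sample_corpus):
        by_forum = dict(forums={"Atoute"})
        by_atc = dict(atc_selector="H03AA01")
        ab = filter_corpus(filter_corpus(sample_corpus, **by_forum), **by_atc)
        ba = filter_corpus(filter_corpus(sample_corpus, **by_atc), **by_forum)
        both = filter_corpus(sample_corpus, **by_forum, **by_atc)
        assert ab == ba == both

    @given(
        dates=st.lists(
            st.dates(dt.date(2017, 1, 1), dt.date(2021, 2, 28)),
            min_size=1,
            max_size=20,
        )
    )
    def test_filter_idempotent(self, dates):
        corpus = AnnotationCorpus(
            lines=[
                AnnotationLine(
                    forum_name="f",
                    post_id=f"p{i}",
                    post_date=d,
                    drug_verbatim="x",
                    drug_atc_code="N02BE01",
                )
                for i, d in enumerate(dates)
            ]
        )
        rng = (dt.date(2018, 1, 1), dt.date(2019, 12, 31))
        once = filter_corpus(corpus, date_range=rng)
        twice = filter_corpus(once, date_range=rng)
        assert once == twice
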