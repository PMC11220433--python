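"""Contingency construction and PRR/ROR estimation."""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phv import (
    AnnotationCorpus,
    ContingencyTable,
    build_contingency,
    cumulative_prr_series,
    prr,
    ror,
)
from phv.errors import EmptyContingencyError
from .conftest import couple_line

cells = st.integers(min_value=1, max_value=500)


class TestBuildContingency:
    def test_six_couple_fixture(self, six_couple_corpus):
        t = build_contingency(six_couple_corpus, "N02BE01", "10016256")
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 2)

    def test_all_drugs_selected_empties_comparator(self, six_couple_corpus):
        """Pooling every drug into the entity of interest leaves no
        comparator events: the other-drugs row is empty."""
        t = build_contingency(
            six_couple_corpus, ["N02BE01", "M01AE01"], "10016256"
        )
        assert t.c == 0 and t.d == 0
        assert t.a + t.b == 6

    def test_sample_corpus_table(self, sample_corpus):
        """The two code-complete rows are both Levothyrox couples: one with
        tiredness (a) and one with another ADE (b)."""
        t = build_contingency(sample_corpus, "H03AA01", "10016256")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 0, 0)

    def test_event_multiplicity_preserved(self):
        lines = [
            couple_line("p1", "N02BE01", "10016256"),
            couple_line("p1", "N02BE01", "10016256"),  # same pair, same post
            couple_line("p1", "M01AE01", "10019211"),
        ]
        t = build_contingency(AnnotationCorpus(lines=lines), "N02BE01", "10016256")
        assert t.a == 2  # counted as many times as annotated

    def test_post_level_sensitivity_mode(self):
        lines = [
            couple_line("p1", "N02BE01", "10016256"),
            couple_line("p1", "N02BE01", "10016256"),
            couple_line("p2", "M01AE01", "10019211"),
        ]
        t = build_contingency(
            AnnotationCorpus(lines=lines), "N02BE01", "10016256", by="posts"
        )
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)

    def test_no_couples_is_error(self):
        with pytest.raises(EmptyContingencyError):
            build_contingency(AnnotationCorpus(), "N02BE01", "10016256")

    def test_matches_pandas_oracle_on_random_corpora(self):
        """Event classification agrees with an independent pandas crosstab."""
        rng = np.random.default_rng(20240901)
        drugs = ["N02BE01", "M01AE01", "H03AA01", "N06AB10"]
        ades = ["10016256", "10019211", "10013573"]
        for _ in range(25):
            n = int(rng.integers(1, 200))
            lines = [
                couple_line(
                    f"p{int(rng.integers(0, 40))}",
                    drugs[int(rng.integers(0, len(drugs)))],
                    ades[int(rng.integers(0, len(ades)))],
                )
                for _ in range(n)
            ]
            corpus = AnnotationCorpus(lines=lines)
            t = build_contingency(corpus, "N02BE01", "10016256")
            df = pd.DataFrame(
                {
                    "drug": [ln.drug_atc_code == "N02BE01" for ln in lines],
                    "ade": [ln.ade_pt_code == "10016256" for ln in lines],
                }
            )
            xt = pd.crosstab(df.drug, df.ade).reindex(
                index=[True, False], columns=[True, False], fill_value=0
            )
            assert (t.a, t.b, t.c, t.d) == (
                xt.loc[True, True],
                xt.loc[True, False],
                xt.loc[False, True],
                xt.loc[False, False],
            )


class TestPrr:
    def test_hand_example_point_and_ci(self):
        est = prr(ContingencyTable(2, 1, 1, 2))
        assert est.point == pytest.approx(2.0)
        expected_low = math.log(2) - 1.96 * math.sqrt(0.5 - 1 / 3 + 1 - 1 / 3)
        assert est.log_ci_low == pytest.approx(expected_low, abs=1e-3)
        assert est.log_ci_low == pytest.approx(-1.096, abs=1e-3)
        assert not est.is_signal

    def test_independence_gives_one(self):
        assert prr(ContingencyTable(5, 5, 5, 5)).point == pytest.approx(1.0)

    def test_tenfold_reporting_rate(self):
        assert prr(ContingencyTable(10, 90, 100, 9900)).point == pytest.approx(10.0)

    def test_zero_cell_strict_not_computable(self):
        est = prr(ContingencyTable(0, 5, 5, 5))
        assert not est.computable and not est.is_signal
        assert math.isnan(est.point)

    def test_zero_cell_haldane(self):
        est = prr(ContingencyTable(0, 5, 5, 5), zero_cell="haldane")
        assert est.computable
        assert est.point == pytest.approx((0.5 / 6) / (5.5 / 11))


class TestRor:
    def test_hand_example(self):
        assert ror(ContingencyTable(2, 1, 1, 2)).point == pytest.approx(4.0)

    def test_independence_gives_one(self):
        assert ror(ContingencyTable(5, 5, 5, 5)).point == pytest.approx(1.0)

    def test_cross_product(self):
        assert ror(ContingencyTable(10, 90, 100, 9900)).point == pytest.approx(11.0)

    def test_signal_rule_is_log_lower_bound(self):
        est = ror(ContingencyTable(50, 10, 10, 50))
        assert est.is_signal and est.log_ci_low > 0
        assert est.log_point == pytest.approx(math.log(est.point))

    @given(a=cells, b=cells, c=cells, d=cells, k=st.integers(2, 9))
    def test_scale_invariance(self, a, b, c, d, k):
        base = prr(ContingencyTable(a, b, c, d)).point
        scaled = prr(ContingencyTable(k * a, k * b, k * c, k * d)).point
        assert scaled == pytest.approx(base)
        base_r = ror(ContingencyTable(a, b, c, d)).point
        scaled_r = ror(ContingencyTable(k * a, k * b, k * c, k * d)).point
        assert scaled_r == pytest.approx(base_r)

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_row_swap_reciprocity(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        assert ror(t.swapped_rows()).point == pytest.approx(1.0 / ror(t).point)


class TestCumulativePrr:
    def test_series_constant_once_counts_stop_changing(self):
        lines = [
            couple_line("p1", "N02BE01", "10016256", dt.date(2018, 1, 5)),
            couple_line("p2", "M01AE01", "10019211", dt.date(2018, 1, 9)),
            couple_line("p3", "M01AE01", "10016256", dt.date(2018, 1, 9)),
            couple_line("p4", "N02BE01", "10019211", dt.date(2018, 1, 20)),
            # empty trailing months: nothing new after January
            couple_line("p5", "M01AE01", "10019211", dt.date(2018, 4, 2)),
        ]
        series = cumulative_prr_series(
            AnnotationCorpus(lines=lines), "N02BE01", "10016256"
        )
        assert len(series) == 4
        points = [e.point for _, e in series]
        assert points[0] == pytest.approx(points[1])

    def test_single_month_equals_whole_corpus(self, six_couple_corpus):
        series = cumulative_prr_series(six_couple_corpus, "N02BE01", "10016256")
        assert len(series) == 1
        whole = prr(build_contingency(six_couple_corpus, "N02BE01", "10016256"))
        assert series[0][1].point == pytest.approx(whole.point)

    def test_two_month_cumulation(self, six_couple_corpus):
        """Adding one (a) and one (d) event in month 2 cumulates the cells to
        (3,1,1,3), whose proportional reporting ratio is (3/4)/(1/4) = 3."""
        extra = [
            couple_line("p7", "N02BE01", "10016256", dt.date(2018, 2, 10)),
            couple_line("p8", "M01AE01", "10019211", dt.date(2018, 2, 11)),
        ]
        corpus = AnnotationCorpus(lines=six_couple_corpus.lines + extra)
        series = cumulative_prr_series(corpus, "N02BE01", "10016256")
        assert len(series) == 2
        assert series[0][1].point == pytest.approx(2.0)
        assert series[1][1].point == pytest.approx(3.0)

    def test_not_computable_months_are_marked(self):
        lines = [
            couple_line("p1", "N02BE01", "10016256", dt.date(2018, 1, 5)),
            couple_line("p2", "M01AE01", "10016256", dt.date(2018, 3, 5)),
        ]
        series = cumulative_prr_series(
            AnnotationCorpus(lines=lines), "N02BE01", "10016256"
        )
        assert not series[0][1].computable  # no comparator events yet
        assert series[-1][1].computable
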