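"""Shared fixtures: the printed-table sample corpus and the toy vocabulary."""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import settings

from phv import AnnotationCorpus, AnnotationLine, Vocabulary

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

#: The published 8-row sample of the annotated database: one post from the
#: Atoute forum, four drug verbatims x two ADE verbatims, with only the two
#: Levothyrox rows carrying both a MedDRA PT code and an ATC code.
SAMPLE_CSV = """\
forum_name,post_id,date,time,ade_verbatim,ade_normalized,cui,meddra_code,drug_verbatim,drug_normalized,active_ingredient,atc_code
Atoute,7354,"October 8, 2018",21:37:00,Maux de tête,Céphalée,C0018681,,Lévothyrox,LEVOTHYROX,Levothyroxine sodique,H03AA01
Atoute,7354,"October 8, 2018",21:37:00,Maux de tête,Céphalée,C0018681,—,Calcium,—,—,—
Atoute,7354,"October 8, 2018",21:37:00,Nodules cancereux,—,—,—,Lévothyrox,LEVOTHYROX,Levothyroxine sodique,H03AA01
Atoute,7354,"October 8, 2018",21:37:00,Nodules cancereux,—,—,—,Calcium,—,—,—
Atoute,7354,"October 8, 2018",21:37:00,Fatigue,Fatigue,C0015672,10016256,Lévothyrox,LEVOTHYROX,Levothyroxine sodique,H03AA01
Atoute,7354,"October 8, 2018",21:37:00,fatigue,Fatigue,C0015672,10016256,Calcium,—,—,—
Atoute,7354,"October 8, 2018",21:37:00,Perte de poids,Poids diminué,C0043096,10048061,Lévothyrox,LEVOTHYROX,Levothyroxine sodique,H03AA01
Atoute,7354,"October 8, 2018",21:37:00,Perte de poids,Poids diminué,C0043096,10048061,Calcium,—,—,—
"""


@pytest.fixture(scope="session")
def vocab() -> Vocabulary:
    return Vocabulary.load_toy()


@pytest.fixture()
def sample_csv_path(tmp_path):
    path = tmp_path / "sample.csv"
    path.write_text(SAMPLE_CSV, encoding="utf-8")
    return path


@pytest.fixture()
def sample_corpus(sample_csv_path):
    from phv import read_annotations

    return read_annotations(sample_csv_path)


def couple_line(
    post_id: str,
    atc: str,
    pt: str,
    date: dt.date = dt.date(2018, 1, 15),
    forum: str = "forum-a",
) -> AnnotationLine:
    """A minimal normalized drug-ADE couple line for hand-built fixtures."""
    return AnnotationLine(
        forum_name=forum,
        post_id=post_id,
        post_date=date,
        ade_verbatim="ade",
        ade_pt_code=pt,
        drug_verbatim="drug",
        drug_atc_code=atc,
    )


@pytest.fixture()
def six_couple_corpus() -> AnnotationCorpus:
    """Six couple events: (D1,E1)x2, (D1,E2)x1, (D2,E1)x1, (D2,E2)x2."""
    d1, d2 = "N02BE01", "M01AE01"
    e1, e2 = "10016256", "10019211"
    lines = [
        couple_line("p1", d1, e1),
        couple_line("p2", d1, e1),
        couple_line("p3", d1, e2),
        couple_line("p4", d2, e1),
        couple_line("p5", d2, e2),
        couple_line("p6", d2, e2),
    ]
    return AnnotationCorpus(lines=lines)
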