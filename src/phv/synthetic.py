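"""Synthetic annotation-corpus generator with controlled ground truth.

Emulates the output of a forum-scraping/NLP-annotation pipeline so that every
analytic module can be exercised offline: each simulated post gets a forum, a
calendar month (optionally volume-shifted at a configured changepoint), a set
of drug mentions, and a set of adverse events whose per-post odds follow a
logistic model — the log-odds of ADE j is its baseline logit plus
sum(ln rho_ij) over mentioned drugs i, so the configured odds multipliers are
exactly the coefficients a lasso-type detector should recover and rho > 1
inflates the couple rate a disproportionality analysis should flag.

Mentions materialize as annotation rows: each co-present (drug, ADE) pair
becomes a couple row with a pairing probability calibrated so the mean number
of couple rows per post matches ``couples_per_post``; mentions left unpaired
become drug-only or ADE-only rows.  Verbatim text fields are lowercase
variants of the catalog labels — schema-complete but with no linguistic
content.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.special import expit

from .annotation_store import AnnotationCorpus, AnnotationLine, Vocabulary
from .errors import ConfigError

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


class DrugSpec(BaseModel):
    atc_code: str
    label: str
    p_mention: float = Field(gt=0.0, le=1.0)


class AdeSpec(BaseModel):
    pt_code: str
    label: str
    p_baseline: float = Field(gt=0.0, lt=1.0)


class RateShift(BaseModel):
    """A step change applied from ``month_index`` (0-based) onward.

    ``target='volume'`` multiplies the monthly post volume;
    ``target=(atc, pt)`` multiplies that pair's association odds.
    """

    month_index: int = Field(ge=0)
    multiplier: float = Field(gt=0.0)
    target: Literal["volume"] | tuple[str, str] = "volume"


class SimulationConfig(BaseModel):
    """Ground-truth description of a simulated corpus.

    Defaults mirror the structure of a large multi-forum corpus at desk
    scale: a couple of thousand posts over four years, about one annotation
    row per five posts, and independence (rho = 1) everywhere unless an
    association is configured.
    """

    n_posts: int = Field(default=2000, ge=0)
    start_month: str = "2017-01"
    n_months: int = Field(default=50, ge=1)
    forum_weights: dict[str, float] = Field(
        default_factory=lambda: {"sante-forum": 0.6, "vivre-mieux": 0.3, "atoute": 0.1}
    )
    drug_catalog: list[DrugSpec] = Field(default_factory=list)
    ade_catalog: list[AdeSpec] = Field(default_factory=list)
    #: (ATC, PT) -> odds multiplier rho; absent pairs default to 1 (independence)
    association: dict[tuple[str, str], float] = Field(default_factory=dict)
    couples_per_post: float = Field(default=0.2, ge=0.0)
    rate_shift: Optional[RateShift] = None
    seed: int = 0

    @field_validator("forum_weights")
    @classmethod
    def _weights_sum_to_one(cls, v: dict[str, float]) -> dict[str, float]:
        if not v:
            raise ValueError("forum_weights must not be empty")
        if any(w < 0 for w in v.values()):
            raise ValueError("forum_weights must be nonnegative")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError(f"forum_weights sum to {sum(v.values())}, expected 1")
        return v

    @field_validator("association")
    @classmethod
    def _rho_nonnegative(cls, v: dict) -> dict:
        for pair, rho in v.items():
            if rho < 0:
                raise ValueError(f"association multiplier for {pair} must be >= 0")
        return v

    @model_validator(mode="after")
    def _shift_in_period(self) -> "SimulationConfig":
        if self.rate_shift is not None and self.rate_shift.month_index >= self.n_months:
            raise ValueError(
                f"rate_shift month_index {self.rate_shift.month_index} outside the "
                f"{self.n_months}-month period"
            )
        return self


@dataclass
class GroundTruth:
    """Everything needed to test recovery of the designed structure."""

    pair_multipliers: dict[tuple[str, str], float]
    true_changepoint_months: list[int]
    posts_per_month: np.ndarray
    #: realized (a, b, c, d) couple-event cells per designed pair
    pair_cells: dict[tuple[str, str], tuple[int, int, int, int]]
    n_couple_events: int
    drug_mention_counts: dict[str, int]
    ade_mention_counts: dict[str, int]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _month_weights(config: SimulationConfig) -> np.ndarray:
    w = np.ones(config.n_months)
    shift = config.rate_shift
    if shift is not None and shift.target == "volume":
        w[shift.month_index :] *= shift.multiplier
    return w / w.sum()


def _verbatim(rng: np.random.Generator, label: str) -> str:
    """A lowercase label variant standing in for free text."""
    text = label.lower()
    return text.capitalize() if rng.random() < 0.3 else text


def simulate_corpus(
    config: SimulationConfig, seed: int | None = None
) -> tuple[AnnotationCorpus, GroundTruth]:
    """Generate a corpus and its ground truth; identical seeds give identical
    corpora byte-for-byte after serialization."""
    if not config.drug_catalog or not config.ade_catalog:
        if config.n_posts > 0:
            raise ConfigError("drug_catalog and ade_catalog must be non-empty")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_posts
    n_drugs = len(config.drug_catalog)
    n_ades = len(config.ade_catalog)
    start = pd.Period(config.start_month, freq="M")
    months_ix = pd.period_range(start, periods=config.n_months, freq="M")

    truth = GroundTruth(
        pair_multipliers=dict(config.association),
        true_changepoint_months=(
            [config.rate_shift.month_index] if config.rate_shift is not None else []
        ),
        posts_per_month=np.zeros(config.n_months, dtype=int),
        pair_cells={pair: (0, 0, 0, 0) for pair in config.association},
        n_couple_events=0,
        drug_mention_counts={d.atc_code: 0 for d in config.drug_catalog},
        ade_mention_counts={a.pt_code: 0 for a in config.ade_catalog},
    )
    corpus = AnnotationCorpus()
    if n == 0:
        return corpus, truth

    # vectorized post-level draws
    month_of_post = rng.choice(config.n_months, size=n, p=_month_weights(config))
    forum_labels = list(config.forum_weights)
    forum_of_post = rng.choice(
        len(forum_labels), size=n, p=np.array(list(config.forum_weights.values()))
    )
    p_mention = np.array([d.p_mention for d in config.drug_catalog])
    mentions = rng.random((n, n_drugs)) < p_mention  # drug presence per post

    # per-ADE log-odds: baseline logit plus sum of ln(rho) over mentioned drugs
    base_logit = np.array(
        [np.log(a.p_baseline / (1 - a.p_baseline)) for a in config.ade_catalog]
    )
    log_rho = np.zeros((n_drugs, n_ades))
    drug_ix = {d.atc_code: i for i, d in enumerate(config.drug_catalog)}
    ade_ix = {a.pt_code: j for j, a in enumerate(config.ade_catalog)}
    for (atc, pt), rho in config.association.items():
        if atc not in drug_ix or pt not in ade_ix:
            raise ConfigError(f"association pair {(atc, pt)} not in the catalogs")
        if rho == 0:
            log_rho[drug_ix[atc], ade_ix[pt]] = -np.inf
        else:
            log_rho[drug_ix[atc], ade_ix[pt]] = np.log(rho)
    shift = config.rate_shift
    pair_shift = shift is not None and shift.target != "volume"
    logits = base_logit + mentions.astype(float) @ np.where(
        np.isneginf(log_rho), -1e9, log_rho
    )
    if pair_shift:
        s_atc, s_pt = shift.target  # type: ignore[misc]
        if s_atc not in drug_ix or s_pt not in ade_ix:
            raise ConfigError(f"rate_shift pair {shift.target} not in the catalogs")
        shifted = (month_of_post >= shift.month_index) & mentions[:, drug_ix[s_atc]]
        logits[shifted, ade_ix[s_pt]] += np.log(shift.multiplier)
    ade_present = rng.random((n, n_ades)) < expit(logits)

    # pairing probability calibrated to couples_per_post at independence
    p_base = np.array([a.p_baseline for a in config.ade_catalog])
    mean_cooccur = float(p_mention.sum() * p_base.sum())
    p_pair = min(1.0, config.couples_per_post / mean_cooccur) if mean_cooccur else 0.0

    pair_cells = {pair: [0, 0, 0, 0] for pair in config.association}
    lines: list[AnnotationLine] = []
    for p in range(n):
        month = months_ix[int(month_of_post[p])]
        truth.posts_per_month[int(month_of_post[p])] += 1
        last_day = calendar.monthrange(month.year, month.month)[1]
        date = dt.date(month.year, month.month, int(rng.integers(1, last_day + 1)))
        time = dt.time(int(rng.integers(0, 24)), int(rng.integers(0, 60)))
        forum = forum_labels[int(forum_of_post[p])]
        post_id = f"P{p:07d}"
        drugs_here = np.flatnonzero(mentions[p])
        ades_here = np.flatnonzero(ade_present[p])
        for i in drugs_here:
            truth.drug_mention_counts[config.drug_catalog[i].atc_code] += 1
        for j in ades_here:
            truth.ade_mention_counts[config.ade_catalog[j].pt_code] += 1
        paired_drugs: set[int] = set()
        paired_ades: set[int] = set()
        for i in drugs_here:
            for j in ades_here:
                if rng.random() >= p_pair:
                    continue
                drug = config.drug_catalog[i]
                ade = config.ade_catalog[j]
                lines.append(
                    AnnotationLine(
                        forum_name=forum,
                        post_id=post_id,
                        post_date=date,
                        post_time=time,
                        ade_verbatim=_verbatim(rng, ade.label),
                        ade_normalized=ade.label,
                        ade_cui="C" + ade.pt_code[1:],
                        ade_pt_code=ade.pt_code,
                        drug_verbatim=_verbatim(rng, drug.label),
                        drug_normalized=drug.label.upper(),
                        active_ingredient=drug.label,
                        drug_atc_code=drug.atc_code,
                    )
                )
                paired_drugs.add(int(i))
                paired_ades.add(int(j))
                truth.n_couple_events += 1
                for pair, cells in pair_cells.items():
                    drug_hit = drug.atc_code == pair[0]
                    ade_hit = ade.pt_code == pair[1]
                    cells[0 if drug_hit and ade_hit else 1 if drug_hit else 2 if ade_hit else 3] += 1
        for i in drugs_here:
            if int(i) in paired_drugs:
                continue
            drug = config.drug_catalog[i]
            lines.append(
                AnnotationLine(
                    forum_name=forum,
                    post_id=post_id,
                    post_date=date,
                    post_time=time,
                    drug_verbatim=_verbatim(rng, drug.label),
                    drug_normalized=drug.label.upper(),
                    active_ingredient=drug.label,
                    drug_atc_code=drug.atc_code,
                )
            )
        for j in ades_here:
            if int(j) in paired_ades:
                continue
            ade = config.ade_catalog[j]
            lines.append(
                AnnotationLine(
                    forum_name=forum,
                    post_id=post_id,
                    post_date=date,
                    post_time=time,
                    ade_verbatim=_verbatim(rng, ade.label),
                    ade_normalized=ade.label,
                    ade_cui="C" + ade.pt_code[1:],
                    ade_pt_code=ade.pt_code,
                )
            )
    corpus.lines = lines
    truth.pair_cells = {pair: tuple(cells) for pair, cells in pair_cells.items()}
    return corpus, truth


# ---------------------------------------------------------------------------
# Packaged surge scenario
# ---------------------------------------------------------------------------

#: Levothyroxine sodium (ATC) and the "Tiredness" preferred term (MedDRA)
LEVO_ATC = "H03AA01"
TIREDNESS_PT = "10016256"
SURGE_MONTH_INDEX = 24


def scenario_levothyrox_config(seed: int = 0) -> SimulationConfig:
    """A 50-month thyroid-forum scenario with a mid-period volume surge.

    One forum dominates the corpus (~82% of posts, mirroring how a drug's
    chatter concentrates on its community forum), the levothyroxine-class
    drug is mentioned in about a third of the posts, its association with
    tiredness is strongly elevated (rho = 8), and the monthly post volume
    triples at month index 24 — a ground-truth changepoint.
    """
    vocab = Vocabulary.load_toy()
    drugs = [
        DrugSpec(atc_code=LEVO_ATC, label=vocab.atc_to_label[LEVO_ATC], p_mention=0.35),
        DrugSpec(atc_code="H03AA02", label=vocab.atc_to_label["H03AA02"], p_mention=0.04),
        DrugSpec(atc_code="N02BE01", label=vocab.atc_to_label["N02BE01"], p_mention=0.10),
        DrugSpec(atc_code="A12AA04", label=vocab.atc_to_label["A12AA04"], p_mention=0.08),
        DrugSpec(atc_code="N06AB10", label=vocab.atc_to_label["N06AB10"], p_mention=0.05),
        DrugSpec(atc_code="C07AB02", label=vocab.atc_to_label["C07AB02"], p_mention=0.05),
        DrugSpec(atc_code="A02BC01", label=vocab.atc_to_label["A02BC01"], p_mention=0.06),
    ]
    ade_labels = {
        TIREDNESS_PT: 0.08,
        "10033371": 0.10,  # Pain
        "10013573": 0.06,  # Dizziness
        "10022437": 0.05,  # Insomnia
        "10021097": 0.08,  # Hypothyroidism
        "10019211": 0.06,  # Headache
        "10028813": 0.05,  # Nausea
        "10048061": 0.05,  # Weight decreased
    }
    ades = [
        AdeSpec(pt_code=pt, label=vocab.pt_to_hierarchy[pt].pt_label, p_baseline=p)
        for pt, p in ade_labels.items()
    ]
    return SimulationConfig(
        n_posts=4000,
        start_month="2017-01",
        n_months=50,
        forum_weights={
            "Vivre sans thyroïde": 0.82,
            "Doctissimo Santé": 0.08,
            "Doctissimo Grossesse": 0.03,
            "Carenity": 0.02,
            "Allo docteurs": 0.02,
            "Atoute": 0.02,
            "Que choisir": 0.01,
        },
        drug_catalog=drugs,
        ade_catalog=ades,
        association={(LEVO_ATC, TIREDNESS_PT): 8.0},
        couples_per_post=0.6,
        rate_shift=RateShift(month_index=SURGE_MONTH_INDEX, multiplier=3.0),
        seed=seed,
    )


def scenario_levothyrox(seed: int = 0) -> tuple[AnnotationCorpus, GroundTruth]:
    """Generate the packaged surge scenario (see
    :func:`scenario_levothyrox_config`)."""
    return simulate_corpus(scenario_levothyrox_config(seed))
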