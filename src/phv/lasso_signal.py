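"""Class-imbalanced subsampling lasso for drug-safety signal detection.

Posts with the adverse event of interest (cases, set S1 of size n1) are vastly
outnumbered by posts without it (set S0 of size n0).  The detector therefore
repeats, over B resamples: draw n1 posts with replacement from S1 and
R = max(4*n1, 4*Nm) posts with replacement from S0 (Nm = number of drug
predictors), then fit an L1-penalized logistic regression of adverse-event
presence on all per-post drug-presence indicators.  Each drug accumulates one
coefficient per draw (0 when shrunk out of the model); a drug is retained as a
signal when the q-th percentile of its coefficient collection across the B
draws is strictly positive, q in {5, 10, 15}.  Lower q is the stricter rule:
the 5th percentile exceeds 0 only when at least ~95% of draws give a positive
coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from pydantic import BaseModel, Field
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

from .annotation_store import AnnotationCorpus, Vocabulary, resolve_meddra_selector
from .errors import DegenerateDesignError, PhvError

# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignMatrix:
    """Per-post outcome indicator and binary drug-presence matrix.

    ``y[p]`` is 1 iff post p carries at least one annotation of the ADE of
    interest; ``X[p, i]`` is 1 iff drug i (an ATC level-5 code) is annotated
    at least once in post p — presence, never multiplicity.  All-zero drug
    columns are dropped and reported in ``dropped_drugs``.
    """

    y: np.ndarray
    X: np.ndarray
    drug_codes: tuple[str, ...]
    post_ids: tuple[str, ...]
    dropped_drugs: tuple[str, ...] = ()

    @property
    def n1(self) -> int:
        return int(self.y.sum())

    @property
    def n0(self) -> int:
        return int(len(self.y) - self.y.sum())

    @property
    def Nm(self) -> int:
        return self.X.shape[1]


def build_design(
    corpus: AnnotationCorpus,
    ade_selector: str | Iterable[str],
    *,
    vocabulary: Vocabulary | None = None,
) -> DesignMatrix:
    """Binary outcome/drug-presence design from a corpus.

    A drug annotated in a post is assumed taken by the author; repeated
    annotations of the same drug in a post still yield a single 1.  Raises
    :class:`DegenerateDesignError` when every post, or no post, has the
    outcome.
    """
    pt_set = resolve_meddra_selector(ade_selector, vocabulary)
    post_ids = sorted(corpus.post_index)
    drug_codes = sorted(
        {ln.drug_atc_code for ln in corpus.lines if ln.drug_atc_code is not None}
    )
    if not post_ids:
        raise DegenerateDesignError("empty corpus")
    col = {code: i for i, code in enumerate(drug_codes)}
    y = np.zeros(len(post_ids), dtype=np.int8)
    X = np.zeros((len(post_ids), len(drug_codes)), dtype=np.int8)
    row = {pid: p for p, pid in enumerate(post_ids)}
    for ln in corpus.lines:
        p = row[ln.post_id]
        if ln.ade_pt_code is not None and ln.ade_pt_code in pt_set:
            y[p] = 1
        if ln.drug_atc_code is not None:
            X[p, col[ln.drug_atc_code]] = 1
    keep = X.any(axis=0)
    dropped = tuple(c for c, k in zip(drug_codes, keep) if not k)
    X = X[:, keep]
    kept_codes = tuple(c for c, k in zip(drug_codes, keep) if k)
    n1 = int(y.sum())
    if n1 == 0 or n1 == len(y):
        raise DegenerateDesignError(
            f"degenerate design: {n1} of {len(y)} posts have the outcome"
        )
    if not kept_codes:
        raise DegenerateDesignError("no drug with at least one mention")
    return DesignMatrix(
        y=y,
        X=X,
        drug_codes=kept_codes,
        post_ids=tuple(post_ids),
        dropped_drugs=dropped,
    )


# ---------------------------------------------------------------------------
# Configuration and result containers
# ---------------------------------------------------------------------------


class CissLassoConfig(BaseModel):
    """Tuning parameters of the subsampling-lasso detector.

    ``B`` resamples of size n1 + max(4*n1, 4*Nm); at most ``max_predictors``
    drugs may enter any fitted model; ``q`` is the retention percentile.  The
    penalty is chosen per draw by walking the regularization path from the
    no-predictor end downward and stopping at the smallest penalty whose
    active set still respects ``max_predictors`` (``lambda_mode='path_cap'``),
    or by cross-validation (``'cv'``).
    """

    B: int = Field(default=250, ge=1)
    max_predictors: int = Field(default=50, ge=1)
    q: Literal[5, 10, 15] = 10
    seed: int = 0
    lambda_mode: Literal["path_cap", "cv"] = "path_cap"
    #: geometric path floor as a fraction of the entry penalty
    lambda_min_ratio: float = Field(default=0.1, gt=0.0, lt=1.0)
    n_lambdas: int = Field(default=15, ge=2)
    #: retention statistic: per-draw coefficients (default) or selection counts
    retention: Literal["coefficients", "selection_counts"] = "coefficients"


@dataclass(frozen=True)
class LassoResult:
    """Per-drug coefficient distribution over the B draws and the retained set."""

    drug_codes: tuple[str, ...]
    coef_samples: np.ndarray  # shape (B, Nm)
    selection_counts: np.ndarray  # per drug: #draws with coefficient > 0
    q_percentiles: np.ndarray  # per drug: q-th percentile of coef_samples
    retained: tuple[str, ...]
    model_sizes: np.ndarray  # per draw: #nonzero coefficients
    n_refit: int  # draws re-drawn once after a convergence failure
    n_failed: int  # draws recorded as all-zero after the retry also failed
    config: CissLassoConfig

    def retained_at(self, q: int) -> tuple[str, ...]:
        """Retained set recomputed at another percentile of the same draws."""
        pct = np.percentile(self.coef_samples, q, axis=0)
        return tuple(c for c, p in zip(self.drug_codes, pct) if p > 0)

    def to_dict(self) -> dict:
        return {
            "drugs": list(self.drug_codes),
            "selection_counts": self.selection_counts.tolist(),
            "q_percentiles": self.q_percentiles.tolist(),
            "retained": list(self.retained),
            "model_sizes": self.model_sizes.tolist(),
            "n_refit": self.n_refit,
            "n_failed": self.n_failed,
            "config": self.config.model_dump(),
        }


# ---------------------------------------------------------------------------
# Per-draw lasso fit
# ---------------------------------------------------------------------------


def _lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Entry penalty: sup-norm of the null-model score, in liblinear's
    sum-loss scale (penalty 1/C multiplies the L1 norm against the summed
    log-likelihood, so the score is not divided by n)."""
    resid = y - y.mean()
    return float(np.max(np.abs(X.T @ resid)))


def _fit_l1(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray | None:
    model = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / lam,
        solver="liblinear",
        max_iter=2000,
        tol=1e-6,
        random_state=0,  # liblinear shuffles internally; pin for replay
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(X, y)
        except ConvergenceWarning:
            return None
    return model.coef_.ravel()


def _fit_path_cap(
    X: np.ndarray, y: np.ndarray, config: CissLassoConfig
) -> np.ndarray | None:
    """Coefficients at the smallest path penalty whose active set respects
    ``max_predictors``, or None on a convergence failure.

    The path runs geometrically from the entry penalty (where the first
    predictor would enter) down to ``lambda_min_ratio`` times it.  The floor
    model is fitted first: when it already respects the cap — always the case
    when there are at most ``max_predictors`` candidate drugs — it is the
    selected model and no other fit is needed.  Otherwise the path is walked
    downward from the entry point and stops just before the cap is exceeded.
    """
    lam_max = _lambda_max(X, y)
    if lam_max <= 0:  # no predictor carries any score: null model
        return np.zeros(X.shape[1])
    lams = lam_max * config.lambda_min_ratio ** (
        np.linspace(0.0, 1.0, config.n_lambdas)
    )
    floor = _fit_l1(X, y, lams[-1])
    if floor is None:
        return None
    if np.count_nonzero(floor) <= config.max_predictors:
        return floor
    best: np.ndarray = np.zeros(X.shape[1])
    for lam in lams[1:-1]:  # lams[0] = entry point, empty model by construction
        coef = _fit_l1(X, y, lam)
        if coef is None:
            return None
        if np.count_nonzero(coef) > config.max_predictors:
            break
        best = coef
    return best


def _fit_cv(X: np.ndarray, y: np.ndarray, config: CissLassoConfig, seed: int):
    model = LogisticRegressionCV(
        l1_ratios=[1.0],
        solver="liblinear",
        scoring="neg_log_loss",
        Cs=10,
        cv=5,
        max_iter=2000,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(X, y)
        except ConvergenceWarning:
            return None
    coef = model.coef_.ravel()
    if np.count_nonzero(coef) > config.max_predictors:
        return None
    return coef


def ciss_lasso(design: DesignMatrix, config: CissLassoConfig) -> LassoResult:
    """Run the subsampling-lasso detector on a design matrix.

    Fully reproducible: the per-draw random streams are spawned
    deterministically from ``config.seed``.  A draw whose fit fails to
    converge is re-drawn once with the spawned retry stream; if that also
    fails the draw is recorded as all-zero and counted in ``n_failed``.
    """
    n1, Nm = design.n1, design.Nm
    if n1 == 0 or design.n0 == 0:
        raise DegenerateDesignError("design has an empty outcome class")
    R = max(4 * n1, 4 * Nm)
    idx1 = np.flatnonzero(design.y == 1)
    idx0 = np.flatnonzero(design.y == 0)
    children = np.random.SeedSequence(config.seed).spawn(config.B)
    coefs = np.zeros((config.B, Nm))
    model_sizes = np.zeros(config.B, dtype=int)
    n_refit = 0
    n_failed = 0
    for b, child in enumerate(children):
        rng = np.random.default_rng(child)
        coef = None
        for attempt in range(2):
            take1 = rng.choice(idx1, size=n1, replace=True)
            take0 = rng.choice(idx0, size=R, replace=True)
            rows = np.concatenate([take1, take0])
            Xb = design.X[rows].astype(np.float64)
            yb = design.y[rows].astype(np.float64)
            if config.lambda_mode == "path_cap":
                coef = _fit_path_cap(Xb, yb, config)
            else:
                coef = _fit_cv(Xb, yb, config, seed=int(child.generate_state(1)[0] >> 1))
            if coef is not None:
                if attempt == 1:
                    n_refit += 1
                break
        if coef is None:
            n_failed += 1
            coef = np.zeros(Nm)
        coefs[b] = coef
        model_sizes[b] = int(np.count_nonzero(coef))

    selection_counts = (coefs > 0).sum(axis=0)
    if config.retention == "coefficients":
        stat = np.percentile(coefs, config.q, axis=0)
    else:
        # selection-count mode: a drug is retained when it is selected
        # (coefficient > 0) in at least (100 - q)% of draws
        stat = selection_counts - (1.0 - config.q / 100.0) * config.B
    retained = tuple(
        code for code, s in zip(design.drug_codes, stat) if s > 0
    )
    return LassoResult(
        drug_codes=design.drug_codes,
        coef_samples=coefs,
        selection_counts=selection_counts,
        q_percentiles=np.percentile(coefs, config.q, axis=0),
        retained=retained,
        model_sizes=model_sizes,
        n_refit=n_refit,
        n_failed=n_failed,
        config=config,
    )
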