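"""CUSUM change-point detection with permutation bootstrap and recursion.

For a segment x_1..x_n with mean m, the CUSUM path is S_0 = 0,
S_i = S_{i-1} + (x_i - m); it ends at S_n = 0 and drifts away from zero when
the segment mean shifts.  The magnitude of the drift, s_diff = max S - min S,
is compared against the same statistic on random reorderings of the segment:
the bootstrap confidence is the fraction of permutations with a smaller
s_diff.  When the confidence reaches the threshold a breakpoint is placed at
the largest |S_i| (earliest index on ties) — the last point of the pre-shift
regime — and the procedure recurses on the sub-segments until no further
significant shift is found.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .descriptives import MonthlyCounts
from .errors import PhvError


@dataclass(frozen=True)
class CusumPath:
    """The cumulative-deviation path of one segment."""

    values: tuple[float, ...]
    mean: float
    S: np.ndarray  # length n+1, S[0] = S[n] = 0 (up to float error)
    s_diff: float
    argmax_abs: int  # index i in 1..n-1 of max |S_i|, earliest on ties


def cusum_path(series: MonthlyCounts | Sequence[float]) -> CusumPath:
    """Cumulative deviations from the segment mean; requires length >= 2."""
    values = np.asarray(
        series.values if isinstance(series, MonthlyCounts) else series, dtype=float
    )
    n = len(values)
    if n < 2:
        raise PhvError(f"cusum_path needs at least 2 points, got {n}")
    mean = float(values.mean())
    S = np.concatenate([[0.0], np.cumsum(values - mean)])
    s_diff = float(S.max() - S.min())
    inner = np.abs(S[1:n])  # S_0 and S_n are 0 by construction
    argmax_abs = int(np.argmax(inner)) + 1
    return CusumPath(
        values=tuple(float(v) for v in values),
        mean=mean,
        S=S,
        s_diff=s_diff,
        argmax_abs=argmax_abs,
    )


class ChangepointConfig(BaseModel):
    """Bootstrap and segmentation parameters."""

    n_bootstrap: int = Field(default=1000, ge=1)
    confidence_threshold: float = Field(default=0.95, gt=0.0, lt=1.0)
    min_segment_length: int = Field(default=6, ge=2)
    seed: int = 0


@dataclass(frozen=True)
class Breakpoint:
    """A detected mean shift after ``index`` observations of the series."""

    index: int
    month: pd.Period | None
    confidence: float
    mean_before: float
    mean_after: float

    @property
    def direction(self) -> int:
        return int(np.sign(self.mean_after - self.mean_before))

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "month": str(self.month) if self.month is not None else None,
            "confidence": self.confidence,
            "mean_before": self.mean_before,
            "mean_after": self.mean_after,
            "direction": self.direction,
        }


def _segment_sdiffs(perms: np.ndarray) -> np.ndarray:
    """s_diff of each row of an (n_perm, n) array of permuted segments."""
    centered = perms - perms.mean(axis=1, keepdims=True)
    cs = np.cumsum(centered, axis=1)
    # include S_0 = 0 in the max/min
    hi = np.maximum(cs.max(axis=1), 0.0)
    lo = np.minimum(cs.min(axis=1), 0.0)
    return hi - lo


def detect_breakpoints(
    series: MonthlyCounts | Sequence[float],
    config: ChangepointConfig | None = None,
) -> list[Breakpoint]:
    """Recursive CUSUM segmentation of a monthly count series.

    Candidate breakpoints are constrained to lie at least
    ``min_segment_length`` observations from each segment boundary, so
    reported breakpoints are pairwise separated by at least that much; a
    segment shorter than twice the minimum is never tested.  Results are
    sorted by index and reproducible for a given seed.
    """
    config = config or ChangepointConfig()
    if isinstance(series, MonthlyCounts):
        values = np.asarray(series.values, dtype=float)
        months = series.months() if not series.is_empty else None
    else:
        values = np.asarray(series, dtype=float)
        months = None
    rng = np.random.default_rng(config.seed)
    found: list[Breakpoint] = []

    def visit(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2 * config.min_segment_length:
            return
        seg = values[lo:hi]
        path = cusum_path(seg)
        if path.s_diff <= 0:
            return
        # candidate split leaving both sides >= min_segment_length
        m = config.min_segment_length
        inner = np.abs(path.S[m : n - m + 1])
        k = int(np.argmax(inner)) + m
        perms = rng.permuted(
            np.broadcast_to(seg, (config.n_bootstrap, n)).copy(), axis=1
        )
        confidence = float(np.mean(_segment_sdiffs(perms) < path.s_diff))
        if confidence < config.confidence_threshold:
            return
        found.append(
            Breakpoint(
                index=lo + k,
                month=months[lo + k] if months is not None else None,
                confidence=confidence,
                mean_before=float(seg[:k].mean()),
                mean_after=float(seg[k:].mean()),
            )
        )
        visit(lo, lo + k)
        visit(lo + k, hi)

    visit(0, len(values))
    return sorted(found, key=lambda bp: bp.index)
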