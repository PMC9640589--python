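"""Group-level inference over per-dataset statistics.

Per-dataset arm correlations and null probabilities are compared between
groups of datasets (e.g. typical vs atypical populations) with a
two-sample equal-variance (homoscedastic) two-tailed t-test, and
summarized descriptively.  No multiple-testing correction is applied: the
design yields a single group test, and the per-dataset probabilities are
descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError

__all__ = ["TTestResult", "GroupSummary", "two_sample_t", "summarize"]


@dataclass(frozen=True)
class TTestResult:
    """Pooled-variance two-sample t-test outcome (df = n1 + n2 - 2)."""

    t: float
    df: int
    p: float
    alpha: float
    mean1: float
    mean2: float
    pooled_var: float

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive summary (mean, min, max) of a list of r or p values."""

    mean: float
    min: float
    max: float
    n: int


def two_sample_t(g1: Sequence[float], g2: Sequence[float],
                 alpha: float = 0.05) -> TTestResult:
    """Homoscedastic two-sample two-tailed t-test.

    Uses the pooled variance estimator with df = n1 + n2 - 2.  Raises
    :class:`DegenerateInputError` when either group has fewer than two
    values or the pooled variance is zero.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError(
            f"two_sample_t needs >= 2 values per group (got {a.size}, {b.size})")
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var == 0:
        raise DegenerateInputError("two_sample_t: zero pooled variance")
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(
        t=float(res.statistic),
        df=int(a.size + b.size - 2),
        p=float(res.pvalue),
        alpha=alpha,
        mean1=float(a.mean()),
        mean2=float(b.mean()),
        pooled_var=float(pooled_var),
    )


def summarize(values: Sequence[float]) -> GroupSummary:
    """Arithmetic mean, minimum and maximum of a non-empty value list."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DegenerateInputError("summarize needs a non-empty list")
    return GroupSummary(mean=float(v.mean()), min=float(v.min()),
                        max=float(v.max()), n=int(v.size))
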