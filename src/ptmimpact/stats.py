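"""Effect-size and significance statistics for group comparisons.

Two-sample comparisons throughout the pipeline use the unpaired
t-test (Student's pooled-variance by default, Welch by flag) and
Cohen's d with the pooled standard deviation

    d = |mean_a - mean_b| / s_pooled,
    s_pooled^2 = ((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2).

Effect sizes follow the conventional bands: d > 0.8 large,
0.5 <= d <= 0.8 medium, 0.2 <= d < 0.5 small, below 0.2 negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "GroupSample",
    "EffectStats",
    "unpaired_t_test",
    "cohens_d",
    "classify_effect_size",
    "compare_groups",
]


@dataclass(frozen=True)
class GroupSample:
    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class EffectStats:
    t: float
    df: float
    p: float
    d: float
    d_signed: float


def unpaired_t_test(
    a: GroupSample, b: GroupSample, equal_variance: bool = True
) -> tuple[float, float, float]:
    """Two-sided unpaired t-test; returns (t, df, p).

    ``equal_variance=True`` is Student's pooled test, ``False`` Welch.
    Two zero-variance groups with equal means give t=0, p=1 by
    convention; a single zero-variance group falls back to Welch.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.values.var(ddof=1), b.values.var(ddof=1)
    if va == 0 and vb == 0:
        df = float(a.n + b.n - 2)
        if a.values.mean() == b.values.mean():
            return 0.0, df, 1.0
        t = math.copysign(math.inf, a.values.mean() - b.values.mean())
        return t, df, 0.0
    if (va == 0) != (vb == 0):
        equal_variance = False  # pooled df misleads with one degenerate group
    res = _sps.ttest_ind(a.values, b.values, equal_var=equal_variance)
    return float(res.statistic), float(res.df), float(res.pvalue)


def cohens_d(a: GroupSample, b: GroupSample) -> tuple[float, float]:
    """Cohen's d with pooled standard deviation; returns (|d|, signed d)."""
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.values.var(ddof=1), b.values.var(ddof=1)
    pooled = ((a.n - 1) * va + (b.n - 1) * vb) / (a.n + b.n - 2)
    if pooled == 0:
        raise ValueError("zero pooled variance")
    d_signed = float((a.values.mean() - b.values.mean()) / math.sqrt(pooled))
    return abs(d_signed), d_signed


def classify_effect_size(d: float) -> str:
    """Conventional bands: > 0.8 large, [0.5, 0.8] medium,
    [0.2, 0.5) small, else negligible."""
    if d < 0:
        raise ValueError("d must be non-negative")
    if d > 0.8:
        return "large"
    if d >= 0.5:
        return "medium"
    if d >= 0.2:
        return "small"
    return "negligible"


def compare_groups(
    a: GroupSample, b: GroupSample, equal_variance: bool = True
) -> EffectStats:
    t, df, p = unpaired_t_test(a, b, equal_variance=equal_variance)
    d, d_signed = cohens_d(a, b)
    return EffectStats(t=t, df=df, p=p, d=d, d_signed=d_signed)
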