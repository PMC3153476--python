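"""Behavioral response-index statistic and the comparisons built on it.

The Petri-dish locomotor assay scores each plate by the response index

    RI = 100 * (n_attracted - n_repulsed) / n_total

which lies in [-100, 100]; positive values mean attraction. Indices are
compared against zero with one-sample t-tests, and masked vs unmasked
conditions with Welch's two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats


class DegenerateTestError(ValueError):
    """The requested test is undefined for the given data (zero variance)."""


@dataclass(frozen=True)
class AssayCount:
    """Larva counts from one plate: attracted / repulsed zones and total."""

    n_att: int
    n_rep: int
    n_tot: int

    def __post_init__(self):
        if self.n_att < 0 or self.n_rep < 0:
            raise ValueError("zone counts must be >= 0")
        if self.n_tot <= 0:
            raise ValueError("n_tot must be > 0")
        if self.n_att + self.n_rep > self.n_tot:
            raise ValueError("zone counts exceed the total number of larvae")


def response_index(a: AssayCount) -> float:
    """100 * (n_att - n_rep) / n_tot, in [-100, 100]."""
    return 100.0 * (a.n_att - a.n_rep) / a.n_tot


def index_vs_zero(indices: Sequence[float]) -> Tuple[float, int, float]:
    """One-sample t-test of response indices against zero.

    Returns (t, df, two-sided p) with df = n - 1.
    """
    x = np.asarray(indices, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 indices")
    if x.std(ddof=1) == 0:
        raise DegenerateTestError("all indices identical; t-test undefined")
    t, p = stats.ttest_1samp(x, 0.0)
    return float(t), int(x.size - 1), float(p)


@dataclass(frozen=True)
class MaskEffect:
    t: float
    df: float
    p: float
    direction: str  # 'reduced', 'increased' or 'none'


def mask_effect(
    no_mask: Sequence[float],
    with_mask: Sequence[float],
    alpha: float = 0.05,
) -> MaskEffect:
    """Welch two-sample comparison of response indices with vs without a
    masking background odor. ``direction`` is 'reduced' when the masked
    indices are significantly lower (two-sided p < alpha), 'increased'
    when significantly higher, else 'none'."""
    x = np.asarray(no_mask, dtype=float)
    y = np.asarray(with_mask, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 indices per condition")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return MaskEffect(0.0, float(x.size + y.size - 2), 1.0, "none")
        raise DegenerateTestError("zero variance in both samples with unequal means")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    # Welch-Satterthwaite degrees of freedom
    sx, sy = vx / x.size, vy / y.size
    df = (sx + sy) ** 2 / (sx**2 / (x.size - 1) + sy**2 / (y.size - 1))
    if p < alpha:
        direction = "reduced" if y.mean() < x.mean() else "increased"
    else:
        direction = "none"
    return MaskEffect(float(t), float(df), float(p), direction)
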