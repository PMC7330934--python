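"""Agreement statistics for method validation.

Implements the intraclass correlation (two-way random effects, absolute
agreement, single measures — ICC(2,1)), pairwise coefficient of variation,
Bland–Altman limits of agreement, and the Wilcoxon signed-rank test with an
exact small-sample null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "RatingsTable",
    "ICCResult",
    "BlandAltmanResult",
    "ratings_from_long",
    "icc_two_way",
    "cv_percent",
    "bland_altman",
    "wilcoxon_signed_rank",
]


@dataclass(frozen=True)
class RatingsTable:
    """n specimens (rows) x k raters/repeats (columns) matrix of counts."""

    values: np.ndarray
    specimens: tuple[str, ...]
    raters: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValidationError(f"ratings must be 2-D, got shape {v.shape}")
        n, k = v.shape
        if n < 2 or k < 2:
            raise ValidationError(f"need >= 2 specimens and >= 2 raters, got {n}x{k}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("ratings contain missing or non-finite cells")
        if np.any(v < 0):
            raise ValidationError("counts must be non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "specimens", tuple(self.specimens))
        object.__setattr__(self, "raters", tuple(self.raters))
        if len(self.specimens) != n or len(self.raters) != k:
            raise ValidationError("label lengths do not match matrix shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_array(cls, values) -> "RatingsTable":
        v = np.asarray(values, dtype=float)
        return cls(
            values=v,
            specimens=tuple(f"s{i + 1}" for i in range(v.shape[0])),
            raters=tuple(f"r{j + 1}" for j in range(v.shape[1])),
        )


def ratings_from_long(df: pd.DataFrame) -> RatingsTable:
    """Pivot a long-form (specimen, rater, count) table into a RatingsTable."""
    required = {"specimen", "rater", "count"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"ratings table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    wide = df.pivot_table(index="specimen", columns="rater", values="count")
    if wide.isna().any().any():
        raise ValidationError("ratings table has missing specimen x rater cells")
    return RatingsTable(
        values=wide.to_numpy(dtype=float),
        specimens=tuple(str(s) for s in wide.index),
        raters=tuple(str(r) for r in wide.columns),
    )


@dataclass(frozen=True)
class ICCResult:
    icc: float
    p_value: float
    model: str
    ms_rows: float
    ms_cols: float
    ms_error: float
    df1: int
    df2: int


def icc_two_way(table: RatingsTable) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    From the two-way ANOVA mean squares (rows = specimens, columns = raters):

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    with the p-value from ``F = MS_R / MS_E`` on (n-1, (n-1)(k-1)) degrees of
    freedom. A constant table leaves the ICC undefined and raises.
    """
    x = table.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    if ss_total == 0:
        raise ValidationError("ratings table is constant; ICC is undefined")
    denom = ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
    if denom == 0:
        raise ValidationError("zero denominator; ICC is undefined for this table")
    icc = (ms_rows - ms_err) / denom
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if ms_err == 0:
        p = 0.0 if ms_rows > 0 else 1.0
    else:
        f = ms_rows / ms_err
        p = float(stats.f.sf(f, df1, df2))
    return ICCResult(
        icc=float(icc),
        p_value=p,
        model="two-way random effects, absolute agreement, single measures (ICC(2,1))",
        ms_rows=float(ms_rows),
        ms_cols=float(ms_cols),
        ms_error=float(ms_err),
        df1=df1,
        df2=df2,
    )


def cv_percent(count_a: float, count_b: float) -> float:
    """Coefficient of variation (%) between two counts: 100·SD/mean.

    Uses the sample SD (n-1 denominator), which for a pair reduces to
    ``100 · sqrt(2) · |a - b| / (a + b)``.
    """
    a, b = float(count_a), float(count_b)
    if a < 0 or b < 0:
        raise ValidationError("counts must be non-negative")
    if a + b == 0:
        raise ValidationError("CV undefined when both counts are zero")
    return 100.0 * np.sqrt(2.0) * abs(a - b) / (a + b)


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_difference: float
    sd_difference: float
    upper_limit: float
    lower_limit: float
    means: np.ndarray
    differences: np.ndarray


def bland_altman(pairs) -> BlandAltmanResult:
    """Bland–Altman agreement: per-pair difference vs mean, 95% limits.

    Differences are ``a - b``; the limits are ``mean ± 1.96 · SD`` of the
    differences (sample SD, no small-n correction).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValidationError("bland_altman needs >= 2 (a, b) pairs")
    diffs = arr[:, 0] - arr[:, 1]
    means = arr.mean(axis=1)
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        mean_difference=mean_diff,
        sd_difference=sd_diff,
        upper_limit=mean_diff + 1.96 * sd_diff,
        lower_limit=mean_diff - 1.96 * sd_diff,
        means=means,
        differences=diffs,
    )


EXACT_ENUMERATION_MAX_N = 25


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p over all sign assignments of the given midranks.

    Midranks are half-integers, so doubling makes the rank-sum distribution
    integer-valued; the distribution is built by dynamic programming rather
    than explicit 2^n enumeration.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total - r + 1]
        counts = counts + shifted
    n_assignments = 2.0 ** len(r2)
    w2 = int(np.rint(2 * w_plus))
    p_le = counts[: w2 + 1].sum() / n_assignments
    p_ge = counts[w2:].sum() / n_assignments
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(pairs) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired data.

    Zero differences are dropped (Wilcoxon's rule) and ties get midranks.
    The statistic is W+, the sum of ranks of positive differences. The
    p-value is exact (full sign-assignment null) for up to 25 informative
    pairs, and a normal approximation with tie correction above that.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValidationError("wilcoxon_signed_rank needs >= 2 (a, b) pairs")
    d = arr[:, 0] - arr[:, 1]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValidationError("all differences are zero; test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_ENUMERATION_MAX_N:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= np.sum(tie_counts**3 - tie_counts) / 48.0
        if var <= 0:
            raise ValidationError("zero variance under the null; test undefined")
        z = (w_plus - mu) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return w_plus, p
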