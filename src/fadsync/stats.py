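"""Group summaries and the independent-samples t-test for cohort comparison.

Populations are summarized as mean ± sample SD with (min, max); pairs of
cohorts are compared with a two-sided independent-samples t-test,
significant at ``P <= 0.01``. Welch's unequal-variance variant is the
default; the classical pooled-variance test is available for exact
reproduction of older analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["Summary", "ComparisonResult", "StatsError", "summarize",
           "ttest_independent"]

#: significance threshold used throughout
ALPHA = 0.01


class StatsError(ValueError):
    pass


@dataclass
class Summary:
    mean: float
    sd: float
    min: float
    max: float
    n: int
    sd_defined: bool = True


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    df: float
    p_value: float
    significant: bool
    variant: str = "welch"
    alpha: float = ALPHA


def summarize(values) -> Summary:
    """Mean, sample (n-1) SD, min, max and n of one group."""
    arr = np.asarray(list(values), dtype=float).ravel()
    if arr.size == 0:
        raise StatsError("cannot summarize an empty group")
    if not np.isfinite(arr).all():
        raise StatsError("non-finite value in group")
    sd_defined = arr.size >= 2
    sd = float(arr.std(ddof=1)) if sd_defined else 0.0
    return Summary(mean=float(arr.mean()), sd=sd, min=float(arr.min()),
                   max=float(arr.max()), n=int(arr.size),
                   sd_defined=sd_defined)


def ttest_independent(a, b, variant: str = "welch",
                      names: tuple[str, str] = ("a", "b"),
                      alpha: float = ALPHA) -> ComparisonResult:
    """Two-sided independent-samples t-test between groups ``a`` and ``b``."""
    if variant not in ("welch", "pooled"):
        raise StatsError(f"unknown t-test variant {variant!r}")
    arr_a = np.asarray(list(a), dtype=float).ravel()
    arr_b = np.asarray(list(b), dtype=float).ravel()
    if arr_a.size < 2 or arr_b.size < 2:
        raise StatsError("each group needs at least 2 values")
    res = sps.ttest_ind(arr_a, arr_b, equal_var=(variant == "pooled"))
    sa, sb = summarize(arr_a), summarize(arr_b)
    p = float(res.pvalue)
    return ComparisonResult(
        group_a=names[0], group_b=names[1], n_a=sa.n, n_b=sb.n,
        mean_a=sa.mean, mean_b=sb.mean, sd_a=sa.sd, sd_b=sb.sd,
        t=float(res.statistic), df=float(res.df), p_value=p,
        significant=bool(p <= alpha), variant=variant, alpha=alpha)
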