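"""Cohort-level aggregation and pairwise method comparison.

Per-method performance is summarised as median ± sample standard deviation.
Methods are compared pairwise with the two-sided Mann–Whitney U test
(unpaired, per-case metric values), Bonferroni-corrected within each metric
family: with k methods there are k(k-1)/2 pairs, and the corrected
significance level is family_alpha divided by that count (6 methods at
alpha 0.05 give 0.05/15 ≈ 0.003).  Direction (A > B / A < B) is derived
from the sample medians and only reported for significant pairs.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "MethodSummary",
    "PairwiseTest",
    "summarize",
    "summarize_methods",
    "mann_whitney_u",
    "pairwise_comparison",
    "pairwise_table",
    "bonferroni_alpha",
]

_METRIC_COLUMNS = {"dsc": "dsc", "rvd": "rvd_percent", "rvd_percent": "rvd_percent"}


def summarize(values: Sequence[float]) -> tuple[float, float]:
    """Sample median and standard deviation (n-1 denominator; 0 for n=1)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(np.median(arr)), sd


@dataclasses.dataclass(frozen=True)
class MethodSummary:
    method: str
    metric: str
    median: float
    sd: float
    n: int


@dataclasses.dataclass(frozen=True)
class PairwiseTest:
    method_a: str
    method_b: str
    metric: str
    u_statistic: float
    p_value: float
    corrected_alpha: float
    significant: bool
    direction: str  # "A>B" | "A<B" | "none"


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact null distribution for small tie-free samples, normal approximation
    with tie correction otherwise.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = _sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def bonferroni_alpha(n_methods: int, family_alpha: float = 0.05) -> float:
    """Corrected per-test alpha for all unordered pairs of ``n_methods``."""
    n_pairs = n_methods * (n_methods - 1) // 2
    return family_alpha / n_pairs


def _metric_column(per_case: pd.DataFrame, metric: str) -> str:
    try:
        col = _METRIC_COLUMNS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; expected 'dsc' or 'rvd'") from None
    if col not in per_case.columns:
        raise ValueError(f"per-case table lacks column {col!r}")
    return col


def summarize_methods(
    per_case: pd.DataFrame, metrics: Iterable[str] = ("dsc", "rvd")
) -> pd.DataFrame:
    """Median ± SD per (method, metric) from a long per-case table."""
    rows = []
    for metric in metrics:
        col = _metric_column(per_case, metric)
        for method, grp in per_case.groupby("method", sort=False):
            vals = grp[col].dropna()
            if vals.empty:
                continue
            median, sd = summarize(vals)
            rows.append(MethodSummary(method, metric, median, sd, len(vals)))
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def pairwise_comparison(
    per_case: pd.DataFrame,
    metric: str,
    family_alpha: float = 0.05,
    require_complete: bool = True,
) -> list[PairwiseTest]:
    """One two-sided Mann–Whitney U test per unordered method pair.

    The Bonferroni-corrected alpha is ``family_alpha / number_of_pairs``
    within the metric family.  With ``require_complete`` every method must
    provide a value for every case; absent (case, method) pairs raise an
    error naming them.
    """
    col = _metric_column(per_case, metric)
    methods = list(dict.fromkeys(per_case["method"]))
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    if require_complete and "case_id" in per_case.columns:
        pivot = per_case.pivot_table(index="case_id", columns="method", values=col, aggfunc="first")
        missing = [
            (case, m)
            for m in methods
            for case in pivot.index[pivot[m].isna()]
        ] if not pivot.notna().all().all() else []
        if missing:
            raise ValueError(f"missing per-case values for: {missing}")
    pairs = list(itertools.combinations(methods, 2))
    alpha = family_alpha / len(pairs)
    tests = []
    for a, b in pairs:
        xa = per_case.loc[per_case["method"] == a, col].dropna().to_numpy()
        xb = per_case.loc[per_case["method"] == b, col].dropna().to_numpy()
        u, p = mann_whitney_u(xa, xb)
        significant = bool(p < alpha)
        if significant:
            direction = "A>B" if np.median(xa) > np.median(xb) else "A<B"
        else:
            direction = "none"
        tests.append(
            PairwiseTest(a, b, metric if metric != "rvd_percent" else "rvd",
                         u, p, alpha, significant, direction)
        )
    return tests


def pairwise_table(tests: Iterable[PairwiseTest]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(t) for t in tests])
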