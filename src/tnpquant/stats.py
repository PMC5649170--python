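"""Rank-sum contrasts and linear fits for abundance tables.

Group comparisons (between size fractions, between regions, between
molecules) use the two-sided Wilcoxon rank-sum / Mann–Whitney test:
exact when both groups have at most 25 observations and the pooled data
are tie-free, otherwise the normal approximation with tie and continuity
corrections — mirroring the behavior of the R ``wilcox.test`` contract.
Relationships between continuous quantities (genome-size proxy vs
transposase fraction, RNA vs DNA abundance) use ordinary least squares
with adjusted R² and the Pearson correlation test.

No multiple-testing correction is applied by default (raw P values are
reported); Benjamini–Hochberg adjustment is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContrastResult",
    "FitResult",
    "wilcoxon_rank_sum",
    "linear_fit",
    "run_contrasts",
]

EXACT_MAX_N = 25


@dataclass
class ContrastResult:
    group_a_label: str
    group_b_label: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    statistic: float  # Mann-Whitney U of group a (W of R's wilcox.test)
    p_value: float
    alternative: str = "two-sided"
    method: str = "exact"
    metric: str = ""


@dataclass
class FitResult:
    slope: float
    intercept: float
    adjusted_r2: float
    pearson_r: float
    p_value: float
    n: int


def _use_exact(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    return no_ties and len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
    metric: str = "",
) -> ContrastResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test between two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    exact = _use_exact(x, y)
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return ContrastResult(
        group_a_label=label_a,
        group_b_label=label_b,
        n_a=int(x.size),
        n_b=int(y.size),
        median_a=float(np.median(x)),
        median_b=float(np.median(y)),
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "asymptotic",
        metric=metric,
    )


def linear_fit(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """Simple OLS of y on x with adjusted R² and Pearson correlation test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; fit undefined")
    lr = sps.linregress(x, y)
    r2 = lr.rvalue ** 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return FitResult(
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        adjusted_r2=float(adj),
        pearson_r=float(lr.rvalue),
        p_value=float(lr.pvalue),
        n=int(n),
    )


def _select(
    abundance: pd.DataFrame, predicate: Mapping[str, object]
) -> pd.DataFrame:
    sel = abundance
    for col, allowed in predicate.items():
        if not isinstance(allowed, (list, tuple, set)):
            allowed = [allowed]
        sel = sel[sel[col].isin(list(allowed))]
    return sel


def _bh_adjust(pvals: list[float]) -> list[float]:
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    prev = 1.0
    for rank, idx in enumerate(order[::-1]):
        k = m - rank
        prev = min(prev, p[idx] * m / k)
        adj[idx] = prev
    return adj.tolist()


def run_contrasts(
    abundance: pd.DataFrame,
    contrasts: Sequence[Mapping],
    adjust: str = "none",
) -> pd.DataFrame:
    """Run a set of rank-sum contrasts against a tidy abundance table.

    Each contrast is a mapping with keys ``name``, ``metric``, optional
    ``scope``/``scope_label`` filters, and ``group_a``/``group_b``
    metadata predicates (column -> allowed value or list of values, e.g.
    ``{"fraction": ["medium", "large"], "molecule": "DNA"}``).  Group
    medians are reported alongside the statistic and P value.
    """
    rows = []
    for spec in contrasts:
        sub = abundance[abundance["metric"] == spec["metric"]]
        if "scope" in spec:
            sub = sub[sub["scope"] == spec["scope"]]
        if "scope_label" in spec:
            sub = sub[sub["scope_label"] == spec["scope_label"]]
        a = _select(sub, spec["group_a"])
        b = _select(sub, spec["group_b"])
        for label, grp in (("group_a", a), ("group_b", b)):
            if grp.empty:
                raise ValueError(
                    f"contrast {spec.get('name', '?')!r}: {label} predicate "
                    f"{spec[label]} selects no samples"
                )
        res = wilcoxon_rank_sum(
            a["value"].to_numpy(), b["value"].to_numpy(),
            label_a=str(spec["group_a"]), label_b=str(spec["group_b"]),
            metric=spec["metric"],
        )
        rows.append({
            "contrast": spec.get("name", ""),
            "metric": spec["metric"],
            "n_a": res.n_a, "n_b": res.n_b,
            "median_a": res.median_a, "median_b": res.median_b,
            "statistic": res.statistic, "p_value": res.p_value,
            "method": res.method,
        })
    out = pd.DataFrame(rows, columns=[
        "contrast", "metric", "n_a", "n_b", "median_a", "median_b",
        "statistic", "p_value", "method",
    ])
    if adjust == "bh" and not out.empty:
        out["p_adjusted"] = _bh_adjust(out["p_value"].tolist())
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out
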