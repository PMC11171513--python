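"""Two-group comparisons: independent-samples t-tests and chi-square tests.

Numeric features are compared with the Welch (unequal-variance) t statistic,
which with equal group sizes coincides with the pooled-SE statistic; the
tests work either from raw vectors or from published (mean, SD, n)
summaries, so a printed summary table can be checked directly.  Count
features use the uncorrected Pearson chi-square on the level x group
contingency table (no Yates continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import NUMERIC, FeatureTable

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Published per-group summary of a numeric feature (native units)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray  # r x c non-negative integers
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")


def t_from_summary(g0: GroupSummary, g1: GroupSummary) -> tuple[float, float, float]:
    """Welch t-test from summary statistics.

    Returns ``(t, df, p)`` with t = (m0 - m1) / sqrt(s0^2/n0 + s1^2/n1),
    Welch-Satterthwaite degrees of freedom and a two-sided p-value.
    """
    v0, v1 = g0.sd**2 / g0.n, g1.sd**2 / g1.n
    if v0 + v1 == 0:
        if g0.mean == g1.mean:
            return 0.0, float(g0.n + g1.n - 2), 1.0
        raise ValueError("both SDs zero with unequal means: statistic is infinite")
    t = (g0.mean - g1.mean) / np.sqrt(v0 + v1)
    df = (v0 + v1) ** 2 / (
        (v0**2 / (g0.n - 1) if v0 else 0.0) + (v1**2 / (g1.n - 1) if v1 else 0.0)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def t_test_raw(x0, x1) -> tuple[float, float, float]:
    """Welch t-test from raw per-group vectors (SD with n-1 denominator)."""
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    if x0.size < 2 or x1.size < 2:
        raise ValueError("each group needs n >= 2")
    g0 = GroupSummary(float(x0.mean()), float(x0.std(ddof=1)), x0.size)
    g1 = GroupSummary(float(x1.mean()), float(x1.std(ddof=1)), x1.size)
    return t_from_summary(g0, g1)


def chi_square(tab: ContingencyTable) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square with expected counts from the margins.

    Returns ``(chi2, df, p)``; a zero row or column margin is an error.
    """
    counts = np.asarray(tab.counts, dtype=float)
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), int(dof), float(p)


def table1_report(table: FeatureTable, alpha: float = ALPHA) -> pd.DataFrame:
    """Per-feature group comparison in the layout of a clinical Table 1.

    Numeric rows report group mean +/- SD and a Welch t; categorical and
    binary rows report per-level counts (%) and a chi-square.  The
    ``significant`` flag applies the two-sided ``alpha`` threshold.
    """
    y = table.labels.to_numpy()
    rows = []
    for name, meta in table.meta.items():
        col = table.values[name]
        x0 = col[y == 0].dropna().to_numpy()
        x1 = col[y == 1].dropna().to_numpy()
        if meta.kind == NUMERIC:
            t, _, p = t_test_raw(x0, x1)
            desc0 = f"{x0.mean():.2f} ± {x0.std(ddof=1):.2f}"
            desc1 = f"{x1.mean():.2f} ± {x1.std(ddof=1):.2f}"
            stat_name, stat = "t", t
        else:
            levels = np.unique(np.concatenate([x0, x1]))
            counts = np.array(
                [[(x0 == lv).sum(), (x1 == lv).sum()] for lv in levels], dtype=int
            )
            chi2, _, p = chi_square(ContingencyTable(counts))
            desc0 = "; ".join(
                f"{int(c)} ({100 * c / max(len(x0), 1):.1f}%)" for c in counts[:, 0]
            )
            desc1 = "; ".join(
                f"{int(c)} ({100 * c / max(len(x1), 1):.1f}%)" for c in counts[:, 1]
            )
            stat_name, stat = "chi2", chi2
        rows.append(
            {
                "feature": name,
                "kind": meta.kind,
                "group0": desc0,
                "group1": desc1,
                "stat_name": stat_name,
                "statistic": stat,
                "p_value": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)
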