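"""Group comparison statistics and multiple-testing correction.

Two-tailed Welch t-tests (from raw data or from published mean/SD/n
summaries), Benjamini-Hochberg step-up adjustment, and assembly of
experiment tables in which every group is normalised to a designated
control and all pairwise comparisons within one experiment form a single
adjustment family.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GroupSummary:
    """Published group summary: label, mean, SD and sample size."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class TestResult:
    """Outcome of one two-group comparison."""

    statistic: float
    df: float
    p_raw: float
    comparison: str = ""
    p_adjusted: float = float("nan")
    degenerate: bool = False


def welch_t_from_summary(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Two-tailed Welch test from summary statistics.

    t = (mean_a - mean_b) / sqrt(sd_a²/n_a + sd_b²/n_b), with the
    Welch-Satterthwaite degrees of freedom and a two-tailed p from the t
    distribution.  If both SDs are zero the test degenerates: p = 1 for
    equal means, else p = 0 with a flag.
    """
    label = f"{a.label} vs {b.label}"
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return TestResult(0.0, float(a.n + b.n - 2), 1.0, label, degenerate=True)
        logger.warning("welch_t_from_summary[%s]: zero variance, unequal means; "
                       "p below machine epsilon", label)
        return TestResult(float("inf"), float(a.n + b.n - 2), 0.0, label,
                          degenerate=True)
    t, p = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=False
    )
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TestResult(float(t), float(df), float(p), label)


def welch_t(a: np.ndarray, b: np.ndarray, label: str = "") -> TestResult:
    """Two-tailed Welch test on raw samples (ties out to the summary path)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, float(a.size + b.size - 2), 1.0, label,
                              degenerate=True)
        logger.warning("welch_t[%s]: zero variance, unequal means", label)
        return TestResult(float("inf"), float(a.size + b.size - 2), 0.0, label,
                          degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), label)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved.

    Equivalent to sorting ascending, taking q_i = min_{j >= i} (p_j * m / j)
    capped at 1, and undoing the sort.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_experiment_table(
    groups: Sequence[GroupSummary],
    comparisons: Sequence[tuple[str, str]],
    control_label: str,
) -> pd.DataFrame:
    """Assemble one experiment's results table.

    Group means and SDs are normalised to the control-group mean (control
    becomes 1 ± SD/control-mean); ``fold`` is the normalised mean.  Each
    requested pairwise Welch comparison is computed from the summaries and
    BH-adjusted within this experiment (one family per experiment).  An
    empty comparison list yields a table without p-value columns.
    """
    by_label = {g.label: g for g in groups}
    if control_label not in by_label:
        raise ValueError(f"control group {control_label!r} not among the groups")
    cmean = by_label[control_label].mean
    if cmean == 0:
        raise ValueError("control mean is zero; cannot normalise")

    tests = [
        welch_t_from_summary(by_label[x], by_label[y]) for x, y in comparisons
    ]
    if tests:
        adj = bh_adjust([t.p_raw for t in tests])
        for t, q in zip(tests, adj):
            t.p_adjusted = float(q)

    rows = []
    for g in groups:
        row = {
            "label": g.label,
            "n": g.n,
            "mean_norm": g.mean / cmean,
            "sd_norm": g.sd / cmean,
            "fold_vs_control": g.mean / cmean,
        }
        if tests:
            for t in tests:
                if t.comparison.startswith(f"{g.label} vs ") or t.comparison.endswith(
                    f" vs {g.label}"
                ):
                    row.setdefault("comparisons", []).append(
                        (t.comparison, t.p_raw, t.p_adjusted)
                    )
        rows.append(row)
    table = pd.DataFrame(
        [{k: v for k, v in r.items() if k != "comparisons"} for r in rows]
    )
    if tests:
        test_frame = pd.DataFrame(
            {
                "comparison": [t.comparison for t in tests],
                "t": [t.statistic for t in tests],
                "df": [t.df for t in tests],
                "p_raw": [t.p_raw for t in tests],
                "p_adjusted": [t.p_adjusted for t in tests],
            }
        )
        table.attrs["tests"] = test_frame
    return table
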