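"""Per-block differential-CNA testing against a binary clinical variable.

Each elementary block's log2 ratios are compared between the two patient
groups (e.g. relapsed vs non-relapsed, synchronous vs metachronous) with a
pooled-variance two-sample Student's t-test, two-sided.  No multiple-testing
correction is applied by default (a Benjamini–Hochberg option exists);
significance at the per-block alpha feeds the downstream chromosome-level
enrichment, which is where genome-wide structure is assessed.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TTestResult", "student_t_test", "test_blocks", "AssociationResult"]


class TTestResult(NamedTuple):
    t_stat: float
    p_value: float
    mean_diff: float
    degenerate: bool = False


def student_t_test(x, y) -> TTestResult:
    """Pooled-variance two-sample t-test, two-sided, df = n1 + n2 - 2.

    ``mean_diff`` is mean(x) - mean(y).  Degenerate zero-variance cases:
    equal means give (t=0, p=1); unequal means are flagged ``degenerate``
    with p=0 (an infinite-evidence artefact of constant groups, surfaced
    rather than hidden).  Missing values are dropped; fewer than two values
    in either group is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 non-missing values")
    mean_diff = float(x.mean() - y.mean())
    pooled = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (len(x) + len(y) - 2)
    if pooled == 0.0:
        if mean_diff == 0.0:
            return TTestResult(0.0, 1.0, 0.0, False)
        return TTestResult(float(np.sign(mean_diff)) * np.inf, 0.0, mean_diff, True)
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return TTestResult(float(t), float(p), mean_diff, False)


class AssociationResult(NamedTuple):
    """Per-block test table plus the blocks that could not be tested."""

    table: pd.DataFrame
    skipped: pd.DataFrame


def test_blocks(
    block_matrix: pd.DataFrame,
    labels: pd.Series,
    variable_name: str,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> AssociationResult:
    """Test every block for differential CNA between label groups.

    Parameters
    ----------
    block_matrix : blocks × patients mean log2 ratios.
    labels : boolean Series indexed by patient id covering all matrix
        columns; True = "yes" group.  mean_diff is group_yes - group_no.
    alpha : two-sided significance threshold (default 0.05).
    bh_correct : apply Benjamini–Hochberg across blocks before thresholding
        (off by default).

    Returns an :class:`AssociationResult`; the table has one row per
    testable block with columns block_id, variable, n_group1, n_group2,
    mean_diff, t_stat, p_value, degenerate, significant.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    missing = [p for p in block_matrix.columns if p not in labels.index]
    if missing:
        raise ValueError(f"labels missing for patients: {missing[:5]}")
    lab = labels.loc[block_matrix.columns].astype(bool)
    if lab.all() or (~lab).all():
        raise ValueError(f"labels for {variable_name!r} are single-class")

    yes = block_matrix.loc[:, lab.to_numpy()]
    no = block_matrix.loc[:, (~lab).to_numpy()]

    rows, skipped = [], []
    for block_id in block_matrix.index:
        x = yes.loc[block_id].to_numpy(dtype=float)
        y = no.loc[block_id].to_numpy(dtype=float)
        n1, n2 = int((~np.isnan(x)).sum()), int((~np.isnan(y)).sum())
        if n1 < 2 or n2 < 2:
            skipped.append((block_id, f"group sizes {n1}/{n2} after removing missing"))
            continue
        res = student_t_test(x, y)
        rows.append((block_id, variable_name, n1, n2, res.mean_diff, res.t_stat, res.p_value, res.degenerate))

    table = pd.DataFrame(
        rows,
        columns=["block_id", "variable", "n_group1", "n_group2", "mean_diff", "t_stat", "p_value", "degenerate"],
    )
    pvals = table["p_value"].to_numpy()
    if bh_correct and len(table):
        pvals = _benjamini_hochberg(pvals)
        table["p_adjusted"] = pvals
    table["significant"] = pvals < alpha
    skipped_df = pd.DataFrame(skipped, columns=["block_id", "reason"])
    return AssociationResult(table, skipped_df)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
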