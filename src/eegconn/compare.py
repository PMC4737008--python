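"""Per-feature group comparison of selected correlations.

For each VIP-selected correlation feature the two groups are compared with a
two-sample t-test (Welch by default), and the group means of the *absolute*
correlation are reported — the features keep their sign for classification,
but positively and negatively correlated epochs would cancel in a signed mean,
so group summaries use |r|. A feature is retained when p < alpha (0.05); no
multiple-testing correction is applied in the retention rule, but a Bonferroni
column is reported alongside for transparency.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import FeatureTable
from .pls import VIPRanking, select_top


def feature_ttest(values_g1: np.ndarray, values_g0: np.ndarray,
                  equal_var: bool = False) -> float:
    """Two-sided two-sample t-test p-value (Welch unless ``equal_var``)."""
    a = np.asarray(values_g1, dtype=float)
    b = np.asarray(values_g0, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def mean_abs_correlation(column: np.ndarray, labels: np.ndarray) -> Tuple[float, float]:
    """(group-1 mean, group-0 mean) of the absolute correlation value."""
    column = np.asarray(column, dtype=float)
    labels = np.asarray(labels, dtype=int)
    g1 = np.abs(column[labels == 1])
    g0 = np.abs(column[labels == 0])
    return (float(g1.mean()) if len(g1) else np.nan,
            float(g0.mean()) if len(g0) else np.nan)


def compare_selected(
    table: FeatureTable,
    ranking: VIPRanking,
    k: int = 10,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Comparison table for the top-k VIP features.

    Columns: rank, feature_index (1-based), lead_pair, vip_score,
    mean_abs_r_group1 (trained), mean_abs_r_group0 (baseline), p_value,
    p_bonferroni, direction ('increased'/'decreased' in the trained group,
    'tie' when the means are equal), retained (p < alpha).
    """
    sel = select_top(ranking, k, annotations=table.annotations)
    rows = []
    for _, row in sel.iterrows():
        pos = int(row["position"])
        col = table.X[:, pos]
        m1, m0 = mean_abs_correlation(col, table.labels)
        p = feature_ttest(col[table.labels == 1], col[table.labels == 0],
                          equal_var=equal_var)
        if m1 > m0:
            direction = "increased"
        elif m1 < m0:
            direction = "decreased"
        else:
            direction = "tie"
        rows.append(
            {
                "rank": int(row["rank"]),
                "feature_index": int(row["feature_index"]),
                "lead_pair": row.get("lead_pair", str(int(row["feature_index"]))),
                "vip_score": float(row["vip_score"]),
                "mean_abs_r_group1": m1,
                "mean_abs_r_group0": m0,
                "p_value": p,
                "p_bonferroni": min(1.0, p * k),
                "direction": direction,
                "retained": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)


def edge_list(comparison: pd.DataFrame) -> pd.DataFrame:
    """Network edge list (source, target, weight, direction) for plotting the
    selected edges; weight is the trained-minus-baseline mean |r| difference."""
    src, tgt = zip(*(lp.split("-") for lp in comparison["lead_pair"]))
    return pd.DataFrame(
        {
            "source": src,
            "target": tgt,
            "weight": comparison["mean_abs_r_group1"] - comparison["mean_abs_r_group0"],
            "direction": comparison["direction"],
        }
    )
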