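"""Two-group comparison of regional cell-type densities.

For every (region, cell type) pair with at least two subjects per group,
a Welch two-sample t-test (or optionally Mann-Whitney U) compares the
per-subject densities between groups; Benjamini-Hochberg FDR control is
applied jointly across all tested pairs.  Effects are reported as the ratio
of group means, mirroring the "more cells in group A" reading of such
screens.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def compare_groups(
    per_subject: pd.DataFrame,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    value_col: str = "density_cells_per_mm3",
    method: str = "welch",
) -> pd.DataFrame:
    """Compare group densities per (region, cell type) with BH-FDR control.

    Parameters
    ----------
    per_subject
        Tidy table with columns region_id, cell_type, subject_id, group and
        *value_col* (one row per subject per region per type).
    group_a, group_b
        Group labels to compare; the statistic is oriented a minus b and the
        effect is mean(a) / mean(b).
    method
        "welch" (unequal-variance t-test) or "mannwhitney".

    Returns a table with group means, effect ratio, statistic, p, BH q and a
    ``tested`` flag (pairs with fewer than two subjects in either group are
    flagged untested and excluded from the correction).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if method not in ("welch", "mannwhitney"):
        raise ValueError(f"unknown test method {method!r}")
    need = {"region_id", "cell_type", "subject_id", "group", value_col}
    if not need.issubset(per_subject.columns):
        raise ValueError(f"per-subject table needs columns {sorted(need)}")

    rows = []
    for (rid, ctype), cell in per_subject.groupby(["region_id", "cell_type"],
                                                  sort=True):
        a = cell.loc[cell["group"] == group_a, value_col].to_numpy(float)
        b = cell.loc[cell["group"] == group_b, value_col].to_numpy(float)
        mean_a = float(a.mean()) if a.size else np.nan
        mean_b = float(b.mean()) if b.size else np.nan
        row = {
            "region_id": rid, "cell_type": ctype,
            "n_a": a.size, "n_b": b.size,
            "mean_a": mean_a, "mean_b": mean_b,
            "effect_ratio": mean_a / mean_b if b.size and mean_b > 0 else np.nan,
            "tested": a.size >= 2 and b.size >= 2,
            "statistic": np.nan, "p": np.nan,
        }
        if row["tested"]:
            if method == "welch":
                res = stats.ttest_ind(a, b, equal_var=False)
                stat, p = float(res.statistic), float(res.pvalue)
                if not np.isfinite(stat):
                    # zero variance in both groups: the test degenerates to
                    # comparing the two constants directly
                    stat = 0.0 if mean_a == mean_b else np.sign(mean_a - mean_b) * np.inf
                    p = 1.0 if mean_a == mean_b else 0.0
                row["statistic"], row["p"] = stat, p
            else:
                res = stats.mannwhitneyu(a, b, alternative="two-sided")
                row["statistic"], row["p"] = float(res.statistic), float(res.pvalue)
        rows.append(row)

    table = pd.DataFrame(rows)
    table["q"] = np.nan
    tested = table["tested"] & table["p"].notna()
    if tested.any():
        table.loc[tested, "q"] = bh_adjust(table.loc[tested, "p"])
    table["significant"] = table["q"] <= alpha
    return table
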