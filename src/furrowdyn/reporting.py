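"""Cohort aggregation, group comparison, and the furrow-length/defect relation."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

# significance star codes: ns p>0.05; * p<0.05; ** p<0.005; *** p<0.0005
STAR_THRESHOLDS = ((0.0005, "***"), (0.005, "**"), (0.05, "*"))


def star_code(p: float) -> str:
    for thresh, code in STAR_THRESHOLDS:
        if p < thresh:
            return code
    return "ns"


def aggregate(
    results: pd.DataFrame,
    group_cols: list[str] | tuple[str, ...] = ("genotype", "cycle"),
    min_n: int = 3,
) -> pd.DataFrame:
    """Cohort summary: mean/SD/n per group for every numeric column.

    Groups with fewer than ``min_n`` embryos are flagged ``low_n`` (the study
    quantifies a minimum of 3 embryos per condition); SD columns are NaN for
    n = 1. Raises on an empty input.
    """
    if len(results) == 0:
        raise ValueError("empty results table")
    group_cols = list(group_cols)
    value_cols = [
        c for c in results.columns
        if c not in group_cols and pd.api.types.is_numeric_dtype(results[c])
    ]
    rows = []
    for keys, grp in results.groupby(group_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        row = dict(zip(group_cols, keys))
        row["n"] = len(grp)
        row["low_n"] = len(grp) < min_n
        for c in value_cols:
            vals = grp[c].dropna().to_numpy(float)
            row[f"{c}_mean"] = float(np.mean(vals)) if len(vals) else np.nan
            row[f"{c}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def compare(group_a, group_b, equal_var: bool = True) -> tuple[float, float, str]:
    """Two-sample Student's t-test with the study's star codes.

    Equal-variance by default; ``equal_var=False`` gives Welch's test.
    Returns (t statistic, p value, star code). Requires n >= 2 per group.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(p):  # zero variance in both groups with equal means
        p = 1.0
        t = 0.0
    return float(t), float(p), star_code(float(p))


def length_defect_relation(summary: pd.DataFrame) -> tuple[pd.DataFrame, float | None, float | None]:
    """Paired furrow length (at metaphase) vs percent mitotic defects per genotype.

    ``summary`` must carry columns ``genotype``, ``furrow_length_metaphase``
    and ``percent_defects``. Returns the paired table plus Spearman rank
    correlation (rho, p); the correlation is omitted (None) with fewer than 3
    complete pairs or a constant column, with the reason in ``table.attrs``.
    """
    cols = ["genotype", "furrow_length_metaphase", "percent_defects"]
    for c in cols:
        if c not in summary.columns:
            raise ValueError(f"missing column: {c}")
    table = summary[cols].dropna().reset_index(drop=True)
    if len(table) < 3:
        table.attrs["correlation_flag"] = "fewer than 3 genotypes; correlation omitted"
        return table, None, None
    x = table["furrow_length_metaphase"].to_numpy(float)
    y = table["percent_defects"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        table.attrs["correlation_flag"] = "constant column; correlation undefined"
        return table, None, None
    rho, p = stats.spearmanr(x, y)
    return table, float(rho), float(p)
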