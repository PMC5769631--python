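"""Group comparison of quadrant-level shortening factors.

Embryo-level shortening values (one per embryo x quadrant) are compared
between experimental groups (e.g. control vs contraction-deficient vs
RBC-depleted) with an unpaired two-sample Student's t-test, pooled
variance, two-tailed, per quadrant.  No multiple-testing correction is
applied across quadrants (each quadrant is reported with its own p-value);
this is recorded in the output metadata.  Welch's unequal-variance variant
is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = ["GroupTable", "summarize", "t_test", "compare_groups"]

REQUIRED_COLUMNS = ("embryo", "group", "quadrant", "shortening")


def GroupTable(rows=None, frame: pd.DataFrame = None) -> pd.DataFrame:
    """Validated long-format table: one row per embryo x quadrant."""
    if frame is None:
        frame = pd.DataFrame(rows, columns=REQUIRED_COLUMNS)
    missing = set(REQUIRED_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"group table missing columns: {sorted(missing)}")
    dup = frame.duplicated(subset=["embryo", "quadrant"])
    if dup.any():
        raise ValueError("one shortening value per embryo x quadrant expected")
    return frame


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group, per-quadrant mean and sample (n-1) standard deviation."""
    table = GroupTable(frame=table)
    g = table.groupby(["group", "quadrant"])["shortening"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    return out


def t_test(a: Sequence[float], b: Sequence[float], welch: bool = False):
    """Unpaired two-sample t-test, two-tailed.

    Returns (t, p, df).  Classic Student pooled-variance form by default
    (df = nA + nB - 2); Welch with ``welch=True``.  Degenerate zero-variance
    input: equal means give (0, 1), unequal means give p = 0 flagged by
    t = +-inf.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0, len(a) + len(b) - 2
        sign = np.sign(np.mean(a) - np.mean(b))
        return sign * np.inf, 0.0, len(a) + len(b) - 2
    res = sstats.ttest_ind(a, b, equal_var=not welch)
    df = len(a) + len(b) - 2 if not welch else res.df
    return float(res.statistic), float(res.pvalue), float(df)


def compare_groups(table: pd.DataFrame, group_a: str, group_b: str,
                   welch: bool = False) -> pd.DataFrame:
    """Per-quadrant test between two groups; returns a tidy frame."""
    table = GroupTable(frame=table)
    rows = []
    for quadrant, sub in table.groupby("quadrant"):
        a = sub.loc[sub["group"] == group_a, "shortening"].to_numpy()
        b = sub.loc[sub["group"] == group_b, "shortening"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            rows.append({"quadrant": quadrant, "t": np.nan, "p": np.nan,
                         "df": np.nan, "n_a": len(a), "n_b": len(b)})
            continue
        t, p, df = t_test(a, b, welch=welch)
        rows.append({"quadrant": quadrant, "t": t, "p": p, "df": df,
                     "n_a": len(a), "n_b": len(b)})
    out = pd.DataFrame(rows)
    out.attrs["test"] = "welch" if welch else "student_pooled"
    out.attrs["multiple_testing_correction"] = "none (per-quadrant p-values)"
    out.attrs["groups"] = (group_a, group_b)
    return out
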