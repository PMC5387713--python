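"""Demographic comparisons between the diagnosis groups.

Welch's unequal-variance t test (from raw vectors or from published summary
statistics), Pearson's chi-square on the 2x2 sex-by-group table, and a
Table-1-style per-descriptor summary of a cohort.

All p-values are two-sided. The chi-square uses no continuity correction by
default (plain Pearson); Yates' correction is available via a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DAS_COLUMNS, CohortTable
from .exceptions import DegenerateDataError

__all__ = [
    "WelchResult",
    "Chi2Result",
    "welch_from_summary",
    "welch_from_vectors",
    "chi2_2x2",
    "summarize_cohort",
]


@dataclass(frozen=True)
class WelchResult:
    """Welch t statistic, Welch-Satterthwaite fractional df, two-sided p."""

    t: float
    df: float
    p: float


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p: float


def welch_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> WelchResult:
    """Welch's t test from group means, standard deviations and sizes.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2); the fractional degrees of
    freedom follow the Welch-Satterthwaite formula. The sign of t follows
    the group order (group 1 minus group 2).
    """
    if s1 <= 0 or s2 <= 0:
        raise DegenerateDataError("standard deviations must be > 0")
    if n1 < 2 or n2 < 2:
        raise DegenerateDataError("each group needs n >= 2")
    v1, v2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


def welch_from_vectors(x1, x2) -> WelchResult:
    """Welch's t test from two raw samples.

    Equivalent to :func:`welch_from_summary` applied to the samples' means,
    standard deviations (ddof=1) and lengths.
    """
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    if x1.size < 2 or x2.size < 2:
        raise DegenerateDataError("each sample needs length >= 2")
    if not (np.isfinite(x1).all() and np.isfinite(x2).all()):
        raise DegenerateDataError("samples must be finite")
    return welch_from_summary(
        x1.mean(), x1.std(ddof=1), x1.size, x2.mean(), x2.std(ddof=1), x2.size
    )


def chi2_2x2(a: int, b: int, c: int, d: int, correction: bool = False) -> Chi2Result:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]], df = 1.

    ``correction=True`` applies Yates' continuity correction. Both margins
    must be nonzero.
    """
    table = np.array([[a, b], [c, d]], float)
    if (table < 0).any():
        raise DegenerateDataError("counts must be >= 0")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateDataError("degenerate 2x2 table: a margin is zero")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=correction)
    return Chi2Result(chi2=float(chi2), df=int(df), p=float(p))


_DESCRIPTORS = ("age", "ticv") + DAS_COLUMNS


def summarize_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Table-1-style summary: per-group mean/sd/range plus Welch t per row.

    Returns a DataFrame indexed by descriptor (age, ticv, das_*) with columns
    ``asd_mean, asd_sd, asd_min, asd_max, td_*, t, df, p, degenerate``. Group
    sex ratios (male:female) are attached as ``DataFrame.attrs``. A row with
    zero variance in either group is flagged degenerate and its Welch test
    skipped (t, df, p = NaN).
    """
    f = cohort.frame
    asd = f[f["diagnosis"] == 1]
    td = f[f["diagnosis"] == -1]
    if len(asd) == 0 or len(td) == 0:
        raise DegenerateDataError("cohort must contain both diagnosis groups")
    rows = {}
    for col in _DESCRIPTORS:
        x1 = asd[col].to_numpy(float)
        x2 = td[col].to_numpy(float)
        row = {
            "asd_mean": x1.mean(),
            "asd_sd": x1.std(ddof=1),
            "asd_min": x1.min(),
            "asd_max": x1.max(),
            "td_mean": x2.mean(),
            "td_sd": x2.std(ddof=1),
            "td_min": x2.min(),
            "td_max": x2.max(),
        }
        degenerate = row["asd_sd"] == 0 or row["td_sd"] == 0 or min(len(x1), len(x2)) < 2
        if degenerate:
            row.update(t=np.nan, df=np.nan, p=np.nan, degenerate=True)
        else:
            res = welch_from_vectors(x1, x2)
            row.update(t=res.t, df=res.df, p=res.p, degenerate=False)
        rows[col] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    counts = cohort.group_counts()
    out.attrs["n_asd"] = counts["asd"]
    out.attrs["n_td"] = counts["td"]
    asd_f, td_f = counts["asd_female"], counts["td_female"]
    out.attrs["sex_ratio_asd"] = (counts["asd"] - asd_f) / asd_f if asd_f else np.inf
    out.attrs["sex_ratio_td"] = (counts["td"] - td_f) / td_f if td_f else np.inf
    chi = chi2_2x2(counts["asd"] - asd_f, asd_f, counts["td"] - td_f, td_f)
    out.attrs["sex_chi2"] = chi.chi2
    out.attrs["sex_chi2_p"] = chi.p
    return out
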