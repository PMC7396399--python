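"""Test–retest repeatability (TRV) and one-way intraclass correlation (ICC).

TRV(%) = |PET2 − PET1| / ((PET1 + PET2)/2) × 100 per subject;
ICC = (s_b² − s_w²) / (s_b² + (n−1)·s_w²) with s_b², s_w² the between- and
within-subject mean squares of the one-way random-effects ANOVA and n the
number of sessions per subject (n = 2 here).  Negative ICC estimates are
reported as computed, not clipped.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["trv", "icc_oneway", "reliability_table", "summary_row"]


def trv(pet1: float, pet2: float) -> float:
    """Test–retest variability in percent of the session mean."""
    mean = 0.5 * (pet1 + pet2)
    if not mean > 0:
        raise ValueError("session mean must be > 0")
    return abs(pet2 - pet1) / mean * 100.0


def icc_oneway(values) -> float:
    """One-way random-effects ICC from a subjects × sessions matrix.

    Uses the ANOVA mean squares: with k subjects and n sessions,
    s_b² = n·Σ(m_i − m)²/(k−1), s_w² = ΣΣ(x_ij − m_i)²/(k(n−1)).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("values must be a subjects × sessions matrix")
    k, n = x.shape
    if k < 3:
        raise ValueError("need at least 3 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    subj_means = x.mean(axis=1)
    grand = x.mean()
    ms_between = n * np.sum((subj_means - grand) ** 2) / (k - 1)
    ms_within = np.sum((x - subj_means[:, None]) ** 2) / (k * (n - 1))
    denom = ms_between + (n - 1) * ms_within
    if denom == 0:
        raise ValueError("zero total variance: ICC undefined")
    return float((ms_between - ms_within) / denom)


def reliability_table(
    values: Mapping[str, np.ndarray], summary_label: str = "mean"
) -> pd.DataFrame:
    """Per-metric TRV mean/SD and ICC over a test–retest cohort.

    Parameters
    ----------
    values : mapping metric -> (subjects × 2) array
        One column per session.  Rows containing NaN (missing session or a
        non-converged fit) are dropped pairwise for that metric only.
    summary_label : str
        Label of the appended summary row: the arithmetic mean of the
        per-metric TRV means and ICCs.

    Returns
    -------
    DataFrame indexed by metric with columns trv_mean, trv_sd, icc, n_subjects.
    """
    rows = {}
    for metric, mat in values.items():
        x = np.asarray(mat, dtype=float)
        if x.ndim != 2 or x.shape[1] != 2:
            raise ValueError(f"metric {metric!r}: expected a subjects × 2 matrix")
        complete = x[np.all(np.isfinite(x), axis=1)]
        if len(complete) < 3:
            # too few complete pairs (missing sessions / non-converged fits):
            # keep the row but leave the statistics undefined
            rows[metric] = {"trv_mean": np.nan, "trv_sd": np.nan,
                            "icc": np.nan, "n_subjects": len(complete)}
            continue
        trvs = np.array([trv(a, b) for a, b in complete])
        rows[metric] = {
            "trv_mean": float(np.mean(trvs)),
            "trv_sd": float(np.std(trvs, ddof=1)),
            "icc": icc_oneway(complete),
            "n_subjects": len(complete),
        }
    if not rows:
        raise ValueError("no metrics supplied")
    if all(np.isnan(r["icc"]) for r in rows.values()):
        raise ValueError("no metric has 3 or more complete test-retest pairs")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.loc[summary_label] = {
        "trv_mean": df["trv_mean"].mean(),
        "trv_sd": df["trv_sd"].mean(),
        "icc": df["icc"].mean(),
        "n_subjects": df["n_subjects"].min(),
    }
    df["n_subjects"] = df["n_subjects"].astype(int)
    return df


def summary_row(per_region: pd.DataFrame) -> pd.Series:
    """Summary of a per-region reliability table: arithmetic mean over regions.

    Columns are averaged independently; NaN cells (e.g. an illegible or
    missing regional entry) are skipped column-wise.
    """
    numeric = per_region.select_dtypes(include=[np.number])
    if numeric.empty:
        raise ValueError("per_region has no numeric columns")
    return numeric.mean(axis=0, skipna=True)
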