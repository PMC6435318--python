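"""Scoring and statistics for 2AFC pitch-classification trial tables.

A trial table is a pandas DataFrame with one row per trial and columns

    subject_id, species, session_id, trial_index, reference_hz, condition,
    f0_class, response, correct, is_probe, is_error_correction

(the schema produced by :mod:`periphpitch.synthetic` and accepted by the CLI).
Analysis follows the task's published pipeline: error-correction trials are
excluded, whole sessions are excluded when standard-trial performance falls
below 60% correct, percent-correct scores are computed per condition, and
probe scores are normalized against standard scores as
``pnorm = (P - 50) / (S - 50)`` so that 1 means unimpaired and 0 means chance.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

REQUIRED_COLUMNS = [
    "subject_id", "species", "session_id", "trial_index", "reference_hz",
    "condition", "f0_class", "response", "correct", "is_probe",
    "is_error_correction",
]

SESSION_EXCLUSION_PCT = 60.0


def validate_trials(trials: pd.DataFrame) -> None:
    """Raise with the missing column names if the schema is incomplete."""
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")


def filter_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Apply the two published exclusions.

    1. Error-correction trials are dropped.
    2. Every trial of any session whose percent correct on (error-correction
       free) standard trials is below 60% is dropped.

    Session-level performance is computed before any other exclusion, so a
    run of forced-repeat trials can never disqualify a session.  A session
    with no standard trials at all is an error.  Idempotent.
    """
    validate_trials(trials)
    session_keys = ["subject_id", "session_id"]
    std = trials[~trials["is_probe"] & ~trials["is_error_correction"]]
    n_std = std.groupby(session_keys).size()
    all_sessions = trials.groupby(session_keys).size()
    empty = all_sessions.index.difference(n_std.index)
    if len(empty) > 0:
        raise ValueError(f"sessions with no standard trials: {list(empty)}")
    pct = std.groupby(session_keys)["correct"].mean() * 100.0
    keep = pct[pct >= SESSION_EXCLUSION_PCT].index
    idx = pd.MultiIndex.from_frame(trials[session_keys])
    return trials[idx.isin(keep) & ~trials["is_error_correction"]].copy()


def percent_correct(trials: pd.DataFrame, group_keys: list[str]) -> pd.DataFrame:
    """Percent correct and trial count per group.

    Groups with no trials are simply absent from the output (a warning is
    emitted when the table itself is empty).
    """
    if len(trials) == 0:
        warnings.warn("empty trial table: no performance rows produced")
        return pd.DataFrame(columns=group_keys + ["n_trials", "percent_correct"])
    g = trials.groupby(group_keys, observed=True)["correct"]
    out = g.agg(n_trials="size", percent_correct="mean").reset_index()
    out["percent_correct"] *= 100.0
    return out


def normalized_score(p: float, s: float) -> float:
    """Probe score normalized against the standard score: (P-50)/(S-50).

    1 means the probe was classified as accurately as the standard; 0 means
    chance.  Undefined (raises) when the standard score is exactly 50%.
    """
    if s == 50.0:
        raise ValueError("normalized score undefined when standard score is 50%")
    return (p - 50.0) / (s - 50.0)


def one_sample_t(values, mu: float) -> tuple[float, float, int]:
    """Two-sided one-sample t-test; returns (t, p, df)."""
    x = np.asarray(values, dtype=np.float64)
    if len(x) < 2:
        raise ValueError("need at least two values")
    s = x.std(ddof=1)
    if s == 0.0:
        raise ValueError("zero variance")
    df = len(x) - 1
    t = (x.mean() - mu) / (s / math.sqrt(len(x)))
    p = 2.0 * float(sstats.t.sf(abs(t), df))
    return float(t), p, df


def paired_t(a, b) -> tuple[float, float, int]:
    """Two-sided paired t-test (one-sample t on the differences)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0)


def two_way_anova(scores: pd.DataFrame, dv: str, factor_a: str,
                  factor_b: str) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction (Type-I sums of squares).

    Returns a tidy table with one row per term (factor_a, factor_b,
    interaction, residual) and columns F, df1, df2, p, sum_sq.  Requires at
    least two levels per factor and at least one observation per cell.
    """
    for f in (factor_a, factor_b):
        if scores[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least two levels")
    cells = scores.groupby([factor_a, factor_b], observed=True).size().unstack()
    if cells.isna().any().any():
        raise ValueError("every factor-level cell needs at least one observation")
    model = ols(f"{dv} ~ C({factor_a}) * C({factor_b})", data=scores).fit()
    table = anova_lm(model, typ=1)
    resid_df = float(table.loc["Residual", "df"])
    rename = {
        f"C({factor_a})": factor_a,
        f"C({factor_b})": factor_b,
        f"C({factor_a}):C({factor_b})": "interaction",
        "Residual": "residual",
    }
    out = pd.DataFrame({
        "term": [rename[i] for i in table.index],
        "sum_sq": table["sum_sq"].to_numpy(),
        "df1": table["df"].to_numpy(),
        "df2": [resid_df] * len(table),
        "F": table["F"].to_numpy(),
        "p": table["PR(>F)"].to_numpy(),
    })
    return out


def tukey_hsd(scores, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (studentized-range based).

    Returns one row per pair with the mean difference, adjusted p and the
    simultaneous confidence interval.
    """
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least two groups")
    res = pairwise_tukeyhsd(np.asarray(scores, dtype=np.float64), groups,
                            alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    frame = frame.rename(columns={"p-adj": "p_adj"})
    frame["p_adj"] = res.pvalues  # full precision, not the rounded summary
    return frame
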