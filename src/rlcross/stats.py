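"""Behavioural summaries and crossover inference.

The study design is a 2 x 2 within-subject crossover (treatment:
placebo/vaccine x valence: gain/loss).  With a single degree of freedom per
factor the repeated-measures ANOVA reduces exactly to paired t tests on
per-subject difference scores: the interaction F equals the squared paired t
on the difference-of-differences.  That identity is how the ANOVA is
computed here, and it is asserted as a self-test elsewhere in the suite.
Sphericity is moot for 2 x 2 within designs (numerator df = 1).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .task import correct_choice


class DesignError(ValueError):
    """Raised when the 2x2 within design is incomplete or degenerate."""


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df: tuple
    p: float
    direction: str


# ---------------------------------------------------------------------------
# trial-level summaries
# ---------------------------------------------------------------------------

def _correct_flags(cell_trials: pd.DataFrame) -> pd.DataFrame:
    conds = set(cell_trials["condition"].unique())
    if len(conds) != 1:
        raise DesignError(f"expected a single condition, got {sorted(conds)}")
    cond = conds.pop()
    target = correct_choice(cond)
    if target is None:
        raise DesignError("accuracy is undefined for the neutral condition")
    out = cell_trials.copy()
    out["correct"] = (out["choice"] == target).astype(float)
    return out


def learning_curve(cell_trials: pd.DataFrame, window: int = 5) -> np.ndarray:
    """Moving-average correct-choice proportion by within-pair trial index.

    Correct = choosing the high-probability win option (gain) or avoiding
    the high-probability loss option (loss).  The per-index proportion is
    averaged over the cell's pairs, then smoothed with a trailing moving
    average (``window = 1`` returns the raw curve).
    """
    df = _correct_flags(cell_trials)
    curve = df.groupby("trial")["correct"].mean().sort_index().to_numpy()
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > curve.size:
        raise ValueError(f"window {window} exceeds sequence length {curve.size}")
    return pd.Series(curve).rolling(window, min_periods=1).mean().to_numpy()


def plateau_accuracy(cell_trials: pd.DataFrame) -> float:
    """Fraction correct over the final half (ceil(n/2)) of trials, pooled over pairs."""
    df = _correct_flags(cell_trials)
    if len(df) < 2:
        raise DesignError("plateau accuracy needs at least 2 trials")
    n = int(df["trial"].max())
    cut = n - int(np.ceil(n / 2))
    tail = df[df["trial"] > cut]
    return float(tail["correct"].mean())


def build_cohort_table(trials: pd.DataFrame, fits: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-cell table feeding the 2x2 inference.

    One row per subject x treatment x valence with plateau accuracy, go
    rate, fitted parameters and per-pair mean log-likelihood.
    """
    rows = []
    for (s, t, c), sub in trials[trials["condition"].isin(("gain", "loss"))].groupby(
        ["subject_id", "treatment", "condition"]
    ):
        row = {
            "subject_id": s,
            "treatment": t,
            "condition": c,
            "plateau_accuracy": plateau_accuracy(sub),
            "go_rate": float(sub["go_flag"].mean()),
        }
        if "session_order" in sub.columns:
            row["session_order"] = int(sub["session_order"].iloc[0])
        rows.append(row)
    table = pd.DataFrame(rows)
    cols = ["subject_id", "treatment", "condition", "alpha", "beta", "r", "mean_ll_per_pair"]
    table = table.merge(fits[cols], on=["subject_id", "treatment", "condition"], how="left")
    # valence-aligned subjective value: |R|, the scale on which gain and loss
    # cells are commensurable in the 2x2 ANOVA (signed R is kept for post hocs)
    table["r_magnitude"] = np.where(table["condition"] == "loss", -table["r"], table["r"])
    return table


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def paired_t(x, y) -> PairedTResult:
    """Classical two-sided paired t test of x vs y.

    Identical vectors give ``t = 0, p = 1``.  A constant nonzero difference
    (zero variance) would make t infinite and is rejected as degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DesignError("paired_t needs two equal-length 1-d vectors")
    n = x.size
    if n < 2:
        raise DesignError("paired_t needs n >= 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0.0):
            return PairedTResult(t=0.0, df=n - 1, p=1.0, mean_diff=0.0)
        raise DesignError("zero variance of nonzero differences: t undefined")
    t, p = sps.ttest_rel(x, y)
    return PairedTResult(t=float(t), df=n - 1, p=float(p), mean_diff=float(d.mean()))


def _pivot_2x2(table: pd.DataFrame, value_col: str, a_col: str, b_col: str,
               subject_col: str) -> tuple[pd.DataFrame, list, list]:
    a_levels = sorted(table[a_col].unique())
    b_levels = sorted(table[b_col].unique())
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise DesignError(
            f"need exactly 2 levels of {a_col} and {b_col}, "
            f"got {a_levels} and {b_levels}"
        )
    wide = table.pivot_table(
        index=subject_col, columns=[a_col, b_col], values=value_col, aggfunc="mean"
    )
    missing = wide.index[wide.isna().any(axis=1)].tolist()
    full = [(a, b) for a in a_levels for b in b_levels]
    if wide.shape[1] < 4 or missing:
        lost = missing or table[subject_col].unique().tolist()
        raise DesignError(f"incomplete 2x2 cells for subjects: {lost}")
    return wide[full], a_levels, b_levels


def _f_from_diffs(d: np.ndarray, effect: str, hi: str, lo: str) -> AnovaResult:
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0.0):
            return AnovaResult(effect, 0.0, (1, n - 1), 1.0, "none")
        raise DesignError(f"zero-variance nonzero contrast for effect {effect}")
    t = d.mean() / (sd / np.sqrt(n))
    F = t * t
    p = float(2 * sps.t.sf(abs(t), n - 1))
    direction = f"{hi} > {lo}" if d.mean() > 0 else (f"{hi} < {lo}" if d.mean() < 0 else "none")
    return AnovaResult(effect, float(F), (1, n - 1), p, direction)


def rm_anova_2x2(
    table: pd.DataFrame,
    value_col: str,
    a_col: str = "treatment",
    b_col: str = "condition",
    subject_col: str = "subject_id",
) -> dict[str, AnovaResult]:
    """2x2 within-subject ANOVA via difference scores.

    Returns main effects of both factors and their interaction.  Each F is
    the square of the paired t on the corresponding per-subject contrast;
    df = (1, n - 1).
    """
    wide, (a1, a2), (b1, b2) = _pivot_2x2(table, value_col, a_col, b_col, subject_col)
    w = {ab: wide[ab].to_numpy(dtype=float) for ab in wide.columns}
    d_a = (w[(a2, b1)] + w[(a2, b2)]) / 2 - (w[(a1, b1)] + w[(a1, b2)]) / 2
    d_b = (w[(a1, b2)] + w[(a2, b2)]) / 2 - (w[(a1, b1)] + w[(a2, b1)]) / 2
    d_ab = (w[(a2, b1)] - w[(a1, b1)]) - (w[(a2, b2)] - w[(a1, b2)])
    return {
        a_col: _f_from_diffs(d_a, a_col, a2, a1),
        b_col: _f_from_diffs(d_b, b_col, b2, b1),
        "interaction": _f_from_diffs(
            d_ab, "interaction", f"{a2}-effect in {b1}", f"{a2}-effect in {b2}"
        ),
    }


def cell_paired_t(table: pd.DataFrame, value_col: str, fix_col: str, fix_level,
                  a_col: str = "treatment", subject_col: str = "subject_id") -> PairedTResult:
    """Paired t between the two ``a_col`` levels within one ``fix_col`` level."""
    sub = table[table[fix_col] == fix_level]
    a_levels = sorted(sub[a_col].unique())
    if len(a_levels) != 2:
        raise DesignError(f"need 2 levels of {a_col}, got {a_levels}")
    wide = sub.pivot_table(index=subject_col, columns=a_col, values=value_col)
    if wide.isna().any().any():
        raise DesignError("unpaired subjects in paired comparison")
    # convention: second (later-sorted) level minus first, e.g. vaccine - placebo
    return paired_t(wide[a_levels[1]], wide[a_levels[0]])


def engagement_check(table: pd.DataFrame) -> dict[str, AnovaResult]:
    """2x2 ANOVA on go rates: equal task engagement across conditions."""
    return rm_anova_2x2(table, "go_rate")


def session_order_anova(table: pd.DataFrame, value_col: str = "plateau_accuracy"):
    """Session (1st vs 2nd) x valence ANOVA — order/practice effect check."""
    if "session_order" not in table.columns:
        raise DesignError("table lacks a session_order column")
    return rm_anova_2x2(table, value_col, a_col="session_order")
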