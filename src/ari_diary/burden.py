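"""Symptom-day burden summaries, prevalence curves and stratum comparisons.

Burden counts operate on symptom days (a child-day with at least one symptom
or diagnosis flag set), independently of whether the day falls inside a
segmented episode — isolated single-B days count toward burden.  Prevalence
curves count child-days lying under an episode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    DIAGNOSIS_COLUMNS,
    ObservationWindow,
    SIX_MONTH_STRATA,
    SYMPTOM_COLUMNS,
)

#: Reporting groups for specific symptoms; cough pools both recorded forms
#: ("cough in various forms").
SYMPTOM_GROUPS: dict[str, tuple[str, ...]] = {
    "cough": ("wet_cough", "dry_cough"),
    "runny_nose": ("runny_or_blocked_nose",),
    "wheeze": ("wheezing",),
    "fever": ("fever",),
    "attachment": ("increased_attachment",),
    "high_need_for_sleep": ("increased_need_to_sleep",),
    "loss_of_appetite": ("loss_of_appetite",),
    "sore_throat": ("sore_throat",),
    "chills": ("chills",),
}

SUMMARY_ROWS = ("min", "q1", "median", "mean", "q3", "max")


def symptomatic_fraction(n_symptomatic_days: int, n_observed_days: int) -> float:
    """Fraction of observed child-days carrying at least one symptom."""
    if n_observed_days <= 0:
        raise ValueError("n_observed_days must be positive")
    return n_symptomatic_days / n_observed_days


def mean_days_per_child(n_symptomatic_days: int, n_children: int) -> float:
    """Cohort mean symptom days per child."""
    if n_children <= 0:
        raise ValueError("n_children must be positive")
    return n_symptomatic_days / n_children


@dataclass
class CohortBurden:
    """Per-child and cohort-level symptom-day burden."""

    per_child: pd.DataFrame          # child x (total, strata, symptom groups)
    summary: pd.DataFrame            # distribution grid over per_child columns
    n_child_days: int                # observed child-days
    n_symptomatic_days: int          # observed child-days with >=1 symptom
    fraction_symptomatic: float


def distribution_grid(per_child: pd.DataFrame) -> pd.DataFrame:
    """min/Q1/median/mean/Q3/max grid over each column (linear quantiles)."""
    rows = {
        "min": per_child.min(),
        "q1": per_child.quantile(0.25),
        "median": per_child.quantile(0.5),
        "mean": per_child.mean(),
        "q3": per_child.quantile(0.75),
        "max": per_child.max(),
    }
    return pd.DataFrame(rows).T.loc[list(SUMMARY_ROWS)]


def symptom_day_summary(diary: pd.DataFrame, child_ids: list[str],
                        window: ObservationWindow | None = None) -> CohortBurden:
    """Count symptom days per child — overall, by six-month stratum, and by
    specific symptom.

    A day is symptomatic iff any symptom flag (or diagnosis flag) is set.
    Per-symptom counts tally every day the flag is set, so a day with fever
    and cough adds to both symptom columns but counts once in the total.
    """
    window = window or ObservationWindow()
    idx = pd.Index(child_ids, name="child_id")
    d = diary.loc[diary["child_id"].isin(idx)].copy()

    sym = d[list(SYMPTOM_COLUMNS)].to_numpy() > 0
    dx = d[list(DIAGNOSIS_COLUMNS)].to_numpy() > 0
    d["is_symptomatic"] = sym.any(axis=1) | dx.any(axis=1)

    per_child = pd.DataFrame(index=idx)
    grouped = d.groupby("child_id")["is_symptomatic"]
    per_child["total"] = grouped.sum().reindex(idx, fill_value=0).astype(int)
    for name, (lo, hi) in SIX_MONTH_STRATA.items():
        in_stratum = d["day_of_life"].between(lo, hi)
        counts = d.loc[in_stratum].groupby("child_id")["is_symptomatic"].sum()
        per_child[name] = counts.reindex(idx, fill_value=0).astype(int)
    for group, cols in SYMPTOM_GROUPS.items():
        flag = (d[list(cols)].to_numpy() > 0).any(axis=1)
        counts = pd.Series(flag, index=d.index).groupby(d["child_id"]).sum()
        per_child[group] = counts.reindex(idx, fill_value=0).astype(int)

    n_days = int(len(d))
    n_sym = int(d["is_symptomatic"].sum())
    return CohortBurden(
        per_child=per_child,
        summary=distribution_grid(per_child),
        n_child_days=n_days,
        n_symptomatic_days=n_sym,
        fraction_symptomatic=symptomatic_fraction(n_sym, n_days) if n_days else 0.0,
    )


def percentile_curves(per_child: pd.DataFrame) -> pd.DataFrame:
    """Empirical cumulative distribution of per-child day counts.

    Tidy output: one row per (column, value) with the cumulative fraction of
    children at or below that value; each curve is monotone and reaches 1.
    """
    frames = []
    n = len(per_child)
    for col in per_child.columns:
        vals = np.sort(per_child[col].to_numpy())
        uniq, counts = np.unique(vals, return_counts=True)
        cum = np.cumsum(counts) / n
        frames.append(pd.DataFrame({"measure": col, "value": uniq, "cum_fraction": cum}))
    return pd.concat(frames, ignore_index=True)


def observed_matrix(diary: pd.DataFrame, child_ids: list[str],
                    window: ObservationWindow) -> np.ndarray:
    """(n_children, n_days) boolean: diary entry present."""
    mat = np.zeros((len(child_ids), window.n_days), dtype=bool)
    row_of = {cid: i for i, cid in enumerate(child_ids)}
    rows = diary.loc[diary["child_id"].isin(row_of), "child_id"].map(row_of).to_numpy()
    cols = diary.loc[diary["child_id"].isin(row_of), "day_of_life"].to_numpy() - window.start_day
    mat[rows, cols] = True
    return mat


def in_episode_matrix(episodes: pd.DataFrame, child_ids: list[str],
                      window: ObservationWindow) -> np.ndarray:
    """(n_children, n_days) boolean: day lies under an episode (start..last)."""
    mat = np.zeros((len(child_ids), window.n_days), dtype=bool)
    row_of = {cid: i for i, cid in enumerate(child_ids)}
    for cid, start, last in episodes[["child_id", "start_day", "last_symptom_day"]].itertuples(index=False):
        if cid in row_of:
            mat[row_of[cid], start - window.start_day: last - window.start_day + 1] = True
    return mat


def prevalence_by_day(diary: pd.DataFrame, episodes: pd.DataFrame,
                      child_ids: list[str],
                      window: ObservationWindow | None = None) -> pd.DataFrame:
    """Proportion of children under an ARI episode per day of life.

    Numerator: observed child-days under an episode; denominator: observed
    child-days.  Tidy output `axis,value,numerator,denominator`.
    """
    window = window or ObservationWindow()
    obs = observed_matrix(diary, child_ids, window)
    in_ep = in_episode_matrix(episodes, child_ids, window) & obs
    num = in_ep.sum(axis=0)
    den = obs.sum(axis=0)
    value = np.divide(num, den, out=np.zeros_like(num, dtype=float), where=den > 0)
    return pd.DataFrame({
        "axis": np.arange(window.start_day, window.end_day + 1),
        "value": value,
        "numerator": num,
        "denominator": den,
    })


def prevalence_by_month(diary: pd.DataFrame, episodes: pd.DataFrame,
                        covariates: pd.DataFrame, child_ids: list[str],
                        window: ObservationWindow | None = None) -> pd.DataFrame:
    """Proportion of observed child-days under an episode per calendar month.

    Uses each day's calendar date, so children born across the year
    contribute to every month at different ages (which is what lets the
    seasonal signal be read separately from the age trend).
    """
    window = window or ObservationWindow()
    obs = observed_matrix(diary, child_ids, window)
    in_ep = in_episode_matrix(episodes, child_ids, window) & obs

    n_days = window.n_days
    months = np.empty((len(child_ids), n_days), dtype=np.int8)
    for i, cid in enumerate(child_ids):
        birth = covariates.loc[cid, "birth_date"]
        dates = pd.date_range(birth + pd.Timedelta(days=window.start_day), periods=n_days)
        months[i] = dates.month

    rows = []
    for m in range(1, 13):
        mask = months == m
        den = int((obs & mask).sum())
        num = int((in_ep & mask).sum())
        rows.append((m, num / den if den else 0.0, num, den))
    return pd.DataFrame(rows, columns=["axis", "value", "numerator", "denominator"])


def welch_mean_difference(group: np.ndarray, reference: np.ndarray,
                          confidence: float = 0.95) -> tuple[float, float, float]:
    """Welch (unequal-variance) mean difference group - reference with CI."""
    res = stats.ttest_ind(np.asarray(group, float), np.asarray(reference, float),
                          equal_var=False)
    ci = res.confidence_interval(confidence)
    diff = float(np.mean(group) - np.mean(reference))
    return diff, float(ci.low), float(ci.high)


def strata_mean_difference(counts: pd.Series, groups: pd.Series,
                           reference: str,
                           level_order: list[str] | None = None) -> pd.DataFrame:
    """Per-level mean episode counts and Welch 95% CI of the difference to the
    reference level.  Children with a missing group label are dropped."""
    keep = groups.notna()
    counts, groups = counts[keep], groups[keep]
    if reference not in set(groups):
        raise ValueError(f"reference level {reference!r} not present")
    ref_vals = counts[groups == reference].to_numpy()
    levels = level_order or sorted(groups.unique(), key=str)
    rows = []
    for lev in levels:
        vals = counts[groups == lev].to_numpy()
        if lev == reference:
            rows.append((lev, len(vals), float(vals.mean()), np.nan, np.nan, np.nan, True))
            continue
        diff, lo, hi = welch_mean_difference(vals, ref_vals)
        rows.append((lev, len(vals), float(vals.mean()), diff, lo, hi, False))
    return pd.DataFrame(rows, columns=["level", "n", "mean", "difference",
                                       "ci_low", "ci_high", "is_reference"])
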