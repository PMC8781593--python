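"""ARI episode segmentation from classified diary days.

An episode opens on the first day carrying at least one A-symptom (or
doctor-diagnosed pneumonia/otitis media) or at least two distinct B-symptoms.
Inside an episode any symptomatic day — including a single B-symptom —
resets the recovery counter; three consecutive symptom-free days terminate
the episode at its last symptomatic day.  A single B-symptom outside any
episode is an orphan symptom day: it counts toward symptom burden but never
starts an episode.

The engine is deterministic; missing diary days are handled by one of two
rules: ``"free"`` (default) counts a missing day toward the three-day
termination run, ``"pause"`` freezes the counter on missing days.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import (
    ALL_STRATA,
    A_SYMPTOMS,
    B_SYMPTOMS,
    DIAGNOSIS_COLUMNS,
    DayClass,
    EPISODE_COLUMNS,
    ObservationWindow,
)

TRIGGER_A = "A_symptom"
TRIGGER_B = "B_pair"

MISSING_RULES = ("free", "pause")


def classify_day(day: pd.Series | dict) -> DayClass:
    """Classify a single diary day (scalar convenience wrapper).

    ``day`` maps symptom/diagnosis names to codes; absent keys count as 0.
    A day with no entry at all is represented by ``entry_present=False``.
    """
    get = day.get
    if not get("entry_present", True):
        return DayClass.MISSING
    if any(get(s, 0) for s in A_SYMPTOMS) or any(get(d, 0) for d in DIAGNOSIS_COLUMNS):
        return DayClass.A_DAY
    n_b = sum(bool(get(s, 0)) for s in B_SYMPTOMS)
    if n_b >= 2:
        return DayClass.B_PAIR
    if n_b == 1:
        return DayClass.SINGLE_B
    return DayClass.FREE


def classify_diary(diary: pd.DataFrame) -> pd.Series:
    """Vectorised day classification for every (present) diary row."""
    a_any = (diary[list(A_SYMPTOMS)].to_numpy() > 0).any(axis=1)
    dx_any = (diary[list(DIAGNOSIS_COLUMNS)].to_numpy() > 0).any(axis=1)
    n_b = (diary[list(B_SYMPTOMS)].to_numpy() > 0).sum(axis=1)
    out = np.full(len(diary), DayClass.FREE, dtype=np.int8)
    out[n_b == 1] = DayClass.SINGLE_B
    out[n_b >= 2] = DayClass.B_PAIR
    out[a_any | dx_any] = DayClass.A_DAY
    return pd.Series(out, index=diary.index, name="day_class")


def day_class_matrix(diary: pd.DataFrame, child_ids: list[str],
                     window: ObservationWindow) -> np.ndarray:
    """(n_children, n_days) array of DayClass codes, MISSING where no row."""
    n = len(child_ids)
    mat = np.full((n, window.n_days), DayClass.MISSING, dtype=np.int8)
    row_of = {cid: i for i, cid in enumerate(child_ids)}
    classes = classify_diary(diary).to_numpy()
    rows = diary["child_id"].map(row_of).to_numpy()
    cols = diary["day_of_life"].to_numpy() - window.start_day
    mat[rows, cols] = classes
    return mat


def _segment_one(classes: np.ndarray, start_day: int, missing_rule: str,
                 ) -> tuple[list[tuple], list[int]]:
    """Single left-to-right pass over one child's day-class sequence."""
    episodes: list[tuple] = []
    orphans: list[int] = []
    in_episode = False
    ep_start = ep_last = -1
    n_sym = 0
    trigger = ""
    free_run = 0
    for offset, c in enumerate(classes):
        d = start_day + offset
        symptomatic = c >= DayClass.SINGLE_B
        if not in_episode:
            if c >= DayClass.B_PAIR:
                in_episode = True
                ep_start = ep_last = d
                n_sym = 1
                trigger = TRIGGER_A if c == DayClass.A_DAY else TRIGGER_B
                free_run = 0
            elif c == DayClass.SINGLE_B:
                orphans.append(d)
        else:
            if symptomatic:
                ep_last = d
                n_sym += 1
                free_run = 0
            elif c == DayClass.FREE or (c == DayClass.MISSING and missing_rule == "free"):
                free_run += 1
                if free_run == 3:
                    episodes.append((ep_start, ep_last, trigger, False, n_sym))
                    in_episode = False
            # MISSING under "pause": counter frozen
    if in_episode:
        episodes.append((ep_start, ep_last, trigger, True, n_sym))
    return episodes, orphans


def segment_episodes(diary: pd.DataFrame,
                     child_ids: list[str] | None = None,
                     window: ObservationWindow | None = None,
                     missing_rule: str = "free",
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment every child's diary into ARI episodes and orphan symptom days.

    Parameters
    ----------
    diary
        Validated diary table with ``day_of_life``; one row per present day.
    child_ids
        Children to segment (default: all children appearing in the diary).
        Children with no rows yield no episodes.
    window
        Observation window; days without a row are materialised as MISSING.
    missing_rule
        How missing days interact with the three-free-day termination rule.

    Returns
    -------
    (episodes, orphans)
        ``episodes`` has columns child_id, start_day, last_symptom_day,
        duration_days, trigger, censored, n_symptom_days; episodes of one
        child are ordered and non-overlapping.  ``orphans`` has columns
        child_id, day_of_life.
    """
    if missing_rule not in MISSING_RULES:
        raise ValueError(f"missing_rule must be one of {MISSING_RULES}")
    window = window or ObservationWindow()
    if child_ids is None:
        child_ids = sorted(diary["child_id"].unique())
    if diary.duplicated(subset=["child_id", "day_of_life"]).any():
        raise ValueError("duplicate child-day rows in diary")

    mat = day_class_matrix(diary, list(child_ids), window)
    ep_rows: list[tuple] = []
    orphan_rows: list[tuple] = []
    for i, cid in enumerate(child_ids):
        eps, orphans = _segment_one(mat[i], window.start_day, missing_rule)
        for start, last, trigger, censored, n_sym in eps:
            ep_rows.append((cid, start, last, last - start + 1, trigger, censored, n_sym))
        orphan_rows.extend((cid, d) for d in orphans)

    episodes = pd.DataFrame(ep_rows, columns=list(EPISODE_COLUMNS))
    episodes = episodes.astype({"start_day": int, "last_symptom_day": int,
                                "duration_days": int, "censored": bool,
                                "n_symptom_days": int})
    orphan_df = pd.DataFrame(orphan_rows, columns=["child_id", "day_of_life"])
    return episodes, orphan_df


def episodes_per_child(episodes: pd.DataFrame, child_ids: list[str],
                       strata: dict[str, tuple[int, int]] | None = None,
                       ) -> pd.DataFrame:
    """Episode counts per child and age stratum, assigned by start day.

    Each episode lands in exactly one six-month (and one yearly) stratum via
    its start day, so counts over disjoint strata sum to the total even when
    an episode spans a boundary.
    """
    strata = strata or ALL_STRATA
    out = pd.DataFrame(0, index=pd.Index(child_ids, name="child_id"),
                       columns=list(strata), dtype=int)
    for name, (lo, hi) in strata.items():
        mask = episodes["start_day"].between(lo, hi)
        counts = episodes.loc[mask].groupby("child_id").size()
        out[name] = counts.reindex(out.index, fill_value=0).astype(int)
    return out


def age_at_first_episode(episodes: pd.DataFrame, child_ids: list[str]) -> pd.Series:
    """Day of life of each child's first episode; NaN when none observed.

    Children with no episode in the window are censored and excluded from
    cohort medians (reported as NaN here).
    """
    first = episodes.groupby("child_id")["start_day"].min()
    return first.reindex(pd.Index(child_ids, name="child_id")).astype(float)


def duration_summary(episodes: pd.DataFrame, level: str = "episode") -> dict[str, float]:
    """Summary statistics of episode duration.

    ``level="episode"`` summarises all episode durations; ``level="child_mean"``
    summarises per-child mean durations.  Quantiles use linear interpolation.
    """
    if level == "episode":
        x = episodes["duration_days"].astype(float)
    elif level == "child_mean":
        x = episodes.groupby("child_id")["duration_days"].mean()
    else:
        raise ValueError("level must be 'episode' or 'child_mean'")
    q1, med, q3 = (np.quantile(x, q) for q in (0.25, 0.5, 0.75)) if len(x) else (np.nan,) * 3
    return {
        "n": int(len(x)),
        "mean": float(x.mean()) if len(x) else float("nan"),
        "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0 if len(x) else float("nan"),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
    }
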