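#!/usr/bin/env python
"""Symptom-day burden and prevalence curves.

Counts days with any symptom (episodes and isolated days alike), overall,
by six-month age stratum and by specific symptom; writes the burden grid,
the cumulative distributions, and daily/monthly in-episode prevalence.
"""

import sys
from pathlib import Path

import pandas as pd

from ari_diary.burden import (
    percentile_curves,
    prevalence_by_day,
    prevalence_by_month,
    symptom_day_summary,
)
from ari_diary.diary_io import apply_inclusion, read_covariates, read_diary

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    if not (OUT / "episodes.csv").exists():
        sys.exit("no episode table: run analysis/02_segment_episodes.py first")
    covariates = read_covariates(DATA / "covariates.csv")
    diary = read_diary(DATA / "diary.csv", covariates)
    included, _ = apply_inclusion(diary, covariates)
    ids = sorted(included)
    diary = diary.loc[diary["child_id"].isin(included)]
    episodes = pd.read_csv(OUT / "episodes.csv", dtype={"child_id": str})

    burden = symptom_day_summary(diary, ids)
    burden.summary.to_csv(OUT / "table2.csv", index_label="statistic")
    percentile_curves(burden.per_child).to_csv(OUT / "percentiles.csv", index=False)
    by_day = prevalence_by_day(diary, episodes, ids)
    by_day.to_csv(OUT / "prevalence_by_day.csv", index=False)
    by_month = prevalence_by_month(diary, episodes, covariates, ids)
    by_month.to_csv(OUT / "prevalence_by_month.csv", index=False)

    pc = burden.per_child
    print(f"{burden.n_symptomatic_days} of {burden.n_child_days} observed "
          f"child-days symptomatic ({100 * burden.fraction_symptomatic:.1f}%)")
    print(f"mean {pc['total'].mean():.1f} symptom days per child over two years")
    print("most common: runny/blocked nose "
          f"({pc['runny_nose'].mean():.1f} d/child), cough "
          f"({pc['cough'].mean():.1f} d/child); rarest: chills "
          f"({pc['chills'].mean():.1f} d/child)")
    m = by_month.set_index("axis")["value"]
    print(f"in-episode prevalence: Dec-Feb {m[[12, 1, 2]].mean():.3f} vs "
          f"Jun-Aug {m[[6, 7, 8]].mean():.3f} (winter excess)")


if __name__ == "__main__":
    main()
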