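#!/usr/bin/env python
"""Apply the inclusion filter and segment diaries into ARI episodes.

Reads the simulated cohort from results/data/, keeps children with >=98%
diary completeness, runs the A/B-symptom episode state machine, and writes
episodes.csv and orphan_days.csv under results/.
"""

import sys
from pathlib import Path

from ari_diary.diary_io import apply_inclusion, read_covariates, read_diary
from ari_diary.episodes import (
    age_at_first_episode,
    duration_summary,
    episodes_per_child,
    segment_episodes,
)

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    if not (DATA / "diary.csv").exists():
        sys.exit("no input data: run analysis/01_simulate_cohort.py first")
    covariates = read_covariates(DATA / "covariates.csv")
    diary = read_diary(DATA / "diary.csv", covariates)
    included, excluded = apply_inclusion(diary, covariates)
    ids = sorted(included)
    diary = diary.loc[diary["child_id"].isin(included)]
    print(f"inclusion: {len(included)} children kept, {len(excluded)} below "
          f"98% diary completeness")

    episodes, orphans = segment_episodes(diary, ids)
    episodes.to_csv(OUT / "episodes.csv", index=False)
    orphans.to_csv(OUT / "orphan_days.csv", index=False)

    counts = episodes_per_child(episodes, ids)["0-24 months"]
    dur = duration_summary(episodes)
    first = age_at_first_episode(episodes, ids)
    print(f"{len(episodes)} episodes in two years "
          f"(mean {counts.mean():.1f}, median {counts.median():.0f} per child)")
    print(f"duration: mean {dur['mean']:.1f} d (SD {dur['sd']:.1f}, "
          f"median {dur['median']:.1f}, IQR {dur['q1']:.0f}-{dur['q3']:.0f})")
    print(f"median age at first episode: {first.median():.0f} days")
    print(f"{len(orphans)} isolated single-B-symptom days outside episodes")


if __name__ == "__main__":
    main()
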