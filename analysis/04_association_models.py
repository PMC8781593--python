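#!/usr/bin/env python
"""Factors associated with two-year ARI frequency.

Builds the descriptive comparison table (mean episode counts with Welch
mean differences per covariate stratum), the per-stratum episode-count
grid, and crude/adjusted Poisson rate-ratio models.
"""

import sys
from pathlib import Path

import pandas as pd

from ari_diary.burden import distribution_grid
from ari_diary.diary_io import apply_inclusion, read_covariates, read_diary
from ari_diary.episodes import episodes_per_child
from ari_diary.pipeline import build_table1
from ari_diary.regression import rate_ratio_table

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    if not (OUT / "episodes.csv").exists():
        sys.exit("no episode table: run analysis/02_segment_episodes.py first")
    covariates = read_covariates(DATA / "covariates.csv")
    diary = read_diary(DATA / "diary.csv", covariates)
    included, _ = apply_inclusion(diary, covariates)
    ids = sorted(included)
    covariates = covariates.loc[ids]
    episodes = pd.read_csv(OUT / "episodes.csv", dtype={"child_id": str})

    counts_grid = episodes_per_child(episodes, ids)
    distribution_grid(counts_grid).to_csv(OUT / "table3.csv", index_label="statistic")
    counts = counts_grid["0-24 months"]
    build_table1(counts, covariates).to_csv(OUT / "table1.csv", index=False)
    table4 = rate_ratio_table(counts, covariates)
    table4.to_csv(OUT / "table4.csv", index=False)

    print(f"episode counts: year 1 mean {counts_grid['0-12 months'].mean():.1f}, "
          f"year 2 mean {counts_grid['13-24 months'].mean():.1f}, "
          f"two-year mean {counts.mean():.1f}")
    est = table4.loc[~table4["is_reference"]].set_index(["covariate", "level"])
    for key, label in [
        (("daycare_entry", "13-26 months"), "daycare entry at 13-26 months"),
        (("older_siblings", "2+"), "2+ older siblings"),
        (("breastfeeding", "1-3 months"), "exclusive breastfeeding 1-3 months"),
    ]:
        row = est.loc[key]
        print(f"adjusted RR, {label}: {row['adj_RR']:.2f} "
              f"({row['adj_lo']:.2f}; {row['adj_hi']:.2f})")


if __name__ == "__main__":
    main()
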