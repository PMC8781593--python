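#!/usr/bin/env python
"""Simulate the default-condition synthetic cohort.

Generates 288 children (the analysed sample size) with two-year daily
symptom diaries, ~1% missing diary days, and exports the latent episode
ground truth.  Downstream analysis steps read from results/data/.
"""

from pathlib import Path

from ari_diary.simulate import SimulationConfig, simulate_cohort

OUT = Path("results/data")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(n_children=288, seed=SEED)
    covariates, diary, truth = simulate_cohort(cfg)

    cov_out = covariates.copy()
    cov_out["birth_date"] = cov_out["birth_date"].dt.strftime("%Y-%m-%d")
    cov_out.to_csv(OUT / "covariates.csv", index=False)
    diary_out = diary.drop(columns="day_of_life").copy()
    diary_out["date"] = diary_out["date"].dt.strftime("%Y-%m-%d")
    diary_out.to_csv(OUT / "diary.csv", index=False)
    truth.to_csv(OUT / "truth_episodes.csv", index=False)

    print(f"simulated {len(covariates)} children, {len(diary)} diary rows "
          f"({len(diary) / (len(covariates) * cfg.window.n_days):.1%} of child-days observed)")
    print(f"latent truth: {len(truth)} episodes "
          f"({len(truth) / len(covariates):.1f} per child)")
    print(f"wrote diary.csv, covariates.csv, truth_episodes.csv to {OUT}/")


if __name__ == "__main__":
    main()
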