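from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from ari_diary.datamodel import DIAGNOSIS_COLUMNS, DIARY_COLUMNS, SYMPTOM_COLUMNS
from ari_diary.simulate import SimulationConfig, simulate_cohort

ALL_FLAG_COLUMNS = SYMPTOM_COLUMNS + DIAGNOSIS_COLUMNS


def diary_from_days(days: dict[int, dict[str, int]], child_id: str = "A",
                    birth: str = "2015-03-01") -> pd.DataFrame:
    """Build a validated-shape diary from {day_of_life: {symptom: code}}.

    Days absent from the dict have no row (missing diary days).
    """
    birth_ts = pd.Timestamp(birth)
    rows = []
    for d in sorted(days):
        row = {c: 0 for c in ALL_FLAG_COLUMNS}
        row.update(days[d])
        row["child_id"] = child_id
        row["date"] = birth_ts + pd.Timedelta(days=d)
        row["day_of_life"] = d
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(DIARY_COLUMNS) + ["day_of_life"])
    return df.astype({c: int for c in ALL_FLAG_COLUMNS})


def covariates_for(child_ids: list[str], birth: str = "2015-03-01") -> pd.DataFrame:
    cov = pd.DataFrame({
        "child_id": child_ids,
        "birth_date": pd.Timestamp(birth),
        "sex": "male",
        "birth_term": "full_term",
        "birth_mode": "vaginal",
        "birth_weight_g": 3400,
        "older_siblings": "0",
        "breastfeeding": "4-6 months",
        "daycare_entry": "none_by_24mo",
        "pets": "no",
    })
    return cov.set_index("child_id", drop=False)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition synthetic cohort, small enough for unit tests."""
    cfg = SimulationConfig(n_children=80, seed=5)
    covariates, diary, truth = simulate_cohort(cfg)
    return cfg, covariates, diary, truth


def random_symptom_diary(rng: np.random.Generator, n_days: int = 60,
                         p_symptom: float = 0.12, p_missing: float = 0.10,
                         p_dx: float = 0.01):
    """Uniform random diary for one child: returns (day -> flag dict or None)."""
    days: dict[int, dict[str, int] | None] = {}
    for d in range(n_days):
        if rng.random() < p_missing:
            days[d] = None
            continue
        flags = {c: 1 for c in SYMPTOM_COLUMNS if rng.random() < p_symptom}
        for c in DIAGNOSIS_COLUMNS:
            if rng.random() < p_dx:
                flags[c] = 1
        days[d] = flags
    return days
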