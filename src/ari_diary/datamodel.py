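"""Core vocabulary for daily-symptom-diary ARI analysis.

The case definition distinguishes A-symptoms (fever, wheezing, wet cough,
plus doctor-diagnosed pneumonia or otitis media) from B-symptoms (dry cough,
chills, sore throat, runny or blocked nose, increased need to sleep, loss of
appetite, increased attachment).  A single A-symptom, or two distinct
B-symptoms on one day, can open an illness episode; a single isolated
B-symptom cannot.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

A_SYMPTOMS: tuple[str, ...] = ("fever", "wheezing", "wet_cough")
B_SYMPTOMS: tuple[str, ...] = (
    "dry_cough",
    "chills",
    "sore_throat",
    "runny_or_blocked_nose",
    "increased_need_to_sleep",
    "loss_of_appetite",
    "increased_attachment",
)
SYMPTOM_COLUMNS: tuple[str, ...] = A_SYMPTOMS + B_SYMPTOMS

#: Doctor-diagnosis flags recorded in the diary; they count as A-symptoms.
DIAGNOSIS_COLUMNS: tuple[str, ...] = ("dx_pneumonia", "dx_otitis_media")

DIARY_COLUMNS: tuple[str, ...] = ("child_id", "date") + SYMPTOM_COLUMNS + DIAGNOSIS_COLUMNS


class DayClass(enum.IntEnum):
    """Mutually exclusive, exhaustive classification of one child-day.

    Ordering matters: any value >= SINGLE_B is a symptomatic day.
    """

    MISSING = 0
    FREE = 1
    SINGLE_B = 2
    B_PAIR = 3
    A_DAY = 4

    @property
    def symptomatic(self) -> bool:
        return self >= DayClass.SINGLE_B

    @property
    def can_start_episode(self) -> bool:
        return self >= DayClass.B_PAIR


@dataclass(frozen=True)
class ObservationWindow:
    """Days of life covered by the analysis (default: first two years).

    ``start_day`` 0 is the birth date; the default window spans days 0-729
    inclusive, i.e. 730 days.  ``completeness_threshold`` is the minimum
    fraction of window days with a diary entry required for inclusion.
    """

    start_day: int = 0
    end_day: int = 729
    completeness_threshold: float = 0.98

    def __post_init__(self) -> None:
        if self.end_day < self.start_day:
            raise ValueError("end_day must be >= start_day")
        if not 0.0 <= self.completeness_threshold <= 1.0:
            raise ValueError("completeness_threshold must be in [0, 1]")

    @property
    def n_days(self) -> int:
        return self.end_day - self.start_day + 1


# Covariate levels exactly as used in the questionnaire tables.  The first
# level of each tuple is the reference level for mean-difference comparisons
# and for the Poisson regression.
COVARIATE_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "birth_term": ("full_term", "early_term"),
    "birth_mode": ("vaginal", "c_section"),
    "older_siblings": ("0", "1", "2+"),
    "breastfeeding": ("4-6 months", "none", "1-3 months", "7-13 months"),
    "daycare_entry": ("none_by_24mo", "0-12 months", "13-26 months"),
}

#: Reference levels for descriptive mean-difference comparisons (the
#: questionnaire table's convention, which for sex differs from the
#: regression reference).
DESCRIPTIVE_REFERENCES: dict[str, str] = {
    "sex": "female",
    "birth_term": "full_term",
    "birth_mode": "vaginal",
    "older_siblings": "0",
    "breastfeeding": "4-6 months",
    "daycare_entry": "none_by_24mo",
    "pets": "no",
}

#: Level display order for descriptive tables (pets is outside the model
#: vocabulary, so it is listed here).
DESCRIPTIVE_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "birth_term": ("full_term", "early_term"),
    "birth_mode": ("vaginal", "c_section"),
    "older_siblings": ("0", "1", "2+"),
    "breastfeeding": ("1-3 months", "4-6 months", "7-13 months", "none"),
    "daycare_entry": ("0-12 months", "13-26 months", "none_by_24mo"),
    "pets": ("yes", "no"),
}

#: Covariates entering the adjusted (multivariable) Poisson model.
MODEL_COVARIATES: tuple[str, ...] = (
    "breastfeeding",
    "daycare_entry",
    "birth_mode",
    "birth_term",
    "sex",
    "older_siblings",
)

COVARIATE_CSV_COLUMNS: tuple[str, ...] = (
    "child_id",
    "birth_date",
    "sex",
    "birth_term",
    "birth_mode",
    "birth_weight_g",
    "older_siblings",
    "breastfeeding",
    "daycare_entry",
    "pets",
)

EPISODE_COLUMNS: tuple[str, ...] = (
    "child_id",
    "start_day",
    "last_symptom_day",
    "duration_days",
    "trigger",
    "censored",
    "n_symptom_days",
)

#: Six-month age strata in days of life (730/4; boundary convention fixed here
#: because the diary is daily and months have no canonical day count).
SIX_MONTH_STRATA: dict[str, tuple[int, int]] = {
    "0-6 months": (0, 182),
    "7-12 months": (183, 365),
    "13-18 months": (366, 547),
    "19-24 months": (548, 729),
}

YEAR_STRATA: dict[str, tuple[int, int]] = {
    "0-12 months": (0, 365),
    "13-24 months": (366, 729),
}

ALL_STRATA: dict[str, tuple[int, int]] = {
    **SIX_MONTH_STRATA,
    **YEAR_STRATA,
    "0-24 months": (0, 729),
}
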