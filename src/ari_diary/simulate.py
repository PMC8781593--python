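"""Synthetic birth-cohort generator: covariates, two-year daily symptom
diaries, and the latent ground-truth episode table.

Episodes arise from a discrete-time daily onset hazard
``h_i * a(age) * s(month)`` where ``h_i`` carries the child's covariate
effects, ``a`` ramps up over the first months of life and ``s`` peaks in
winter (both normalised to mean 1).  Covariate effects are specified as
rate ratios on the *expected two-year episode count*; the generator inverts
the occupancy relation ``c = h * (T - c * Dbar)`` (Dbar = mean episode
length + 3 refractory days) so that fitted Poisson rate ratios recover the
configured ones rather than attenuated hazard ratios.

Within an episode the first day is guaranteed to satisfy the start rule
(one A-symptom or two distinct B-symptoms, per the configured trigger mix)
and every episode day carries at least one symptom; at least three
symptom-free days follow each episode, so with missingness and orphan noise
switched off the definition-based segmentation recovers the latent truth
exactly.  Isolated single-B-symptom days are sprinkled outside episodes
(never within three days after one, so they cannot extend it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (
    A_SYMPTOMS,
    B_SYMPTOMS,
    DIAGNOSIS_COLUMNS,
    DIARY_COLUMNS,
    EPISODE_COLUMNS,
    ObservationWindow,
    SYMPTOM_COLUMNS,
)
from .episodes import TRIGGER_A, TRIGGER_B

# Covariate margins of the emulated cohort (fractions of children).
DEFAULT_COVARIATE_PROBS: dict[str, dict[str, float]] = {
    "sex": {"male": 0.48, "female": 0.52},
    "birth_term": {"full_term": 0.924, "early_term": 0.076},
    "birth_mode": {"vaginal": 0.77, "c_section": 0.23},
    "older_siblings": {"0": 0.682, "1": 0.255, "2+": 0.063},
    "breastfeeding": {"4-6 months": 0.618, "none": 0.056,
                      "1-3 months": 0.094, "7-13 months": 0.232},
    "daycare_entry": {"none_by_24mo": 0.156, "0-12 months": 0.340,
                      "13-26 months": 0.504},
    "pets": {"yes": 0.278, "no": 0.722},
}

# Rate ratios on the expected two-year episode count (reference levels 1.0).
DEFAULT_RATE_RATIOS: dict[str, dict[str, float]] = {
    "sex": {"female": 1.01},
    "birth_term": {"early_term": 1.10},
    "birth_mode": {"c_section": 0.99},
    "older_siblings": {"1": 1.08, "2+": 1.17},
    "breastfeeding": {"none": 0.90, "1-3 months": 0.78, "7-13 months": 1.00},
    "daycare_entry": {"0-12 months": 1.27, "13-26 months": 1.27},
}

# Daily within-episode emission probability per symptom.  Runny/blocked nose
# dominates, cough (either form) is next, chills are nearly absent —
# matching the rank order and rough per-child day totals of diary cohorts.
DEFAULT_SYMPTOM_PROBS: dict[str, float] = {
    "fever": 0.09,
    "wheezing": 0.075,
    "wet_cough": 0.30,
    "dry_cough": 0.28,
    "chills": 0.003,
    "sore_throat": 0.021,
    "runny_or_blocked_nose": 0.83,
    "increased_need_to_sleep": 0.155,
    "loss_of_appetite": 0.15,
    "increased_attachment": 0.27,
}

# Age multiplier knots (day of life, relative hazard): a convex ramp over
# the first half year, a broad peak in the second year.
DEFAULT_AGE_KNOTS: tuple[tuple[int, float], ...] = (
    (0, 0.05), (91, 0.45), (182, 1.05), (456, 1.17), (729, 1.05),
)


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fully determines the output."""

    n_children: int = 288
    seed: int = 0
    covariate_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_PROBS.items()})
    rate_ratios: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_RATE_RATIOS.items()})
    #: target cohort mean two-year episode count (calibrates the hazard)
    mean_episodes: float = 13.7
    #: explicit per-day baseline onset hazard; overrides calibration if set
    baseline_hazard: float | None = None
    age_knots: tuple[tuple[int, float], ...] = DEFAULT_AGE_KNOTS
    seasonal_amplitude: float = 0.3
    seasonal_peak_month: int = 1
    #: optional per-month multiplier table {1..12: mult}; overrides sinusoid
    season_table: dict[int, float] | None = None
    duration_mean_days: float = 11.0
    duration_sd_days: float = 5.8
    #: probability that an episode opens with an A-symptom day (else B-pair)
    p_a_trigger: float = 0.6
    symptom_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SYMPTOM_PROBS))
    #: probability of a recorded doctor diagnosis on an A-triggered first day
    dx_prob: float = 0.01
    #: daily rate of isolated single-B-symptom days outside episodes
    orphan_rate: float = 0.01
    #: daily probability that a diary entry is missing
    missing_rate: float = 0.01
    birth_year: int = 2015
    window: ObservationWindow = field(default_factory=ObservationWindow)

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def validate(self) -> None:
        for name, probs in self.covariate_probs.items():
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ValueError(f"covariate_probs[{name!r}] must sum to 1")
        for p in (self.p_a_trigger, self.orphan_rate, self.missing_rate, self.dx_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.missing_rate > 0.02 + 1e-12:
            raise ValueError("missing_rate above the 2% design cap")
        if self.duration_mean_days < 1:
            raise ValueError("duration_mean_days must be >= 1")

    @property
    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of the lognormal duration with the configured moments."""
        m, s = self.duration_mean_days, self.duration_sd_days
        sigma2 = math.log(1.0 + (s / m) ** 2)
        return math.log(m) - sigma2 / 2.0, math.sqrt(sigma2)


def age_multiplier(config: SimulationConfig) -> np.ndarray:
    """Per-day age multiplier over the window, normalised to mean 1."""
    days = np.arange(config.window.start_day, config.window.end_day + 1)
    xs = [k[0] for k in config.age_knots]
    ys = [k[1] for k in config.age_knots]
    a = np.interp(days, xs, ys)
    return a / a.mean()


def season_multiplier(config: SimulationConfig) -> np.ndarray:
    """Month multipliers (index 0 = January), normalised to mean 1."""
    if config.season_table is not None:
        s = np.array([config.season_table.get(m, 1.0) for m in range(1, 13)])
    else:
        months = np.arange(1, 13)
        s = 1.0 + config.seasonal_amplitude * np.cos(
            2 * np.pi * (months - config.seasonal_peak_month) / 12.0)
    if (s < 0).any():
        raise ValueError("seasonal multipliers must be non-negative")
    return s / s.mean()


def _relative_rates(covariates: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    rel = np.ones(len(covariates))
    for name, ratios in config.rate_ratios.items():
        rel *= covariates[name].map(lambda lev: ratios.get(lev, 1.0)).to_numpy(float)
    return rel


def simulate_covariates(config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw independent covariates for each child from the configured margins.

    Birth dates are uniform over the configured calendar year so that age
    and season effects are separable in expectation.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_children
    width = max(4, len(str(n)))
    child_ids = [f"C{i:0{width}d}" for i in range(1, n + 1)]
    cov = pd.DataFrame({"child_id": child_ids})
    year_start = pd.Timestamp(f"{config.birth_year}-01-01")
    offsets = rng.integers(0, 365, size=n)
    cov["birth_date"] = [year_start + pd.Timedelta(days=int(o)) for o in offsets]
    for name, probs in config.covariate_probs.items():
        levels = list(probs)
        p = np.array([probs[lev] for lev in levels], dtype=float)
        cov[name] = rng.choice(levels, size=n, p=p / p.sum())
    cov["birth_weight_g"] = np.clip(
        rng.normal(3400.0, 488.0, size=n), 500, 6000).round().astype(int)
    cov = cov[["child_id", "birth_date", "sex", "birth_term", "birth_mode",
               "birth_weight_g", "older_siblings", "breastfeeding",
               "daycare_entry", "pets"]]
    return cov.set_index("child_id", drop=False)


def _emit_episode(L: int, trigger: str, probs: np.ndarray, b_probs: np.ndarray,
                  a_probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """(L, n_symptoms) presence matrix for one episode honouring the start rule."""
    n_sym = len(SYMPTOM_COLUMNS)
    mat = rng.random((L, n_sym)) < probs
    n_a = len(A_SYMPTOMS)
    if trigger == TRIGGER_A:
        if not mat[0, :n_a].any():
            mat[0, rng.choice(n_a, p=a_probs)] = True
    else:
        mat[0, :n_a] = False  # a B-pair start must carry no A-symptom
        while mat[0, n_a:].sum() < 2:
            mat[0, n_a + rng.choice(len(B_SYMPTOMS), p=b_probs)] = True
    # every episode day is symptomatic
    empty = ~mat.any(axis=1)
    if empty.any():
        idx = np.flatnonzero(empty)
        mat[idx, rng.choice(n_sym, size=len(idx), p=probs / probs.sum())] = True
    return mat


def simulate_diaries(covariates: pd.DataFrame, config: SimulationConfig,
                     rng: np.random.Generator | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate daily diaries and export the latent episode ground truth.

    Returns ``(diary, truth_episodes)``: the diary has one row per
    *observed* child-day (missing days are absent rows) with severity-coded
    symptom columns; the truth table uses the same schema as the
    segmentation output.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 1)
    window = config.window
    n_days = window.n_days
    T = float(n_days)

    rel = _relative_rates(covariates, config)
    if config.baseline_hazard is not None:
        hazards = config.baseline_hazard * rel
    else:
        lam0 = config.mean_episodes / rel.mean()
        target = lam0 * rel  # expected two-year count per child
        dbar = config.duration_mean_days + 3.0
        denom = np.maximum(T - target * dbar, 1.0)
        hazards = target / denom

    a_arr = age_multiplier(config)
    s_arr = season_multiplier(config)
    mu, sigma = config.lognormal_params
    probs = np.array([config.symptom_probs[s] for s in SYMPTOM_COLUMNS])
    n_a = len(A_SYMPTOMS)
    a_probs = probs[:n_a] / probs[:n_a].sum()
    b_probs = probs[n_a:] / probs[n_a:].sum()

    sym_blocks: list[np.ndarray] = []
    dx_blocks: list[np.ndarray] = []
    truth_rows: list[tuple] = []
    sev_choices = np.array([1, 2, 3], dtype=np.int8)
    sev_p = np.array([0.6, 0.3, 0.1])

    for i, (cid, birth) in enumerate(zip(covariates["child_id"], covariates["birth_date"])):
        months = pd.date_range(birth + pd.Timedelta(days=window.start_day),
                               periods=n_days).month.to_numpy()
        p_day = np.minimum(1.0, hazards[i] * a_arr * s_arr[months - 1])
        u = rng.random(n_days)
        sym = np.zeros((n_days, len(SYMPTOM_COLUMNS)), dtype=np.int8)
        dx = np.zeros((n_days, 2), dtype=np.int8)
        blocked = np.zeros(n_days, dtype=bool)  # episode days + refractory tail

        d = 0
        while d < n_days:
            if u[d] < p_day[d]:
                dur = max(1, int(round(rng.lognormal(mu, sigma))))
                end = min(d + dur - 1, n_days - 1)
                L = end - d + 1
                trigger = TRIGGER_A if rng.random() < config.p_a_trigger else TRIGGER_B
                present = _emit_episode(L, trigger, probs, b_probs, a_probs, rng)
                sev = rng.choice(sev_choices, size=present.shape, p=sev_p)
                sym[d:end + 1] = present * sev
                if trigger == TRIGGER_A and rng.random() < config.dx_prob:
                    dx[d, rng.integers(0, 2)] = 1
                censored = (n_days - 1 - end) < 3
                truth_rows.append((cid, window.start_day + d, window.start_day + end,
                                   L, trigger, censored, L))
                blocked[d:min(end + 4, n_days)] = True
                d = end + 4  # guaranteed >= 3 symptom-free days
            else:
                d += 1

        if config.orphan_rate > 0:
            eligible = ~blocked
            orphan_mask = eligible & (rng.random(n_days) < config.orphan_rate)
            for od in np.flatnonzero(orphan_mask):
                b_idx = n_a + rng.choice(len(B_SYMPTOMS), p=b_probs)
                sym[od, b_idx] = rng.choice(sev_choices, p=sev_p)

        sym_blocks.append(sym)
        dx_blocks.append(dx)

    n = len(covariates)
    sym_all = np.concatenate(sym_blocks)
    dx_all = np.concatenate(dx_blocks)
    day_of_life = np.tile(np.arange(window.start_day, window.end_day + 1), n)
    child_rep = np.repeat(covariates["child_id"].to_numpy(), n_days)
    births = np.repeat(covariates["birth_date"].to_numpy().astype("datetime64[D]"), n_days)
    dates = births + day_of_life.astype("timedelta64[D]")

    diary = pd.DataFrame({"child_id": child_rep, "date": pd.to_datetime(dates)})
    for j, col in enumerate(SYMPTOM_COLUMNS):
        diary[col] = sym_all[:, j]
    for j, col in enumerate(DIAGNOSIS_COLUMNS):
        diary[col] = dx_all[:, j]
    diary["day_of_life"] = day_of_life

    if config.missing_rate > 0:
        present = rng.random(len(diary)) >= config.missing_rate
        diary = diary.loc[present].reset_index(drop=True)

    truth = pd.DataFrame(truth_rows, columns=list(EPISODE_COLUMNS))
    truth = truth.astype({"start_day": int, "last_symptom_day": int,
                          "duration_days": int, "censored": bool,
                          "n_symptom_days": int})
    return diary[list(DIARY_COLUMNS) + ["day_of_life"]], truth


def simulate_cohort(config: SimulationConfig,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Covariates, diary and latent truth from one root seed."""
    rng = np.random.default_rng(config.seed)
    covariates = simulate_covariates(config, rng)
    diary, truth = simulate_diaries(covariates, config, rng)
    return covariates, diary, truth
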