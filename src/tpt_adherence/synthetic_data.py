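"""Synthetic matched sub-study generator with known ground-truth adherence.

Emulates a 1:4 weight- and sex-matched case-control sub-study nested in a
TB-preventive-therapy trial: 28 cases each matched with 4 controls,
per-day Bernoulli dose-taking with lower adherence probability in cases,
PK-model-generated plasma concentrations at visits in weeks 2, 4 and 8
(~24 h post-dose), bioanalytical residual error, and left-censoring at
the assay LLOQ.  Every record carries a hidden truth channel (dose-taken
history, true time since last dose, noise-free concentration) so each
downstream stage can be validated without any external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .pk_models import (
    DrugModelSpec,
    IndividualParameters,
    PatientCovariates,
    concentration_history_linear,
    concentration_history_saturable,
    fat_free_mass,
    sample_individual,
)

__all__ = [
    "CohortConfig",
    "assign_dose",
    "generate_cohort",
    "simulate_adherence",
    "simulate_observations",
    "generate_study",
    "design_odds_ratio",
]

# WHO-style 4-band fixed-dose-combination table (bands half-open):
# [30,38) -> 2 tablets, [38,55) -> 3, [55,71) -> 4, [71,inf) -> 5.
DOSE_BANDS = (38.0, 55.0, 71.0)
TABLET_MG = {"rifampicin": 150.0, "pyrazinamide": 400.0}

VISIT_DAY = {2: 14, 4: 28, 8: 56}


@dataclass
class CohortConfig:
    """Study-design knobs of the synthetic sub-study.

    Covariate distributions are anchored on the published participant
    characteristics (median weight 56 kg, range 30-81; heights ~1.63 m
    female / 1.65 m male; 50% male).  Daily adherence probabilities
    default to values that land the pyrazinamide non-adherence
    frequencies near the study's (~20% cases vs ~14% controls at the
    LLOQ); the end-to-end validation scenarios override them.
    """

    n_cases: int = 28
    control_ratio: int = 4
    weight_median: float = 56.0
    weight_log_sd: float = 0.19
    weight_range: tuple[float, float] = (30.0, 81.0)
    height_mean: dict[str, float] = field(
        default_factory=lambda: {"male": 1.65, "female": 1.63}
    )
    height_sd: float = 0.06
    height_range: tuple[float, float] = (1.48, 1.89)
    p_male: float = 0.5
    weight_caliper: float = 5.0
    adherence_p_case: float = 0.70
    adherence_p_control: float = 0.82
    markov_rho: float = 0.0  # 0 = i.i.d. days; >0 = streaky (persistent) behaviour
    visit_weeks: tuple[int, ...] = (2, 4, 8)
    n_days: int = 70
    jitter_sd_h: float = 2.0
    jitter_limit_h: float = 6.0
    prop_error_cv: float = 0.20
    add_error_sd: float = 0.02
    lloq: dict[str, float] = field(
        default_factory=lambda: {"pyrazinamide": 0.203, "rifampicin": 0.075}
    )
    late_week8_fraction: float = 29.0 / 140.0
    late_week8_days: tuple[int, int] = (57, 64)
    missing_case_sample_p: float = 5.0 / 84.0
    report_missed_prob: float = 0.15
    induction_day: float = 14.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_male", "adherence_p_case", "adherence_p_control",
            "late_week8_fraction", "missing_case_sample_p", "report_missed_prob",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability, got {value}")
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        if self.control_ratio < 1:
            raise ValueError("control_ratio must be >= 1")


def assign_dose(weight: float) -> dict[str, float]:
    """Daily fixed-dose-combination doses (mg) from the weight-band table."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    if weight < 30.0:
        warnings.warn(
            f"weight {weight} kg below the lowest band; using 2 tablets",
            stacklevel=2,
        )
    tablets = 2 + int(np.searchsorted(DOSE_BANDS, weight, side="right"))
    return {drug: tablets * mg for drug, mg in TABLET_MG.items()}


def _truncated_lognormal(
    rng: np.random.Generator, median: float, log_sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    mu = np.log(median)
    a = (np.log(lo) - mu) / log_sd
    b = (np.log(hi) - mu) / log_sd
    return np.exp(truncnorm.rvs(a, b, loc=mu, scale=log_sd, size=size, random_state=rng))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(cfg: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Participants with 1:m matched sets (exact sex, +/-5 kg weight caliper).

    Control weights are drawn from the population weight distribution
    conditioned on the case's caliper window, i.e. matching is built into
    the generative process.  If a caliper window is empty it is widened
    with a warning (cannot occur while case weights respect the population
    range).  Deterministic given the config seed.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    lo, hi = cfg.weight_range
    rows = []
    case_weights = _truncated_lognormal(
        rng, cfg.weight_median, cfg.weight_log_sd, lo, hi, cfg.n_cases
    )
    case_sexes = np.where(rng.random(cfg.n_cases) < cfg.p_male, "male", "female")
    pid = 0
    for s in range(cfg.n_cases):
        set_id = f"S{s + 1:03d}"
        members = [("case", case_weights[s], case_sexes[s])]
        caliper = cfg.weight_caliper
        for _ in range(cfg.control_ratio):
            w_lo, w_hi = max(lo, case_weights[s] - caliper), min(hi, case_weights[s] + caliper)
            if w_lo >= w_hi:
                caliper *= 2.0
                warnings.warn(
                    f"empty caliper window for set {set_id}; widening to {caliper} kg",
                    stacklevel=2,
                )
                w_lo, w_hi = max(lo, case_weights[s] - caliper), min(hi, case_weights[s] + caliper)
            w = _truncated_lognormal(rng, cfg.weight_median, cfg.weight_log_sd, w_lo, w_hi, 1)[0]
            members.append(("control", w, case_sexes[s]))
        for group, weight, sex in members:
            pid += 1
            height = _truncated_normal(
                rng, cfg.height_mean[sex], cfg.height_sd, *cfg.height_range, size=1
            )[0]
            cov = PatientCovariates(weight=weight, height=height, sex=sex)
            doses = assign_dose(weight)
            rows.append(
                {
                    "participant_id": f"P{pid:03d}",
                    "set_id": set_id,
                    "group": group,
                    "sex": sex,
                    "weight_kg": weight,
                    "height_m": height,
                    "ffm_kg": fat_free_mass(cov),
                    "dose_pyrazinamide_mg": doses["pyrazinamide"],
                    "dose_rifampicin_mg": doses["rifampicin"],
                }
            )
    columns = [
        "participant_id", "set_id", "group", "sex", "weight_kg", "height_m",
        "ffm_kg", "dose_pyrazinamide_mg", "dose_rifampicin_mg",
    ]
    return pd.DataFrame(rows, columns=columns)


def simulate_adherence(
    cfg: CohortConfig, participants: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Boolean dose-taken matrix (n_participants, n_days).

    Default behaviour: independent Bernoulli per day with the
    group-specific probability.  With ``markov_rho`` > 0 the chain is
    persistent with the same stationary probability:
    P(take | took) = p + rho (1-p), P(take | missed) = p (1 - rho).
    """
    p = np.where(
        participants["group"].to_numpy() == "case",
        cfg.adherence_p_case,
        cfg.adherence_p_control,
    )
    n, d = len(p), cfg.n_days
    u = rng.random((n, d))
    if cfg.markov_rho <= 0:
        return u < p[:, None]
    taken = np.zeros((n, d), dtype=bool)
    taken[:, 0] = u[:, 0] < p
    for t in range(1, d):
        p_cond = np.where(
            taken[:, t - 1], p + cfg.markov_rho * (1 - p), p * (1 - cfg.markov_rho)
        )
        taken[:, t] = u[:, t] < p_cond
    return taken


def design_odds_ratio(cfg: CohortConfig) -> float:
    """Odds ratio of missing the pre-visit dose implied by the daily probabilities.

    Degenerate designs (a group that never or always misses) return
    ``nan``/``inf`` as appropriate rather than raising.
    """
    q_case = 1.0 - cfg.adherence_p_case
    q_ctrl = 1.0 - cfg.adherence_p_control
    with np.errstate(divide="ignore", invalid="ignore"):
        odds_case = np.divide(q_case, 1.0 - q_case)
        odds_ctrl = np.divide(q_ctrl, 1.0 - q_ctrl)
        return float(np.divide(odds_case, odds_ctrl))


def _draw_visit_days(
    cfg: CohortConfig, n: int, rng: np.random.Generator
) -> dict[int, np.ndarray]:
    days = {}
    for week in cfg.visit_weeks:
        base = np.full(n, VISIT_DAY[week])
        if week == 8 and cfg.late_week8_fraction > 0:
            late = rng.random(n) < cfg.late_week8_fraction
            lo, hi = cfg.late_week8_days
            base = np.where(late, rng.integers(lo, hi + 1, size=n), base)
        days[week] = base
    return days


def simulate_observations(
    cfg: CohortConfig,
    participants: pd.DataFrame,
    taken: np.ndarray,
    specs: dict[str, DrugModelSpec],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed concentration records plus the per-record truth channel.

    Each participant's true PK parameters are drawn once per drug (shared
    across visits).  The visit sample is taken at ``24*(visit day) +
    jitter`` hours; its concentration superposes the doses actually taken
    (full multi-dose integration for the saturable drug, with induction
    switching on at ``induction_day``).  Residual error is applied, values
    below the LLOQ are flagged BLQ and masked, and a fraction of case
    samples goes missing.
    """
    n = len(participants)
    is_case = participants["group"].to_numpy() == "case"
    visit_days = _draw_visit_days(cfg, n, rng)
    jitter = {
        week: np.clip(
            rng.normal(0.0, cfg.jitter_sd_h, size=n),
            -cfg.jitter_limit_h,
            cfg.jitter_limit_h,
        )
        for week in cfg.visit_weeks
    }
    missing = {
        week: is_case & (rng.random(n) < cfg.missing_case_sample_p)
        for week in cfg.visit_weeks
    }
    reported = {
        week: rng.random(n) < cfg.report_missed_prob for week in cfg.visit_weeks
    }

    obs_rows, truth_rows = [], []
    for drug, spec in specs.items():
        dose = participants[f"dose_{drug}_mg"].to_numpy(dtype=float)
        ffm = participants["ffm_kg"].to_numpy(dtype=float)
        ind = sample_individual(spec, ffm, rng, n=n)
        # Noise-free concentration at every (participant, week) sample time.
        requests, meta = [], []
        for week in cfg.visit_weeks:
            for i in range(n):
                day = int(visit_days[week][i])
                taken_before = np.flatnonzero(taken[i, :day])
                t_sample = 24.0 * day + jitter[week][i]
                last = taken_before.max() if taken_before.size else None
                t_since = t_sample - 24.0 * last if last is not None else np.nan
                requests.append((i, t_sample))
                meta.append((week, i, day, t_since))
        # The visit sample precedes that day's dose (samples are ~24 h after
        # the previous day's dose), so only doses on earlier days contribute.
        if spec.elimination == "first-order":
            conc_true = np.zeros(len(requests))
            for r, ((i, t_sample), (week, _, day, _)) in enumerate(zip(requests, meta)):
                ind_i = IndividualParameters(
                    elimination=ind.elimination,
                    clearance=ind.clearance[i],
                    volume=ind.volume[i],
                    ka=ind.ka[i],
                    mtt=ind.mtt[i],
                    bioavailability=ind.bioavailability[i],
                    n_transit=ind.n_transit,
                )
                dose_times = 24.0 * np.flatnonzero(taken[i, :day])
                conc_true[r] = concentration_history_linear(
                    ind_i, dose[i], dose_times, [t_sample]
                )[0]
        else:
            conc_true = concentration_history_saturable(
                ind,
                dose,
                taken,
                requests,
                sample_days=[day for (_, _, day, _) in meta],
                induction_day=cfg.induction_day,
            )
        noise = conc_true * (1.0 + rng.normal(0.0, cfg.prop_error_cv, len(requests)))
        conc_obs = np.maximum(noise + rng.normal(0.0, cfg.add_error_sd, len(requests)), 0.0)
        lloq = cfg.lloq[drug]
        for r, (week, i, day, t_since) in enumerate(meta):
            pid = participants["participant_id"].iloc[i]
            if missing[week][i]:
                continue
            blq = bool(conc_obs[r] < lloq)
            missed_yesterday = not taken[i, day - 1]
            obs_rows.append(
                {
                    "participant_id": pid,
                    "drug": drug,
                    "week": week,
                    "visit_day": day,
                    "concentration_mg_L": np.nan if blq else conc_obs[r],
                    "blq": blq,
                    "reported_missed_yesterday": bool(
                        missed_yesterday and reported[week][i]
                    ),
                }
            )
            truth_rows.append(
                {
                    "participant_id": pid,
                    "drug": drug,
                    "week": week,
                    "visit_day": day,
                    "time_since_last_dose_h": t_since,
                    "true_concentration_mg_L": conc_true[r],
                    "missed_yesterday": bool(missed_yesterday),
                }
            )
    observations = pd.DataFrame(
        obs_rows,
        columns=[
            "participant_id", "drug", "week", "visit_day",
            "concentration_mg_L", "blq", "reported_missed_yesterday",
        ],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "participant_id", "drug", "week", "visit_day",
            "time_since_last_dose_h", "true_concentration_mg_L", "missed_yesterday",
        ],
    )
    return observations, truth


def generate_study(
    cfg: CohortConfig,
    specs: dict[str, DrugModelSpec],
    seed: int | None = None,
) -> dict[str, object]:
    """Full synthetic sub-study: participants, observations, truth channel.

    Returns a dict with keys ``participants``, ``observations``, ``truth``,
    ``history`` (long dose-taken table) and ``design_odds_ratio``.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    participants = generate_cohort(cfg, rng)
    taken = simulate_adherence(cfg, participants, rng)
    observations, truth = simulate_observations(cfg, participants, taken, specs, rng)
    history = pd.DataFrame(
        {
            "participant_id": np.repeat(
                participants["participant_id"].to_numpy(), cfg.n_days
            ),
            "day": np.tile(np.arange(cfg.n_days), len(participants)),
            "taken": taken.ravel(),
        }
    )
    return {
        "participants": participants,
        "observations": observations,
        "truth": truth,
        "history": history,
        "design_odds_ratio": design_odds_ratio(cfg),
    }
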