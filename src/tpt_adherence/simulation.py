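"""Monte-Carlo personalised non-adherence thresholds.

For each participant, visit and drug, ``n_sim`` virtual individuals are
drawn from the population model sharing the participant's fat-free mass
and dose.  Their steady-state concentrations at 24 h and 48 h after the
last dose — assuming perfect adherence and, for rifampicin, full
autoinduction — form a personalised reference distribution; its 2.5th and
5th percentiles are the thresholds below which an observed concentration
flags non-adherence.  A threshold below the assay LLOQ is uninformative:
even a fully adherent participant would then be expected to measure BLQ,
so such cells are excluded from classification.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

from .pk_models import (
    DosingRegimen,
    DrugModelSpec,
    PatientCovariates,
    concentration_linear,
    concentration_saturable,
    fat_free_mass,
    sample_individual,
)

__all__ = [
    "empirical_percentile",
    "simulate_thresholds",
    "informativeness",
    "cohort_thresholds",
    "threshold_stream_seed",
    "threshold_calibration",
]

DEFAULT_N_SIM = 500
DEFAULT_TIMES = (24.0, 48.0)
DEFAULT_PERCENTILES = (2.5, 5.0)

_DRUG_CODES = {"pyrazinamide": 1, "rifampicin": 2}


def empirical_percentile(values: Iterable[float], p: float) -> float:
    """p-th percentile with linear interpolation between order statistics.

    The interpolated rank is ``1 + (p/100) * (n - 1)``; p = 0 and p = 100
    return the minimum and maximum.
    """
    values = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, float)
    if values.size == 0:
        raise ValueError("cannot take a percentile of an empty sample")
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percentile must be in [0, 100], got {p}")
    return float(np.percentile(values, p, method="linear"))


def threshold_stream_seed(master_seed: int, participant_id: str, drug: str, week: int) -> np.random.SeedSequence:
    """Deterministic per-(participant, drug, week) random stream.

    Keyed on the identifiers, not the processing order, so per-participant
    thresholds are reproducible in isolation.
    """
    pid_key = int.from_bytes(str(participant_id).encode(), "little") % (2**31)
    drug_key = _DRUG_CODES.get(drug, sum(drug.encode()) % 997)
    return np.random.SeedSequence([int(master_seed), pid_key, drug_key, int(week)])


def _simulate_concentrations(
    spec: DrugModelSpec,
    ffm: float,
    regimen: DosingRegimen,
    times: np.ndarray,
    n_sim: int,
    rng: np.random.Generator,
    residual_error: tuple[float, float] | None = None,
) -> np.ndarray:
    ind = sample_individual(spec, ffm, rng, n=n_sim)
    if spec.elimination == "first-order":
        conc = concentration_linear(ind, regimen, times)
    else:
        conc = concentration_saturable(ind, regimen, times, induced=True)
    if residual_error is not None:
        prop_cv, add_sd = residual_error
        noise = conc * (1.0 + rng.normal(0.0, prop_cv, conc.shape))
        conc = np.maximum(noise + rng.normal(0.0, add_sd, conc.shape), 0.0)
    return conc


def simulate_thresholds(
    cov: PatientCovariates,
    spec: DrugModelSpec,
    regimen: DosingRegimen,
    visit_week: int,
    n_sim: int = DEFAULT_N_SIM,
    times: Iterable[float] = DEFAULT_TIMES,
    percentiles: Iterable[float] = DEFAULT_PERCENTILES,
    seed: int | np.random.SeedSequence = 0,
    participant_id: str = "",
    lloq: float | None = None,
    residual_error: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Personalised thresholds for one participant, drug and visit.

    Returns a tidy frame with one row per (time after dose, percentile):
    columns ``participant_id, drug, week, time_h, percentile,
    threshold_mg_L, informative, n_sim, seed``.  ``informative`` is filled
    only when ``lloq`` is given.  Deterministic for a given seed.
    """
    import warnings

    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if n_sim < 40:
        warnings.warn(
            f"n_sim={n_sim} is too small for a stable 2.5th percentile",
            stacklevel=2,
        )
    percentiles = sorted(float(p) for p in percentiles)
    for p in percentiles:
        if not 0.0 <= p <= 100.0:
            raise ValueError(f"invalid percentile {p}")
    times = np.asarray(sorted(float(t) for t in times))
    if isinstance(seed, np.random.SeedSequence):
        seed_seq, seed_label = seed, seed.entropy
    else:
        seed_seq, seed_label = np.random.SeedSequence(int(seed)), int(seed)
    rng = np.random.default_rng(seed_seq)
    ffm = fat_free_mass(cov)
    conc = _simulate_concentrations(
        spec, ffm, regimen, times, n_sim, rng, residual_error
    )
    rows = []
    for j, t in enumerate(times):
        for p in percentiles:
            thr = empirical_percentile(conc[:, j], p)
            rows.append(
                {
                    "participant_id": participant_id,
                    "drug": spec.drug,
                    "week": int(visit_week),
                    "time_h": float(t),
                    "percentile": p,
                    "threshold_mg_L": thr,
                    "informative": informativeness(thr, lloq) if lloq is not None else pd.NA,
                    "n_sim": int(n_sim),
                    "seed": str(seed_label),
                }
            )
    return pd.DataFrame(rows)


def informativeness(threshold: float, lloq: float) -> bool:
    """A threshold is informative iff it is at or above the assay LLOQ.

    Below the LLOQ the expected concentration of even a fully adherent
    participant is unquantifiable, so a BLQ measurement carries no
    adherence information at that drug/timepoint.
    """
    if lloq <= 0:
        raise ValueError("lloq must be positive")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return bool(threshold >= lloq)


def cohort_thresholds(
    participants: pd.DataFrame,
    specs: dict[str, DrugModelSpec],
    lloq: dict[str, float],
    weeks: Iterable[int] = (2, 4, 8),
    n_sim: int = DEFAULT_N_SIM,
    times: Iterable[float] = DEFAULT_TIMES,
    percentiles: Iterable[float] = DEFAULT_PERCENTILES,
    master_seed: int = 0,
    residual_error: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Thresholds for every participant x drug x week in a cohort table.

    ``participants`` needs columns ``participant_id, sex, weight_kg,
    height_m`` and per-drug dose columns ``dose_<drug>_mg``.  Each cell
    uses an independent seed stream derived from ``master_seed`` and the
    cell identifiers.
    """
    from .pk_models import IndividualParameters

    times = np.asarray(sorted(float(t) for t in times))
    percentiles = sorted(float(p) for p in percentiles)
    weeks = list(weeks)
    rows = []
    for drug, spec in specs.items():
        dose_col = f"dose_{drug}_mg"
        # One BSV sample per (participant, week) cell from its own stream,
        # then a single batched concentration evaluation for the drug.
        cells, inds, rngs = [], [], []
        for row in participants.itertuples(index=False):
            cov = PatientCovariates(
                weight=row.weight_kg, height=row.height_m, sex=row.sex
            )
            ffm = fat_free_mass(cov)
            for week in weeks:
                seed_seq = threshold_stream_seed(
                    master_seed, row.participant_id, drug, week
                )
                rng = np.random.default_rng(seed_seq)
                inds.append(sample_individual(spec, ffm, rng, n=n_sim))
                rngs.append(rng)
                cells.append((row.participant_id, week, float(getattr(row, dose_col))))
        if not cells:
            continue
        batch = IndividualParameters(
            elimination=spec.elimination,
            clearance=np.concatenate([i.clearance for i in inds]),
            volume=np.concatenate([i.volume for i in inds]),
            ka=np.concatenate([i.ka for i in inds]),
            mtt=np.concatenate([i.mtt for i in inds]),
            bioavailability=np.concatenate([i.bioavailability for i in inds]),
            n_transit=spec.n_transit,
            km=spec.km,
            induction_fold=spec.induction_fold,
        )
        dose = np.repeat([dose for _, _, dose in cells], n_sim)
        regimen = DosingRegimen(dose_amount=dose)
        if spec.elimination == "first-order":
            conc = concentration_linear(batch, regimen, times)
        else:
            conc = concentration_saturable(batch, regimen, times, induced=True)
        conc = conc.reshape(len(cells), n_sim, times.size)
        if residual_error is not None:
            prop_cv, add_sd = residual_error
            for c, rng in enumerate(rngs):
                noise = conc[c] * (1.0 + rng.normal(0.0, prop_cv, conc[c].shape))
                conc[c] = np.maximum(
                    noise + rng.normal(0.0, add_sd, conc[c].shape), 0.0
                )
        drug_lloq = lloq.get(drug)
        for c, (pid, week, _) in enumerate(cells):
            for j, t in enumerate(times):
                for p in percentiles:
                    thr = empirical_percentile(conc[c, :, j], p)
                    rows.append(
                        {
                            "participant_id": pid,
                            "drug": drug,
                            "week": int(week),
                            "time_h": float(t),
                            "percentile": p,
                            "threshold_mg_L": thr,
                            "informative": informativeness(thr, drug_lloq)
                            if drug_lloq is not None
                            else pd.NA,
                            "n_sim": int(n_sim),
                            "seed": str(master_seed),
                        }
                    )
    columns = [
        "participant_id", "drug", "week", "time_h", "percentile",
        "threshold_mg_L", "informative", "n_sim", "seed",
    ]
    return pd.DataFrame(rows, columns=columns)


def threshold_calibration(
    spec: DrugModelSpec,
    n_participants: int = 10_000,
    n_sim: int = DEFAULT_N_SIM,
    percentile: float = 2.5,
    time_h: float = 24.0,
    seed: int = 0,
    chunk: int = 500,
) -> dict[str, float]:
    """False-flag rate of a personalised threshold among adherent patients.

    Draws virtual participants from the synthetic cohort's covariate
    distributions, gives each a personalised ``percentile`` threshold from
    ``n_sim`` model draws at its own fat-free mass and dose, then draws one
    more steady-state concentration from the same model (perfect adherence,
    no residual error) as that participant's "observation".  Returns the
    percentage of observations falling below their own threshold; for a
    well-calibrated p-th percentile threshold this converges to ~p%.

    Only first-order drugs are supported (the experiment targets the drug
    and timepoint that survive the informativeness rule).
    """
    from .synthetic_data import CohortConfig, _truncated_lognormal, assign_dose

    if spec.elimination != "first-order":
        raise ValueError("calibration experiment requires a first-order drug model")
    cfg = CohortConfig()
    rng = np.random.default_rng(seed)
    times = np.array([float(time_h)])
    below = 0
    for start in range(0, n_participants, chunk):
        m = min(chunk, n_participants - start)
        weights = _truncated_lognormal(
            rng, cfg.weight_median, cfg.weight_log_sd, *cfg.weight_range, size=m
        )
        sexes = np.where(rng.random(m) < cfg.p_male, "male", "female")
        heights = np.array(
            [
                rng.normal(cfg.height_mean[s], cfg.height_sd)
                for s in sexes
            ]
        ).clip(*cfg.height_range)
        ffm = np.array(
            [
                fat_free_mass(PatientCovariates(w, h, s))
                for w, h, s in zip(weights, heights, sexes)
            ]
        )
        doses = np.array([assign_dose(w)[spec.drug] for w in weights])
        draws = n_sim + 1
        ind = sample_individual(spec, np.repeat(ffm, draws), rng, n=m * draws)
        regimen = DosingRegimen(dose_amount=np.repeat(doses, draws))
        conc = concentration_linear(ind, regimen, times).reshape(m, draws)
        thresholds = np.percentile(conc[:, :n_sim], percentile, axis=1, method="linear")
        below += int(np.sum(conc[:, n_sim] < thresholds))
    return {
        "percent_below": 100.0 * below / n_participants,
        "n": n_participants,
        "percentile": percentile,
    }
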