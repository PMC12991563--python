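"""Concentration-based non-adherence classification and frequency tables.

Two thresholding rules are supported, applied per drug and visit:

* ``lloq`` — non-adherent iff the observed concentration is at or below
  the assay lower limit of quantification (BLQ records count as below).
* ``personalised`` — non-adherent iff the observation falls strictly
  below the participant's simulated 2.5th or 5th percentile threshold.

A concentration above a threshold never *confirms* adherence — it only
fails to rule it out — hence the complementary status is
``not-confirmed`` rather than ``adherent``.  Personalised classification
is refused at uninformative drug/timepoints (threshold below LLOQ).
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "classify_lloq",
    "classify_personalised",
    "classify_records",
    "tabulate",
    "pool_frequency_table",
    "sensitivity_filter",
    "UninformativeTimepointError",
]

NON_ADHERENT = "non-adherent"
NOT_CONFIRMED = "not-confirmed"


class UninformativeTimepointError(ValueError):
    """Raised when classifying against a threshold below the assay LLOQ."""


def _check_concentration(concentration: float | None, blq: bool) -> None:
    if not blq and (concentration is None or np.isnan(concentration)):
        raise ValueError("non-BLQ record must carry a concentration")
    if not blq and concentration < 0:
        raise ValueError(f"negative concentration {concentration}")


def classify_lloq(concentration: float | None, blq: bool, lloq: float) -> str:
    """LLOQ rule: non-adherent iff BLQ or concentration <= LLOQ (inclusive)."""
    if lloq <= 0:
        raise ValueError("lloq must be positive")
    _check_concentration(concentration, blq)
    if blq or concentration <= lloq:
        return NON_ADHERENT
    return NOT_CONFIRMED


def classify_personalised(
    concentration: float | None,
    blq: bool,
    threshold: float,
    informative: bool,
    lloq: float,
) -> str:
    """Personalised rule: non-adherent iff strictly below the threshold.

    BLQ records are below the LLOQ and an informative threshold is at or
    above the LLOQ, so they are always non-adherent here.  Classification
    at an uninformative timepoint is refused.
    """
    if not informative:
        raise UninformativeTimepointError(
            "uninformative timepoint: threshold below LLOQ; even full "
            "adherence is expected to measure BLQ"
        )
    _check_concentration(concentration, blq)
    if blq or concentration < threshold:
        return NON_ADHERENT
    return NOT_CONFIRMED


def classify_records(
    records: pd.DataFrame,
    lloq: dict[str, float],
    thresholds: pd.DataFrame | None = None,
    time_h: float = 24.0,
) -> pd.DataFrame:
    """Apply the LLOQ rule and, where informative, the personalised rules.

    ``records`` columns: participant_id, drug, week, concentration_mg_L,
    blq.  ``thresholds`` is the tidy output of
    :func:`tpt_adherence.simulation.cohort_thresholds`; only cells flagged
    informative produce personalised calls.  Samples are assumed to be
    ``time_h`` (default 24 h) after the last dose.  Returns one row per
    record x method with columns participant_id, drug, week, method,
    status.
    """
    calls = []
    for row in records.itertuples(index=False):
        drug_lloq = lloq[row.drug]
        conc = row.concentration_mg_L
        blq = bool(row.blq)
        calls.append(
            {
                "participant_id": row.participant_id,
                "drug": row.drug,
                "week": int(row.week),
                "method": "lloq",
                "status": classify_lloq(conc, blq, drug_lloq),
            }
        )
    calls = pd.DataFrame(calls)
    if thresholds is None:
        return calls

    informative = thresholds[
        (thresholds["time_h"] == time_h) & thresholds["informative"].astype(bool)
    ]
    keyed = informative.set_index(["participant_id", "drug", "week", "percentile"])[
        "threshold_mg_L"
    ]
    pers = []
    for row in records.itertuples(index=False):
        for p in sorted(informative["percentile"].unique()):
            key = (row.participant_id, row.drug, int(row.week), p)
            if key not in keyed.index:
                continue
            status = classify_personalised(
                row.concentration_mg_L,
                bool(row.blq),
                keyed.loc[key],
                True,
                lloq[row.drug],
            )
            pers.append(
                {
                    "participant_id": row.participant_id,
                    "drug": row.drug,
                    "week": int(row.week),
                    "method": f"personalised-{p:g}",
                    "status": status,
                }
            )
    return pd.concat([calls, pd.DataFrame(pers)], ignore_index=True)


def tabulate(calls: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    """Frequency table of non-adherence by group x week x drug x method.

    Adds an ``overall`` row per group/drug/method pooling the visits; the
    printed percentage is rounded to whole percent.  Empty input yields an
    empty table.
    """
    cols = ["group", "drug", "method", "week", "n_non_adherent", "n_total", "percent"]
    if calls.empty:
        return pd.DataFrame(columns=cols)
    merged = calls.merge(
        participants[["participant_id", "group"]], on="participant_id", how="left"
    )
    grouped = (
        merged.assign(non_adherent=merged["status"] == NON_ADHERENT)
        .groupby(["group", "drug", "method", "week"], as_index=False)
        .agg(n_non_adherent=("non_adherent", "sum"), n_total=("non_adherent", "size"))
    )
    overall = (
        grouped.groupby(["group", "drug", "method"], as_index=False)[
            ["n_non_adherent", "n_total"]
        ]
        .sum()
        .assign(week="overall")
    )
    out = pd.concat([grouped.astype({"week": object}), overall], ignore_index=True)
    out["percent"] = (100.0 * out["n_non_adherent"] / out["n_total"]).round().astype(int)
    return out[cols]


def pool_frequency_table(per_week: pd.DataFrame) -> pd.DataFrame:
    """Pool printed per-week non-adherence counts into overall proportions.

    ``per_week`` columns: label (any grouping key, e.g. "rifampicin cases"),
    week, n_non_adherent, n_total.  Returns one row per label with pooled
    counts and the percentage rounded to whole percent, mirroring how an
    overall row of a published frequency table is formed from its visits.
    """
    pooled = per_week.groupby("label", as_index=False)[["n_non_adherent", "n_total"]].sum()
    pooled["percent"] = (
        100.0 * pooled["n_non_adherent"] / pooled["n_total"]
    ).round().astype(int)
    return pooled


def sensitivity_filter(
    records: pd.DataFrame,
    max_day: int = 56,
    week: int = 8,
) -> pd.DataFrame:
    """Drop week-8 records whose actual visit day exceeds ``max_day``.

    Participants whose final visit slipped past 8 weeks may already have
    stopped pyrazinamide per protocol, making those samples unreliable;
    the sensitivity analysis excludes them.  Requires a ``visit_day``
    column.
    """
    if records.empty:
        return records.copy()
    late = (records["week"] == week) & (records["visit_day"] > max_day)
    return records.loc[~late].reset_index(drop=True)
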