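"""Prescription-to-episode linkage and small-cell suppression.

Each non-excluded episode is linked to at most one dispensation — the first
systemic-antibacterial (ATC J01) dispensation falling in the inclusive
window from the index date to the last visit plus a 5-day follow-up — so
that the linked record reflects empiric therapy. Duration of therapy is the
dispensed days supply verbatim; average daily dose is total dispensed mass
over days supply (for combination products the strength is the amoxicillin
component, a documented convention of the dispensation schema).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import DataError

logger = logging.getLogger(__name__)

SUPPRESSED_DEFAULT = "<6"

LINKED_COLUMNS = [
    "episode_id", "patient_id", "index_date", "end_date", "prescribed",
    "record_id", "agent", "atc_code", "avg_daily_dose_mg", "duration_days",
    "dispense_offset",
]


def average_daily_dose(strength_mg, quantity, days_supply):
    """Average daily dose in mg/day: strength x quantity / days supply.

    Accepts scalars or aligned array-likes; days supply must be positive.
    """
    strength = np.asarray(strength_mg, dtype=float)
    qty = np.asarray(quantity, dtype=float)
    days = np.asarray(days_supply, dtype=float)
    if np.any(days <= 0):
        raise DataError("average_daily_dose: days_supply must be positive")
    out = strength * qty / days
    return float(out) if out.ndim == 0 else out


def link_prescriptions(
    episodes: pd.DataFrame,
    dispensations: pd.DataFrame,
    followup_days: int = 5,
    atc_prefix: str = "J01",
) -> pd.DataFrame:
    """Link the first in-window antibiotic dispensation to each episode.

    Candidates for an episode are same-patient dispensations with ATC code
    starting with ``atc_prefix`` and dispense date in the inclusive window
    [index_date, end_date + followup_days]. The earliest by date is kept,
    ties broken by smallest record_id. Episodes with no candidate are
    emitted with ``prescribed = False``. If one dispensation is eligible
    for two episodes of the same patient (overlapping windows), it is
    assigned to the episode with the later index date and a warning logged.
    """
    kept = episodes.loc[~episodes["excluded"].astype(bool)].copy()
    base = kept[["episode_id", "patient_id", "index_date", "end_date"]].copy()
    base["index_date"] = pd.to_datetime(base["index_date"])
    base["end_date"] = pd.to_datetime(base["end_date"])

    if dispensations.empty or base.empty:
        out = base.assign(
            prescribed=False, record_id=pd.NA, agent=pd.NA, atc_code=pd.NA,
            avg_daily_dose_mg=np.nan, duration_days=np.nan, dispense_offset=np.nan,
        )
        return out[LINKED_COLUMNS]

    disp = dispensations.copy()
    disp = disp.loc[disp["atc_code"].astype(str).str.startswith(atc_prefix)]
    disp["dispense_date"] = pd.to_datetime(disp["dispense_date"]).dt.normalize()

    cand = base.merge(disp, on="patient_id", how="inner")
    in_window = (cand["dispense_date"] >= cand["index_date"]) & (
        cand["dispense_date"] <= cand["end_date"] + pd.Timedelta(days=followup_days)
    )
    cand = cand.loc[in_window]

    # overlapping-episode pathology: a record eligible for several episodes
    # of one patient goes to the episode with the latest index date.
    if not cand.empty:
        dup = cand.groupby("record_id")["episode_id"].transform("nunique") > 1
        if dup.any():
            n = cand.loc[dup, "record_id"].nunique()
            logger.warning(
                "%d dispensation(s) eligible for multiple episodes; "
                "assigned to the later-index episode", n,
            )
            cand = cand.sort_values(["record_id", "index_date"], kind="mergesort")
            cand = cand.groupby("record_id", sort=False).tail(1)

    cand = cand.sort_values(["episode_id", "dispense_date", "record_id"], kind="mergesort")
    first = cand.groupby("episode_id", sort=False).head(1).copy()
    first["avg_daily_dose_mg"] = average_daily_dose(
        first["strength_mg"], first["quantity"], first["days_supply"]
    )
    first["duration_days"] = first["days_supply"].astype(float)
    first["dispense_offset"] = (first["dispense_date"] - first["index_date"]).dt.days

    out = base.merge(
        first[["episode_id", "record_id", "agent", "atc_code",
               "avg_daily_dose_mg", "duration_days", "dispense_offset"]],
        on="episode_id", how="left",
    )
    out["prescribed"] = out["record_id"].notna()
    return out[LINKED_COLUMNS]


def suppress_small_cells(
    table: pd.DataFrame,
    min_n: int = 6,
    marker: str = SUPPRESSED_DEFAULT,
    count_columns: list[str] | None = None,
    derived_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Replace count cells below ``min_n`` with a suppression marker.

    ``count_columns`` defaults to all numeric columns; ``derived_columns``
    (rates/percentages computed from the counts) are suppressed wherever any
    count in the same row is suppressed. Idempotent: already-suppressed
    cells are non-numeric and left untouched.
    """
    out = table.copy()
    if count_columns is None:
        count_columns = [c for c in out.columns
                         if pd.api.types.is_numeric_dtype(out[c])]
    row_hit = pd.Series(False, index=out.index)
    for col in count_columns:
        numeric = pd.to_numeric(out[col], errors="coerce")
        small = numeric.notna() & (numeric < min_n)
        if small.any():
            out[col] = out[col].astype(object)
            out.loc[small, col] = marker
        row_hit |= small
    for col in derived_columns or []:
        if row_hit.any():
            out[col] = out[col].astype(object)
            out.loc[row_hit, col] = marker
    return out
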