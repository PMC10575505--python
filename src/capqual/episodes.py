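"""Episode-of-care construction from physician visit claims.

An acute CAP episode is a run of pneumonia-coded physician visits merged by
a maximum inter-visit gap (default 14 days, rolling). Its index date is the
first visit of the run. Episodes spanning more than 30 days are chronic and
flagged excluded, as are episodes followed by a hospital admission within 5
days of the last visit (treated-as-inpatient assumption). Exclusions are
flags, never row deletions, so excluded counts remain reportable.
"""

from __future__ import annotations

import pandas as pd

from .config import CodeConfig, InputError, expand_code_set

EXCLUSION_NONE = "none"
EXCLUSION_CHRONIC = "chronic_span"
EXCLUSION_HOSPITALIZED = "hospitalized"


def _to_datetime(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series, format="ISO8601", errors="raise")


def identify_cap_visits(visits: pd.DataFrame, code_config: CodeConfig | None = None) -> pd.DataFrame:
    """Filter visit claims to pneumonia case-finding codes.

    Matching is exact-string after whitespace strip, per tagged coding
    system, with 3-digit numeric ranges in the configured list expanded to
    stems and stems matching any code sharing the first three characters.
    """
    code_config = code_config or CodeConfig()
    if visits.empty:
        return visits.copy()
    systems = visits["code_system"].astype(str).str.strip()
    unknown = set(systems.unique()) - set(code_config.cap_codes)
    if unknown:
        raise InputError(f"unknown code-system tag(s) in visits: {sorted(unknown)}")
    codes = visits["diagnostic_code"].astype(str).str.strip()
    keep = pd.Series(False, index=visits.index)
    for system, entries in code_config.cap_codes.items():
        stems = set(expand_code_set(entries))
        in_system = systems == system
        # exact match or 3-char stem match
        keep |= in_system & (codes.isin(stems) | codes.str[:3].isin(stems))
    return visits.loc[keep].copy()


def build_episodes(
    cap_visits: pd.DataFrame,
    gap_days: int = 14,
    max_span_days: int = 30,
    gap_mode: str = "rolling",
) -> pd.DataFrame:
    """Chain CAP visits into episodes per patient.

    ``rolling`` (default): a visit joins the current episode iff it falls
    within ``gap_days`` of the *previous* visit. ``from_index``: within
    ``gap_days`` of the episode's first visit. Episodes whose span exceeds
    ``max_span_days`` are flagged ``excluded(chronic_span)``.

    Returns one row per episode with columns ``episode_id, patient_id,
    index_date, end_date, span_days, n_visits, visit_dates, excluded,
    exclusion_reason``; ``visit_dates`` is the ordered list of visit dates.
    """
    cols = [
        "episode_id", "patient_id", "index_date", "end_date", "span_days",
        "n_visits", "visit_dates", "excluded", "exclusion_reason",
    ]
    if cap_visits.empty:
        return pd.DataFrame(columns=cols)
    if gap_mode not in ("rolling", "from_index"):
        raise InputError(f"gap_mode must be 'rolling' or 'from_index', got {gap_mode!r}")

    df = cap_visits[["patient_id", "service_date"]].copy()
    df["service_date"] = _to_datetime(df["service_date"]).dt.normalize()
    df = df.sort_values(["patient_id", "service_date"], kind="mergesort")

    if gap_mode == "rolling":
        same_patient = df["patient_id"].eq(df["patient_id"].shift())
        gap = df["service_date"].diff().dt.days
        new_episode = ~(same_patient & (gap <= gap_days))
        df["episode_key"] = new_episode.cumsum()
    else:
        keys = []
        key = 0
        prev_patient = None
        index_date = None
        for patient, date in zip(df["patient_id"].to_numpy(), df["service_date"].to_numpy()):
            if (
                patient != prev_patient
                or (date - index_date) / pd.Timedelta(days=1) > gap_days
            ):
                key += 1
                index_date = date
            keys.append(key)
            prev_patient = patient
        df["episode_key"] = keys

    grouped = df.groupby("episode_key", sort=True)
    episodes = grouped.agg(
        patient_id=("patient_id", "first"),
        index_date=("service_date", "min"),
        end_date=("service_date", "max"),
        n_visits=("service_date", "size"),
        visit_dates=("service_date", lambda s: list(s)),
    ).reset_index(drop=True)
    episodes["span_days"] = (episodes["end_date"] - episodes["index_date"]).dt.days
    episodes["excluded"] = episodes["span_days"] > max_span_days
    episodes["exclusion_reason"] = episodes["excluded"].map(
        {True: EXCLUSION_CHRONIC, False: EXCLUSION_NONE}
    )
    seq = episodes.groupby("patient_id", sort=False).cumcount() + 1
    episodes["episode_id"] = episodes["patient_id"].astype(str) + "-E" + seq.astype(str)
    return episodes[cols]


def exclude_hospitalized(
    episodes: pd.DataFrame,
    admissions: pd.DataFrame,
    followup_days: int = 5,
) -> pd.DataFrame:
    """Flag episodes with a hospital admission in [index, end + followup].

    The window includes the episode itself: an admission during the visit
    run also implies inpatient treatment. Endpoints are inclusive; the
    operation is idempotent and never overwrites an existing chronic-span
    flag.
    """
    out = episodes.copy()
    if out.empty or admissions.empty:
        return out
    adm = admissions[["patient_id", "admission_date"]].copy()
    adm["admission_date"] = _to_datetime(adm["admission_date"]).dt.normalize()
    merged = out.reset_index()[["index", "patient_id", "index_date", "end_date"]].merge(
        adm, on="patient_id", how="inner"
    )
    in_window = (merged["admission_date"] >= merged["index_date"]) & (
        merged["admission_date"] <= merged["end_date"] + pd.Timedelta(days=followup_days)
    )
    hit_idx = merged.loc[in_window, "index"].unique()
    hit = out.index.isin(hit_idx) & (out["exclusion_reason"] == EXCLUSION_NONE)
    out.loc[hit, "excluded"] = True
    out.loc[hit, "exclusion_reason"] = EXCLUSION_HOSPITALIZED
    return out


def filter_registry(registry: pd.DataFrame, min_age: int = 65) -> pd.DataFrame:
    """Apply cohort eligibility: age >= 65 and not resident in long-term care."""
    out = registry.copy()
    keep = out["age"] >= min_age
    if "ltc_flag" in out.columns:
        keep &= ~out["ltc_flag"].astype(bool)
    return out.loc[keep]


def episodes_to_csv(episodes: pd.DataFrame, path) -> None:
    """Serialize episodes; visit dates become a semicolon-joined ISO string."""
    out = episodes.copy()
    for col in ("index_date", "end_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out["visit_dates"] = out["visit_dates"].map(
        lambda dates: ";".join(pd.Timestamp(d).strftime("%Y-%m-%d") for d in dates)
    )
    out.to_csv(path, index=False)


def episodes_from_csv(path) -> pd.DataFrame:
    out = pd.read_csv(path)
    for col in ("index_date", "end_date"):
        out[col] = pd.to_datetime(out[col])
    out["visit_dates"] = out["visit_dates"].map(
        lambda s: [pd.Timestamp(x) for x in str(s).split(";")]
    )
    return out
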