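"""Five-category quality classification of linked CAP prescriptions.

Categories are mutually exclusive and exhaustive over linked prescriptions:

* ``guideline_adherent`` — first-line agent, dose and duration both within
  the guideline bounds;
* ``clinically_appropriate`` — non-first-line agent (any dose/duration) in
  the presence of at least one patient clinical justification, or an
  undertreatment prescription reclassified because of chronic kidney
  disease (renal dosing adjustment proxy);
* ``effective_but_unnecessary`` — first-line agent with excess dose and/or
  duration and no subtherapeutic axis;
* ``undertreatment`` — first-line agent with a subtherapeutic dose and/or
  duration; any subtherapeutic axis dominates, which also settles the
  opposing-direction tie in favour of undertreatment;
* ``not_recommended`` — non-first-line agent with no justification at all.

Clinical justifications are comorbidity diagnoses (outpatient ICD-9/OHIP
visit codes or hospital ICD-10 discharge codes in a lookback window before
the index date), dispensations of immunosuppressive or interacting
medications in the same window, and a moderate/severe Charlson score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CodeConfig, ConfigError
from .guidelines import ConcordanceResult, GuidelineRuleSet, assess_concordance

GUIDELINE_ADHERENT = "guideline_adherent"
CLINICALLY_APPROPRIATE = "clinically_appropriate"
EFFECTIVE_BUT_UNNECESSARY = "effective_but_unnecessary"
UNDERTREATMENT = "undertreatment"
NOT_RECOMMENDED = "not_recommended"


@dataclass
class JustificationProfile:
    """Clinical-justification flags for one episode at its index date."""

    conditions: dict[str, bool] = field(default_factory=dict)
    interacting_drugs: bool = False
    immunosuppressive_meds: bool = False
    charlson_score: int = 0
    charlson_threshold: int = 3

    @property
    def ckd(self) -> bool:
        return bool(self.conditions.get("ckd", False))

    @property
    def has_any_justification(self) -> bool:
        return (
            any(self.conditions.values())
            or self.interacting_drugs
            or self.immunosuppressive_meds
            or self.charlson_score >= self.charlson_threshold
        )


@dataclass
class ClassifiedPrescription:
    episode_id: str
    category: str
    concordance: ConcordanceResult
    has_any_justification: bool
    ckd: bool
    reclassified_from_undertreatment: bool
    reason_trace: list[str]


def compute_charlson(condition_flags: dict[str, bool],
                     weight_table: dict[str, int]) -> int:
    """Weighted Charlson comorbidity sum over the present conditions."""
    score = 0
    for cond, present in condition_flags.items():
        if cond not in weight_table:
            raise ConfigError(f"charlson weight table: missing condition {cond!r}")
        if present:
            score += int(weight_table[cond])
    return score


# --------------------------------------------------------------------------
# Justification lookup
# --------------------------------------------------------------------------


def _stem_match(codes: pd.Series, stems: list[str]) -> pd.Series:
    """True where a code starts with any configured stem."""
    keep = pd.Series(False, index=codes.index)
    for stem in stems:
        keep |= codes.str.startswith(stem)
    return keep


def _condition_events(
    visits: pd.DataFrame,
    admissions: pd.DataFrame,
    code_config: CodeConfig,
) -> pd.DataFrame:
    """Long table (patient_id, date, condition) of coded condition records."""
    frames = []
    if visits is not None and not visits.empty:
        v = visits[["patient_id", "service_date", "diagnostic_code", "code_system"]].copy()
        v["date"] = pd.to_datetime(v["service_date"]).dt.normalize()
        codes = v["diagnostic_code"].astype(str).str.strip()
        for cond, per_system in code_config.condition_codes.items():
            # OHIP diagnostic codes are truncated ICD-9, so ICD9 stems apply
            stems = list(per_system.get("ICD9", []))
            from .config import expand_code_set

            stems = expand_code_set(stems)
            if not stems:
                continue
            hit = _stem_match(codes, stems) & v["code_system"].isin(["ICD9", "OHIP"])
            if hit.any():
                frames.append(
                    pd.DataFrame({"patient_id": v.loc[hit, "patient_id"],
                                  "date": v.loc[hit, "date"], "condition": cond})
                )
    if admissions is not None and not admissions.empty and "diagnosis_codes" in admissions:
        a = admissions[["patient_id", "admission_date", "diagnosis_codes"]].copy()
        a["date"] = pd.to_datetime(a["admission_date"]).dt.normalize()
        a = a.assign(code=a["diagnosis_codes"].astype(str).str.split(";")).explode("code")
        a["code"] = a["code"].str.strip()
        for cond, per_system in code_config.condition_codes.items():
            stems = list(per_system.get("ICD10", []))
            if not stems:
                continue
            hit = _stem_match(a["code"], stems)
            if hit.any():
                frames.append(
                    pd.DataFrame({"patient_id": a.loc[hit, "patient_id"],
                                  "date": a.loc[hit, "date"], "condition": cond})
                )
    if not frames:
        return pd.DataFrame(columns=["patient_id", "date", "condition"])
    return pd.concat(frames, ignore_index=True)


def _medication_events(dispensations: pd.DataFrame, code_config: CodeConfig) -> pd.DataFrame:
    if dispensations is None or dispensations.empty:
        return pd.DataFrame(columns=["patient_id", "date", "condition"])
    d = dispensations[["patient_id", "dispense_date", "atc_code"]].copy()
    d["date"] = pd.to_datetime(d["dispense_date"]).dt.normalize()
    atc = d["atc_code"].astype(str)
    frames = []
    for med_class, prefixes in code_config.medication_classes.items():
        hit = _stem_match(atc, prefixes)
        if hit.any():
            frames.append(
                pd.DataFrame({"patient_id": d.loc[hit, "patient_id"],
                              "date": d.loc[hit, "date"], "condition": med_class})
            )
    if not frames:
        return pd.DataFrame(columns=["patient_id", "date", "condition"])
    return pd.concat(frames, ignore_index=True)


def build_justification_table(
    episodes: pd.DataFrame,
    visits: pd.DataFrame,
    admissions: pd.DataFrame,
    dispensations: pd.DataFrame,
    code_config: CodeConfig | None = None,
) -> pd.DataFrame:
    """Justification flags for every episode, keyed by episode_id.

    A flag is true iff at least one qualifying coded record of the same
    patient falls in the inclusive window
    [index_date - lookback, index_date] for that condition or medication
    class.
    """
    code_config = (code_config or CodeConfig()).validate()
    conditions = list(code_config.condition_codes)
    med_classes = list(code_config.medication_classes)
    flag_cols = conditions + med_classes

    base = episodes[["episode_id", "patient_id", "index_date"]].copy()
    base["index_date"] = pd.to_datetime(base["index_date"])
    for col in flag_cols:
        base[col] = False

    parts = [
        _condition_events(visits, admissions, code_config),
        _medication_events(dispensations, code_config),
    ]
    parts = [p for p in parts if not p.empty]
    events = (pd.concat(parts, ignore_index=True) if parts
              else pd.DataFrame(columns=["patient_id", "date", "condition"]))
    if not events.empty:
        merged = base[["episode_id", "patient_id", "index_date"]].merge(
            events, on="patient_id", how="inner"
        )
        lookback = merged["condition"].map(code_config.lookback_for)
        in_window = (
            merged["date"] >= merged["index_date"] - pd.to_timedelta(lookback, unit="D")
        ) & (merged["date"] <= merged["index_date"])
        hits = merged.loc[in_window, ["episode_id", "condition"]].drop_duplicates()
        if not hits.empty:
            wide = pd.crosstab(hits["episode_id"], hits["condition"]).astype(bool)
            base = base.set_index("episode_id")
            for col in wide.columns:
                base.loc[wide.index, col] = wide[col]
            base = base.reset_index()

    weights = code_config.charlson_weights
    weight_vec = np.array([weights.get(c, 0) for c in conditions])
    base["charlson_score"] = base[conditions].to_numpy(dtype=int) @ weight_vec
    base["has_any_justification"] = (
        base[flag_cols].any(axis=1)
        | (base["charlson_score"] >= code_config.charlson_threshold)
    )
    base = base.rename(columns={"interacting_drugs": "interacting_drugs",
                                "immunosuppressive_meds": "immunosuppressive_meds"})
    return base


def build_justifications(
    patient_id,
    index_date,
    visits: pd.DataFrame,
    admissions: pd.DataFrame,
    dispensations: pd.DataFrame,
    code_config: CodeConfig | None = None,
    lookback_days: int | None = None,
) -> JustificationProfile:
    """Single-episode convenience wrapper over :func:`build_justification_table`."""
    code_config = code_config or CodeConfig()
    if lookback_days is not None:
        import dataclasses

        code_config = dataclasses.replace(code_config, lookback_days=lookback_days)
    episode = pd.DataFrame(
        {"episode_id": ["_single"], "patient_id": [patient_id], "index_date": [index_date]}
    )

    def _only(df):
        if df is None or df.empty:
            return df
        return df.loc[df["patient_id"] == patient_id]

    table = build_justification_table(
        episode, _only(visits), _only(admissions), _only(dispensations), code_config
    )
    row = table.iloc[0]
    conditions = {c: bool(row[c]) for c in code_config.condition_codes}
    return JustificationProfile(
        conditions=conditions,
        interacting_drugs=bool(row.get("interacting_drugs", False)),
        immunosuppressive_meds=bool(row.get("immunosuppressive_meds", False)),
        charlson_score=int(row["charlson_score"]),
        charlson_threshold=code_config.charlson_threshold,
    )


# --------------------------------------------------------------------------
# Decision table
# --------------------------------------------------------------------------


def classify(
    rx,
    conc: ConcordanceResult,
    just: JustificationProfile,
    unknown_agent_policy: str = "non_first_line",
) -> ClassifiedPrescription:
    """Assign one linked prescription to exactly one quality category.

    The ordered decision table:

    1. non-first-line agent with >= 1 justification -> clinically appropriate;
    2. non-first-line agent with no justification -> not recommended;
    3. first-line, dose within and duration within -> guideline adherent;
    4. first-line with any subtherapeutic axis -> undertreatment (this also
       resolves opposing-direction deviations in favour of undertreatment);
    5. first-line with an excess axis and no subtherapeutic axis ->
       effective but unnecessary;

    then an undertreatment call in the presence of chronic kidney disease is
    reclassified to clinically appropriate (renal dosing proxy).
    """
    if unknown_agent_policy != "non_first_line":
        raise ConfigError(
            f"unknown_agent_policy: unsupported policy {unknown_agent_policy!r}"
        )
    episode_id = rx["episode_id"] if isinstance(rx, (dict, pd.Series)) else rx.episode_id
    trace: list[str] = []
    if conc.unknown_agent:
        trace.append("unknown_agent_as_non_first_line")

    if not conc.agent_concordant:
        if just.has_any_justification:
            trace.append("non_first_line_justified")
            category = CLINICALLY_APPROPRIATE
        else:
            trace.append("non_first_line_unjustified")
            category = NOT_RECOMMENDED
        reclassified = False
    else:
        dose, dur = conc.dose_direction, conc.duration_direction
        if dose == "within" and dur == "within":
            trace.append("first_line_fully_concordant")
            category = GUIDELINE_ADHERENT
            reclassified = False
        elif dose == "below" or dur == "below":
            trace.append("subtherapeutic_axis")
            category = UNDERTREATMENT
            reclassified = False
            if just.ckd:
                trace.append("ckd_reclassification")
                category = CLINICALLY_APPROPRIATE
                reclassified = True
        else:
            trace.append("excess_axis_only")
            category = EFFECTIVE_BUT_UNNECESSARY
            reclassified = False

    return ClassifiedPrescription(
        episode_id=episode_id,
        category=category,
        concordance=conc,
        has_any_justification=just.has_any_justification,
        ckd=just.ckd,
        reclassified_from_undertreatment=reclassified,
        reason_trace=trace,
    )


def classify_table(
    linked: pd.DataFrame,
    justifications: pd.DataFrame,
    rules: GuidelineRuleSet,
    code_config: CodeConfig | None = None,
) -> pd.DataFrame:
    """Classify every prescribed row of a linked-prescription table.

    Returns one row per prescribed episode with the category, concordance
    directions, justification summary, reclassification flag and the
    semicolon-joined reason trace.
    """
    code_config = code_config or CodeConfig()
    conditions = list(code_config.condition_codes)
    rx = linked.loc[linked["prescribed"].astype(bool)].copy()
    just_idx = justifications.set_index("episode_id")
    rows = []
    for row in rx.itertuples(index=False):
        conc = assess_concordance(
            row.agent, row.atc_code, row.avg_daily_dose_mg, row.duration_days, rules
        )
        j = just_idx.loc[row.episode_id]
        profile = JustificationProfile(
            conditions={c: bool(j[c]) for c in conditions},
            interacting_drugs=bool(j.get("interacting_drugs", False)),
            immunosuppressive_meds=bool(j.get("immunosuppressive_meds", False)),
            charlson_score=int(j["charlson_score"]),
            charlson_threshold=code_config.charlson_threshold,
        )
        cls = classify(row._asdict(), conc, profile)
        rows.append(
            {
                "episode_id": row.episode_id,
                "patient_id": row.patient_id,
                "record_id": row.record_id,
                "agent": row.agent,
                "atc_code": row.atc_code,
                "avg_daily_dose_mg": row.avg_daily_dose_mg,
                "duration_days": row.duration_days,
                "category": cls.category,
                "agent_concordant": conc.agent_concordant,
                "dose_direction": conc.dose_direction,
                "duration_direction": conc.duration_direction,
                "has_any_justification": cls.has_any_justification,
                "ckd": cls.ckd,
                "charlson_score": profile.charlson_score,
                "reclassified_from_undertreatment": cls.reclassified_from_undertreatment,
                "reason_trace": ";".join(cls.reason_trace),
            }
        )
    return pd.DataFrame(rows)
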