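"""Synthetic administrative-claims generator with known ground truth.

Emits the four linked tables an outpatient antibiotic-quality analysis
consumes — patient registry, physician visit claims, drug dispensations,
hospital admissions — plus a truth table holding every generated episode's
intended prescribed flag and quality category. Generation works backwards
from the intended category: the agent, daily dose, days supply and the
patient's coded justification records are constructed so that the episode
builder, linkage and classifier provably recover the intended label.

Two structural guarantees make the round trip exact:

* episodes of one patient are spaced at least ~400 days apart, so linkage
  windows and pre-index lookback records can never leak across episodes;
* dose menus are whole units/day, so the derived average daily dose is
  exactly ``strength x units_per_day`` with no rounding near a bound.

Deliberate edge cases (chronic long-span episodes, post-episode
admissions, decoy dispensations, long-term-care residents) are generated
at configurable rates and are off under :meth:`SimConfig.noiseless`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import JustificationProfile, classify
from .config import CodeConfig, ConfigError, InputError, SimConfig, expand_code_set
from .guidelines import assess_concordance, default_rules

# Regimen menus: units of the given strength per day, by dose direction
# relative to the shipped guideline bounds (10% tolerance). Doses are exact
# multiples of the unit strength, keeping every generated dispensation
# strictly on one side of the widened bounds.
FIRST_LINE_MENUS: dict[str, dict] = {
    "amoxicillin": {"atc": "J01CA04", "strength": 500.0,
                    "within": [4, 5, 6], "below": [2, 3], "above": [8]},
    "amoxicillin-clavulanate": {"atc": "J01CR02", "strength": 875.0,
                                "within": [2], "below": [1], "above": [4]},
    "doxycycline": {"atc": "J01AA02", "strength": 100.0,
                    "within": [2], "below": [1], "above": [4]},
}

#: (ATC code, unit strength mg, units per day) for non-first-line agents;
#: dose and duration are unconstrained for these ("any dose or duration").
NON_FIRST_LINE_REGIMENS: dict[str, tuple[str, float, int]] = {
    "azithromycin": ("J01FA10", 250.0, 1),
    "clarithromycin": ("J01FA09", 500.0, 2),
    "levofloxacin": ("J01MA12", 500.0, 1),
    "moxifloxacin": ("J01MA14", 400.0, 1),
    "cefuroxime": ("J01DC02", 500.0, 2),
    "cephalexin": ("J01DB01", 500.0, 4),
}

IMMUNOSUPPRESSANT_ATCS = ["L04AA13", "H02AB06", "L01BA01"]
INTERACTING_ATCS = ["B01AA03"]

CAP_ADMISSION_CODE = "J18"

# per-episode spacing guarantees (days); see module docstring
_EPISODE_SLOT_MIN = 430
_COMORBIDITY_OFFSET = (30, 280)


@dataclass
class GroundTruth:
    """Intended labels for every generated episode (one row per episode)."""

    episodes: pd.DataFrame

    @property
    def dispensed(self) -> pd.DataFrame:
        """Rows with an intended first dispensation (prescribed, not excluded)."""
        return self.episodes.loc[self.episodes["record_id"].notna()]

    def patient_comorbidities(self) -> pd.DataFrame:
        cols = ["patient_id", "true_comorbidities"]
        return self.episodes[cols].drop_duplicates("patient_id").reset_index(drop=True)


def _day_to_date(epoch: pd.Timestamp, day: int) -> str:
    return (epoch + pd.Timedelta(days=int(day))).strftime("%Y-%m-%d")


def _choice(rng: np.random.Generator, pmf: dict) -> object:
    keys = list(pmf.keys())
    probs = np.array([pmf[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate the patient registry: demographics plus exclusion flags.

    Ages are truncated-normal with a hard floor of 65; a configurable
    fraction of patients is flagged as long-term-care residents so the
    eligibility filter can be exercised downstream.
    """
    config.validate()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed, 0])))
    n = config.n_patients
    columns = ["patient_id", "age", "sex", "province", "ltc_flag",
               "income_quintile", "rural"]
    if n == 0:
        return pd.DataFrame(columns=columns)

    labels = list(config.provinces)
    shares = np.array([config.provinces[p] for p in labels], dtype=float)
    province = rng.choice(labels, size=n, p=shares / shares.sum())

    age = np.empty(n)
    sex = np.empty(n, dtype=object)
    for prov in labels:
        mask = province == prov
        m = int(mask.sum())
        if m == 0:
            continue
        mean = float(config.resolve("age_mean", prov))
        sd = float(config.resolve("age_sd", prov))
        draws = rng.normal(mean, sd, size=m)
        # redraw outside the cohort's age range rather than clipping, to
        # avoid a spike at the floor
        for _ in range(40):
            bad = (draws < config.age_min) | (draws > config.age_max)
            if not bad.any():
                break
            draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        draws = np.clip(draws, config.age_min, config.age_max)
        age[mask] = np.floor(draws)
        pf = float(config.resolve("prop_female", prov))
        sex[mask] = np.where(rng.random(m) < pf, "F", "M")

    registry = pd.DataFrame(
        {
            "patient_id": [f"P{i:07d}" for i in range(n)],
            "age": age.astype(int),
            "sex": sex,
            "province": province,
            "ltc_flag": rng.random(n) < config.ltc_fraction,
            "income_quintile": rng.integers(1, 6, size=n),
            "rural": rng.random(n) < 0.16,
        }
    )
    return registry[columns]


def _stratum_mixes(config: SimConfig) -> tuple[float, dict[str, float], dict[str, float]]:
    """Stratum-conditional category mixes whose mixture over the clean /
    justified patient strata equals the configured marginal category mix."""
    mix = {c: config.category_mix.get(c, 0.0) for c in (
        "guideline_adherent", "clinically_appropriate",
        "effective_but_unnecessary", "undertreatment", "not_recommended")}
    nr, ca = mix["not_recommended"], mix["clinically_appropriate"]
    q = min(max(config.p_clean_patient, nr), 1.0 - ca)
    rest = {k: mix[k] for k in ("guideline_adherent", "effective_but_unnecessary",
                                "undertreatment")}
    w = sum(rest.values())

    def _fill(mass: float) -> dict[str, float]:
        if w <= 0 or mass <= 0:
            return {k: 0.0 for k in rest}
        return {k: mass * v / w for k, v in rest.items()}

    clean = {"not_recommended": nr / q if q > 0 else 0.0, "clinically_appropriate": 0.0}
    clean.update(_fill(1.0 - clean["not_recommended"]))
    justified = {"clinically_appropriate": ca / (1 - q) if q < 1 else 0.0,
                 "not_recommended": 0.0}
    justified.update(_fill(1.0 - justified["clinically_appropriate"]))
    return q, clean, justified


def _draw_justifications(config: SimConfig, rng: np.random.Generator,
                         clean: bool) -> tuple[dict[str, bool], bool, bool]:
    conditions = list(config.comorbidity_prevalence)
    if clean:
        return {c: False for c in conditions}, False, False
    for _ in range(200):
        flags = {c: bool(rng.random() < config.comorbidity_prevalence[c])
                 for c in conditions}
        interacting = bool(rng.random() < config.p_interacting_drugs)
        immuno = bool(rng.random() < config.p_immunosuppressive)
        if any(flags.values()) or interacting or immuno:
            return flags, interacting, immuno
    flags = {c: False for c in conditions}
    flags["hypertension"] = True
    return flags, False, False


def _pmf_above(pmf: dict[int, float], threshold: int) -> dict[int, float]:
    out = {d: p for d, p in pmf.items() if d > threshold}
    return out if out else {threshold + 2: 1.0}


def _first_line_dispensation(rng: np.random.Generator, config: SimConfig,
                             agent: str, dose_dir: str, duration: int):
    menu = FIRST_LINE_MENUS[agent]
    units_per_day = int(menu[dose_dir][rng.integers(len(menu[dose_dir]))])
    strength = menu["strength"]
    return menu["atc"], strength, units_per_day * duration, duration


def _category_regimen(rng: np.random.Generator, config: SimConfig, category: str):
    """Agent/dose/duration realizing the intended category exactly.

    Returns (agent, atc, strength, quantity, days_supply). For first-line
    categories, the dose direction and duration are drawn from the
    configured deviation sub-patterns.
    """
    if category in ("clinically_appropriate", "not_recommended"):
        agent = _choice(rng, config.non_first_line_mix)
        atc, strength, per_day = NON_FIRST_LINE_REGIMENS[agent]
        duration = int(_choice(rng, config.duration_pmf))
        return agent, atc, strength, per_day * duration, duration

    agent = _choice(rng, config.first_line_mix)
    rec = 5  # recommended duration for all shipped first-line agents
    if category == "guideline_adherent":
        dose_dir, duration = "within", rec
    elif category == "effective_but_unnecessary":
        pattern = _choice(rng, config.ebu_pattern)
        dose_dir = "above" if pattern == "dose_and_duration_above" else "within"
        duration = int(_choice(rng, _pmf_above(config.duration_pmf, rec)))
    elif category in ("undertreatment", "_reclassified"):
        pattern = _choice(rng, config.ut_pattern)
        if pattern == "dose_below_duration_above":
            dose_dir = "below"
            duration = int(_choice(rng, _pmf_above(config.duration_pmf, rec)))
        elif pattern == "duration_below":
            dose_dir = "within"
            duration = int(_choice(rng, config.short_duration_pmf))
        elif pattern == "dose_below":
            dose_dir, duration = "below", rec
        else:  # both_below
            dose_dir = "below"
            duration = int(_choice(rng, config.short_duration_pmf))
    else:
        raise ConfigError(f"unknown category {category!r}")
    atc, strength, quantity, duration = _first_line_dispensation(
        rng, config, agent, dose_dir, duration
    )
    return agent, atc, strength, quantity, duration


def generate_claims(
    config: SimConfig,
    registry: pd.DataFrame,
    validate: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate visit, dispensation and admission claims plus ground truth.

    Every intended episode is a visit run with inter-visit gaps <= 14 days
    and span <= 28 days (unless deliberately chronic); every prescribed
    episode carries exactly one intended first dispensation inside its
    linkage window, optionally followed by decoys; justification records
    (comorbidity-coded visits/admissions, medication dispensations) are
    emitted inside the lookback window of each episode of the patient.
    """
    config.validate()
    required = {"patient_id", "age", "province"}
    missing = required - set(registry.columns)
    if missing:
        raise InputError(f"registry is missing columns {sorted(missing)}")
    unknown_prov = set(registry["province"].unique()) - set(config.provinces)
    if unknown_prov:
        raise InputError(f"registry has unknown province labels {sorted(unknown_prov)}")
    if registry["patient_id"].duplicated().any():
        raise InputError("registry has duplicated patient ids")

    epoch = pd.Timestamp(config.epoch)
    horizon = config.horizon_days
    rng_struct = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed, 1])))
    rng_rx = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed, 2])))
    rng_just = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed, 3])))
    rng_decoy = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed, 4])))
    rng_adm = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed, 5])))

    q, clean_mix, justified_mix = _stratum_mixes(config)
    conditions = list(config.comorbidity_prevalence)
    code_config = CodeConfig()
    icd9_of = {c: expand_code_set(code_config.condition_codes[c]["ICD9"])
               for c in conditions}
    icd10_of = {c: code_config.condition_codes[c]["ICD10"] for c in conditions}

    cap_codes = {"BC_style": ["480", "4809", "481", "4811", "486"],
                 "ON_style": ["486", "986"]}

    visits_rows: list[tuple] = []
    disp_rows: list[tuple] = []
    adm_rows: list[tuple] = []
    truth_rows: list[dict] = []
    record_id = 0

    k_max = max(1, horizon // _EPISODE_SLOT_MIN)

    for patient in registry.itertuples(index=False):
        pid = patient.patient_id
        prov = patient.province
        ltc = bool(getattr(patient, "ltc_flag", False))
        uses_icd9 = prov != "ON"
        cap_pool = cap_codes["BC_style"] if uses_icd9 else cap_codes["ON_style"]
        cap_system = "ICD9" if uses_icd9 else "OHIP"

        clean = bool(rng_just.random() < q)
        flags, interacting, immuno = _draw_justifications(config, rng_just, clean)
        true_set = ";".join(sorted(c for c, v in flags.items() if v))
        mix = clean_mix if clean else justified_mix

        n_episodes = min(k_max, 1 + int(rng_struct.poisson(
            max(config.episodes_per_patient_mean - 1.0, 0.0))))
        slot = horizon / n_episodes
        jitter_max = max(slot - 400.0, 1.0)
        visit_pmf = config.resolve("visit_count_pmf", prov)
        prescribe_p = float(config.resolve("prescribe_prob", prov))

        for ep in range(n_episodes):
            index_day = int(ep * slot + rng_struct.random() * jitter_max)

            chronic = bool(rng_struct.random() < config.chronic_rate)
            if chronic:
                gaps = [13, 13, 13]  # span 39 > 30, each gap <= 14
            else:
                n_visits = int(_choice(rng_struct, visit_pmf))
                gaps = [int(rng_struct.integers(1, 8)) for _ in range(n_visits - 1)]
                while sum(gaps) > 28:
                    gaps = gaps[:-1]
            visit_days = [index_day]
            for g in gaps:
                visit_days.append(visit_days[-1] + g)
            end_day = visit_days[-1]

            for d in visit_days:
                code = cap_pool[int(rng_struct.integers(len(cap_pool)))]
                visits_rows.append((pid, _day_to_date(epoch, d), code, cap_system, "GP"))

            hospitalized = (not chronic) and bool(
                rng_struct.random() < config.hospitalization_prob
            )
            if hospitalized:
                a = end_day + int(rng_adm.integers(0, 6))
                adm_rows.append(
                    (pid, _day_to_date(epoch, a),
                     _day_to_date(epoch, a + int(rng_adm.integers(3, 11))),
                     CAP_ADMISSION_CODE)
                )

            excluded_intent = (
                "ltc" if ltc else
                "chronic_span" if chronic else
                "hospitalized" if hospitalized else "none"
            )

            # justification records for every episode of a justified patient
            if not clean:
                for cond, present in flags.items():
                    if not present:
                        continue
                    off = int(rng_just.integers(_COMORBIDITY_OFFSET[0],
                                                _COMORBIDITY_OFFSET[1] + 1))
                    day = index_day - off
                    if rng_just.random() < 0.8:
                        code = icd9_of[cond][int(rng_just.integers(len(icd9_of[cond])))]
                        if rng_just.random() < 0.5:
                            code = code + "0"
                        visits_rows.append(
                            (pid, _day_to_date(epoch, day), code, "ICD9", "GP")
                        )
                    else:
                        stems = icd10_of[cond]
                        code = stems[int(rng_just.integers(len(stems)))]
                        adm_rows.append(
                            (pid, _day_to_date(epoch, day),
                             _day_to_date(epoch, day + int(rng_just.integers(1, 8))),
                             code)
                        )
                for active, atcs in ((interacting, INTERACTING_ATCS),
                                     (immuno, IMMUNOSUPPRESSANT_ATCS)):
                    if active:
                        off = int(rng_just.integers(_COMORBIDITY_OFFSET[0],
                                                    _COMORBIDITY_OFFSET[1] + 1))
                        atc = atcs[int(rng_just.integers(len(atcs)))]
                        record_id += 1
                        disp_rows.append(
                            (record_id, pid, _day_to_date(epoch, index_day - off),
                             "other-medication", atc, 5.0, 30, 30, "tablet")
                        )

            prescribed = (excluded_intent == "none") and bool(
                rng_rx.random() < prescribe_p
            )
            category = None
            reclassified = False
            agent = None
            duration = None
            daily_dose = None
            rx_record = None
            if prescribed:
                category = _choice(rng_rx, mix)
                if category == "undertreatment" and flags.get("ckd", False):
                    reclassified = True
                agent, atc, strength, quantity, duration = _category_regimen(
                    rng_rx, config, category
                )
                daily_dose = strength * quantity / duration
                if reclassified:
                    category = "clinically_appropriate"
                offset = int(rng_rx.integers(0, 3))
                record_id += 1
                rx_record = record_id
                disp_rows.append(
                    (record_id, pid, _day_to_date(epoch, index_day + offset),
                     agent, atc, strength, quantity, duration, "tablet")
                )
                if rng_decoy.random() < config.decoy_rate:
                    window_end = end_day + 5
                    in_window = rng_decoy.random() < 0.5
                    rx_day = index_day + offset
                    if in_window and rx_day < window_end:
                        d_day = rx_day + 1 + int(
                            rng_decoy.integers(0, window_end - rx_day)
                        )
                    else:
                        d_day = window_end + 1 + int(rng_decoy.integers(0, 20))
                    d_agent = list(NON_FIRST_LINE_REGIMENS)[
                        int(rng_decoy.integers(len(NON_FIRST_LINE_REGIMENS)))
                    ]
                    d_atc, d_strength, d_per_day = NON_FIRST_LINE_REGIMENS[d_agent]
                    record_id += 1
                    disp_rows.append(
                        (record_id, pid, _day_to_date(epoch, d_day), d_agent,
                         d_atc, d_strength, d_per_day * 7, 7, "tablet")
                    )

            truth_rows.append(
                {
                    "patient_id": pid,
                    "province": prov,
                    "episode_seq": ep + 1,
                    "index_date": _day_to_date(epoch, index_day),
                    "end_date": _day_to_date(epoch, end_day),
                    "year": (epoch + pd.Timedelta(days=index_day)).year,
                    "prescribed": prescribed,
                    "excluded_intent": excluded_intent,
                    "record_id": rx_record,
                    "category": category,
                    "reclassified": reclassified,
                    "agent": agent,
                    "duration_days": duration,
                    "avg_daily_dose_mg": daily_dose,
                    "has_any_justification": not clean,
                    "interacting_drugs": interacting,
                    "immunosuppressive_meds": immuno,
                    "true_comorbidities": true_set,
                }
            )

    visits = pd.DataFrame(
        visits_rows,
        columns=["patient_id", "service_date", "diagnostic_code", "code_system",
                 "provider_type"],
    )
    dispensations = pd.DataFrame(
        disp_rows,
        columns=["record_id", "patient_id", "dispense_date", "agent", "atc_code",
                 "strength_mg", "quantity", "days_supply", "form"],
    )
    admissions = pd.DataFrame(
        adm_rows,
        columns=["patient_id", "admission_date", "discharge_date", "diagnosis_codes"],
    )
    truth = GroundTruth(episodes=pd.DataFrame(truth_rows))

    if validate and not truth.episodes.empty:
        _validate_truth(config, truth)
    return visits, dispensations, admissions, truth


def _validate_truth(config: SimConfig, truth: GroundTruth) -> None:
    """Re-derive every intended category through the real decision table.

    Uses the intended agent, average daily dose and days supply exactly as
    the linkage stage would compute them; any mismatch is a generator bug,
    not a data feature, hence the hard failure.
    """
    rules = default_rules()
    conditions = list(config.comorbidity_prevalence)
    for row in truth.dispensed.itertuples(index=False):
        menu = FIRST_LINE_MENUS.get(row.agent)
        atc = menu["atc"] if menu is not None else NON_FIRST_LINE_REGIMENS[row.agent][0]
        flags = (set(str(row.true_comorbidities).split(";"))
                 if row.true_comorbidities else set())
        profile = JustificationProfile(
            conditions={c: c in flags for c in conditions},
            interacting_drugs=bool(row.interacting_drugs),
            immunosuppressive_meds=bool(row.immunosuppressive_meds),
            charlson_score=0,
            charlson_threshold=99,
        )
        conc = assess_concordance(
            row.agent, atc, row.avg_daily_dose_mg, row.duration_days, rules
        )
        got = classify({"episode_id": "check"}, conc, profile)
        if got.category != row.category:
            raise AssertionError(
                f"generator inconsistency: intended {row.category}, "
                f"decision table yields {got.category} for {row.agent} "
                f"{row.avg_daily_dose_mg} mg/day x {row.duration_days} d"
            )


def write_dataset(
    out_dir: str | Path,
    config: SimConfig,
) -> dict[str, Path]:
    """Generate and serialize the full dataset plus a data dictionary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    registry = generate_cohort(config)
    visits, dispensations, admissions, truth = generate_claims(config, registry)
    paths = {}
    for name, df in (
        ("registry", registry),
        ("visits", visits),
        ("dispensations", dispensations),
        ("admissions", admissions),
        ("truth", truth.episodes),
    ):
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    dict_path = out_dir / "data_dictionary.md"
    dict_path.write_text(DATA_DICTIONARY)
    paths["data_dictionary"] = dict_path
    return paths


DATA_DICTIONARY = """\
# Synthetic claims data dictionary

All dates are ISO-8601 calendar dates generated as whole-day offsets from
the configured epoch.

## registry.csv
- patient_id: opaque identifier (stable across all tables)
- age: integer years at cohort entry (>= 65)
- sex: F | M
- province: cohort label (e.g. BC, ON)
- ltc_flag: True for long-term-care residents (excluded by the pipeline)
- income_quintile: 1-5 (independent categorical draw)
- rural: boolean (independent categorical draw)

## visits.csv
- patient_id
- service_date
- diagnostic_code: pneumonia case-finding code or comorbidity diagnosis
- code_system: ICD9 | OHIP (OHIP codes are truncated ICD-9)
- provider_type: GP

## dispensations.csv
- record_id: integer, unique, monotone in generation order
- patient_id
- dispense_date
- agent: canonical drug name ("other-medication" for non-antibiotics)
- atc_code: WHO ATC code (J01... for systemic antibacterials)
- strength_mg: mg per unit; for amoxicillin-clavulanate this is the
  amoxicillin component
- quantity: units dispensed
- days_supply: days
- form: tablet

## admissions.csv
- patient_id
- admission_date, discharge_date
- diagnosis_codes: semicolon-joined ICD-10 codes

## truth.csv (generator ground truth; never an analysis input)
- patient_id, province, episode_seq, index_date, end_date, year
- prescribed: intended antibiotic dispensation flag
- excluded_intent: none | chronic_span | hospitalized | ltc
- record_id: the intended first dispensation (blank if unprescribed)
- category: intended quality category (post CKD-reclassification)
- reclassified: True when an undertreatment draw became clinically
  appropriate through chronic kidney disease
- agent, duration_days: intended prescription parameters
- has_any_justification / interacting_drugs / immunosuppressive_meds /
  true_comorbidities: the patient's true justification profile
"""
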