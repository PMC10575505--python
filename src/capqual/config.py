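"""Configuration objects for the synthetic generator and the analysis pipeline.

Everything that the original provincial analyses would have taken from
validated code algorithms (diagnosis code lists, medication ATC classes,
Charlson weights) is plain configuration here, with shipped defaults that
follow standard ICD-9 / ICD-10 / ATC conventions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is invalid; names the offending field."""


class InputError(ValueError):
    """Raised when input tables are inconsistent with each other or a config."""


class DataError(ValueError):
    """Raised when a data row violates a hard invariant (e.g. days_supply <= 0)."""


# --------------------------------------------------------------------------
# Diagnosis / medication code configuration
# --------------------------------------------------------------------------

#: Pneumonia case-finding codes per coding system. Entries may be single
#: codes or 3-digit-stem ranges ("480-481"); matching is by 3-character stem.
DEFAULT_CAP_CODES: dict[str, list[str]] = {
    "ICD9": ["480-481", "486"],
    "OHIP": ["486", "986"],
}

#: Comorbid-condition code stems per coding system. Outpatient visit claims
#: carry ICD9/OHIP codes (OHIP diagnostic codes are truncated ICD-9, so they
#: are matched against the ICD9 stems); hospital discharge diagnoses carry
#: ICD10 codes. Matching is prefix-on-stem.
DEFAULT_CONDITION_CODES: dict[str, dict[str, list[str]]] = {
    "diabetes": {"ICD9": ["250"], "ICD10": ["E10", "E11"]},
    "chf": {"ICD9": ["428"], "ICD10": ["I50"]},
    "mi": {"ICD9": ["410", "412"], "ICD10": ["I21", "I22"]},
    "copd": {"ICD9": ["491", "492", "496"], "ICD10": ["J43", "J44"]},
    "asthma": {"ICD9": ["493"], "ICD10": ["J45"]},
    "cad": {"ICD9": ["414"], "ICD10": ["I25"]},
    "hypertension": {"ICD9": ["401", "402"], "ICD10": ["I10", "I11"]},
    "cancer": {"ICD9": ["140-208"], "ICD10": ["C18", "C34", "C50", "C61"]},
    "ckd": {"ICD9": ["585"], "ICD10": ["N18"]},
}

#: ATC prefixes identifying medication-based clinical justifications:
#: immunosuppressants (anti-rheumatic biologics/DMARDs L04, systemic
#: glucocorticoids H02AB, antineoplastics L01) and agents with
#: moderate/severe interactions against the first-line CAP antibiotics
#: (vitamin-K antagonists B01AA).
DEFAULT_MEDICATION_CLASSES: dict[str, list[str]] = {
    "immunosuppressive_meds": ["L04A", "H02AB", "L01"],
    "interacting_drugs": ["B01AA"],
}

#: Classic Charlson weights for the conditions tracked here. Hypertension and
#: coronary artery disease are clinical justifications but carry no Charlson
#: weight; renal disease and malignancy carry weight 2.
DEFAULT_CHARLSON_WEIGHTS: dict[str, int] = {
    "diabetes": 1,
    "chf": 1,
    "mi": 1,
    "copd": 1,
    "asthma": 1,
    "cad": 0,
    "hypertension": 0,
    "cancer": 2,
    "ckd": 2,
}

DEFAULT_CHARLSON_THRESHOLD = 3  # "moderate/severe" Charlson score


@dataclass
class CodeConfig:
    """Code lists driving case finding and justification lookups."""

    cap_codes: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CAP_CODES.items()}
    )
    condition_codes: dict[str, dict[str, list[str]]] = field(
        default_factory=lambda: {
            c: {s: list(v) for s, v in m.items()} for c, m in DEFAULT_CONDITION_CODES.items()
        }
    )
    medication_classes: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MEDICATION_CLASSES.items()}
    )
    charlson_weights: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHARLSON_WEIGHTS)
    )
    charlson_threshold: int = DEFAULT_CHARLSON_THRESHOLD
    #: days to look back from the index date for justification records;
    #: per-condition overrides mimic inter-jurisdiction lookback differences.
    lookback_days: int = 365
    lookback_overrides: dict[str, int] = field(default_factory=dict)

    def lookback_for(self, condition: str) -> int:
        return int(self.lookback_overrides.get(condition, self.lookback_days))

    def validate(self) -> "CodeConfig":
        for cond in self.condition_codes:
            if cond not in self.charlson_weights:
                raise ConfigError(
                    f"charlson_weights: no weight configured for condition {cond!r}"
                )
        if not self.cap_codes:
            raise ConfigError("cap_codes: at least one coding system is required")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CodeConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown code-config keys: {sorted(bad)}")
        return cls(**raw).validate()


def expand_code_entry(entry: str) -> list[str]:
    """Expand a code-list entry into its 3-character stems.

    ``"480-481"`` expands to ``["480", "481"]``; plain entries pass through.
    Only numeric 3-digit stem ranges are expanded.
    """
    entry = entry.strip()
    if "-" in entry:
        lo, hi = entry.split("-", 1)
        lo, hi = lo.strip(), hi.strip()
        if lo.isdigit() and hi.isdigit() and len(lo) == 3 and len(hi) == 3:
            return [f"{i:03d}" for i in range(int(lo), int(hi) + 1)]
    return [entry]


def expand_code_set(entries: list[str]) -> list[str]:
    out: list[str] = []
    for e in entries:
        out.extend(expand_code_entry(e))
    return out


# --------------------------------------------------------------------------
# Synthetic-data configuration
# --------------------------------------------------------------------------

QUALITY_CATEGORIES = (
    "guideline_adherent",
    "clinically_appropriate",
    "effective_but_unnecessary",
    "undertreatment",
    "not_recommended",
)


def _default_category_mix() -> dict[str, float]:
    # Blend of the two provincial category distributions reported for
    # outpatient CAP prescribing in adults >= 65.
    return {
        "guideline_adherent": 0.015,
        "clinically_appropriate": 0.680,
        "effective_but_unnecessary": 0.130,
        "undertreatment": 0.115,
        "not_recommended": 0.060,
    }


def _default_comorbidity_prevalence() -> dict[str, float]:
    # Episode-level comorbidity prevalences in the elderly CAP cohort
    # (roughly the mid-point of the two provinces).
    return {
        "diabetes": 0.35,
        "chf": 0.17,
        "mi": 0.05,
        "copd": 0.37,
        "asthma": 0.20,
        "cad": 0.16,
        "hypertension": 0.78,
        "cancer": 0.41,
        "ckd": 0.13,
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic claims generator.

    Defaults emulate the published cohort: mean age ~77 (SD ~8, floor 65),
    ~55% female, ~2.3 CAP episodes per patient over 2014-2018, mean visits
    per episode ~1.75/1.35 by province, 46-52% of episodes prescribed, a
    clinically-appropriate-dominated category mix, and a dispensed-duration
    distribution with mode 7 days, then 10, then 5.
    """

    seed: int = 0
    n_patients: int = 1000
    start_year: int = 2014
    end_year: int = 2018
    epoch: str = "2014-01-01"

    provinces: dict[str, float] = field(default_factory=lambda: {"BC": 0.27, "ON": 0.73})
    age_mean: float = 77.2
    age_sd: float = 8.1
    age_min: int = 65
    age_max: int = 105
    prop_female: float = 0.545
    ltc_fraction: float = 0.03

    episodes_per_patient_mean: float = 2.3
    visit_count_pmf: dict[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.24, 3: 0.12, 4: 0.06, 5: 0.03}
    )
    prescribe_prob: float = 0.49
    category_mix: dict[str, float] = field(default_factory=_default_category_mix)
    #: probability a patient has no clinical justification of any kind;
    #: such "clean" patients are the only possible source of not-recommended
    #: prescribing.
    p_clean_patient: float = 0.10

    comorbidity_prevalence: dict[str, float] = field(
        default_factory=_default_comorbidity_prevalence
    )
    p_interacting_drugs: float = 0.005
    p_immunosuppressive: float = 0.21

    first_line_mix: dict[str, float] = field(
        default_factory=lambda: {
            "amoxicillin": 0.50,
            "amoxicillin-clavulanate": 0.20,
            "doxycycline": 0.30,
        }
    )
    non_first_line_mix: dict[str, float] = field(
        default_factory=lambda: {
            "azithromycin": 0.30,
            "clarithromycin": 0.22,
            "levofloxacin": 0.20,
            "moxifloxacin": 0.13,
            "cefuroxime": 0.10,
            "cephalexin": 0.05,
        }
    )
    duration_pmf: dict[int, float] = field(
        default_factory=lambda: {7: 0.54, 10: 0.25, 5: 0.21}
    )
    short_duration_pmf: dict[int, float] = field(default_factory=lambda: {3: 0.5, 4: 0.5})
    #: sub-pattern of excess prescribing: excess duration only vs excess
    #: dose and duration.
    ebu_pattern: dict[str, float] = field(
        default_factory=lambda: {"duration_above": 0.93, "dose_and_duration_above": 0.07}
    )
    #: sub-pattern of subtherapeutic prescribing.
    ut_pattern: dict[str, float] = field(
        default_factory=lambda: {
            "dose_below_duration_above": 0.79,
            "duration_below": 0.09,
            "dose_below": 0.05,
            "both_below": 0.07,
        }
    )

    # deliberate edge cases; zero them (SimConfig.noiseless) for exact
    # ground-truth round trips with no excluded episodes.
    chronic_rate: float = 0.02
    hospitalization_prob: float = 0.03
    decoy_rate: float = 0.10

    #: optional (province, year) -> cohort denominator table for rates; when
    #: absent, the per-province registry count is used for every year.
    annual_population: dict[str, dict[int, int]] | None = None
    province_overrides: dict[str, dict] = field(
        default_factory=lambda: {
            "BC": {"prescribe_prob": 0.46, "age_mean": 77.98, "age_sd": 8.37,
                   "prop_female": 0.533,
                   "visit_count_pmf": {1: 0.55, 2: 0.24, 3: 0.12, 4: 0.06, 5: 0.03}},
            "ON": {"prescribe_prob": 0.52, "age_mean": 76.97, "age_sd": 7.85,
                   "prop_female": 0.551,
                   "visit_count_pmf": {1: 0.75, 2: 0.17, 3: 0.06, 4: 0.02}},
        }
    )

    # ---- helpers -----------------------------------------------------

    def resolve(self, name: str, province: str):
        """Per-province override of a top-level parameter, if configured."""
        ov = self.province_overrides.get(province, {})
        return ov.get(name, getattr(self, name))

    @property
    def horizon_days(self) -> int:
        import datetime as _dt

        start = _dt.date(self.start_year, 1, 1)
        end = _dt.date(self.end_year, 12, 31)
        return (end - start).days + 1

    @classmethod
    def noiseless(cls, **kwargs) -> "SimConfig":
        """Config with all deliberate edge cases off (exact round trips)."""
        kwargs.setdefault("chronic_rate", 0.0)
        kwargs.setdefault("hospitalization_prob", 0.0)
        kwargs.setdefault("decoy_rate", 0.0)
        kwargs.setdefault("ltc_fraction", 0.0)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown sim-config keys: {sorted(bad)}")
        for key in ("visit_count_pmf", "duration_pmf", "short_duration_pmf"):
            if key in raw:
                raw[key] = {int(k): float(v) for k, v in raw[key].items()}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> "SimConfig":
        def _check_prob(name: str, value: float) -> None:
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name}: probability {value!r} outside [0, 1]")

        if self.n_patients < 0:
            raise ConfigError(f"n_patients: must be >= 0, got {self.n_patients}")
        if self.end_year < self.start_year:
            raise ConfigError("end_year: must be >= start_year")
        if self.age_min < 65:
            raise ConfigError(f"age_min: cohort floor is 65, got {self.age_min}")
        for name in (
            "prop_female",
            "ltc_fraction",
            "prescribe_prob",
            "p_clean_patient",
            "p_interacting_drugs",
            "p_immunosuppressive",
            "chronic_rate",
            "hospitalization_prob",
            "decoy_rate",
        ):
            _check_prob(name, getattr(self, name))
        for cond, p in self.comorbidity_prevalence.items():
            _check_prob(f"comorbidity_prevalence[{cond}]", p)
        mix_total = sum(self.category_mix.values())
        if abs(mix_total - 1.0) > 1e-9:
            raise ConfigError(f"category_mix: probabilities sum to {mix_total}, not 1")
        unknown = set(self.category_mix) - set(QUALITY_CATEGORIES)
        if unknown:
            raise ConfigError(f"category_mix: unknown categories {sorted(unknown)}")
        for name in ("visit_count_pmf", "duration_pmf", "short_duration_pmf",
                     "first_line_mix", "non_first_line_mix", "ebu_pattern", "ut_pattern"):
            pmf = getattr(self, name)
            if not pmf:
                raise ConfigError(f"{name}: must be non-empty")
            for k, v in pmf.items():
                _check_prob(f"{name}[{k}]", v)
            if abs(sum(pmf.values()) - 1.0) > 1e-6:
                raise ConfigError(f"{name}: probabilities must sum to 1")
        for d in self.duration_pmf:
            if not (1 <= int(d) <= 30):
                raise ConfigError(f"duration_pmf: day count {d} outside [1, 30]")
        for k in self.visit_count_pmf:
            if int(k) < 1:
                raise ConfigError("visit_count_pmf: support must be positive integers")
        share = sum(self.provinces.values())
        if abs(share - 1.0) > 1e-9:
            raise ConfigError(f"provinces: shares sum to {share}, not 1")
        return self


# --------------------------------------------------------------------------
# Pipeline configuration
# --------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters and file locations."""

    out_dir: str = "capqual_out"
    registry: str | None = None
    visits: str | None = None
    dispensations: str | None = None
    admissions: str | None = None
    code_config: str | None = None  # YAML; defaults shipped in-package
    rules: str | None = None  # guideline YAML; defaults shipped in-package

    gap_days: int = 14
    gap_mode: str = "rolling"
    max_span_days: int = 30
    followup_days: int = 5
    linkage_followup_days: int = 5
    lookback_days: int = 365
    min_cell: int = 6
    charlson_threshold: int = DEFAULT_CHARLSON_THRESHOLD
    dose_tolerance: float = 0.10
    duration_tolerance_days: int = 0
    reference_year: int | None = None
    seed: int = 0

    simulate: bool = False
    sim: SimConfig | None = None

    def validate(self) -> "PipelineConfig":
        for name in ("gap_days", "max_span_days", "followup_days",
                     "linkage_followup_days", "lookback_days"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0")
        if self.gap_mode not in ("rolling", "from_index"):
            raise ConfigError(f"gap_mode: must be 'rolling' or 'from_index', got {self.gap_mode!r}")
        if self.min_cell < 1:
            raise ConfigError("min_cell: must be >= 1")
        if not self.simulate:
            for name in ("registry", "visits", "dispensations", "admissions"):
                path = getattr(self, name)
                if path is None:
                    raise ConfigError(f"{name}: path is required when simulate is off")
                if not Path(path).exists():
                    raise ConfigError(f"{name}: file not found: {path}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown pipeline-config keys: {sorted(bad)}")
        cfg = cls(**raw)
        if sim_raw is not None:
            for key in ("visit_count_pmf", "duration_pmf", "short_duration_pmf"):
                if key in sim_raw:
                    sim_raw[key] = {int(k): float(v) for k, v in sim_raw[key].items()}
            cfg.sim = SimConfig(**sim_raw).validate()
        return cfg
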