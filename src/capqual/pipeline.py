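"""End-to-end pipeline: (simulate) -> episodes -> link -> classify -> report.

Every stage writes its table under the output directory and contributes row
counts to a JSON manifest (input hashes, parameters, per-stage counts,
warnings) so a rerun with the same inputs and seed is bit-reproducible.
Exclusions are accounted, never dropped: episodes_in = kept + chronic +
hospitalized is asserted at the episode stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import episodes as ep
from . import trends as tr
from .classifier import build_justification_table, classify_table
from .config import CodeConfig, PipelineConfig, SimConfig
from .guidelines import GuidelineRuleSet, default_rules
from .linkage import link_prescriptions, suppress_small_cells
from .synthetic import generate_claims, generate_cohort

AGE_BANDS = [(65, 79, "65-79"), (80, 200, "80+")]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _age_band(age: int) -> str:
    for lo, hi, label in AGE_BANDS:
        if lo <= age <= hi:
            return label
    return "under-65"


def _load_inputs(config: PipelineConfig, out_dir: Path):
    warnings: list[str] = []
    hashes: dict[str, str] = {}
    if config.simulate:
        sim = config.sim or SimConfig(seed=config.seed)
        registry = generate_cohort(sim)
        visits, dispensations, admissions, truth = generate_claims(sim, registry)
        data_dir = out_dir / "data"
        data_dir.mkdir(parents=True, exist_ok=True)
        for name, df in (("registry", registry), ("visits", visits),
                         ("dispensations", dispensations),
                         ("admissions", admissions), ("truth", truth.episodes)):
            path = data_dir / f"{name}.csv"
            df.to_csv(path, index=False)
            hashes[name] = _sha256(path)
    else:
        registry = pd.read_csv(config.registry)
        visits = pd.read_csv(config.visits)
        dispensations = pd.read_csv(config.dispensations)
        admissions = pd.read_csv(config.admissions)
        truth = None
        for name in ("registry", "visits", "dispensations", "admissions"):
            hashes[name] = _sha256(Path(getattr(config, name)))
    return registry, visits, dispensations, admissions, truth, hashes, warnings


def _populations(config: PipelineConfig, registry: pd.DataFrame,
                 years: list[int]) -> pd.DataFrame:
    sim = config.sim
    rows = []
    annual = sim.annual_population if (sim and sim.annual_population) else None
    for prov, n in registry.groupby("province").size().items():
        for year in years:
            pop = int(annual[prov][year]) if annual else int(n)
            rows.append({"province": prov, "year": year, "population": pop})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    code_config = (CodeConfig.from_yaml(config.code_config)
                   if config.code_config else CodeConfig())
    code_config.lookback_days = config.lookback_days
    code_config.charlson_threshold = config.charlson_threshold
    code_config.validate()
    rules = (GuidelineRuleSet.from_yaml(config.rules) if config.rules
             else default_rules(dose_tolerance=config.dose_tolerance,
                                duration_tolerance_days=config.duration_tolerance_days))

    registry, visits, dispensations, admissions, truth, hashes, warnings = \
        _load_inputs(config, out_dir)

    eligible = ep.filter_registry(registry)
    ids = set(eligible["patient_id"])
    visits_e = visits.loc[visits["patient_id"].isin(ids)]
    disp_e = dispensations.loc[dispensations["patient_id"].isin(ids)]
    adm_e = admissions.loc[admissions["patient_id"].isin(ids)]

    cap_visits = ep.identify_cap_visits(visits_e, code_config)
    episodes = ep.build_episodes(cap_visits, gap_days=config.gap_days,
                                 max_span_days=config.max_span_days,
                                 gap_mode=config.gap_mode)
    episodes = ep.exclude_hospitalized(episodes, adm_e,
                                       followup_days=config.followup_days)
    n_total = len(episodes)
    n_chronic = int((episodes["exclusion_reason"] == ep.EXCLUSION_CHRONIC).sum())
    n_hosp = int((episodes["exclusion_reason"] == ep.EXCLUSION_HOSPITALIZED).sum())
    n_kept = int((episodes["exclusion_reason"] == ep.EXCLUSION_NONE).sum())
    assert n_total == n_kept + n_chronic + n_hosp, "episode accounting broke"

    linked = link_prescriptions(episodes, disp_e,
                                followup_days=config.linkage_followup_days)
    justifications = build_justification_table(
        episodes.loc[~episodes["excluded"].astype(bool)],
        visits_e, adm_e, disp_e, code_config,
    )
    classified = classify_table(linked, justifications, rules, code_config)

    meta = eligible[["patient_id", "age", "sex", "province"]].copy()
    meta["age_band"] = meta["age"].map(_age_band)
    linked = linked.merge(meta, on="patient_id", how="left")
    linked["year"] = pd.to_datetime(linked["index_date"]).dt.year
    classified = classified.merge(
        linked[["episode_id", "province", "year", "age_band", "sex"]],
        on="episode_id", how="left",
    )

    years = sorted(linked["year"].unique().tolist())
    populations = _populations(config, eligible, years)
    counts = tr.annual_category_counts(classified, populations)

    trend_rows = []
    for (prov, cat), group in counts.groupby(["province", "category"]):
        series = group.rename(columns={"count": "count"})[["year", "count", "population"]]
        full = pd.DataFrame({"year": years}).merge(series, on="year", how="left")
        pop_map = populations.set_index(["province", "year"])["population"]
        full["population"] = [pop_map[(prov, y)] for y in full["year"]]
        full["count"] = full["count"].fillna(0)
        if len(full) < 2:
            warnings.append(f"trend skipped for {prov}/{cat}: single year")
            continue
        try:
            res = tr.poisson_trend(full, reference_year=config.reference_year,
                                   zero_count_strategy="add_half")
        except Exception as exc:  # degenerate cells stay reportable
            warnings.append(f"trend failed for {prov}/{cat}: {exc}")
            continue
        first, last = full["year"].min(), full["year"].max()
        rate = {y: tr.rate_per_1000(c, p) for y, c, p in
                zip(full["year"], full["count"], full["population"])}
        trend_rows.append(
            {
                "province": prov, "category": cat,
                "reference_year": res.reference_year,
                "comparison_year": res.comparison_year,
                "rate_ratio": res.rate_ratio, "ci_low": res.ci_low,
                "ci_high": res.ci_high, "p_value": res.p_value,
                "rate_start": rate[first], "rate_end": rate[last],
                "pct_difference": tr.pct_difference(rate[first], rate[last]),
                "continuity_corrected": res.continuity_corrected,
            }
        )
    trends = pd.DataFrame(trend_rows)

    duration_freq = tr.duration_frequency(
        linked.loc[linked["prescribed"]], strata=["province"], min_n=config.min_cell
    )
    atc_breakdown = tr.atc_class_breakdown(
        classified, strata=["province"], min_n=config.min_cell
    )

    # Table-2-like report: per province/category counts per year + trend
    table2 = suppress_small_cells(
        counts.pivot_table(index=["province", "category"], columns="year",
                           values="count", fill_value=0).reset_index(),
        min_n=config.min_cell,
    )
    # Table-1-like report: cohort characteristics of prescribed episodes
    rx = linked.loc[linked["prescribed"]]
    table1_rows = []
    for prov, grp in rx.groupby("province"):
        table1_rows.append(
            {
                "province": prov,
                "episodes_total": int((linked["province"] == prov).sum()),
                "episodes_prescribed": int(len(grp)),
                "prescribed_pct": round(100.0 * len(grp)
                                        / max((linked["province"] == prov).sum(), 1), 1),
                "age_mean": round(grp["age"].mean(), 2),
                "pct_female": round(100.0 * (grp["sex"] == "F").mean(), 1),
                "pct_80_plus": round(100.0 * (grp["age_band"] == "80+").mean(), 1),
            }
        )
    table1 = pd.DataFrame(table1_rows)

    outputs = {
        "episodes": episodes, "linked": linked, "classified": classified,
        "counts": counts, "trends": trends, "duration_freq": duration_freq,
        "atc_breakdown": atc_breakdown, "table1": table1, "table2": table2,
    }
    for name, df in outputs.items():
        if name == "episodes":
            ep.episodes_to_csv(df, out_dir / "episodes.csv")
        else:
            df.to_csv(out_dir / f"{name}.csv", index=False)

    manifest = {
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k not in ("sim",) and not isinstance(v, dict)
        },
        "sim": dataclasses.asdict(config.sim) if config.sim else None,
        "input_hashes": hashes,
        "row_counts": {
            "registry": int(len(registry)),
            "registry_eligible": int(len(eligible)),
            "visits": int(len(visits)),
            "cap_visits": int(len(cap_visits)),
            "episodes_total": n_total,
            "episodes_kept": n_kept,
            "episodes_excluded_chronic": n_chronic,
            "episodes_excluded_hospitalized": n_hosp,
            "linked_prescribed": int(linked["prescribed"].sum()),
            "classified": int(len(classified)),
        },
        "category_counts": classified["category"].value_counts().to_dict(),
        "warnings": warnings,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
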