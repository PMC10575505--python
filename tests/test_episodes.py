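"""Episode construction: code filtering, gap chaining, exclusions."""

import numpy as np
import pandas as pd
import pytest

from capqual.config import CodeConfig, InputError
from capqual.episodes import (
    EXCLUSION_CHRONIC,
    EXCLUSION_HOSPITALIZED,
    build_episodes,
    exclude_hospitalized,
    filter_registry,
    identify_cap_visits,
)
from conftest import make_visits
from helpers_oracles import chain_episodes_oracle, hospitalized_flags_oracle

EPOCH = pd.Timestamp("2014-01-01")


def _adm(patient_id, day, length=3):
    return {
        "patient_id": patient_id,
        "admission_date": (EPOCH + pd.Timedelta(days=day)).strftime("%Y-%m-%d"),
        "discharge_date": (EPOCH + pd.Timedelta(days=day + length)).strftime("%Y-%m-%d"),
        "diagnosis_codes": "J18",
    }


class TestIdentifyCapVisits:
    def test_icd9_pneumonia_code_retained(self):
        out = identify_cap_visits(make_visits([0], code="481"))
        assert len(out) == 1

    def test_four_digit_code_matches_stem(self):
        out = identify_cap_visits(make_visits([0], code="4809"))
        assert len(out) == 1

    def test_bc_style_config_can_exclude_486(self):
        config = CodeConfig(cap_codes={"ICD9": ["480-481"], "OHIP": ["486", "986"]})
        out = identify_cap_visits(make_visits([0], code="486"), config)
        assert out.empty

    def test_unknown_code_system_raises(self):
        with pytest.raises(InputError, match="code-system"):
            identify_cap_visits(make_visits([0], system="ICD10"))

    def test_set_membership_on_random_codes(self):
        rng = np.random.default_rng(0)
        cap_codes = ["480", "481", "486"]
        non_cap = [str(c) for c in rng.integers(100, 999, size=2000)
                   if str(c)[:3] not in cap_codes]
        codes = non_cap[:900] + [rng.choice(cap_codes) for _ in range(100)]
        rng.shuffle(codes)
        visits = make_visits(range(len(codes)))
        visits["diagnostic_code"] = codes
        out = identify_cap_visits(visits)
        assert len(out) == 100


class TestBuildEpisodes:
    def test_single_visit(self):
        eps = build_episodes(make_visits([0]))
        assert len(eps) == 1
        row = eps.iloc[0]
        assert row["span_days"] == 0 and row["n_visits"] == 1 and not row["excluded"]

    def test_rolling_gaps_merge_within_fourteen_days(self):
        eps = build_episodes(make_visits([0, 10, 22]))
        assert len(eps) == 1
        assert eps.iloc[0]["span_days"] == 22
        assert not eps.iloc[0]["excluded"]

    def test_long_rolling_chain_flagged_chronic(self):
        eps = build_episodes(make_visits([0, 14, 28, 42]))
        assert len(eps) == 1
        assert eps.iloc[0]["exclusion_reason"] == EXCLUSION_CHRONIC

    def test_span_of_exactly_thirty_days_is_kept(self):
        eps = build_episodes(make_visits([0, 14, 28, 30]))
        assert eps.iloc[0]["span_days"] == 30
        assert not eps.iloc[0]["excluded"]

    def test_fifteen_day_gap_starts_new_episode(self):
        eps = build_episodes(make_visits([0, 15]))
        assert len(eps) == 2

    def test_from_index_mode_windows_from_first_visit(self):
        # rolling keeps {0, 10, 20} together; from_index splits at day 20
        days = [0, 10, 20]
        assert len(build_episodes(make_visits(days), gap_mode="rolling")) == 1
        assert len(build_episodes(make_visits(days), gap_mode="from_index")) == 2

    def test_empty_input(self):
        eps = build_episodes(make_visits([]).iloc[0:0])
        assert eps.empty

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_chaining_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        days = sorted(rng.integers(0, 200, size=rng.integers(1, 40)).tolist())
        eps = build_episodes(make_visits(days))
        expected = chain_episodes_oracle(days)
        got = [sorted({(d - EPOCH).days for d in dates})
               for dates in eps["visit_dates"]]
        assert got == [sorted(set(c)) for c in expected]

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_and_idempotence(self, seed):
        rng = np.random.default_rng(100 + seed)
        days = rng.integers(0, 300, size=30).tolist()
        visits = make_visits(days)
        eps = build_episodes(visits)
        # partition: every visit row lands in exactly one episode
        all_days = sorted(d for dates in eps["visit_dates"]
                          for d in [(x - EPOCH).days for x in dates])
        assert all_days == sorted(days)
        # rebuild from the episodes' own visits reproduces the episodes
        flat = [(x - EPOCH).days for dates in eps["visit_dates"] for x in dates]
        eps2 = build_episodes(make_visits(flat))
        assert len(eps2) == len(eps)
        assert eps2["span_days"].tolist() == eps["span_days"].tolist()

    @pytest.mark.parametrize("seed", range(10))
    def test_episode_count_monotone_in_gap_days(self, seed):
        rng = np.random.default_rng(200 + seed)
        days = rng.integers(0, 365, size=25).tolist()
        counts = [len(build_episodes(make_visits(days), gap_days=g))
                  for g in (3, 7, 14, 30)]
        assert counts == sorted(counts, reverse=True)


class TestExcludeHospitalized:
    def _one_episode(self, days=(0, 3)):
        return build_episodes(make_visits(list(days)))

    def test_admission_five_days_after_end_excludes(self):
        eps = self._one_episode()
        adm = pd.DataFrame([_adm("P1", 3 + 5)])
        out = exclude_hospitalized(eps, adm)
        assert out.iloc[0]["exclusion_reason"] == EXCLUSION_HOSPITALIZED

    def test_admission_six_days_after_end_keeps(self):
        eps = self._one_episode()
        adm = pd.DataFrame([_adm("P1", 3 + 6)])
        out = exclude_hospitalized(eps, adm)
        assert not out.iloc[0]["excluded"]

    def test_intra_episode_admission_excludes(self):
        eps = self._one_episode((0, 6))
        adm = pd.DataFrame([_adm("P1", 2)])
        out = exclude_hospitalized(eps, adm)
        assert out.iloc[0]["exclusion_reason"] == EXCLUSION_HOSPITALIZED

    def test_idempotent(self):
        eps = self._one_episode()
        adm = pd.DataFrame([_adm("P1", 4)])
        once = exclude_hospitalized(eps, adm)
        twice = exclude_hospitalized(once, adm)
        pd.testing.assert_frame_equal(once, twice)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force_interval_scan(self, seed):
        rng = np.random.default_rng(300 + seed)
        frames, spec_eps = [], []
        for pid in ("A", "B", "C"):
            start = int(rng.integers(0, 100))
            end = start + int(rng.integers(0, 10))
            frames.append(make_visits([start, end], patient_id=pid))
            spec_eps.append((pid, start, end))
        eps = build_episodes(pd.concat(frames, ignore_index=True))
        admissions = [(str(rng.choice(["A", "B", "C", "D"])), int(rng.integers(0, 130)))
                      for _ in range(6)]
        adm = pd.DataFrame([_adm(p, d) for p, d in admissions])
        out = exclude_hospitalized(eps, adm)
        eps_tuples = [(r["patient_id"], (r["index_date"] - EPOCH).days,
                       (r["end_date"] - EPOCH).days) for _, r in out.iterrows()]
        expected = hospitalized_flags_oracle(eps_tuples, admissions)
        assert out["excluded"].tolist() == expected


def test_filter_registry_drops_ltc_and_underage():
    registry = pd.DataFrame(
        {"patient_id": ["a", "b", "c"], "age": [70, 64, 80],
         "ltc_flag": [False, False, True]}
    )
    out = filter_registry(registry)
    assert out["patient_id"].tolist() == ["a"]
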