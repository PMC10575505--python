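"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle is written directly from the stated rule, without reusing any
package internals, so agreement with the package is a genuine cross-check.
"""

from __future__ import annotations


def chain_episodes_oracle(days: list[int], gap_days: int = 14) -> list[list[int]]:
    """Greedy rolling-gap chaining of sorted day offsets for one patient."""
    chains: list[list[int]] = []
    for day in sorted(days):
        if chains and day - chains[-1][-1] <= gap_days:
            chains[-1].append(day)
        else:
            chains.append([day])
    return chains


def hospitalized_flags_oracle(
    episodes: list[tuple[str, int, int]],
    admissions: list[tuple[str, int]],
    followup_days: int = 5,
) -> list[bool]:
    """Pairwise interval scan: episode (patient, index, end) x admission
    (patient, day); flag iff any same-patient admission in
    [index, end + followup]."""
    out = []
    for patient, index, end in episodes:
        hit = any(
            p == patient and index <= day <= end + followup_days
            for p, day in admissions
        )
        out.append(hit)
    return out


def link_oracle(
    episodes: list[tuple[str, str, int, int]],
    dispensations: list[tuple[int, str, int]],
    followup_days: int = 5,
) -> dict[str, int | None]:
    """Brute-force first-in-window linkage.

    episodes: (episode_id, patient, index_day, end_day); dispensations:
    (record_id, patient, day). A record eligible for several episodes of
    one patient goes to the one with the latest index day; per episode the
    earliest record wins, ties by smallest record id.
    """
    eligible: dict[int, list[tuple[str, int]]] = {}
    for eid, patient, index, end in episodes:
        for rid, p, day in dispensations:
            if p == patient and index <= day <= end + followup_days:
                eligible.setdefault(rid, []).append((eid, index))
    assignment: dict[int, str] = {}
    for rid, eps in eligible.items():
        assignment[rid] = max(eps, key=lambda t: t[1])[0]
    links: dict[str, int | None] = {eid: None for eid, *_ in episodes}
    for eid, patient, index, end in episodes:
        candidates = [
            (day, rid)
            for rid, p, day in dispensations
            if p == patient and index <= day <= end + followup_days
            and assignment.get(rid) == eid
        ]
        if candidates:
            links[eid] = min(candidates)[1]
    return links


def classify_oracle(first_line: bool, dose_dir: str | None, dur_dir: str | None,
                    justified: bool, ckd: bool) -> tuple[str, bool]:
    """Brute-force five-category decision table; returns (category,
    reclassified). Justification presence is (justified or ckd) since
    chronic kidney disease is itself a clinical justification."""
    has_just = justified or ckd
    if not first_line:
        return (("clinically_appropriate", False) if has_just
                else ("not_recommended", False))
    if dose_dir == "below" or dur_dir == "below":
        if ckd:
            return "clinically_appropriate", True
        return "undertreatment", False
    if dose_dir == "within" and dur_dir == "within":
        return "guideline_adherent", False
    return "effective_but_unnecessary", False
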