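"""Guideline rule set for outpatient CAP therapy and concordance assessment.

First-line oral agents for non-severe outpatient CAP are amoxicillin
(1 g two or three times daily), amoxicillin-clavulanate (875 mg amoxicillin
component twice daily), and doxycycline (200 mg on day 1 then 100 mg twice
daily, collapsed to its 5-day mean of 200 mg/day); recommended duration is
5 days for all three. The numeric daily-dose bounds below are derived from
those regimens; the entire rule set is external configuration so alternative
guideline vintages can be swapped in.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .config import ConfigError


@dataclass(frozen=True)
class AgentRule:
    """Dose/duration recommendation for one antibiotic agent."""

    name: str
    atc_code: str
    dose_lower_mg_day: float
    dose_upper_mg_day: float
    recommended_duration_days: int = 5
    is_first_line: bool = True

    def __post_init__(self) -> None:
        if self.dose_lower_mg_day > self.dose_upper_mg_day:
            raise ConfigError(
                f"{self.name}: dose_lower_mg_day > dose_upper_mg_day"
            )
        if self.recommended_duration_days < 1:
            raise ConfigError(f"{self.name}: recommended_duration_days must be >= 1")


@dataclass(frozen=True)
class ConcordanceResult:
    """Per-axis concordance of one linked prescription.

    ``dose_direction`` / ``duration_direction`` are one of ``below``,
    ``within``, ``above`` and are defined only for first-line agents —
    non-first-line use is assessed "of any dose or duration".
    """

    agent_concordant: bool
    dose_direction: str | None = None
    duration_direction: str | None = None
    unknown_agent: bool = False


@dataclass
class GuidelineRuleSet:
    """First-line agent rules plus tolerances used for concordance."""

    rules: dict[str, AgentRule]
    #: relative widening applied to each daily-dose bound, e.g. 0.10 widens
    #: [2000, 3000] to [1800, 3300].
    dose_tolerance: float = 0.10
    #: +/- days around the recommended duration still counted as "within";
    #: 0 means exact equality (the guideline states 5 days).
    duration_tolerance_days: int = 0

    def __post_init__(self) -> None:
        if not any(r.is_first_line for r in self.rules.values()):
            raise ConfigError("rules: first-line agent set must be non-empty")
        if self.dose_tolerance < 0:
            raise ConfigError("dose_tolerance: must be >= 0")
        self._by_atc = {r.atc_code: r for r in self.rules.values()}

    def lookup(self, agent: str | None, atc_code: str | None) -> AgentRule | None:
        """Find the rule for a prescription, by ATC code first, then name."""
        if atc_code is not None and atc_code in self._by_atc:
            return self._by_atc[atc_code]
        if agent is not None and agent in self.rules:
            return self.rules[agent]
        return None

    def dose_bounds(self, rule: AgentRule) -> tuple[float, float]:
        tol = self.dose_tolerance
        return (rule.dose_lower_mg_day * (1 - tol), rule.dose_upper_mg_day * (1 + tol))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GuidelineRuleSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "agents" not in raw or not raw["agents"]:
            raise ConfigError("rules file: 'agents' section is required and non-empty")
        rules = {}
        for name, entry in raw["agents"].items():
            try:
                rules[name] = AgentRule(
                    name=name,
                    atc_code=str(entry["atc_code"]),
                    dose_lower_mg_day=float(entry["dose_lower_mg_day"]),
                    dose_upper_mg_day=float(entry["dose_upper_mg_day"]),
                    recommended_duration_days=int(entry.get("recommended_duration_days", 5)),
                    is_first_line=bool(entry.get("is_first_line", True)),
                )
            except KeyError as exc:
                raise ConfigError(f"rules file: agent {name!r} is missing field {exc}") from exc
        known = {"agents", "dose_tolerance", "duration_tolerance_days"}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"rules file: unknown keys {sorted(bad)}")
        return cls(
            rules=rules,
            dose_tolerance=float(raw.get("dose_tolerance", 0.10)),
            duration_tolerance_days=int(raw.get("duration_tolerance_days", 0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "dose_tolerance": self.dose_tolerance,
            "duration_tolerance_days": self.duration_tolerance_days,
            "agents": {
                name: {
                    k: v
                    for k, v in dataclasses.asdict(rule).items()
                    if k != "name"
                }
                for name, rule in self.rules.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def default_rules(dose_tolerance: float = 0.10,
                  duration_tolerance_days: int = 0) -> GuidelineRuleSet:
    """Shipped first-line rule set.

    amoxicillin 2000-3000 mg/day (1 g BID-TID); amoxicillin-clavulanate
    1750 mg/day amoxicillin component (875 mg BID); doxycycline 200 mg/day
    (mean of the loading schedule); all for 5 days.
    """
    rules = {
        "amoxicillin": AgentRule("amoxicillin", "J01CA04", 2000.0, 3000.0),
        "amoxicillin-clavulanate": AgentRule(
            "amoxicillin-clavulanate", "J01CR02", 1750.0, 1750.0
        ),
        "doxycycline": AgentRule("doxycycline", "J01AA02", 200.0, 200.0),
    }
    return GuidelineRuleSet(
        rules=rules,
        dose_tolerance=dose_tolerance,
        duration_tolerance_days=duration_tolerance_days,
    )


def _direction(value: float, low: float, high: float) -> str:
    if value < low:
        return "below"
    if value > high:
        return "above"
    return "within"


def assess_concordance(
    agent: str | None,
    atc_code: str | None,
    avg_daily_dose_mg: float,
    duration_days: float,
    rules: GuidelineRuleSet,
) -> ConcordanceResult:
    """Assess one prescription against the first-line rule set.

    A prescription is agent-concordant iff its agent is in the first-line
    set (matched by ATC code, falling back to canonical name). Dose is
    compared to the tolerance-widened daily-dose bounds; duration to the
    recommended duration +/- the duration tolerance. Agents carrying a
    systemic-antibacterial ATC code (J01...) that are not in the rule set
    are ordinary non-first-line agents; anything else is flagged unknown.
    """
    rule = rules.lookup(agent, atc_code)
    if rule is None or not rule.is_first_line:
        known = rule is not None or (atc_code or "").startswith("J01")
        return ConcordanceResult(agent_concordant=False, unknown_agent=not known)
    if avg_daily_dose_mg <= 0 or duration_days <= 0:
        raise ConfigError("assess_concordance: dose and duration must be positive")
    low, high = rules.dose_bounds(rule)
    dur_tol = rules.duration_tolerance_days
    rec = rule.recommended_duration_days
    return ConcordanceResult(
        agent_concordant=True,
        dose_direction=_direction(avg_daily_dose_mg, low, high),
        duration_direction=_direction(duration_days, rec - dur_tol, rec + dur_tol),
    )
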