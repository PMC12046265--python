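"""Rule-based heart-check triage against the stored event profile.

An episode *qualifies* when it is similar to the profile (symptom sets
intersect on enough of the four comparison dimensions) or carries high-risk
symptoms (three or more new typical chest-pain features, or any new
associated symptom). Qualifying episodes within 24 hours classify red;
beyond 24 hours but within 7 days, yellow; otherwise green. Multiple
episodes reduce by maximum severity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Any

import yaml

from .core_model import (
    EventProfile,
    HeartCheck,
    SymptomEpisode,
    ValidationError,
    episode_age_hours,
    parse_timestamp,
)

__all__ = [
    "RiskLevel",
    "SimilarityResult",
    "HighRiskResult",
    "RiskCategory",
    "TriageConfig",
    "similarity",
    "is_high_risk",
    "classify_heart_check",
    "RECOMMENDATIONS",
]


class RiskLevel(enum.IntEnum):
    """Ordered triage outcome: green < yellow < red."""

    GREEN = 0
    YELLOW = 1
    RED = 2

    @property
    def label(self) -> str:
        return self.name.lower()


#: Care recommendation keyed by level; a level fully determines the action.
RECOMMENDATIONS: dict[RiskLevel, str] = {
    RiskLevel.RED: "notify_family_call_911",
    RiskLevel.YELLOW: "primary_care_48h",
    RiskLevel.GREEN: "continue_app_access",
}

_DIMENSIONS = ("quality", "location", "radiation", "associated")
_DIM_ATTR = {
    "quality": "qualities",
    "location": "locations",
    "radiation": "radiation",
    "associated": "associated",
}


@dataclass(frozen=True)
class TriageConfig:
    """Tunable triage rule parameters; the defaults encode the shipped rules."""

    similarity_min_dimensions: int = 2
    high_risk_typical_set: frozenset[str] = frozenset({"dull", "heavy", "tight"})
    high_risk_min_new_typical: int = 3
    high_risk_min_new_associated: int = 1
    red_window_hours: float = 24.0
    yellow_window_hours: float = 168.0

    def __post_init__(self) -> None:
        if self.similarity_min_dimensions < 1:
            raise ValidationError("similarity_min_dimensions must be >= 1")
        if not self.red_window_hours < self.yellow_window_hours:
            raise ValidationError("red window must be shorter than yellow window")

    @classmethod
    def from_file(cls, path: str | Path) -> "TriageConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        for key in (
            "similarity_min_dimensions",
            "high_risk_min_new_typical",
            "high_risk_min_new_associated",
            "red_window_hours",
            "yellow_window_hours",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "high_risk_typical_set" in raw:
            kwargs["high_risk_typical_set"] = frozenset(raw["high_risk_typical_set"])
        return cls(**kwargs)


@dataclass(frozen=True)
class SimilarityResult:
    matched_dimensions: frozenset[str]
    is_similar: bool


@dataclass(frozen=True)
class HighRiskResult:
    new_typical_features: frozenset[str]
    new_associated: frozenset[str]
    is_high_risk: bool


@dataclass(frozen=True)
class RiskCategory:
    level: RiskLevel
    rationale: tuple[dict[str, Any], ...]
    recommendation: str

    def to_dict(self) -> dict[str, Any]:
        return {
            "level": self.level.label,
            "recommendation": self.recommendation,
            "rationale": [dict(r) for r in self.rationale],
        }


def similarity(
    episode: SymptomEpisode,
    profile: EventProfile,
    config: TriageConfig = TriageConfig(),
) -> SimilarityResult:
    """Compare an episode to the profile on the four symptom dimensions.

    A dimension matches iff the episode's and profile's sets intersect;
    the episode is similar iff at least ``similarity_min_dimensions`` match.
    """
    matched = frozenset(
        dim
        for dim in _DIMENSIONS
        if getattr(episode, _DIM_ATTR[dim]) & getattr(profile, _DIM_ATTR[dim])
    )
    return SimilarityResult(
        matched_dimensions=matched,
        is_similar=len(matched) >= config.similarity_min_dimensions,
    )


def is_high_risk(
    episode: SymptomEpisode,
    profile: EventProfile,
    config: TriageConfig = TriageConfig(),
) -> HighRiskResult:
    """Apply the high-risk rule.

    "New" means present in the episode and absent from the profile's
    corresponding set. High risk iff the episode carries at least
    ``high_risk_min_new_typical`` new typical features or any new
    associated symptom.
    """
    new_typical = (episode.qualities - profile.qualities) & config.high_risk_typical_set
    new_associated = episode.associated - profile.associated
    return HighRiskResult(
        new_typical_features=new_typical,
        new_associated=new_associated,
        is_high_risk=(
            len(new_typical) >= config.high_risk_min_new_typical
            or len(new_associated) >= config.high_risk_min_new_associated
        ),
    )


def _window(age_hours: float, config: TriageConfig) -> str:
    # Half-open at the top: red = age <= 24 h; yellow = 24 h < age <= 168 h.
    if age_hours <= config.red_window_hours:
        return "red"
    if age_hours <= config.yellow_window_hours:
        return "yellow"
    return "expired"


def classify_heart_check(
    check: HeartCheck,
    profile: EventProfile,
    now: datetime | str,
    config: TriageConfig = TriageConfig(),
) -> RiskCategory:
    """Assign a red/yellow/green level of care to one heart check.

    Episode age is measured from symptom onset to the evaluation clock
    ``now`` (not to the time the check was asked). The rationale lists
    every qualifying episode with the rules it triggered and its window.
    """
    now = parse_timestamp(now)
    level = RiskLevel.GREEN
    rationale: list[dict[str, Any]] = []
    for index, episode in enumerate(check.episodes):
        age = episode_age_hours(episode, now)  # raises if onset is after now
        sim = similarity(episode, profile, config)
        risk = is_high_risk(episode, profile, config)
        if not (sim.is_similar or risk.is_high_risk):
            continue
        rules = []
        if sim.is_similar:
            rules.append("similar")
        if risk.is_high_risk:
            rules.append("high_risk")
        window = _window(age, config)
        rationale.append(
            {
                "episode_index": index,
                "rules": rules,
                "age_hours": round(age, 6),
                "window": window,
            }
        )
        if window == "red":
            level = max(level, RiskLevel.RED)
        elif window == "yellow":
            level = max(level, RiskLevel.YELLOW)
    return RiskCategory(
        level=level,
        rationale=tuple(rationale),
        recommendation=RECOMMENDATIONS[level],
    )
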