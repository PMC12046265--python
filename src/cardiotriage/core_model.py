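"""Domain types, symptom vocabularies, body-map regions, and validation.

Every record that enters the triage or wellness pipelines passes through the
validators here. Vocabularies are *closed* per run: they are loaded once from
a config file (or the packaged defaults) and any symptom code outside them is
a hard :class:`ValidationError`, never a warning — an unrecognized token in a
safety-critical triage input must stop processing.

Timestamps are ISO-8601 with an explicit UTC offset; all age/window arithmetic
is done in seconds on timezone-aware datetimes so daylight-saving transitions
cannot shift a triage window. No function in this package reads the system
clock — callers inject ``now``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

__all__ = [
    "ValidationError",
    "BodyRegion",
    "Vocabulary",
    "EventProfile",
    "SymptomEpisode",
    "HeartCheck",
    "canonicalize_code",
    "parse_timestamp",
    "format_timestamp",
    "validate_event_profile",
    "validate_symptom_episode",
    "validate_heart_check",
    "episode_age_hours",
]

#: Dimensions along which an episode is compared to the stored profile.
SYMPTOM_DIMENSIONS = ("qualities", "locations", "radiation", "associated")

#: Region code stems that every body-map config must cover.
REQUIRED_REGION_GROUPS = ("chest", "jaw", "shoulder", "back", "arm", "axilla")

_CODE_JUNK = re.compile(r"[\s\-]+")


class ValidationError(ValueError):
    """Raised when a record violates a structural or vocabulary invariant."""


def canonicalize_code(code: str) -> str:
    """Canonicalize a symptom/region token: lowercase, underscore-joined."""
    if not isinstance(code, str):
        raise ValidationError(f"code must be a string, got {type(code).__name__}")
    canon = _CODE_JUNK.sub("_", code.strip().lower()).strip("_")
    if not canon:
        raise ValidationError("empty code")
    return canon


def parse_timestamp(value: Any) -> datetime:
    """Parse an ISO-8601 timestamp into a timezone-aware UTC datetime.

    Accepts ``datetime`` instances and strings (``Z`` suffix allowed).
    Naive timestamps are rejected: window arithmetic must be unambiguous.
    """
    if isinstance(value, datetime):
        dt = value
    elif isinstance(value, str):
        try:
            dt = datetime.fromisoformat(value.replace("Z", "+00:00"))
        except ValueError as exc:
            raise ValidationError(f"unparseable timestamp {value!r}") from exc
    else:
        raise ValidationError(f"unparseable timestamp {value!r}")
    if dt.tzinfo is None:
        raise ValidationError(f"timestamp {value!r} lacks a UTC offset")
    return dt.astimezone(timezone.utc)


def format_timestamp(dt: datetime) -> str:
    return dt.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


@dataclass(frozen=True)
class BodyRegion:
    """One coded region of the front/back body map."""

    code: str
    side: str  # "front" | "back"
    label: str

    def __post_init__(self) -> None:
        if self.side not in ("front", "back"):
            raise ValidationError(f"region {self.code!r}: side must be front|back")


@dataclass(frozen=True)
class Vocabulary:
    """Closed symptom vocabularies and the body-map region set for one run."""

    qualities: frozenset[str]
    associated: frozenset[str]
    regions: Mapping[str, BodyRegion]

    def __post_init__(self) -> None:
        for group in REQUIRED_REGION_GROUPS:
            if not any(code.startswith(group) for code in self.regions):
                raise ValidationError(f"body map missing required region group {group!r}")

    @property
    def region_codes(self) -> frozenset[str]:
        return frozenset(self.regions)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "Vocabulary":
        try:
            qualities = frozenset(canonicalize_code(c) for c in raw["qualities"])
            associated = frozenset(canonicalize_code(c) for c in raw["associated_symptoms"])
            regions_raw = raw["body_regions"]
        except KeyError as exc:
            raise ValidationError(f"vocabulary config missing key {exc.args[0]!r}") from exc
        regions: dict[str, BodyRegion] = {}
        for entry in regions_raw:
            region = BodyRegion(
                code=canonicalize_code(entry["code"]),
                side=entry["side"],
                label=entry.get("label", entry["code"]),
            )
            if region.code in regions:
                raise ValidationError(f"duplicate body region code {region.code!r}")
            regions[region.code] = region
        return cls(qualities=qualities, associated=associated, regions=regions)

    @classmethod
    def from_file(cls, path: str | Path) -> "Vocabulary":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_mapping(raw)

    @classmethod
    def default(cls) -> "Vocabulary":
        text = resources.files("cardiotriage.data").joinpath("vocabulary.yaml").read_text()
        return cls.from_mapping(yaml.safe_load(text))


def _codes(raw: Any, what: str) -> frozenset[str]:
    if raw is None:
        return frozenset()
    if isinstance(raw, str) or not isinstance(raw, Iterable):
        raise ValidationError(f"{what} must be a list of codes")
    return frozenset(canonicalize_code(c) for c in raw)


def _check_member(codes: frozenset[str], allowed: frozenset[str], what: str) -> None:
    unknown = codes - allowed
    if unknown:
        raise ValidationError(f"unknown {what} code(s): {', '.join(sorted(unknown))}")


@dataclass(frozen=True)
class EventProfile:
    """Stored baseline description of the user's index cardiac event."""

    user_id: str
    qualities: frozenset[str]
    locations: frozenset[str]
    radiation: frozenset[str]
    associated: frozenset[str]
    recorded_at: datetime

    def to_dict(self) -> dict[str, Any]:
        return {
            "user_id": self.user_id,
            "qualities": sorted(self.qualities),
            "locations": sorted(self.locations),
            "radiation": sorted(self.radiation),
            "associated": sorted(self.associated),
            "recorded_at": format_timestamp(self.recorded_at),
        }


@dataclass(frozen=True)
class SymptomEpisode:
    """One current pain/symptom report; the unit compared to the profile."""

    qualities: frozenset[str]
    locations: frozenset[str]
    radiation: frozenset[str]
    associated: frozenset[str]
    onset_at: datetime

    def to_dict(self) -> dict[str, Any]:
        return {
            "qualities": sorted(self.qualities),
            "locations": sorted(self.locations),
            "radiation": sorted(self.radiation),
            "associated": sorted(self.associated),
            "onset_at": format_timestamp(self.onset_at),
        }


@dataclass(frozen=True)
class HeartCheck:
    """A recurring symptom check-in: zero or more episodes plus ask time."""

    user_id: str
    episodes: tuple[SymptomEpisode, ...]
    asked_at: datetime

    def to_dict(self) -> dict[str, Any]:
        return {
            "user_id": self.user_id,
            "episodes": [e.to_dict() for e in self.episodes],
            "asked_at": format_timestamp(self.asked_at),
        }


def _as_mapping(raw: Any) -> Mapping[str, Any]:
    if hasattr(raw, "to_dict"):
        return raw.to_dict()
    if not isinstance(raw, Mapping):
        raise ValidationError(f"expected a mapping record, got {type(raw).__name__}")
    return raw


def validate_event_profile(
    raw: Any,
    vocab: Vocabulary | None = None,
    *,
    now: datetime | None = None,
) -> EventProfile:
    """Validate and canonicalize a raw event-profile record.

    The profile must name at least one location or associated symptom.
    When ``now`` is given, ``recorded_at`` may not lie in the future.
    """
    vocab = vocab or Vocabulary.default()
    rec = _as_mapping(raw)
    qualities = _codes(rec.get("qualities"), "qualities")
    locations = _codes(rec.get("locations"), "locations")
    radiation = _codes(rec.get("radiation"), "radiation")
    associated = _codes(rec.get("associated"), "associated")
    _check_member(qualities, vocab.qualities, "symptom quality")
    _check_member(locations, vocab.region_codes, "body region")
    _check_member(radiation, vocab.region_codes, "body region")
    _check_member(associated, vocab.associated, "associated symptom")
    if not locations and not associated:
        raise ValidationError(
            "empty profile: at least one location or associated symptom required"
        )
    if "recorded_at" not in rec:
        raise ValidationError("event profile missing recorded_at")
    recorded_at = parse_timestamp(rec["recorded_at"])
    if now is not None and recorded_at > now:
        raise ValidationError("recorded_at lies in the future")
    return EventProfile(
        user_id=str(rec.get("user_id", "")),
        qualities=qualities,
        locations=locations,
        radiation=radiation,
        associated=associated,
        recorded_at=recorded_at,
    )


def validate_symptom_episode(
    raw: Any,
    vocab: Vocabulary | None = None,
    *,
    now: datetime | None = None,
) -> SymptomEpisode:
    """Validate one symptom episode; at least one symptom set must be nonempty."""
    vocab = vocab or Vocabulary.default()
    rec = _as_mapping(raw)
    qualities = _codes(rec.get("qualities"), "qualities")
    locations = _codes(rec.get("locations"), "locations")
    radiation = _codes(rec.get("radiation"), "radiation")
    associated = _codes(rec.get("associated"), "associated")
    _check_member(qualities, vocab.qualities, "symptom quality")
    _check_member(locations, vocab.region_codes, "body region")
    _check_member(radiation, vocab.region_codes, "body region")
    _check_member(associated, vocab.associated, "associated symptom")
    if not (qualities or locations or radiation or associated):
        raise ValidationError("empty episode: all four symptom sets are empty")
    if "onset_at" not in rec:
        raise ValidationError("episode missing onset_at")
    onset_at = parse_timestamp(rec["onset_at"])
    if now is not None and onset_at > now:
        raise ValidationError("episode onset lies in the future")
    return SymptomEpisode(
        qualities=qualities,
        locations=locations,
        radiation=radiation,
        associated=associated,
        onset_at=onset_at,
    )


def validate_heart_check(
    raw: Any,
    vocab: Vocabulary | None = None,
) -> HeartCheck:
    """Validate a heart-check record; episodes come out sorted by onset."""
    vocab = vocab or Vocabulary.default()
    rec = _as_mapping(raw)
    if "asked_at" not in rec:
        raise ValidationError("heart check missing asked_at")
    asked_at = parse_timestamp(rec["asked_at"])
    episodes = tuple(
        sorted(
            (validate_symptom_episode(e, vocab) for e in rec.get("episodes", [])),
            key=lambda e: e.onset_at,
        )
    )
    for ep in episodes:
        if ep.onset_at > asked_at:
            raise ValidationError("episode onset is after asked_at")
    return HeartCheck(user_id=str(rec.get("user_id", "")), episodes=episodes, asked_at=asked_at)


def episode_age_hours(episode: SymptomEpisode, now: datetime) -> float:
    """Age of an episode at ``now``, in hours, exact to the second."""
    now = parse_timestamp(now)
    delta = (now - episode.onset_at).total_seconds()
    if delta < 0:
        raise ValidationError("episode onset lies in the future relative to now")
    return delta / 3600.0


def read_session(path: str | Path) -> dict[str, Any]:
    """Read one user's session log (JSON) without validating its contents."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValidationError("session log must be a JSON object")
    return raw
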