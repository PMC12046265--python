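"""Seven-domain wellness scoring and threshold-driven content selection.

Scores are oriented so that higher means better wellness (0 worst, 10 best).
A domain whose score is at or below the threshold (default 4) is flagged, and
library items addressing at least one flagged domain are recommended, ordered
by how many flagged domains they cover and then by item id — recommendations
are fully deterministic.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

from .core_model import ValidationError, format_timestamp, parse_timestamp

__all__ = [
    "WELLNESS_DOMAINS",
    "WellnessCheck",
    "LibraryItem",
    "WellnessRecommendation",
    "validate_wellness_check",
    "flag_domains",
    "recommend_content",
    "load_library",
]

log = logging.getLogger(__name__)

#: The seven life domains scored at every wellness check.
WELLNESS_DOMAINS = (
    "general_activities",
    "work",
    "walking",
    "mood",
    "relations",
    "sleep",
    "enjoyment",
)

SCORE_MIN, SCORE_MAX = 0, 10
DEFAULT_THRESHOLD = 4

ITEM_KINDS = ("article", "lay_summary", "video", "podcast")


@dataclass(frozen=True)
class WellnessCheck:
    user_id: str
    scores: Mapping[str, int]
    asked_at: datetime

    def to_dict(self) -> dict[str, Any]:
        return {
            "user_id": self.user_id,
            "scores": {d: self.scores[d] for d in WELLNESS_DOMAINS},
            "asked_at": format_timestamp(self.asked_at),
        }


@dataclass(frozen=True)
class LibraryItem:
    item_id: str
    kind: str
    domains: frozenset[str]
    title: str

    def __post_init__(self) -> None:
        if self.kind not in ITEM_KINDS:
            raise ValidationError(f"library item {self.item_id!r}: unknown kind {self.kind!r}")
        if not self.domains:
            raise ValidationError(f"library item {self.item_id!r}: empty domain set")
        unknown = self.domains - set(WELLNESS_DOMAINS)
        if unknown:
            raise ValidationError(
                f"library item {self.item_id!r}: unknown domain(s) {sorted(unknown)}"
            )


@dataclass(frozen=True)
class WellnessRecommendation:
    flagged_domains: frozenset[str]
    items: tuple[str, ...]

    def to_dict(self) -> dict[str, Any]:
        return {"flagged_domains": sorted(self.flagged_domains), "items": list(self.items)}


def validate_wellness_check(raw: Any) -> WellnessCheck:
    """Validate one wellness check: exactly the 7 domains, scores 0-10."""
    if hasattr(raw, "to_dict"):
        raw = raw.to_dict()
    if not isinstance(raw, Mapping):
        raise ValidationError("wellness check must be a mapping record")
    scores_raw = raw.get("scores")
    if not isinstance(scores_raw, Mapping):
        raise ValidationError("wellness check missing scores mapping")
    missing = set(WELLNESS_DOMAINS) - set(scores_raw)
    extra = set(scores_raw) - set(WELLNESS_DOMAINS)
    if missing:
        raise ValidationError(f"wellness check missing domain(s): {sorted(missing)}")
    if extra:
        raise ValidationError(f"wellness check has unknown domain(s): {sorted(extra)}")
    scores: dict[str, int] = {}
    for domain in WELLNESS_DOMAINS:
        value = scores_raw[domain]
        if not isinstance(value, int) or isinstance(value, bool):
            raise ValidationError(f"domain {domain!r}: score must be an integer")
        if not SCORE_MIN <= value <= SCORE_MAX:
            raise ValidationError(
                f"domain {domain!r}: score {value} outside [{SCORE_MIN}, {SCORE_MAX}]"
            )
        scores[domain] = value
    if "asked_at" not in raw:
        raise ValidationError("wellness check missing asked_at")
    return WellnessCheck(
        user_id=str(raw.get("user_id", "")),
        scores=scores,
        asked_at=parse_timestamp(raw["asked_at"]),
    )


def flag_domains(check: WellnessCheck, threshold: int = DEFAULT_THRESHOLD) -> frozenset[str]:
    """Return exactly the domains whose score is <= ``threshold``."""
    return frozenset(d for d in WELLNESS_DOMAINS if check.scores[d] <= threshold)


def recommend_content(
    flagged: Iterable[str],
    library: Sequence[LibraryItem],
) -> WellnessRecommendation:
    """Select library items addressing at least one flagged domain.

    Items are ordered by number of flagged domains covered (descending),
    then by item id (ascending). An empty library with flagged domains is
    logged as a warning, not an error: there is simply nothing to suggest.
    """
    flagged_set = frozenset(flagged)
    unknown = flagged_set - set(WELLNESS_DOMAINS)
    if unknown:
        raise ValidationError(f"unknown flagged domain(s): {sorted(unknown)}")
    if not flagged_set:
        return WellnessRecommendation(flagged_domains=frozenset(), items=())
    if not library:
        log.warning("wellness library is empty; flagged domains %s go unanswered",
                    sorted(flagged_set))
        return WellnessRecommendation(flagged_domains=flagged_set, items=())
    seen: set[str] = set()
    for item in library:
        if item.item_id in seen:
            raise ValidationError(f"duplicate library item id {item.item_id!r}")
        seen.add(item.item_id)
    hits = [
        (len(item.domains & flagged_set), item.item_id)
        for item in library
        if item.domains & flagged_set
    ]
    hits.sort(key=lambda pair: (-pair[0], pair[1]))
    return WellnessRecommendation(
        flagged_domains=flagged_set,
        items=tuple(item_id for _, item_id in hits),
    )


def _item_from_mapping(entry: Mapping[str, Any]) -> LibraryItem:
    domains = entry["domains"]
    if isinstance(domains, str):
        domains = [d for d in domains.replace(",", ";").split(";") if d.strip()]
    return LibraryItem(
        item_id=str(entry["item_id"]),
        kind=str(entry["kind"]),
        domains=frozenset(d.strip() for d in domains),
        title=str(entry.get("title", "")),
    )


def load_library(path: str | Path) -> list[LibraryItem]:
    """Load a library index from JSON (list of objects) or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, newline="", encoding="utf-8") as fh:
            entries: list[Mapping[str, Any]] = list(csv.DictReader(fh))
    else:
        with open(path, encoding="utf-8") as fh:
            entries = json.load(fh)
    items = [_item_from_mapping(e) for e in entries]
    ids = [i.item_id for i in items]
    if len(ids) != len(set(ids)):
        raise ValidationError("library index contains duplicate item ids")
    return items
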