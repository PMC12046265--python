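"""Seeded synthetic users: event profiles, episode streams, wellness
trajectories, and SUS response tables.

Similarity and high-risk are injected *by construction* — a "similar"
episode copies at least two profile dimensions verbatim, a "high-risk"
episode carries three new typical features or one new associated symptom —
so every generated episode has an exact ground-truth triage label that the
engines can be checked against.

All randomness flows from one seed; each user gets an independent substream
keyed by (seed, user index), so adding or removing users never perturbs the
data of the others.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from .core_model import (
    EventProfile,
    SymptomEpisode,
    ValidationError,
    Vocabulary,
    format_timestamp,
)
from .usability_stats import N_SUS_ITEMS, SusResponse, sus_score
from .wellness_engine import WELLNESS_DOMAINS, WellnessCheck

__all__ = [
    "CohortConfig",
    "SyntheticUser",
    "generate_cohort",
    "generate_sus_responses",
    "write_cohort",
]

#: Regions a synthetic profile may use; disjoint from the neutral pool below,
#: so a non-similar episode can always pick a location the profile lacks.
_PROFILE_REGIONS = (
    "chest_center",
    "chest_left",
    "chest_right",
    "jaw",
    "shoulder_left",
    "shoulder_right",
    "arm_left",
)
_NEUTRAL_REGIONS = ("back_upper", "back_mid", "back_lower", "abdomen_upper", "neck")

_TYPICAL = ("dull", "heavy", "tight")

_EPOCH = datetime(2021, 1, 4, 8, 0, tzinfo=timezone.utc)


@dataclass(frozen=True)
class CohortConfig:
    n_users: int = 10
    seed: int = 0
    episode_rate_per_week: float = 1.0
    p_similar: float = 0.3
    p_high_risk: float = 0.1
    wellness_drift_mean: float = 0.0
    wellness_drift_sd: float = 1.5
    horizon_weeks: int = 8

    def __post_init__(self) -> None:
        if self.n_users < 1 or self.horizon_weeks < 1:
            raise ValidationError("n_users and horizon_weeks must be positive")
        if self.episode_rate_per_week < 0:
            raise ValidationError("episode_rate_per_week must be nonnegative")
        for p in (self.p_similar, self.p_high_risk):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticUser:
    profile: EventProfile
    episodes: tuple[SymptomEpisode, ...]
    #: ground-truth (is_similar, is_high_risk) per episode, by construction
    episode_labels: tuple[tuple[bool, bool], ...]
    wellness_series: tuple[WellnessCheck, ...]
    sus: SusResponse

    def to_session_dict(self) -> dict[str, Any]:
        horizon_end = max(
            [self.profile.recorded_at]
            + [e.onset_at for e in self.episodes]
            + [w.asked_at for w in self.wellness_series]
        )
        return {
            "event_profile": self.profile.to_dict(),
            "heart_checks": [
                {
                    "user_id": self.profile.user_id,
                    "episodes": [e.to_dict() for e in self.episodes],
                    "asked_at": format_timestamp(horizon_end),
                }
            ],
            "wellness_checks": [w.to_dict() for w in self.wellness_series],
        }


def _user_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, index])


def _pick(rng: np.random.Generator, pool: Sequence[str], k: int) -> frozenset[str]:
    k = min(k, len(pool))
    return frozenset(rng.choice(list(pool), size=k, replace=False).tolist())


def _make_profile(rng: np.random.Generator, user_id: str, vocab: Vocabulary) -> EventProfile:
    qualities = _pick(rng, sorted(vocab.qualities), int(rng.integers(1, 3)))
    locations = _pick(rng, _PROFILE_REGIONS, int(rng.integers(1, 3)))
    radiation = _pick(rng, _PROFILE_REGIONS, int(rng.integers(0, 2)))
    # keep at most one baseline associated symptom so a new one is always injectable
    associated = _pick(rng, sorted(vocab.associated), int(rng.integers(0, 2)))
    return EventProfile(
        user_id=user_id,
        qualities=qualities,
        locations=locations,
        radiation=radiation,
        associated=associated,
        recorded_at=_EPOCH,
    )


def _make_episode(
    rng: np.random.Generator,
    profile: EventProfile,
    onset: datetime,
    similar: bool,
    high_risk: bool,
    vocab: Vocabulary,
) -> SymptomEpisode:
    qualities: set[str] = set()
    locations: set[str] = set()
    radiation: set[str] = set()
    associated: set[str] = set()
    if similar:
        # copy two full dimensions verbatim -> matches >= 2 of 4 by construction
        qualities |= profile.qualities
        locations |= profile.locations
        if not qualities:  # profile qualities can't be empty, but stay safe
            radiation |= profile.radiation
    else:
        # one location the profile never uses: zero dimension overlap
        locations.add(str(rng.choice(_NEUTRAL_REGIONS)))
    if high_risk:
        new_typical = set(_TYPICAL) - profile.qualities
        if len(new_typical) >= 3 and rng.random() < 0.5:
            qualities |= new_typical
        else:
            candidates = sorted(vocab.associated - profile.associated)
            associated.add(str(rng.choice(candidates)))
    return SymptomEpisode(
        qualities=frozenset(qualities),
        locations=frozenset(locations),
        radiation=frozenset(radiation),
        associated=frozenset(associated),
        onset_at=onset,
    )


def _make_wellness(
    rng: np.random.Generator,
    user_id: str,
    config: CohortConfig,
) -> tuple[WellnessCheck, ...]:
    scores = {d: int(rng.integers(5, 11)) for d in WELLNESS_DOMAINS}
    series = []
    for week in range(config.horizon_weeks):
        asked_at = _EPOCH + timedelta(weeks=week + 1)
        steps = rng.normal(config.wellness_drift_mean, config.wellness_drift_sd,
                           size=len(WELLNESS_DOMAINS))
        for d, s in zip(WELLNESS_DOMAINS, steps):
            scores[d] = int(np.clip(scores[d] + round(float(s)), 0, 10))
        series.append(WellnessCheck(user_id=user_id, scores=dict(scores), asked_at=asked_at))
    return tuple(series)


def generate_cohort(
    config: CohortConfig,
    vocab: Vocabulary | None = None,
) -> list[SyntheticUser]:
    """Generate ``config.n_users`` synthetic users, deterministic in the seed.

    Episode onsets follow a homogeneous arrival process at
    ``episode_rate_per_week`` over ``horizon_weeks``. Each episode is
    independently made similar with probability ``p_similar`` and high-risk
    with probability ``p_high_risk``; otherwise it shares nothing with the
    profile and carries no high-risk features.
    """
    vocab = vocab or Vocabulary.default()
    users = []
    horizon_hours = config.horizon_weeks * 7 * 24
    for index in range(config.n_users):
        rng = _user_rng(config.seed, index)
        user_id = f"user-{index:04d}"
        profile = _make_profile(rng, user_id, vocab)
        n_episodes = int(rng.poisson(config.episode_rate_per_week * config.horizon_weeks))
        offsets = np.sort(rng.uniform(0, horizon_hours, size=n_episodes))
        episodes = []
        labels = []
        for offset in offsets:
            onset = _EPOCH + timedelta(hours=float(offset))
            similar = bool(rng.random() < config.p_similar)
            high = bool(rng.random() < config.p_high_risk)
            episodes.append(_make_episode(rng, profile, onset, similar, high, vocab))
            labels.append((similar, high))
        target = float(np.clip(rng.normal(75.0, 15.0), 0.0, 100.0))
        sus = _response_for_score(_snap_to_lattice(target), rng)
        users.append(
            SyntheticUser(
                profile=profile,
                episodes=tuple(episodes),
                episode_labels=tuple(labels),
                wellness_series=_make_wellness(rng, user_id, config),
                sus=sus,
            )
        )
    return users


# --- SUS response synthesis -------------------------------------------------

_LATTICE = 2.5  # SUS scores are multiples of 2.5


def _snap_to_lattice(score: float) -> float:
    return float(np.clip(round(score / _LATTICE) * _LATTICE, 0.0, 100.0))


def _response_for_score(score: float, rng: np.random.Generator) -> SusResponse:
    """Build a valid 10-item vector scoring exactly ``score``.

    The raw point total (score / 2.5, in 0..40) is spread evenly across the
    ten items, with any remainder assigned to randomly chosen items.
    """
    total = int(round(score / _LATTICE))
    base, remainder = divmod(total, N_SUS_ITEMS)
    contributions = [base] * N_SUS_ITEMS
    if remainder:
        bumped = rng.choice(N_SUS_ITEMS, size=remainder, replace=False)
        for j in bumped:
            contributions[int(j)] += 1
    items = tuple(
        (c + 1) if (i + 1) % 2 == 1 else (5 - c) for i, c in enumerate(contributions)
    )
    adjective = int(np.clip(round(1 + 6 * score / 100.0), 1, 7))
    return SusResponse(items=items, adjective=adjective)


def _sample_stats(scores: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(scores, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def generate_sus_responses(
    n: int,
    target_mean: float,
    target_sd: float,
    seed: int,
) -> list[SusResponse]:
    """Generate ``n`` SUS responses whose scored mean/SD approach the targets.

    Scores live on the lattice of multiples of 2.5 in [0, 100]; a symmetric
    two-point construction is refined by greedy +/-2.5 moves until no single
    move improves the squared (mean, SD) error. For n >= 10 the achieved
    mean and SD land within 2.5 of any feasible target.
    """
    if n < 1:
        raise ValidationError("n must be positive")
    if not 0.0 <= target_mean <= 100.0:
        raise ValidationError("target_mean must lie in [0, 100]")
    if target_sd < 0:
        raise ValidationError("target_sd must be nonnegative")
    if target_sd > 0 and n < 2:
        raise ValidationError("nonzero target_sd is infeasible with n < 2")
    max_sd = 50.0 * np.sqrt(n / max(n - 1, 1))
    if target_sd > max_sd:
        raise ValidationError(f"target_sd {target_sd} exceeds the maximum {max_sd:.2f}")

    rng = np.random.default_rng(seed)
    # symmetric seed construction: half at mean+d, half at mean-d
    d = target_sd * np.sqrt((n - 1) / n) if n > 1 else 0.0
    scores = []
    for i in range(n):
        offset = d if i % 2 == 0 else -d
        if n % 2 == 1 and i == n - 1:
            offset = 0.0
        scores.append(_snap_to_lattice(target_mean + offset))

    def loss(vals: Sequence[float]) -> float:
        m, s = _sample_stats(vals)
        return (m - target_mean) ** 2 + (s - target_sd) ** 2

    current = loss(scores)
    for _ in range(400):  # greedy refinement on the lattice
        best: tuple[float, int, float] | None = None
        for i in range(n):
            for delta in (-_LATTICE, _LATTICE):
                candidate = scores[i] + delta
                if not 0.0 <= candidate <= 100.0:
                    continue
                trial = scores[:i] + [candidate] + scores[i + 1 :]
                trial_loss = loss(trial)
                if trial_loss < current - 1e-12 and (best is None or trial_loss < best[0]):
                    best = (trial_loss, i, candidate)
        if best is None:
            break
        current, i, candidate = best
        scores[i] = candidate
    return [_response_for_score(score, rng) for score in scores]


def write_cohort(users: Sequence[SyntheticUser], outdir: str | Path) -> None:
    """Write one session-log JSON per user, a manifest, and a SUS CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for user in users:
        name = f"{user.profile.user_id}.json"
        with open(outdir / name, "w", encoding="utf-8") as fh:
            json.dump(user.to_session_dict(), fh, indent=2, sort_keys=True)
        manifest.append(
            {
                "user_id": user.profile.user_id,
                "session_file": name,
                "n_episodes": len(user.episodes),
                "n_wellness_checks": len(user.wellness_series),
            }
        )
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(outdir / "sus.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([f"q{i}" for i in range(1, N_SUS_ITEMS + 1)] + ["adjective", "score"])
        for user in users:
            writer.writerow(list(user.sus.items) + [user.sus.adjective, sus_score(user.sus)])
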