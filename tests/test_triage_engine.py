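"""Triage rules checked against independent oracles: a set-intersection
similarity oracle, an exhaustive truth table for the high-risk formula, and
a hand-written decision table plus brute-force reduction for classification."""

import itertools
from datetime import timedelta

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cardiotriage.core_model import EventProfile, SymptomEpisode
from cardiotriage.triage_engine import (
    RECOMMENDATIONS,
    RiskLevel,
    TriageConfig,
    classify_heart_check,
    is_high_risk,
    similarity,
)
from conftest import NOW, make_check, make_episode

TYPICAL = ("dull", "heavy", "tight")
ASSOCIATED = (
    "shortness_of_breath",
    "palpitations",
    "racing_heart",
    "lightheaded",
    "faint",
    "dizzy",
)


# --- independent oracles ----------------------------------------------------

def oracle_matched_dims(episode, profile):
    dims = []
    if set(episode.qualities) & set(profile.qualities):
        dims.append("quality")
    if set(episode.locations) & set(profile.locations):
        dims.append("location")
    if set(episode.radiation) & set(profile.radiation):
        dims.append("radiation")
    if set(episode.associated) & set(profile.associated):
        dims.append("associated")
    return set(dims)


def oracle_high_risk(episode, profile):
    new_typical = {q for q in episode.qualities if q in TYPICAL and q not in profile.qualities}
    new_assoc = {a for a in episode.associated if a not in profile.associated}
    return len(new_typical) >= 3 or len(new_assoc) >= 1


def oracle_level(qualifying_ages):
    """Decision table: max severity over per-episode window assignment."""
    level = "green"
    for age in qualifying_ages:
        if age <= 24:
            return "red"
        if age <= 168:
            level = "yellow"
    return level


class TestSimilarity:
    def test_two_dimensions_match(self, profile):
        ep = make_episode(qualities={"heavy"}, locations={"chest_center"})
        result = similarity(ep, profile)
        assert result.matched_dimensions == frozenset({"quality", "location"})
        assert result.is_similar

    def test_disjoint_episode_not_similar(self, profile):
        ep = make_episode(qualities={"sharp"}, locations={"back_lower"},
                          radiation={"back_upper"}, associated={"dizzy"})
        result = similarity(ep, profile)
        assert result.matched_dimensions == frozenset()
        assert not result.is_similar

    def test_identical_episode_matches_all_dimensions(self, profile):
        ep = make_episode(
            qualities=profile.qualities,
            locations=profile.locations,
            radiation=profile.radiation,
            associated=profile.associated,
        )
        result = similarity(ep, profile)
        assert result.matched_dimensions == frozenset(
            {"quality", "location", "radiation", "associated"}
        )
        assert result.is_similar

    def test_single_match_below_default_threshold(self, profile):
        ep = make_episode(qualities={"heavy"}, locations={"back_lower"})
        assert not similarity(ep, profile).is_similar
        loose = TriageConfig(similarity_min_dimensions=1)
        assert similarity(ep, profile, loose).is_similar

    def test_against_set_intersection_oracle(self, profile):
        rng = np.random.default_rng(7)
        pool_q = ("dull", "heavy", "tight", "pressure", "sharp", "burning")
        pool_l = ("chest_center", "chest_left", "jaw", "back_upper", "arm_left")
        for _ in range(200):
            ep = make_episode(
                qualities=[q for q in pool_q if rng.random() < 0.3],
                locations=[l for l in pool_l if rng.random() < 0.3],
                radiation=[l for l in pool_l if rng.random() < 0.2],
                associated=[a for a in ASSOCIATED if rng.random() < 0.2],
            )
            result = similarity(ep, profile)
            expected = oracle_matched_dims(ep, profile)
            assert set(result.matched_dimensions) == expected
            assert result.is_similar == (len(expected) >= 2)


class TestHighRisk:
    def test_three_new_typical_features(self):
        profile = EventProfile(
            user_id="u", qualities=frozenset({"sharp"}),
            locations=frozenset({"chest_center"}), radiation=frozenset(),
            associated=frozenset(), recorded_at=NOW - timedelta(days=10),
        )
        ep = make_episode(qualities={"dull", "heavy", "tight"})
        result = is_high_risk(ep, profile)
        assert result.is_high_risk
        assert result.new_typical_features == frozenset({"dull", "heavy", "tight"})

    def test_any_new_associated_symptom(self):
        profile = EventProfile(
            user_id="u", qualities=frozenset({"sharp"}),
            locations=frozenset({"chest_center"}), radiation=frozenset(),
            associated=frozenset(), recorded_at=NOW - timedelta(days=10),
        )
        ep = make_episode(associated={"palpitations"})
        result = is_high_risk(ep, profile)
        assert result.is_high_risk
        assert result.new_associated == frozenset({"palpitations"})

    def test_features_already_in_profile_are_not_new(self, profile):
        # profile already has heavy+tight; only "dull" is new -> not high risk
        ep = make_episode(qualities={"dull", "heavy", "tight"})
        assert not is_high_risk(ep, profile).is_high_risk

    @pytest.mark.parametrize(
        "profile_qualities,profile_associated",
        [(frozenset(), frozenset()), (frozenset({"dull"}), frozenset({"palpitations"}))],
    )
    def test_exhaustive_truth_table(self, profile_qualities, profile_associated):
        """All 2^3 x 2^6 feature subsets against the boolean formula."""
        profile = EventProfile(
            user_id="u", qualities=profile_qualities,
            locations=frozenset({"chest_center"}), radiation=frozenset(),
            associated=profile_associated, recorded_at=NOW - timedelta(days=10),
        )
        for r_t in range(len(TYPICAL) + 1):
            for typ in itertools.combinations(TYPICAL, r_t):
                for r_a in range(len(ASSOCIATED) + 1):
                    for assoc in itertools.combinations(ASSOCIATED, r_a):
                        ep = make_episode(qualities=typ, associated=assoc,
                                          locations={"back_lower"})
                        assert (
                            is_high_risk(ep, profile).is_high_risk
                            == oracle_high_risk(ep, profile)
                        )


class TestClassifyHeartCheck:
    def test_qualifying_episode_within_24h_is_red(self, profile):
        ep = make_episode(hours_ago=12, qualities={"heavy"}, locations={"chest_center"})
        result = classify_heart_check(make_check([ep]), profile, NOW)
        assert result.level is RiskLevel.RED
        assert result.recommendation == "notify_family_call_911"
        assert result.rationale[0]["window"] == "red"

    def test_qualifying_episode_at_72h_is_yellow(self, profile):
        ep = make_episode(hours_ago=72, qualities={"heavy"}, locations={"chest_center"})
        result = classify_heart_check(make_check([ep]), profile, NOW)
        assert result.level is RiskLevel.YELLOW
        assert result.recommendation == "primary_care_48h"

    def test_empty_episode_list_is_green(self, profile):
        result = classify_heart_check(make_check([]), profile, NOW)
        assert result.level is RiskLevel.GREEN
        assert result.recommendation == "continue_app_access"
        assert result.rationale == ()

    def test_non_qualifying_recent_episode_is_green(self, profile):
        ep = make_episode(hours_ago=1, locations={"back_lower"})
        assert classify_heart_check(make_check([ep]), profile, NOW).level is RiskLevel.GREEN

    @pytest.mark.parametrize("qualifies", [False, True])
    @pytest.mark.parametrize("age", [12.0, 72.0, 200.0])
    def test_decision_table(self, profile, qualifies, age):
        if qualifies:
            ep = make_episode(hours_ago=age, qualities={"heavy"}, locations={"chest_center"})
        else:
            ep = make_episode(hours_ago=age, locations={"back_lower"})
        expected = oracle_level([age] if qualifies else [])
        result = classify_heart_check(make_check([ep]), profile, NOW)
        assert result.level.label == expected

    @pytest.mark.parametrize("age,expected", [
        (23.999, "red"), (24.0, "red"), (24.001, "yellow"),
        (167.999, "yellow"), (168.0, "yellow"), (168.001, "green"),
    ])
    def test_window_boundaries_half_open_at_top(self, profile, age, expected):
        ep = make_episode(hours_ago=age, qualities={"heavy"}, locations={"chest_center"})
        assert classify_heart_check(make_check([ep]), profile, NOW).level.label == expected

    def test_future_onset_rejected(self, profile):
        ep = make_episode(hours_ago=1)
        from cardiotriage.core_model import ValidationError

        with pytest.raises(ValidationError):
            classify_heart_check(make_check([ep]), profile, NOW - timedelta(hours=2))

    def test_brute_force_on_random_fixtures(self, profile):
        """1,000 seeded random checks vs per-episode oracle + max severity."""
        rng = np.random.default_rng(42)
        pool_q = ("dull", "heavy", "tight", "pressure", "sharp", "burning")
        pool_l = ("chest_center", "chest_left", "jaw", "back_upper", "arm_left", "axilla_left")
        for _ in range(1000):
            n_ep = int(rng.integers(0, 4))
            episodes, qualifying_ages = [], []
            for _ in range(n_ep):
                age = float(rng.uniform(0, 400))
                ep = make_episode(
                    hours_ago=age,
                    qualities=[q for q in pool_q if rng.random() < 0.3],
                    locations=[l for l in pool_l if rng.random() < 0.3],
                    radiation=[l for l in pool_l if rng.random() < 0.15],
                    associated=[a for a in ASSOCIATED if rng.random() < 0.15],
                )
                episodes.append(ep)
                sim = len(oracle_matched_dims(ep, profile)) >= 2
                if sim or oracle_high_risk(ep, profile):
                    qualifying_ages.append(age)
            result = classify_heart_check(make_check(episodes), profile, NOW)
            assert result.level.label == oracle_level(qualifying_ages)

    def test_monotonicity_adding_episode_never_lowers_level(self, profile):
        rng = np.random.default_rng(3)
        base_eps = [
            make_episode(hours_ago=float(rng.uniform(0, 300)),
                         qualities={"heavy"}, locations={"chest_center"})
            for _ in range(2)
        ]
        for _ in range(100):
            subset = [e for e in base_eps if rng.random() < 0.7]
            extra = make_episode(
                hours_ago=float(rng.uniform(0, 300)),
                qualities=[q for q in ("dull", "heavy", "tight") if rng.random() < 0.5],
                locations=["chest_center"] if rng.random() < 0.5 else ["back_lower"],
            )
            before = classify_heart_check(make_check(subset), profile, NOW).level
            after = classify_heart_check(make_check(subset + [extra]), profile, NOW).level
            assert after >= before

    def test_config_neutrality_everything_green(self, profile):
        config = TriageConfig(
            similarity_min_dimensions=5,
            high_risk_typical_set=frozenset(),
            high_risk_min_new_typical=99,
            high_risk_min_new_associated=99,
        )
        # an episode that would normally be red: identical + new associated, recent
        ep = make_episode(
            hours_ago=1,
            qualities=profile.qualities,
            locations=profile.locations,
            radiation=profile.radiation,
            associated={"dizzy", "faint"},
        )
        result = classify_heart_check(make_check([ep]), profile, NOW, config)
        assert result.level is RiskLevel.GREEN

    def test_rationale_lists_qualifying_episodes(self, profile):
        eps = [
            make_episode(hours_ago=12, qualities={"heavy"}, locations={"chest_center"}),
            make_episode(hours_ago=300, qualities={"heavy"}, locations={"chest_center"}),
            make_episode(hours_ago=5, locations={"back_lower"}),  # non-qualifying
        ]
        result = classify_heart_check(make_check(eps), profile, NOW)
        windows = {r["window"] for r in result.rationale}
        assert len(result.rationale) == 2
        assert windows == {"red", "expired"}

    def test_to_dict_stable_keys(self, profile):
        result = classify_heart_check(make_check([]), profile, NOW)
        assert list(result.to_dict()) == ["level", "recommendation", "rationale"]


class TestTriageConfig:
    def test_defaults(self):
        config = TriageConfig()
        assert config.similarity_min_dimensions == 2
        assert config.high_risk_typical_set == frozenset({"dull", "heavy", "tight"})
        assert config.red_window_hours == 24.0
        assert config.yellow_window_hours == 168.0

    def test_invalid_windows_rejected(self):
        from cardiotriage.core_model import ValidationError

        with pytest.raises(ValidationError):
            TriageConfig(red_window_hours=200, yellow_window_hours=100)

    def test_recommendation_map_is_total(self):
        assert set(RECOMMENDATIONS) == set(RiskLevel)
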