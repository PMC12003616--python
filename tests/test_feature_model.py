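"""Feature vocabulary and composite-feature derivation rules."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pspmax import (
    TIME_CONSTRAINED_FEATURES,
    CbsSubitems,
    Domain,
    FeatureCode,
    FeatureProfile,
    FrontalSubitems,
    LevodopaChallenge,
    PullTestObservation,
    apply_temporal_gate,
    assess_levodopa_resistance,
    derive_cbs,
    derive_frontal_presentation,
    derive_pull_test_feature,
)


class TestVocabulary:
    def test_sixteen_codes_with_domains_and_strata(self):
        assert len(FeatureCode) == 16
        for domain, n in [(Domain.OCULAR_MOTOR, 3), (Domain.POSTURAL_INSTABILITY, 3),
                          (Domain.AKINESIA, 3), (Domain.COGNITIVE, 3),
                          (Domain.CLINICAL_CLUE, 4)]:
            codes = [c for c in FeatureCode if c.domain is domain]
            assert len(codes) == n
            if domain is Domain.CLINICAL_CLUE:
                assert all(c.stratum is None for c in codes)
            else:
                assert sorted(c.stratum for c in codes) == [1, 2, 3]

    def test_starred_set_is_time_constrained(self):
        starred = {c for c in FeatureCode if c.time_constrained}
        assert starred == {FeatureCode.P1, FeatureCode.P2, FeatureCode.P3, FeatureCode.A1}


class TestFeatureProfile:
    def test_onset_only_for_present_features(self):
        with pytest.raises(ValueError, match="absent feature"):
            FeatureProfile.from_codes(["O1"], {"P1": 6})

    def test_onset_must_be_non_negative(self):
        with pytest.raises(ValueError, match=">= 0"):
            FeatureProfile.from_codes(["P1"], {"P1": -1})

    def test_mask_round_trip(self):
        profile = FeatureProfile.from_codes(["O1", "P2", "CC4"])
        assert FeatureProfile.from_mask(profile.mask).present == profile.present


class TestFrontalPresentation:
    def test_matches_three_of_five_threshold_exhaustively(self):
        for flags in itertools.product([False, True], repeat=5):
            items = FrontalSubitems(*flags)
            assert derive_frontal_presentation(items) == (sum(flags) >= 3)

    def test_three_items_qualify_and_two_do_not(self):
        assert derive_frontal_presentation(
            FrontalSubitems(True, True, True, False, False)
        )
        for pair in itertools.combinations(range(5), 2):
            flags = [i in pair for i in range(5)]
            assert not derive_frontal_presentation(FrontalSubitems(*flags))


class TestCbs:
    def test_matches_one_per_category_exhaustively(self):
        for flags in itertools.product([False, True], repeat=6):
            items = CbsSubitems(*flags)
            expected = any(flags[:3]) and any(flags[3:])
            assert derive_cbs(items) == expected

    def test_one_cortical_and_one_movement_sign(self):
        assert derive_cbs(CbsSubitems(False, False, True, True, False, False))
        assert not derive_cbs(CbsSubitems(True, True, True, False, False, False))
        assert not derive_cbs(CbsSubitems(False, False, False, False, False, False))


class TestLevodopaResistance:
    @pytest.mark.parametrize(
        "challenge, expected",
        [
            # 25% improvement under a 200 mg challenge: resistant.
            (LevodopaChallenge(40, 30, challenge_dose_mg=200), True),
            # 50% improvement: responsive.
            (LevodopaChallenge(40, 20, challenge_dose_mg=250), False),
            # Sub-threshold challenge dose, no sustained regimen: not assessable.
            (LevodopaChallenge(40, 30, challenge_dose_mg=100), None),
            # Sustained regimen qualifies at 1000 mg for 30 days.
            (LevodopaChallenge(40, 30, sustained_dose_mg=1000,
                               sustained_duration_days=30), True),
            (LevodopaChallenge(40, 30, sustained_dose_mg=1000,
                               sustained_duration_days=20), None),
            # Exactly 30% improvement still counts as resistant.
            (LevodopaChallenge(100, 70, challenge_dose_mg=200), True),
            # Worsening counts as resistant.
            (LevodopaChallenge(40, 50, challenge_dose_mg=200), True),
            # Zero pre-score leaves the ratio undefined.
            (LevodopaChallenge(0, 0, challenge_dose_mg=200), None),
        ],
    )
    def test_regimen_and_improvement_threshold(self, challenge, expected):
        assert assess_levodopa_resistance(challenge) is expected

    @given(
        pre=st.floats(1, 150),
        post_hi=st.floats(0, 150),
        delta=st.floats(0, 150),
    )
    @settings(derandomize=True, max_examples=200)
    def test_more_improvement_never_flips_to_resistant(self, pre, post_hi, delta):
        post_lo = max(post_hi - delta, 0.0)
        hi = assess_levodopa_resistance(
            LevodopaChallenge(pre, post_hi, challenge_dose_mg=200)
        )
        lo = assess_levodopa_resistance(
            LevodopaChallenge(pre, post_lo, challenge_dose_mg=200)
        )
        # Decreasing the post score (more improvement) can only lose resistance.
        assert not (hi is False and lo is True)


class TestPullTest:
    @pytest.mark.parametrize(
        "obs, expected",
        [
            (PullTestObservation(would_fall_if_not_caught=True), FeatureCode.P2),
            (PullTestObservation(False, steps_backward=3, unaided_recovery=True),
             FeatureCode.P3),
            (PullTestObservation(False, steps_backward=2, unaided_recovery=True), None),
            (PullTestObservation(False, steps_backward=5, unaided_recovery=False), None),
        ],
    )
    def test_outcome_mapping(self, obs, expected):
        assert derive_pull_test_feature(obs) is expected


onset_profiles = st.builds(
    FeatureProfile,
    present=st.frozensets(st.sampled_from(list(FeatureCode))),
).flatmap(
    lambda p: st.fixed_dictionaries(
        {},
        optional={
            code: st.floats(0, 120, allow_nan=False) for code in p.present
        },
    ).map(lambda onsets: FeatureProfile(p.present, onsets))
)


class TestTemporalGate:
    def test_gates_late_starred_features_only(self):
        profile = FeatureProfile.from_codes(
            ["P1", "P2", "A1", "O1"],
            {"P1": 40, "P2": 36, "A1": 37, "O1": 60},
        )
        gated = apply_temporal_gate(profile)
        # P1 and A1 exceed 36 months; P2 sits on the inclusive boundary;
        # O1 is not time-constrained.
        assert gated.present == {FeatureCode.P2, FeatureCode.O1}
        assert FeatureCode.P1 not in gated.onset_month

    def test_features_without_onset_are_trusted(self):
        profile = FeatureProfile.from_codes(["P1"])
        assert apply_temporal_gate(profile) == profile

    @given(profile=onset_profiles)
    @settings(derandomize=True, max_examples=200)
    def test_idempotent_and_only_removes_starred(self, profile):
        once = apply_temporal_gate(profile)
        assert apply_temporal_gate(once) == once
        assert once.present <= profile.present
        assert profile.present - once.present <= TIME_CONSTRAINED_FEATURES

    def test_rejects_non_positive_window(self):
        with pytest.raises(ValueError):
            apply_temporal_gate(FeatureProfile(), 0)
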