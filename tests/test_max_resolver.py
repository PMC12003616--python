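"""MAX resolution of multiple allocations and the 4R-tauopathy flag."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pspmax import (
    MAX_RULE_1,
    MAX_RULE_2,
    MAX_RULE_3,
    TIEBREAK_RULE,
    Allocation,
    Certainty,
    FeatureCode,
    FeatureProfile,
    Phenotype,
    default_resolution,
    flag_4r_tauopathy,
    highest_certainty,
    phenotype_onset,
    resolve_max,
)

O1, O2, P1, P2, A1, A2 = (
    FeatureCode.O1, FeatureCode.O2, FeatureCode.P1,
    FeatureCode.P2, FeatureCode.A1, FeatureCode.A2,
)


class TestPhenotypeOnset:
    def test_earliest_onset_among_satisfying_features(self):
        profile = FeatureProfile({O1, P1}, {O1: 10, P1: 6})
        allocation = Allocation(Phenotype.RS, Certainty.PROBABLE, frozenset({O1, P1}))
        assert phenotype_onset(allocation, profile) == 6

    def test_singleton(self):
        profile = FeatureProfile({A1}, {A1: 3})
        allocation = Allocation(Phenotype.PGF, Certainty.POSSIBLE, frozenset({A1}))
        assert phenotype_onset(allocation, profile) == 3

    def test_unknown_when_any_contributor_lacks_onset(self):
        profile = FeatureProfile({O1, P1}, {O1: 10})
        allocation = Allocation(Phenotype.RS, Certainty.PROBABLE, frozenset({O1, P1}))
        assert phenotype_onset(allocation, profile) is None


class TestResolveMax:
    def test_certainty_extinguishes_lower_allocations(self):
        profile = FeatureProfile({O1, P1})
        allocations = {
            Allocation(Phenotype.RS, Certainty.PROBABLE, frozenset({O1, P1})),
            Allocation(Phenotype.OM, Certainty.POSSIBLE, frozenset({O1})),
            Allocation(Phenotype.PI, Certainty.SUGGESTIVE_OF, frozenset({P1})),
        }
        diagnosis = resolve_max(allocations, profile)
        assert diagnosis.phenotype is Phenotype.RS
        assert {rule for _, rule in diagnosis.extinguished} == {MAX_RULE_1}
        assert len(diagnosis.extinguished) == 2

    def test_earlier_onset_beats_rs_precedence_at_tied_certainty(self):
        profile = FeatureProfile({O1, P1, A1}, {O1: 6, P1: 6, A1: 3})
        rs = Allocation(Phenotype.RS, Certainty.PROBABLE, frozenset({O1, P1}))
        pgf = Allocation(Phenotype.PGF, Certainty.PROBABLE, frozenset({O1, A1}))
        diagnosis = resolve_max({rs, pgf}, profile)
        assert diagnosis.phenotype is Phenotype.PGF
        assert diagnosis.extinguished == ((rs, MAX_RULE_2),)

    def test_rs_prevails_when_all_onsets_equal(self):
        profile = FeatureProfile({O1, P1, A1}, {O1: 6, P1: 6, A1: 6})
        rs = Allocation(Phenotype.RS, Certainty.PROBABLE, frozenset({O1, P1}))
        pgf = Allocation(Phenotype.PGF, Certainty.PROBABLE, frozenset({O1, A1}))
        diagnosis = resolve_max({rs, pgf}, profile)
        assert diagnosis.phenotype is Phenotype.RS
        assert diagnosis.extinguished == ((pgf, MAX_RULE_3),)

    def test_unknown_onset_never_beats_known(self):
        # PGF's onset is unknown (A1 lacks a time); RS has a known onset.
        profile = FeatureProfile({O1, P1, A1}, {O1: 12, P1: 12})
        rs = Allocation(Phenotype.RS, Certainty.PROBABLE, frozenset({O1, P1}))
        pgf = Allocation(Phenotype.PGF, Certainty.PROBABLE, frozenset({O1, A1}))
        diagnosis = resolve_max({rs, pgf}, profile)
        assert diagnosis.phenotype is Phenotype.RS
        assert diagnosis.extinguished == ((pgf, MAX_RULE_2),)

    def test_residual_variant_tie_falls_to_configured_order(self):
        profile = FeatureProfile.from_codes(["C1", "C3"])
        sl = Allocation(Phenotype.SL, Certainty.SUGGESTIVE_OF, frozenset({FeatureCode.C1}))
        cbs = Allocation(Phenotype.CBS, Certainty.SUGGESTIVE_OF, frozenset({FeatureCode.C3}))
        diagnosis = resolve_max({sl, cbs}, profile)
        # PSP-SL precedes PSP-CBS in the shipped tie-break order.
        assert diagnosis.phenotype is Phenotype.SL
        assert diagnosis.extinguished == ((cbs, TIEBREAK_RULE),)

    def test_empty_input_yields_no_diagnosis_and_empty_trace(self):
        diagnosis = resolve_max(set(), FeatureProfile())
        assert diagnosis.final is None
        assert diagnosis.tauopathy_4r is False
        assert diagnosis.extinguished == ()
        assert diagnosis.trace == ()

    def test_partition_and_trace_name_each_extinction_rule(self):
        profile = FeatureProfile({O1, P2, A2})
        allocations = {
            Allocation(Phenotype.RS, Certainty.PROBABLE, frozenset({O1, P2})),
            Allocation(Phenotype.P, Certainty.PROBABLE, frozenset({O1, A2})),
            Allocation(Phenotype.OM, Certainty.POSSIBLE, frozenset({O1})),
            Allocation(Phenotype.PI, Certainty.SUGGESTIVE_OF, frozenset({P2})),
        }
        diagnosis = resolve_max(allocations, profile)
        extinguished = {a for a, _ in diagnosis.extinguished}
        assert extinguished | {diagnosis.final} == allocations
        assert len(diagnosis.extinguished) + 1 == len(allocations)
        assert all(rule for _, rule in diagnosis.extinguished)
        assert diagnosis.trace  # the trace narrates the applied steps

    @given(
        data=st.lists(
            st.tuples(
                st.sampled_from(list(Phenotype)),
                st.sampled_from(list(Certainty)),
            ),
            min_size=1,
            max_size=8,
            unique_by=lambda t: t[0],
        )
    )
    @settings(derandomize=True, max_examples=200)
    def test_single_survivor_at_the_maximum_certainty(self, data):
        allocations = {Allocation(p, c) for p, c in data}
        diagnosis = resolve_max(allocations, FeatureProfile())
        assert diagnosis.final in allocations
        assert diagnosis.certainty == highest_certainty(allocations)
        assert len(diagnosis.extinguished) + 1 == len(allocations)


class TestTauopathyFlag:
    def test_no_diagnosis_is_no(self):
        assert flag_4r_tauopathy(None) is False

    @pytest.mark.parametrize(
        "phenotype, certainty, expected",
        [
            (Phenotype.RS, Certainty.PROBABLE, True),
            (Phenotype.P, Certainty.PROBABLE, True),
            (Phenotype.CBS, Certainty.POSSIBLE, True),
            (Phenotype.CBS, Certainty.SUGGESTIVE_OF, False),
            (Phenotype.OM, Certainty.POSSIBLE, False),
            (Phenotype.PI, Certainty.SUGGESTIVE_OF, False),
        ],
    )
    def test_default_map_probable_psp_or_possible_cbs(self, phenotype, certainty, expected):
        allocation = Allocation(phenotype, certainty)
        assert flag_4r_tauopathy(allocation) is expected

    def test_map_is_total_over_all_pairs(self):
        tau_map = default_resolution().tau_map
        for phenotype in Phenotype:
            for certainty in Certainty:
                assert isinstance(tau_map.is_4r(phenotype, certainty), bool)
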