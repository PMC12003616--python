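import pytest

from pspmax import (
    N_PROFILES,
    FeatureProfile,
    default_rules,
    evaluate_allocations,
)


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def exhaustive_allocations(rules):
    """Allocation sets for every mask over the 16-feature boolean cube.

    Indexed by mask (bit i = i-th feature code in canonical order). Shared
    across the exhaustive equivalence and invariant tests so the sweep runs
    once per session.
    """
    return [
        evaluate_allocations(FeatureProfile.from_mask(mask), rules)
        for mask in range(N_PROFILES)
    ]
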