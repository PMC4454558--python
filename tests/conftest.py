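import pytest
from hypothesis import settings

from sentsim.backends import build_mini_lexicon
from sentsim.preprocess import process

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

# The two outcome statements used as the running worked example: a pair of
# clinical-trial adverse-event sentences with high lexical overlap.
OUTCOME_A = (
    "No clinically relevant adverse events, such as urinary retention, "
    "respiratory disturbances, or wound infections were reported in the "
    "M-ADL group."
)
OUTCOME_B = (
    "Neither intra-operative nor post-operative clinically relevant adverse "
    "events, such as urinary retention, respiratory disturbances, or wound "
    "infections, were observed."
)


@pytest.fixture(scope="session")
def bundle():
    return build_mini_lexicon(0)


@pytest.fixture(scope="session")
def outcome_pair():
    return process(OUTCOME_A), process(OUTCOME_B)


@pytest.fixture(scope="session")
def outcome_pair_nv():
    """The same pair under the stricter nouns+verbs effective-word policy."""
    return (
        process(OUTCOME_A, effective_policy="nouns_verbs"),
        process(OUTCOME_B, effective_policy="nouns_verbs"),
    )
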