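import pytest

from idpseq import permtest, sspredict, synthetic_data


@pytest.fixture(scope="session")
def emission_model():
    return synthetic_data.default_ss_emission_model()


@pytest.fixture(scope="session")
def labeled_corpus(emission_model):
    """A moderate labeled corpus for predictor training tests."""
    return synthetic_data.generate_labeled_corpus(
        emission_model, n=120, length_range=(60, 120), seed=41
    )


@pytest.fixture(scope="session")
def gor_model(labeled_corpus):
    return sspredict.train_gor(labeled_corpus)


@pytest.fixture(scope="session")
def property_suite():
    """The default consensus/aggregation property suite (GOR model cached)."""
    return permtest.default_property_suite()


def count_adjacent_identical(sequence: str) -> float:
    """Number of positions i with sequence[i] == sequence[i+1].

    A genuinely sequence-dependent (non-compositional) property used across
    the permutation tests.
    """
    return float(sum(a == b for a, b in zip(sequence, sequence[1:])))
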