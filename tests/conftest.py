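import pytest

from mhpulse.lexicon import (
    load_default_gazetteer,
    load_default_hcw_lexicon,
    load_default_mh_lexicon,
)
from mhpulse.synthetic import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def mh_lexicon():
    return load_default_mh_lexicon()


@pytest.fixture(scope="session")
def hcw_lexicon():
    return load_default_hcw_lexicon()


@pytest.fixture(scope="session")
def gazetteer():
    return load_default_gazetteer()


@pytest.fixture(scope="session")
def small_corpus():
    """Small synthetic corpus with noise and spam for cascade tests."""
    cfg = SynthConfig(
        n_users=300,
        tweets_per_user_mean=8.0,
        spam_users=2,
        spam_threshold=50,
        seed=11,
    )
    records, gt = generate_corpus(cfg)
    return cfg, records, gt
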