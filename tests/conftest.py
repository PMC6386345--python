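import pytest
from hypothesis import settings

from firstline import FirstLineClassifier, compile_lexicon, default_lexicon

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def lex():
    return default_lexicon()


@pytest.fixture(scope="session")
def matcher(lex):
    return compile_lexicon(lex)


@pytest.fixture(scope="session")
def clf():
    return FirstLineClassifier().fit()


# The eight published one-vs-rest validation tables (tp, fp, fn, tn) at
# n = 17,310, used as exact inputs for metric reproduction tests.
PUBLISHED_TABLES = {
    "platinum_doublet": (2442, 90, 246, 14532),
    "pemetrexed_based": (1974, 159, 140, 15037),
    "bevacizumab_based": (467, 35, 63, 16745),
    "pem_bev": (618, 114, 17, 16561),
    "single_agent": (288, 189, 37, 16796),
    "tki": (1599, 287, 117, 15307),
    "no_treatment": (4844, 895, 642, 10929),
    "unknown": (2836, 473, 981, 13020),
}


@pytest.fixture(scope="session")
def published_tables():
    return PUBLISHED_TABLES
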