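import numpy as np
import pytest

from primetrack.lm_backend import BigramBackend
from primetrack.surprisal import score_corpus
from primetrack.synthetic_data import CohortParams, generate_cohort


def score_cohort(cohort):
    """Fit a bigram backend to the cohort's correct target sentences and score."""
    targets = sorted({r.target for r in cohort.records if r.correct == 1})
    backend = BigramBackend(targets)
    return score_corpus(backend, cohort.records)


@pytest.fixture(scope="session")
def default_cohort():
    """Study-roster cohort (24 PWA / 16 AEM, 15 trials per session)."""
    return generate_cohort(seed=0)


@pytest.fixture(scope="session")
def scored_default(default_cohort):
    return score_cohort(default_cohort)


@pytest.fixture(scope="session")
def large_cohort():
    """A 4x roster at the same rates, for qualitative-pattern checks that
    need statistical resolution beyond the 24/16 study roster."""
    return generate_cohort(CohortParams(n_pwa=96, n_aem=64), seed=0)


@pytest.fixture(scope="session")
def scored_large(large_cohort):
    return score_cohort(large_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
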