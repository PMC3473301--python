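import warnings

import numpy as np
import pytest

from codingseq import synthetic


@pytest.fixture(autouse=True)
def _quiet_em_warnings():
    # tiny corpora in unit tests can push EM to the iteration cap; the
    # returned weights are still the intended ones
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="EM for interpolation weights")
        yield


@pytest.fixture(scope="session")
def small_contrast_fixture():
    """Codon-biased positives with out-of-frame negatives (1:5), 60 positives."""
    return synthetic.make_classification_fixture(
        n_positives=60, length_range=(80, 160), seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
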