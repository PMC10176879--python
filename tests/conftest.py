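import numpy as np
import pytest

from nps_ehr.categories import ALL_CATEGORIES
from nps_ehr.preprocessing import DocTermMatrix, PreprocessConfig
from nps_ehr.synthetic_corpus import SyntheticConfig, generate_corpus

import scipy.sparse as sp


@pytest.fixture(scope="session")
def small_corpus():
    """120 patients, moderate prevalence, default lexicon."""
    config = SyntheticConfig(
        n_patients=120,
        true_prevalence={c: 0.35 for c in ALL_CATEGORIES},
        seed=7,
    )
    docs, gold = generate_corpus(config)
    return config, docs, gold


@pytest.fixture(scope="session")
def small_dtm(small_corpus):
    from nps_ehr.preprocessing import build_doc_term_matrix

    _, docs, _ = small_corpus
    return build_doc_term_matrix(docs, PreprocessConfig())


def make_dtm(array, vocabulary=None, doc_ids=None) -> DocTermMatrix:
    """Wrap a dense array as a DocTermMatrix for unit tests."""
    array = np.asarray(array, dtype=float)
    n, p = array.shape
    vocabulary = vocabulary or [f"f{j}" for j in range(p)]
    doc_ids = doc_ids or [f"d{i}" for i in range(n)]
    return DocTermMatrix(sp.csr_matrix(array), doc_ids, vocabulary)
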