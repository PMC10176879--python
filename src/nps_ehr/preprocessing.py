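"""Text preprocessing: tokenization, negation removal, stemming, n-grams.

The pipeline order is fixed: tokenize -> remove negated phrases -> stop-word
removal and stemming -> unigram/bigram extraction -> counting. Negation
removal runs first so negation cue lists can match surface forms; bigrams
never cross sentence boundaries.
"""

from __future__ import annotations

import hashlib
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from . import _porter

#: Sentence-boundary sentinel kept in token streams to block bigrams and
#: truncate negation windows. Never emitted as a feature.
BOUNDARY = "<s>"

_TOKEN_RE = re.compile(r"[^\W_]+|[.!?;:,\n]", re.UNICODE)
_BOUNDARY_CHARS = set(".!?;:,\n")

DEFAULT_NEGATION_CUES = ("no", "not", "denies", "without", "geen", "zonder")

# small neutral stop list; callers supply domain/language lists
DEFAULT_STOPWORDS = frozenset(
    "the a an and or of in on at to is was were be been has have had "
    "with for from by this that it as".split()
)

_STEMMERS = {
    "identity": lambda token: token,
    "porter": _porter.stem,
    "english": _porter.stem,
}


@dataclass
class PreprocessConfig:
    stopword_list: frozenset[str] = DEFAULT_STOPWORDS
    stemmer: str = "identity"
    negation_cues: tuple[str, ...] = DEFAULT_NEGATION_CUES
    negation_window: int = 3
    lowercase: bool = True
    min_document_frequency: int = 2
    binary_counts: bool = False

    def __post_init__(self) -> None:
        self.stopword_list = frozenset(self.stopword_list)
        self.negation_cues = tuple(self.negation_cues)
        if self.negation_window < 1:
            raise ValueError("negation_window must be >= 1")
        if self.min_document_frequency < 1:
            raise ValueError("min_document_frequency must be >= 1")
        if self.stemmer not in _STEMMERS:
            raise ValueError(
                f"unknown stemmer {self.stemmer!r}; "
                f"available: {sorted(_STEMMERS)}"
            )


def tokenize(text: str, lowercase: bool = True) -> list[str]:
    """Split text into word tokens with internal sentence-boundary markers.

    Tokens are maximal runs of letters/digits; sentence punctuation becomes
    a :data:`BOUNDARY` marker. Consecutive, leading, and trailing markers
    are collapsed away, so ``""`` tokenizes to ``[]``.
    """
    out: list[str] = []
    for match in _TOKEN_RE.findall(text):
        if match in _BOUNDARY_CHARS:
            if out and out[-1] != BOUNDARY:
                out.append(BOUNDARY)
        else:
            out.append(match.lower() if lowercase else match)
    if out and out[-1] == BOUNDARY:
        out.pop()
    return out


def remove_negated_phrases(
    tokens: list[str],
    negation_cues: tuple[str, ...] = DEFAULT_NEGATION_CUES,
    negation_window: int = 3,
) -> list[str]:
    """Drop each negation cue and up to ``negation_window`` following tokens.

    Removal is truncated at a sentence boundary; internal boundary markers
    are retained but leading/trailing/duplicate markers left behind by a
    removal are collapsed.
    """
    cues = set(negation_cues)
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        tok = tokens[i]
        if tok in cues:
            i += 1
            removed = 0
            while i < n and removed < negation_window and tokens[i] != BOUNDARY:
                i += 1
                removed += 1
        else:
            if tok != BOUNDARY or (out and out[-1] != BOUNDARY):
                out.append(tok)
            i += 1
    while out and out[-1] == BOUNDARY:
        out.pop()
    return out


def stem_and_filter(
    tokens: list[str],
    stopword_list: frozenset[str] = DEFAULT_STOPWORDS,
    stemmer: str = "identity",
) -> list[str]:
    """Remove stop-words, then apply the named stemmer."""
    try:
        stem = _STEMMERS[stemmer]
    except KeyError:
        raise ValueError(
            f"unknown stemmer {stemmer!r}; available: {sorted(_STEMMERS)}"
        ) from None
    return [
        tok if tok == BOUNDARY else stem(tok)
        for tok in tokens
        if tok == BOUNDARY or tok not in stopword_list
    ]


def extract_ngrams(tokens: list[str]) -> Counter:
    """Count unigrams plus boundary-respecting adjacent bigrams.

    Bigrams are joined with an underscore; pairs spanning a
    :data:`BOUNDARY` marker are skipped.
    """
    counts: Counter = Counter()
    prev: str | None = None
    for tok in tokens:
        if tok == BOUNDARY:
            prev = None
            continue
        counts[tok] += 1
        if prev is not None:
            counts[f"{prev}_{tok}"] += 1
        prev = tok
    return counts


def preprocess_text(text: str, config: PreprocessConfig) -> Counter:
    """Run the full preprocessing pipeline on one document."""
    tokens = tokenize(text, config.lowercase)
    tokens = remove_negated_phrases(
        tokens, config.negation_cues, config.negation_window
    )
    tokens = stem_and_filter(tokens, config.stopword_list, config.stemmer)
    return extract_ngrams(tokens)


@dataclass
class DocTermMatrix:
    """Documents × n-gram features count matrix with a frozen vocabulary."""

    matrix: sp.csr_matrix
    doc_ids: list[str]
    vocabulary: list[str]
    _vocab_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.doc_ids), len(self.vocabulary)):
            raise ValueError("matrix shape does not match doc_ids × vocabulary")
        self._vocab_index = {f: i for i, f in enumerate(self.vocabulary)}

    @property
    def vocabulary_hash(self) -> str:
        payload = "\n".join(self.vocabulary).encode("utf-8")
        return hashlib.sha256(payload).hexdigest()

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def column(self, feature: str) -> np.ndarray:
        return np.asarray(
            self.matrix[:, self._vocab_index[feature]].todense()
        ).ravel()

    def save(self, prefix) -> None:
        """Write matrix as MTX plus vocabulary and doc-id sidecar files."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        from scipy.io import mmwrite

        mmwrite(str(prefix.with_suffix(".mtx")), self.matrix.tocoo())
        prefix.with_suffix(".vocab.txt").write_text(
            "\n".join(self.vocabulary) + "\n", encoding="utf-8"
        )
        prefix.with_suffix(".docs.txt").write_text(
            "\n".join(self.doc_ids) + "\n", encoding="utf-8"
        )

    @classmethod
    def load(cls, prefix) -> "DocTermMatrix":
        from scipy.io import mmread

        prefix = Path(prefix)
        matrix = sp.csr_matrix(mmread(str(prefix.with_suffix(".mtx"))))
        vocab = prefix.with_suffix(".vocab.txt").read_text(
            encoding="utf-8"
        ).splitlines()
        docs = prefix.with_suffix(".docs.txt").read_text(
            encoding="utf-8"
        ).splitlines()
        return cls(matrix, docs, vocab)


def _doc_stream(corpus) -> list[tuple[str, str]]:
    pairs = []
    for i, doc in enumerate(corpus):
        if hasattr(doc, "doc_id") and hasattr(doc, "text"):
            pairs.append((doc.doc_id, doc.text))
        elif isinstance(doc, str):
            pairs.append((f"doc{i:05d}", doc))
        else:
            doc_id, text = doc
            pairs.append((doc_id, text))
    return pairs


def build_doc_term_matrix(corpus, config: PreprocessConfig) -> DocTermMatrix:
    """Featurize a training corpus, pruning by document frequency.

    The vocabulary keeps features occurring in at least
    ``min_document_frequency`` documents of *this* corpus, sorted
    lexicographically for stable column order.
    """
    pairs = _doc_stream(corpus)
    if not pairs:
        raise ValueError("corpus is empty")
    doc_counts = [preprocess_text(text, config) for _, text in pairs]
    df_counter: Counter = Counter()
    for counts in doc_counts:
        df_counter.update(counts.keys())
    vocabulary = sorted(
        f for f, df in df_counter.items() if df >= config.min_document_frequency
    )
    if not vocabulary:
        raise ValueError(
            "vocabulary is empty after document-frequency pruning; "
            "lower min_document_frequency"
        )
    return _assemble(pairs, doc_counts, vocabulary, config)


def featurize_with_vocabulary(
    corpus, config: PreprocessConfig, vocabulary: list[str]
) -> DocTermMatrix:
    """Featurize a corpus against a frozen training vocabulary.

    Out-of-vocabulary features are dropped; no document-frequency statistics
    of this corpus are consulted, so external data cannot leak into the
    feature space.
    """
    pairs = _doc_stream(corpus)
    doc_counts = [preprocess_text(text, config) for _, text in pairs]
    return _assemble(pairs, doc_counts, list(vocabulary), config)


def _assemble(pairs, doc_counts, vocabulary, config) -> DocTermMatrix:
    index = {f: j for j, f in enumerate(vocabulary)}
    rows, cols, vals = [], [], []
    for i, counts in enumerate(doc_counts):
        for feature, count in counts.items():
            j = index.get(feature)
            if j is not None:
                rows.append(i)
                cols.append(j)
                vals.append(1 if config.binary_counts else count)
    matrix = sp.csr_matrix(
        (vals, (rows, cols)),
        shape=(len(pairs), len(vocabulary)),
        dtype=np.float64,
    )
    return DocTermMatrix(matrix, [doc_id for doc_id, _ in pairs], vocabulary)
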