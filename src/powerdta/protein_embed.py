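"""Protein sequences as overlapping 3-gram "biological words" with learned
word vectors.

A single residue carries little signal on its own, so sequences are
tokenized into overlapping n-grams (n = 3 by default; with 20 amino-acid
letters the vocabulary is bounded by 20^3).  Each word maps to a dense
vector from an embedding dictionary, giving a fixed-shape matrix per
protein: sequences are first cut or zero-padded to a fixed length L
(1000 by default), then split, yielding exactly L - 2 rows.  Words that
straddle the pad boundary or are missing from the dictionary embed as
zero vectors.

The dictionary is pluggable: load one from the standard word2vec text
format, or train one on any corpus with the built-in skip-gram trainer
(negative sampling, single-threaded and fully seeded, so runs are
bit-reproducible).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Reserved pad character; outside the amino-acid alphabet.
PAD_SYMBOL = "0"
DEFAULT_MAX_LEN = 1000
DEFAULT_NGRAM = 3


def split_ngrams(sequence: str, n: int = DEFAULT_NGRAM) -> list[str]:
    """All max(0, L - n + 1) overlapping length-n substrings, stride 1.

    >>> split_ngrams("MKKFD", 3)
    ['MKK', 'KKF', 'KFD']
    """
    if n < 1:
        raise ValueError("n-gram length must be >= 1")
    return [sequence[i:i + n] for i in range(len(sequence) - n + 1)]


def fix_length(sequence: str, max_len: int = DEFAULT_MAX_LEN,
               pad_symbol: str = PAD_SYMBOL) -> str:
    """Truncate to the first max_len residues or right-pad to max_len."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if len(sequence) >= max_len:
        return sequence[:max_len]
    return sequence + pad_symbol * (max_len - len(sequence))


@dataclass
class EmbeddingDictionary:
    """Mapping from 3-letter words to real vectors of one fixed dimension."""

    word_to_vector: dict[str, np.ndarray]

    def __post_init__(self):
        dims = {v.shape for v in self.word_to_vector.values()}
        if len(dims) > 1:
            raise ValueError(f"inconsistent vector shapes: {dims}")

    @property
    def dimension(self) -> int:
        return next(iter(self.word_to_vector.values())).shape[0]

    @property
    def vocabulary_size(self) -> int:
        return len(self.word_to_vector)

    def __contains__(self, word: str) -> bool:
        return word in self.word_to_vector

    def __getitem__(self, word: str) -> np.ndarray:
        return self.word_to_vector[word]

    def save(self, path) -> None:
        """Write in word2vec text format: a count/dimension header line,
        then one `word v1 ... vd` line per word."""
        with open(path, "w") as fh:
            fh.write(f"{self.vocabulary_size} {self.dimension}\n")
            for word, vec in self.word_to_vector.items():
                fh.write(word + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")

    @classmethod
    def load(cls, path) -> "EmbeddingDictionary":
        with open(path) as fh:
            header = fh.readline().split()
            n_words, dim = int(header[0]), int(header[1])
            mapping: dict[str, np.ndarray] = {}
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise ValueError(f"malformed embedding line: {line!r}")
                mapping[parts[0]] = np.array([float(x) for x in parts[1:]])
        if len(mapping) != n_words:
            raise ValueError(
                f"header promised {n_words} words, file has {len(mapping)}")
        return cls(mapping)


@dataclass
class ProteinEmbedding:
    """Fixed-shape (max_len - 2) x d word-vector matrix for one protein."""

    matrix: np.ndarray
    source_length: int


def embed_sequence(sequence: str, dictionary: EmbeddingDictionary,
                   max_len: int = DEFAULT_MAX_LEN) -> ProteinEmbedding:
    """Fix the length, split into 3-grams and look each word up.

    Rows for pad-straddling or out-of-vocabulary words are zero vectors.
    """
    if dictionary.vocabulary_size == 0:
        raise ValueError("embedding dictionary is empty")
    d = dictionary.dimension
    fixed = fix_length(sequence, max_len)
    words = split_ngrams(fixed, DEFAULT_NGRAM)
    matrix = np.zeros((max_len - DEFAULT_NGRAM + 1, d))
    for i, word in enumerate(words):
        if PAD_SYMBOL in word:
            continue
        if word in dictionary:
            matrix[i] = dictionary[word]
        else:
            logger.debug("out-of-vocabulary word %r at position %d", word, i)
    return ProteinEmbedding(matrix=matrix, source_length=len(sequence))


def one_hot_protein(sequence: str, max_len: int = DEFAULT_MAX_LEN) -> np.ndarray:
    """Residue-level one-hot over the 20-letter alphabet, rows past the
    sequence end (and non-standard letters) all-zero.  Ablation encoder."""
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    matrix = np.zeros((max_len, len(AMINO_ACIDS)))
    for i, residue in enumerate(sequence[:max_len]):
        pos = index.get(residue)
        if pos is not None:
            matrix[i, pos] = 1.0
    return matrix


# ---------------------------------------------------------------------------
# Skip-gram word-vector training (negative sampling)
# ---------------------------------------------------------------------------

def train_embedding_dictionary(corpus, d: int = 100, window: int = 5,
                               seed: int = 0, n: int = DEFAULT_NGRAM,
                               min_count: int = 1, epochs: int = 5,
                               negative: int = 5,
                               learning_rate: float = 0.025,
                               ) -> EmbeddingDictionary:
    """Fit skip-gram word vectors on a corpus of protein sequences.

    Each sequence becomes one sentence of overlapping n-grams.  Training
    is plain SGD with negative sampling from the unigram^(3/4)
    distribution, single-threaded, with every random draw taken from one
    seeded generator — identical (corpus, seed) pairs give identical
    vectors.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("corpus is empty")
    sentences = [split_ngrams(seq, n) for seq in corpus]
    counts: dict[str, int] = {}
    for sentence in sentences:
        for word in sentence:
            counts[word] = counts.get(word, 0) + 1
    vocab = sorted(w for w, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError("no word reaches the minimum count")
    word_index = {w: i for i, w in enumerate(vocab)}

    rng = np.random.default_rng(seed)
    w_in = (rng.random((len(vocab), d)) - 0.5) / d
    w_out = np.zeros((len(vocab), d))

    freq = np.array([counts[w] for w in vocab], dtype=float) ** 0.75
    noise_p = freq / freq.sum()

    def sigmoid(x):
        return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))

    for _ in range(epochs):
        for sentence in sentences:
            ids = [word_index[w] for w in sentence if w in word_index]
            for pos, center in enumerate(ids):
                lo = max(0, pos - window)
                hi = min(len(ids), pos + window + 1)
                for ctx_pos in range(lo, hi):
                    if ctx_pos == pos:
                        continue
                    context = ids[ctx_pos]
                    negatives = rng.choice(len(vocab), size=negative,
                                           p=noise_p)
                    targets = np.concatenate(([context], negatives))
                    labels = np.zeros(len(targets))
                    labels[0] = 1.0
                    v = w_in[center]
                    u = w_out[targets]
                    scores = sigmoid(u @ v)
                    gradient = (scores - labels) * learning_rate
                    w_in[center] = v - gradient @ u
                    w_out[targets] -= np.outer(gradient, v)

    return EmbeddingDictionary({w: w_in[word_index[w]].copy() for w in vocab})
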