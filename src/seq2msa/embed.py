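"""Encoder embeddings of unaligned sequences and fixed-size compression.

The encoder of a trained aligner maps a concatenated input sentence to
one vector per token (the decoder is never run).  For n sequences of
total length l the matrix has d x (l + n - 1) entries, which depends on
sequence length; averaging each sequence's token vectors and keeping the
n - 1 pipe-token vectors verbatim compresses it to exactly d x (2n - 1)
entries — a fixed-size representation suitable as a feature vector for
downstream learning.  As a demonstration, an ordinary least-squares
regression on these features recovers the root (ancestral) sequence
length of simulated records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_squared_error, r2_score

from .represent import Sentence
from .types import PIPE


@dataclass
class EmbeddingMatrix:
    """Per-token encoder vectors plus the token ranges of each segment.

    ``segments`` alternates sequence and pipe spans in sentence order:
    [(seq1_start, seq1_end), (pipe1, pipe1+1), (seq2_start, seq2_end), ...],
    half-open, partitioning 0..L.
    """

    values: np.ndarray              # (L, d)
    segments: list[tuple[int, int]]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def n_tokens(self) -> int:
        return self.values.shape[0]

    @property
    def n_sequences(self) -> int:
        return (len(self.segments) + 1) // 2


@dataclass
class CompressedEmbedding:
    """2n - 1 blocks of width d: per-sequence means interleaved with pipe vectors."""

    blocks: np.ndarray              # (2n - 1, d)

    @property
    def d(self) -> int:
        return self.blocks.shape[1]

    @property
    def n_blocks(self) -> int:
        return self.blocks.shape[0]

    @property
    def n_entries(self) -> int:
        return int(self.blocks.size)

    def flat(self) -> np.ndarray:
        return self.blocks.reshape(-1)


def _segment_spans(tokens: list[str]) -> list[tuple[int, int]]:
    spans: list[tuple[int, int]] = []
    start = 0
    for i, t in enumerate(tokens):
        if t == PIPE:
            spans.append((start, i))   # the sequence before this pipe
            spans.append((i, i + 1))   # the pipe itself
            start = i + 1
    spans.append((start, len(tokens)))
    return spans


def extract(model, sentence: Sentence) -> EmbeddingMatrix:
    """Encoder states of a concat sentence, one row per token; decoder skipped.

    Only the concat scheme carries pipe separators, so only it defines the
    segment boundaries the compression step needs.
    """
    if sentence.scheme != "concat":
        raise ValueError(f"segment boundaries are undefined for scheme {sentence.scheme!r}")
    if len(sentence) == 0:
        raise ValueError("empty sentence")
    if len(sentence) > model.config.max_positions:
        raise ValueError(f"input of {len(sentence)} tokens exceeds max_positions="
                         f"{model.config.max_positions}")
    values = model.encode_tokens(sentence.tokens)
    spans = _segment_spans(sentence.tokens)
    for lo, hi in spans:
        if lo >= hi:
            raise ValueError("empty segment between pipes")
    return EmbeddingMatrix(values=np.asarray(values, float), segments=spans)


def compress(matrix: EmbeddingMatrix) -> CompressedEmbedding:
    """Mean-pool each sequence segment; copy pipe vectors verbatim.

    Block order follows the sentence: seq1, pipe1, seq2, pipe2, ..., seqn.
    """
    if not matrix.segments:
        raise ValueError("matrix has no segments")
    blocks = []
    for lo, hi in matrix.segments:
        if lo >= hi:
            raise ValueError(f"empty segment ({lo}, {hi})")
        blocks.append(matrix.values[lo:hi].mean(axis=0))
    return CompressedEmbedding(np.stack(blocks))


@dataclass
class RegressionResult:
    model: LinearRegression
    r2: float
    mse: float
    n_train: int
    n_test: int


def root_length_regression(features: np.ndarray, root_lengths: np.ndarray,
                           test_fraction: float = 0.1,
                           rng: np.random.Generator | None = None) -> RegressionResult:
    """OLS regression of root length on compressed embeddings; held-out scores.

    ``features`` is (n_records, d * (2n - 1)).  The split is 90/10 by
    record by default.  A degenerate design (all features constant) is
    refused rather than silently fit.
    """
    X = np.asarray(features, float)
    y = np.asarray(root_lengths, float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("need one feature row per root length")
    if len(X) < 2:
        raise ValueError("need at least 2 examples")
    if np.ptp(X, axis=0).max() == 0:
        raise ValueError("degenerate design: all features are constant")
    rng = rng or np.random.default_rng(0)
    order = rng.permutation(len(X))
    n_test = max(1, int(round(test_fraction * len(X))))
    test, train = order[:n_test], order[n_test:]
    if len(train) == 0:
        raise ValueError("no training examples left after split")
    reg = LinearRegression().fit(X[train], y[train])
    pred = reg.predict(X[test])
    return RegressionResult(model=reg, r2=float(r2_score(y[test], pred)),
                            mse=float(mean_squared_error(y[test], pred)),
                            n_train=len(train), n_test=len(test))
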