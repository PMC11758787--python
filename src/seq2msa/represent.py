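"""Sentence representations of unaligned sequences and alignments.

A sequence-to-sequence aligner consumes one token sentence and emits one
token sentence, so the k unaligned sequences must be folded into a single
input sentence and the model's output sentence unfolded back into an MSA.

Input schemes
    concat      sequences concatenated with a pipe token "|" between them
    crisscross  characters interleaved round-robin, exhausted sequences
                padded with the gap token

Output schemes
    spaces      the alignment read column-major, one character per token
    pairs       one token per column, the column's k characters joined

Decoding never throws on model output: it returns a verdict describing
why a sentence is not a valid alignment of the given input sequences
(length not divisible by k, a mutated character, a truncated sequence, an
illegal token such as a pipe).  Crisp validity drives the fallback chain
and the coverage statistic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum

from .types import ALPHABETS, GAP, PIPE, Msa, SequenceSet, normalize_gaps

SCHEMES = ("concat", "crisscross", "spaces", "pairs")


@dataclass
class Sentence:
    """A token stream under a named transformation scheme for k sequences."""

    tokens: list[str]
    scheme: str
    k: int

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    def __len__(self) -> int:
        return len(self.tokens)

    def text(self) -> str:
        return " ".join(self.tokens)

    @classmethod
    def from_text(cls, text: str, scheme: str, k: int) -> "Sentence":
        return cls(normalize_gaps(text).split(), scheme, k)


class Reason(str, Enum):
    OK = "ok"
    LENGTH_NOT_DIVISIBLE = "length_not_divisible"
    ROW_LENGTH_MISMATCH = "row_length_mismatch"
    CHARACTER_MUTATION = "character_mutation"
    ILLEGAL_TOKEN = "illegal_token"
    TRUNCATED_SEQUENCE = "truncated_sequence"


@dataclass
class ValidityVerdict:
    valid: bool
    reason: Reason
    detail: str = ""

    def __post_init__(self) -> None:
        assert self.valid == (self.reason is Reason.OK)


OK = ValidityVerdict(True, Reason.OK)


@dataclass
class SchemeVocabulary:
    scheme: str
    alphabet_size: int
    k: int
    tokens: list[str]

    @property
    def size(self) -> int:
        return len(self.tokens)


def vocabulary(scheme: str, alphabet: str = "DNA", k: int = 1) -> SchemeVocabulary:
    """Enumerate the token set of a scheme.

    For ``pairs`` the all-gap column token is excluded (such a column cannot
    exist), giving (A+1)^k - 1 tokens; the single-character schemes have
    A + 1 tokens (the alphabet plus pipe or gap).
    """
    letters = ALPHABETS[alphabet]
    if scheme == "concat":
        toks = list(letters) + [PIPE]
    elif scheme in ("crisscross", "spaces"):
        toks = list(letters) + [GAP]
    elif scheme == "pairs":
        toks = ["".join(t) for t in itertools.product(letters + GAP, repeat=k)]
        toks.remove(GAP * k)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return SchemeVocabulary(scheme, len(letters), k, toks)


# ---------------------------------------------------------------- input side


def encode_concat(seqset: SequenceSet) -> Sentence:
    """seq1 chars, "|", seq2 chars, ... — exactly k-1 pipe tokens."""
    if len(seqset) == 0:
        raise ValueError("empty sequence set")
    tokens: list[str] = []
    for i, s in enumerate(seqset.seqs):
        if i:
            tokens.append(PIPE)
        tokens.extend(s)
    return Sentence(tokens, "concat", len(seqset))


def encode_crisscross(seqset: SequenceSet) -> Sentence:
    """Round-robin interleave; shorter sequences padded with the gap token."""
    if len(seqset) == 0:
        raise ValueError("empty sequence set")
    width = max(len(s) for s in seqset.seqs)
    tokens = [s[t] if t < len(s) else GAP for t in range(width) for s in seqset.seqs]
    return Sentence(tokens, "crisscross", len(seqset))


def decode_crisscross(sentence: Sentence) -> SequenceSet | None:
    """De-interleave and strip padding; None if the length is not divisible by k."""
    k = sentence.k
    if len(sentence) % k:
        return None
    seqs = ["".join(sentence.tokens[i::k]).rstrip(GAP) for i in range(k)]
    return SequenceSet([f"seq{i + 1}" for i in range(k)], seqs)


# --------------------------------------------------------------- output side


def encode_spaces(msa: Msa) -> Sentence:
    """Column-major read-out: column 1's k characters, then column 2's, ..."""
    tokens = [msa.rows[i][c] for c in range(msa.n_columns) for i in range(len(msa))]
    return Sentence(tokens, "spaces", len(msa))


def encode_pairs(msa: Msa) -> Sentence:
    return Sentence([msa.column(c) for c in range(msa.n_columns)], "pairs", len(msa))


def _verdict_against(rows: list[str], seqset: SequenceSet) -> Msa | ValidityVerdict:
    """Shared validation: rows must ungap to the input sequences exactly."""
    for i, row in enumerate(rows):
        got = row.replace(GAP, "")
        want = seqset.seqs[i]
        if got == want:
            continue
        if want.startswith(got):
            return ValidityVerdict(False, Reason.TRUNCATED_SEQUENCE, f"row {i} short by {len(want) - len(got)} characters")
        return ValidityVerdict(False, Reason.CHARACTER_MUTATION, f"row {i} ungaps to {got!r}, expected {want!r}")
    try:
        return Msa(list(seqset.ids), rows, seqset.alphabet)
    except Exception as exc:  # e.g. an all-gap column
        return ValidityVerdict(False, Reason.ILLEGAL_TOKEN, str(exc))


def decode_spaces(sentence: Sentence, seqset: SequenceSet) -> Msa | ValidityVerdict:
    """Reshape a spaces sentence into k rows and validate it against the input.

    Returns the Msa when the sentence is a valid alignment of ``seqset``
    and a ValidityVerdict naming the failure otherwise; never raises on
    model output.
    """
    k = len(seqset)
    allowed = set(ALPHABETS[seqset.alphabet]) | {GAP}
    for t in sentence.tokens:
        if len(t) != 1 or t not in allowed:
            return ValidityVerdict(False, Reason.ILLEGAL_TOKEN, f"token {t!r}")
    if len(sentence) == 0 or len(sentence) % k:
        return ValidityVerdict(False, Reason.LENGTH_NOT_DIVISIBLE, f"{len(sentence)} tokens for {k} rows")
    n_cols = len(sentence) // k
    rows = ["".join(sentence.tokens[c * k + i] for c in range(n_cols)) for i in range(k)]
    return _verdict_against(rows, seqset)


def decode_pairs(sentence: Sentence, seqset: SequenceSet) -> Msa | ValidityVerdict:
    k = len(seqset)
    allowed = set(ALPHABETS[seqset.alphabet]) | {GAP}
    for t in sentence.tokens:
        if len(t) != k or not set(t) <= allowed or set(t) == {GAP}:
            return ValidityVerdict(False, Reason.ILLEGAL_TOKEN, f"token {t!r}")
    if len(sentence) == 0:
        return ValidityVerdict(False, Reason.LENGTH_NOT_DIVISIBLE, "empty sentence")
    rows = ["".join(t[i] for t in sentence.tokens) for i in range(k)]
    return _verdict_against(rows, seqset)


def encode_input(seqset: SequenceSet, scheme: str = "concat") -> Sentence:
    if scheme == "concat":
        return encode_concat(seqset)
    if scheme == "crisscross":
        return encode_crisscross(seqset)
    raise ValueError(f"{scheme!r} is not an input scheme")


def encode_output(msa: Msa, scheme: str = "spaces") -> Sentence:
    if scheme == "spaces":
        return encode_spaces(msa)
    if scheme == "pairs":
        return encode_pairs(msa)
    raise ValueError(f"{scheme!r} is not an output scheme")


def decode_output(sentence: Sentence, seqset: SequenceSet) -> Msa | ValidityVerdict:
    if sentence.scheme == "spaces":
        return decode_spaces(sentence, seqset)
    if sentence.scheme == "pairs":
        return decode_pairs(sentence, seqset)
    raise ValueError(f"{sentence.scheme!r} is not an output scheme")
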