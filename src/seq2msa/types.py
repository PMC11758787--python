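"""Core domain containers: unaligned sequence sets, alignments, trees.

Sequence order is significant everywhere: it defines the concatenation
order of the sentence representations, and permutation identity matters
for ensemble generation.  Nothing in this package ever sorts records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

DNA_ALPHABET = "TCAG"  # stationary-frequency order used by the substitution model
PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
#: gap characters accepted on input (hyphen and en-dash); output is always "-"
GAP_INPUT_CHARS = "-–"
PIPE = "|"

ALPHABETS = {"DNA": DNA_ALPHABET, "protein": PROTEIN_ALPHABET}


class FormatError(ValueError):
    """Malformed input file or record (e.g. ragged alignment rows)."""


class AlphabetError(ValueError):
    """Sequence contains characters outside the declared alphabet."""


def normalize_gaps(s: str) -> str:
    for ch in GAP_INPUT_CHARS[1:]:
        s = s.replace(ch, GAP)
    return s


def infer_alphabet(seqs: Sequence[str]) -> str:
    """Guess DNA vs protein from residue content (gaps ignored)."""
    chars = set("".join(seqs)) - set(GAP_INPUT_CHARS)
    if chars <= set(DNA_ALPHABET):
        return "DNA"
    if chars <= set(PROTEIN_ALPHABET):
        return "protein"
    raise AlphabetError(f"characters {sorted(chars - set(PROTEIN_ALPHABET))!r} fit neither DNA nor protein")


@dataclass
class SequenceSet:
    """Ordered, ungapped uppercase sequences with identifiers."""

    ids: list[str]
    seqs: list[str]
    alphabet: str = "DNA"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError(f"{len(self.ids)} ids for {len(self.seqs)} sequences")
        if self.alphabet not in ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        allowed = set(ALPHABETS[self.alphabet])
        for i, s in enumerate(self.seqs):
            if not s:
                raise ValueError(f"sequence {self.ids[i]!r} is empty")
            bad = set(s) - allowed
            if bad:
                raise AlphabetError(f"sequence {self.ids[i]!r} has characters {sorted(bad)!r} outside {self.alphabet}")

    def __len__(self) -> int:
        return len(self.seqs)

    def permuted(self, perm: Sequence[int]) -> "SequenceSet":
        """Reorder records; ``perm[i]`` is the original index placed at position i."""
        check_permutation(perm, len(self))
        return SequenceSet([self.ids[j] for j in perm], [self.seqs[j] for j in perm], self.alphabet)


@dataclass
class Msa:
    """A gapped alignment: equal-length rows whose ungapped content is the input.

    Invariants enforced: all rows the same positive length, no all-gap
    column, each row ungaps to a nonempty sequence over the alphabet.
    """

    ids: list[str]
    rows: list[str]
    alphabet: str = "DNA"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError(f"{len(self.ids)} ids for {len(self.rows)} rows")
        self.rows = [normalize_gaps(r) for r in self.rows]
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise FormatError(f"alignment rows have unequal lengths {sorted(widths)}")
        if widths == {0}:
            raise FormatError("alignment has zero columns")
        for c in range(self.n_columns):
            if all(r[c] == GAP for r in self.rows):
                raise FormatError(f"column {c} consists entirely of gaps")
        # ungapped rows must be valid sequences; reuse SequenceSet validation
        SequenceSet(self.ids, [r.replace(GAP, "") for r in self.rows], self.alphabet)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.rows)

    def ungapped(self) -> SequenceSet:
        return SequenceSet(list(self.ids), [r.replace(GAP, "") for r in self.rows], self.alphabet)

    def column(self, c: int) -> str:
        return "".join(r[c] for r in self.rows)

    def column_keys(self) -> list[tuple]:
        """Residue-ordinal identity of each column.

        Entry i of a key is the 1-based ordinal of row i's residue within its
        ungapped sequence, or None at a gap.  Two alignments of the same
        sequence set share a column exactly when these keys are equal,
        irrespective of alignment width or column index.
        """
        counters = [0] * len(self.rows)
        keys = []
        for c in range(self.n_columns):
            key = []
            for i, r in enumerate(self.rows):
                if r[c] == GAP:
                    key.append(None)
                else:
                    counters[i] += 1
                    key.append(counters[i])
            keys.append(tuple(key))
        return keys

    def depermuted(self, perm: Sequence[int]) -> "Msa":
        """Undo ``SequenceSet.permuted(perm)``: row at position i returns to index perm[i]."""
        check_permutation(perm, len(self))
        ids = [""] * len(self)
        rows = [""] * len(self)
        for pos, orig in enumerate(perm):
            ids[orig] = self.ids[pos]
            rows[orig] = self.rows[pos]
        return Msa(ids, rows, self.alphabet)


def check_permutation(perm: Sequence[int], k: int) -> None:
    if sorted(perm) != list(range(k)):
        raise ValueError(f"{list(perm)!r} is not a permutation of 0..{k - 1}")


@dataclass
class PhyloTree:
    """Rooted binary tree with branch lengths, as a lightweight node table.

    ``parent[i]`` is the parent index of node i (root has parent -1) and
    ``length[i]`` the length of the branch above node i.  Leaves carry labels;
    internal nodes have label None.  Children of any internal node appear
    after it, so a preorder traversal is simply index order.
    """

    parent: list[int]
    length: list[float]
    labels: list[str | None]

    @property
    def n_leaves(self) -> int:
        return sum(1 for lb in self.labels if lb is not None)

    @property
    def total_length(self) -> float:
        return float(sum(self.length[i] for i in range(len(self.parent)) if self.parent[i] >= 0))

    def children(self, i: int) -> list[int]:
        return [j for j, p in enumerate(self.parent) if p == i]

    def leaf_labels(self) -> list[str]:
        return [lb for lb in self.labels if lb is not None]

    def to_newick(self) -> str:
        def render(i: int) -> str:
            kids = self.children(i)
            if not kids:
                body = self.labels[i] or ""
            else:
                body = "(" + ",".join(render(j) for j in kids) + ")"
            if self.parent[i] >= 0:
                body += f":{self.length[i]:.12g}"
            return body

        root = self.parent.index(-1)
        return render(root) + ";"


@dataclass
class DatasetRecord:
    """One simulated training example: sentence pair plus its provenance.

    ``source``/``target`` are Sentence objects (see .represent); the truth
    alignment and the simulation parameters that produced it ride along.
    """

    source: object
    target: object
    truth: Msa
    params: dict = field(default_factory=dict)
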