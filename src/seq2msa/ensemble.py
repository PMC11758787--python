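"""Alternative alignments by input permutation, and certainty-based selection.

An aligner that consumes its inputs as an ordered sentence produces a
different alignment for each input order, so permuting the k sequences
(k! orders) and/or switching between trained model configurations yields
an ensemble of candidate alignments of the same data.  Columns are
compared by residue identity — which residue ordinals of which rows a
column pairs, not where the column sits — so the same pairing counts as
shared between alignments of different widths.

The column certainty of a column of alignment x against a set Y of
alternatives is the fraction of members of Y containing an identical
column; the alignment certainty is the mean over x's columns.  Selection
scores every valid candidate against the leave-one-out set of the other
candidates and returns the maximizer — a majority vote in which
candidates that agree with many alternatives win.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .represent import Reason, ValidityVerdict
from .types import Msa, SequenceSet, check_permutation

# re-exported conveniences
permute = SequenceSet.permuted
depermute = Msa.depermuted


@dataclass
class Candidate:
    """One ensemble member: a decoded alignment (rows in canonical input order)
    or, when decoding failed, just the verdict explaining why."""

    msa: Msa | None
    config_index: int
    config_name: str
    permutation: tuple[int, ...]
    verdict: ValidityVerdict
    certainty: float | None = None

    @property
    def valid(self) -> bool:
        return self.msa is not None


@dataclass
class AlternativeEnsemble:
    seqset: SequenceSet
    candidates: list[Candidate] = field(default_factory=list)

    def valid_candidates(self) -> list[Candidate]:
        return [c for c in self.candidates if c.valid]


def column_certainty(x: Msa, Y: Sequence[Msa]) -> np.ndarray:
    """Per-column fraction of members of Y containing an identical column.

    Columns are identified by residue ordinals per row (rows in canonical
    order); all alignments must be over the same sequence set.
    """
    if len(Y) == 0:
        raise ValueError("need at least one alternative alignment")
    ref = x.ungapped()
    key_sets = []
    for y in Y:
        u = y.ungapped()
        if u.seqs != ref.seqs or u.ids != ref.ids:
            raise ValueError("alternative alignment is not over the same sequence set")
        key_sets.append(set(y.column_keys()))
    keys = x.column_keys()
    return np.array([sum(k in ks for ks in key_sets) / len(Y) for k in keys])


def alignment_certainty(x: Msa, Y: Sequence[Msa]) -> float:
    """Mean of the column certainties of x against Y."""
    return float(column_certainty(x, Y).mean())


@dataclass
class SelectionReport:
    ranking: list[Candidate]        # valid candidates, best first
    selected: Candidate | None
    n_invalid: int

    @property
    def failed(self) -> bool:
        return self.selected is None


def select_best(candidates: Sequence[Candidate]) -> SelectionReport:
    """Return the valid candidate with the highest leave-one-out certainty.

    Each valid candidate is scored against all the other valid candidates;
    a lone valid candidate gets certainty 1.0 by convention.  Ties break
    by provenance order (configuration first, then permutation order), so
    selection is deterministic.  With no valid candidate the report is a
    failure — a coverage event for the caller.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    valid = [c for c in candidates if c.valid]
    n_invalid = len(candidates) - len(valid)
    for c in valid:
        others = [o.msa for o in valid if o is not c]
        c.certainty = alignment_certainty(c.msa, others) if others else 1.0
    order = sorted(range(len(valid)), key=lambda i: (-valid[i].certainty, i))
    ranking = [valid[i] for i in order]
    return SelectionReport(ranking, ranking[0] if ranking else None, n_invalid)


def sample_permutations(k: int, n: int, rng: np.random.Generator) -> list[tuple[int, ...]]:
    """n distinct permutations of 0..k-1 (identity first), without replacement.

    Requests beyond k! are clamped.  For small k the space is enumerated;
    for larger k distinct permutations are drawn by rejection.
    """
    import logging
    import math
    total = math.factorial(k)
    if n > total:
        logging.getLogger(__name__).warning("only %d permutations exist for k=%d; clamping", total, k)
    n = min(n, total)
    if n == 0:
        return []
    if total <= 5040:  # k <= 7: enumerate, shuffle the non-identity tail
        perms = list(itertools.permutations(range(k)))
        tail = perms[1:]
        rng.shuffle(tail)
        return [perms[0]] + tail[:n - 1]
    chosen = {tuple(range(k))}
    out = [tuple(range(k))]
    while len(out) < n:
        p = tuple(int(i) for i in rng.permutation(k))
        if p not in chosen:
            chosen.add(p)
            out.append(p)
    return out


def generate_alternatives(seqset: SequenceSet, models: Sequence, n_permutations: int,
                          rng: np.random.Generator,
                          aligner: Callable | None = None) -> AlternativeEnsemble:
    """Ensemble of |models| x n_permutations candidates.

    For each model, n_permutations distinct input orders are sampled, the
    permuted input aligned, and the result de-permuted to canonical row
    order; invalid outputs are kept as candidates carrying their verdict.
    ``aligner(model, seqset) -> Msa | ValidityVerdict`` may override the
    default backend call (useful for testing the selection machinery with
    synthetic aligners).
    """
    if not models:
        raise ValueError("need at least one model")
    if aligner is None:
        from .backend import align_with_fallback

        def aligner(model, ss):
            res = align_with_fallback(ss, [model])
            return res.msa if res.valid else res.verdicts[0]

    k = len(seqset)
    ensemble = AlternativeEnsemble(seqset)
    for mi, model in enumerate(models):
        name = getattr(getattr(model, "config", None), "name", f"model{mi}")
        for perm in sample_permutations(k, n_permutations, rng):
            out = aligner(model, seqset.permuted(perm))
            if isinstance(out, Msa):
                ensemble.candidates.append(Candidate(out.depermuted(perm), mi, name, perm,
                                                     ValidityVerdict(True, Reason.OK)))
            else:
                ensemble.candidates.append(Candidate(None, mi, name, perm, out))
    return ensemble


def align_by_certainty(seqset: SequenceSet, models: Sequence, n_permutations: int,
                       rng: np.random.Generator) -> SelectionReport:
    """Generate alternatives and return the certainty-maximizing alignment."""
    ens = generate_alternatives(seqset, models, n_permutations, rng)
    return select_best(ens.candidates)
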