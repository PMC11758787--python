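"""Alternative-alignment ensembles and certainty-based selection."""

import numpy as np
import pytest

from seq2msa import (
    Msa,
    SequenceSet,
    alignment_certainty,
    column_certainty,
    generate_alternatives,
    sample_permutations,
    select_best,
    shuffle_gaps,
)
from seq2msa.ensemble import Candidate
from seq2msa.represent import OK


def cand(msa, i=0, perm=(0, 1)):
    return Candidate(msa, i, f"cfg{i}", tuple(perm), OK)


class TestCertainty:
    X = Msa(["a", "b"], ["AAGT", "ACGT"])
    Y = [Msa(["a", "b"], ["AAG-T", "A-CGT"]), Msa(["a", "b"], ["AAGT", "ACGT"])]

    def test_worked_example_column_certainties(self):
        """AA appears in both alternatives (2/2); AC only in the second (1/2)."""
        cc = column_certainty(self.X, self.Y)
        assert cc[0] == 1.0 and cc[1] == 0.5
        assert list(cc) == [1.0, 0.5, 0.5, 1.0]

    def test_worked_example_alignment_certainty(self):
        assert alignment_certainty(self.X, self.Y) == 0.75

    def test_self_set_gives_all_ones(self):
        assert alignment_certainty(self.X, [self.X]) == 1.0
        assert (column_certainty(self.X, [self.X]) == 1.0).all()

    def test_duplicate_member_never_decreases_certainty(self):
        base = alignment_certainty(self.X, self.Y)
        more = alignment_certainty(self.X, self.Y + [self.X])
        assert more >= base

    def test_mismatched_sequence_sets_rejected(self):
        other = Msa(["a", "b"], ["AAAA", "ACGT"])
        with pytest.raises(ValueError):
            column_certainty(self.X, [other])

    def test_certainty_is_permutation_invariant(self, rng):
        """Permuting inputs and de-permuting candidates leaves certainties unchanged."""
        x = Msa(["a", "b", "c"], ["AAG-T", "A-CGT", "AAC-T"])
        y1 = Msa(["a", "b", "c"], ["AAGT", "ACGT", "AACT"])
        base = alignment_certainty(x, [y1])
        for _ in range(10):
            perm = list(rng.permutation(3))
            xp = Msa([x.ids[j] for j in perm], [x.rows[j] for j in perm]).depermuted(perm)
            y1p = Msa([y1.ids[j] for j in perm], [y1.rows[j] for j in perm]).depermuted(perm)
            assert alignment_certainty(xp, [y1p]) == base


class TestSelectBest:
    def test_majority_duplicate_wins(self):
        a = Msa(["a", "b"], ["AAGT", "ACGT"])
        b = Msa(["a", "b"], ["AAG-T", "A-CGT"])
        rep = select_best([cand(a, 0), cand(a, 1), cand(b, 2)])
        assert rep.selected.msa.rows == a.rows
        assert rep.ranking[0].certainty > rep.ranking[-1].certainty

    def test_single_candidate_certainty_is_one(self):
        a = Msa(["a", "b"], ["AAGT", "ACGT"])
        rep = select_best([cand(a)])
        assert rep.selected.certainty == 1.0

    def test_no_valid_candidate_is_failure(self):
        from seq2msa.represent import Reason, ValidityVerdict
        bad = Candidate(None, 0, "cfg0", (0, 1), ValidityVerdict(False, Reason.CHARACTER_MUTATION))
        rep = select_best([bad])
        assert rep.failed and rep.n_invalid == 1

    def test_ties_break_by_provenance_order(self):
        a = Msa(["a", "b"], ["AAGT", "ACGT"])
        rep = select_best([cand(a, 0), cand(a, 1)])
        assert rep.selected.config_index == 0


class TestPermutations:
    def test_three_sequences_have_six_permutations(self, rng):
        perms = sample_permutations(3, 6, rng)
        assert len(perms) == len(set(perms)) == 6

    def test_request_beyond_factorial_is_clamped(self, rng):
        assert len(sample_permutations(3, 50, rng)) == 6

    def test_identity_always_included(self, rng):
        assert sample_permutations(4, 3, rng)[0] == (0, 1, 2, 3)


class TestGenerateAlternatives:
    @staticmethod
    def _perfect_aligner(truth):
        def align(model, seqset):
            # reorder the truth rows to the permuted input order
            order = [truth.ids.index(i) for i in seqset.ids]
            return Msa([truth.ids[j] for j in order], [truth.rows[j] for j in order],
                       truth.alphabet)
        return align

    def test_ensemble_size_and_determinism(self, small_records):
        truth = small_records[0].truth
        ss = truth.ungapped()
        align = self._perfect_aligner(truth)
        e1 = generate_alternatives(ss, ["m1", "m2"], 4, np.random.default_rng(0), aligner=align)
        e2 = generate_alternatives(ss, ["m1", "m2"], 4, np.random.default_rng(0), aligner=align)
        assert len(e1.candidates) == 2 * 4
        assert [c.permutation for c in e1.candidates] == [c.permutation for c in e2.candidates]

    def test_candidates_are_depermuted_to_canonical_order(self, small_records):
        truth = small_records[0].truth
        ss = truth.ungapped()
        ens = generate_alternatives(ss, ["m"], 6, np.random.default_rng(1),
                                    aligner=self._perfect_aligner(truth))
        for c in ens.candidates:
            assert c.msa.ids == truth.ids
            assert c.msa.rows == truth.rows


class TestSelectionBeatsRandomChoice:
    def test_certainty_selection_on_corrupted_ensembles(self, small_records, rng):
        """Majority voting over truth + corruptions beats a uniformly random pick."""
        from seq2msa import column_score
        sel_cs, rand_cs = [], []
        gappy = [r for r in small_records if "-" in "".join(r.truth.rows)]
        for rec in gappy[:15]:
            cands = []
            for j, moves in enumerate([0, 0, 1, 2, 3, 4]):
                m = shuffle_gaps(rec.truth, moves, rng)
                cands.append(cand(m, j))
            rep = select_best(cands)
            sel_cs.append(column_score(rep.selected.msa, rec.truth).cs)
            rand_cs.append(np.mean([column_score(c.msa, rec.truth).cs for c in cands]))
        assert np.mean(sel_cs) >= np.mean(rand_cs)

    def test_most_accurate_candidate_usually_ranks_first(self, small_records, rng):
        """Across ensembles, rank 1 by certainty is the most frequent home of the best candidate."""
        from seq2msa import column_score
        ranks = []
        gappy = [r for r in small_records if "-" in "".join(r.truth.rows)]
        for rec in gappy[:15]:
            cands = [cand(shuffle_gaps(rec.truth, m, rng), j)
                     for j, m in enumerate([0, 0, 1, 2, 3, 4])]
            rep = select_best(cands)
            scores = [column_score(c.msa, rec.truth).cs for c in rep.ranking]
            ranks.append(int(np.argmax(scores)))  # highest rank of the most accurate
        counts = np.bincount(ranks, minlength=6)
        assert counts[0] == counts.max()
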