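"""Aligner backend: loss closed forms, training contract, fallback chain."""

import math

import numpy as np
import pytest

from seq2msa import (
    Dictionary,
    ModelConfig,
    Msa,
    Sentence,
    SequenceSet,
    align_with_fallback,
    cross_entropy_loss,
    fit,
    pairwise_config,
    simulate_dataset,
    translate,
)
from seq2msa.backend import PRESETS, AlignerModel


class TestCrossEntropy:
    def test_certain_prediction_has_zero_loss(self):
        d = np.eye(5)[[0, 3, 2]]
        assert cross_entropy_loss(d, [0, 3, 2]) == 0.0

    def test_half_probability_gives_ln2(self):
        d = np.array([[0.5, 0.5, 0.0, 0.0, 0.0]])
        assert cross_entropy_loss(d, [0]) == pytest.approx(math.log(2))

    @pytest.mark.parametrize("length", [1, 7, 40])
    def test_uniform_distribution_gives_ln5_for_any_length(self, length):
        d = np.full((length, 5), 0.2)
        assert cross_entropy_loss(d, [0] * length) == pytest.approx(math.log(5))

    def test_zero_probability_is_floored_not_infinite(self):
        d = np.array([[1.0, 0.0]])
        loss = cross_entropy_loss(d, [1])
        assert np.isfinite(loss) and loss > 20

    def test_rows_must_be_distributions(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.array([[0.5, 0.4]]), [0])


class TestConfig:
    def test_max_positions_capped_at_1024(self):
        with pytest.raises(ValueError):
            ModelConfig(max_positions=2048)

    def test_published_presets_metadata(self):
        assert PRESETS["original"].max_tokens == 4096
        assert PRESETS["alternative"].max_tokens == 2048
        for name in ("original", "alternative"):
            p = PRESETS[name]
            assert (p.learning_rate, p.warmup_updates) == (5e-5, 3000)
            assert (p.n_heads, p.embed_dim, p.n_layers) == (16, 1024, 6)


class TestFit:
    def test_training_reduces_loss(self, tiny_model):
        assert tiny_model.loss_history[-1] < tiny_model.loss_history[0]

    def test_same_seed_gives_identical_trajectory(self):
        recs = simulate_dataset(pairwise_config(n_records=40, root_length_range=(6, 9), seed=2))
        data = [(r.source, r.target) for r in recs]
        cfg = ModelConfig(epochs=2, seed=3)
        m1 = fit(data, cfg)
        m2 = fit(data, cfg)
        assert m1.loss_history == m2.loss_history
        assert all(np.array_equal(m1.params[k].data, m2.params[k].data) for k in m1.params)

    def test_warm_start_requires_matching_dictionary(self, tiny_model):
        recs = simulate_dataset(pairwise_config(n_records=5, root_length_range=(6, 9), seed=4))
        data = [(r.source, r.target) for r in recs]
        other = fit(data, ModelConfig(epochs=1), alphabet="protein")
        with pytest.raises(ValueError, match="dictionary"):
            fit(data, ModelConfig(epochs=1), warm_start=other)

    def test_warm_start_beats_random_initialization(self, tiny_model):
        """Transferred weights start with lower loss than fresh ones, across seeds."""
        wins = 0
        for seed in range(5):
            recs = simulate_dataset(pairwise_config(n_records=30, root_length_range=(8, 12),
                                                    seed=100 + seed))
            data = [(r.source, r.target) for r in recs]
            warm = fit(data, ModelConfig(epochs=0, seed=seed), warm_start=tiny_model)
            cold = fit(data, ModelConfig(epochs=0, seed=seed))
            if warm.loss_history[0] <= cold.loss_history[0]:
                wins += 1
        assert wins >= 4
        assert any("warm-start" in p for p in warm.provenance)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            fit([], ModelConfig(epochs=1))


class TestTranslate:
    def test_rejects_overlong_input(self, tiny_model):
        s = Sentence(["A"] * 1025, "concat", 1)
        with pytest.raises(ValueError, match="max_positions"):
            translate(tiny_model, s)

    def test_rejects_empty_input(self, tiny_model):
        with pytest.raises(ValueError):
            translate(tiny_model, Sentence([], "concat", 1))

    def test_deterministic(self, tiny_model):
        s = Sentence(list("ACGTACGT") + ["|"] + list("ACGTACG"), "concat", 2)
        a = translate(tiny_model, s)
        b = translate(tiny_model, s)
        assert a.tokens == b.tokens

    def test_beam_equals_greedy_at_width_one_vs_close(self, tiny_model):
        s = Sentence(list("ACGTACGT") + ["|"] + list("ACGTACGT"), "concat", 2)
        greedy = tiny_model.greedy_decode(s.tokens, 64)
        beam = tiny_model.beam_decode(s.tokens, 64, 2)
        assert isinstance(beam, list) and len(greedy) > 0


class TestFallback:
    @staticmethod
    def _stub(tokens_out):
        """Model stand-in emitting a fixed output sentence."""

        class Stub:
            config = ModelConfig()
            input_scheme = "concat"
            output_scheme = "spaces"

            def greedy_decode(self, tokens, max_out):
                return list(tokens_out)

        return Stub()

    SS = SequenceSet(["a", "b"], ["AAGT", "ACGT"])

    def test_first_valid_model_wins(self):
        truth_tokens = "AAACGGTT"             # column-major read of AAGT/ACGT
        bad_mut = self._stub("AGACGGTT")      # mutated row
        bad_trunc = self._stub("AAAC")        # truncated
        good = self._stub(truth_tokens)
        res = align_with_fallback(self.SS, [bad_mut, bad_trunc, good])
        assert res.valid and res.model_index == 2
        assert [v.reason.value for v in res.verdicts] == ["character_mutation", "truncated_sequence", "ok"]

    def test_valid_first_model_short_circuits(self):
        good = self._stub("AAACGGTT")  # 4 columns -> rows AAGT/ACGT: exactly the inputs
        res = align_with_fallback(self.SS, [good, self._stub("XX")])
        assert res.valid and res.model_index == 0 and len(res.verdicts) == 1

    def test_all_invalid_is_a_failure(self):
        res = align_with_fallback(self.SS, [self._stub("A"), self._stub("C")])
        assert not res.valid and res.msa is None and len(res.verdicts) == 2

    def test_fallback_never_returns_invalid_alignment(self, small_records, rng):
        """Whatever the stubs emit, a returned MSA always ungaps to the input."""
        for rec in small_records[:5]:
            ss = rec.truth.ungapped()
            junk = ["".join(rng.choice(list("ACGT-"), size=20)) for _ in range(3)]
            res = align_with_fallback(ss, [self._stub(j) for j in junk])
            if res.valid:
                assert res.msa.ungapped().seqs == ss.seqs


class TestCheckpointRoundtrip:
    def test_save_load_preserves_behaviour(self, tiny_model, tmp_path):
        p = tmp_path / "model.npz"
        tiny_model.save(p)
        back = AlignerModel.load(p)
        s = Sentence(list("ACGTAC") + ["|"] + list("ACGTAC"), "concat", 2)
        assert translate(back, s).tokens == translate(tiny_model, s).tokens
        assert back.dictionary == tiny_model.dictionary
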