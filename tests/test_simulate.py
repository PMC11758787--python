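"""Evolutionary simulator: trees, indel lengths, substitution dynamics."""

import numpy as np
import pytest
from scipy import stats

from seq2msa import (
    IndelModel,
    PhyloTree,
    SimulationConfig,
    SubstitutionModel,
    evolve,
    sample_tree,
    sample_zipf_length,
    simulate_dataset,
)
from seq2msa.simulate import discrete_gamma_rates


class TestTreeSampling:
    def test_total_length_within_range(self, rng):
        for _ in range(20):
            t = sample_tree(10, (0.05, 0.1), rng)
            assert 0.05 <= t.total_length <= 0.1
            assert t.n_leaves == 10

    def test_two_leaves_degenerate_range(self, rng):
        t = sample_tree(2, (0.1, 0.1), rng)
        assert t.n_leaves == 2
        assert abs(t.total_length - 0.1) < 1e-12

    def test_rejects_single_leaf(self, rng):
        with pytest.raises(ValueError):
            sample_tree(1, (0.05, 0.1), rng)

    def test_mean_total_length_matches_uniform_law(self, rng):
        draws = np.array([sample_tree(4, (0.05, 0.1), rng).total_length for _ in range(1000)])
        se = (0.1 - 0.05) / np.sqrt(12) / np.sqrt(len(draws))
        assert abs(draws.mean() - 0.075) < 3 * se


class TestZipfLengths:
    def test_boundaries(self, rng):
        assert sample_zipf_length(50.0, 50, rng) == 1  # mass collapses to k=1
        assert sample_zipf_length(1.5, 1, rng) == 1
        with pytest.raises(ValueError):
            sample_zipf_length(1.0, 50, rng)

    def test_mean_matches_exact_pmf(self, rng):
        a, m = 2.0, 50
        k = np.arange(1, m + 1)
        exact_mean = (k * k**-a).sum() / (k**-a).sum()
        exact_var = (k**2 * k**-a).sum() / (k**-a).sum() - exact_mean**2
        draws = np.array([sample_zipf_length(a, m, rng) for _ in range(100_000)])
        se = np.sqrt(exact_var / len(draws))
        assert abs(draws.mean() - exact_mean) < 3 * se


class TestSubstitutionModel:
    def test_rate_matrix_rows_sum_to_zero(self):
        for kind in ("GTR+G", "WAG+G"):
            q = SubstitutionModel(kind=kind).Q
            assert np.abs(q.sum(axis=1)).max() < 1e-12

    def test_transition_matrix_is_stochastic_and_converges_to_stationarity(self):
        sm = SubstitutionModel()
        p = sm.transition_matrix(0.5)
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-12
        p_inf = sm.transition_matrix(500.0)
        assert np.abs(p_inf - np.asarray(sm.freqs)).max() < 1e-9

    def test_gamma_categories_average_to_one(self):
        for shape in (0.3, 1.0, 5.0):
            r = discrete_gamma_rates(shape, 4)
            assert abs(r.mean() - 1) < 1e-9

    def test_large_shape_approaches_homogeneous_rates(self):
        r = discrete_gamma_rates(1e6, 4)
        assert np.abs(r - 1).max() < 1e-2

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ValueError):
            SubstitutionModel(freqs=(0.5, 0.3, 0.1, 0.05))


class TestEvolve:
    def test_no_indels_gives_gapless_root_width_alignment(self, rng):
        t = sample_tree(6, (0.05, 0.1), rng)
        msa, ss = evolve(t, 40, SubstitutionModel(), IndelModel(RI=0, RD=0), rng)
        assert msa.n_columns == 40
        assert all("-" not in r for r in msa.rows)
        assert all(len(s) == 40 for s in ss.seqs)

    def test_zero_branch_lengths_copy_the_root(self, rng):
        t = PhyloTree([-1, 0, 0], [0.0, 0.0, 0.0], [None, "seq1", "seq2"])
        msa, ss = evolve(t, 30, SubstitutionModel(), IndelModel(), rng)
        assert ss.seqs[0] == ss.seqs[1]

    def test_leaf_composition_reaches_stationarity(self, rng):
        """Long branch from the root: leaf bases follow the GTR stationary law."""
        sm = SubstitutionModel()
        t = PhyloTree([-1, 0, 0], [0.0, 10.0, 10.0], [None, "seq1", "seq2"])
        msa, ss = evolve(t, 10_000, sm, IndelModel(RI=0, RD=0), rng)
        counts = np.array([ss.seqs[0].count(b) for b in "TCAG"], float)
        freqs = counts / counts.sum()
        se = np.sqrt(np.asarray(sm.freqs) * (1 - np.asarray(sm.freqs)) / 10_000)
        assert (np.abs(freqs - sm.freqs) < 3.5 * se).all()

    def test_rows_ungap_to_leaf_sequences(self, small_records):
        for rec in small_records:
            assert rec.truth.ungapped().seqs == [r.replace("-", "") for r in rec.truth.rows]

    def test_insertion_deletion_event_ratio(self, rng):
        """Insertion vs deletion event counts scale like RI : RD."""
        sm = SubstitutionModel()
        ins = dels = 0
        for _ in range(300):
            t = PhyloTree([-1, 0, 0], [0.0, 0.5, 0.5], [None, "seq1", "seq2"])
            indel = IndelModel(RI=0.04, RD=0.02, AI=1.5, AD=1.5)
            msa, ss = evolve(t, 50, sm, indel, rng)
            # count events from the alignment: root columns missing in a leaf
            # are deletions, extra columns are insertions (proxy via lengths)
            for s in ss.seqs:
                d = len(s) - 50
                if d > 0:
                    ins += d
                elif d < 0:
                    dels += -d
        assert ins > dels  # RI twice RD => materially more inserted than deleted sites

    def test_protein_simulation(self, rng):
        t = sample_tree(3, (0.05, 0.1), rng)
        msa, ss = evolve(t, 25, SubstitutionModel(kind="WAG+G"), IndelModel(), rng)
        assert msa.alphabet == "protein"
        assert set("".join(ss.seqs)) <= set("ARNDCQEGHILKMFPSTWYV")


class TestSimulateDataset:
    def test_reproducible_from_seed(self):
        cfg = SimulationConfig(n_sequences=4, n_records=3, seed=1)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert all(x.truth.rows == y.truth.rows for x, y in zip(a, b))
        assert all(x.params == y.params for x, y in zip(a, b))

    def test_all_records_satisfy_alignment_invariants(self, small_records):
        from seq2msa.types import Msa
        for rec in small_records:
            Msa(rec.truth.ids, rec.truth.rows, rec.truth.alphabet)  # revalidates

    def test_sampled_rates_are_uniform(self):
        cfg = SimulationConfig(n_sequences=2, n_records=400, root_length_range=(5, 8), seed=9)
        recs = simulate_dataset(cfg)
        ri = np.array([r.params["RI"] for r in recs])
        assert stats.kstest(ri, "uniform", args=(0, 0.05)).pvalue > 0.01

    def test_nested_range_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(RI_range=(0.05, 0.0))
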