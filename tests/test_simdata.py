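import logging

import numpy as np
import pytest

from corrank import (
    AR1Cov,
    BlockCov,
    DenseCov,
    ExperimentParams,
    FactorCov,
    IdentityCov,
    SpikeParams,
    ValidationError,
    as_cov_spec,
    brca_like_cov,
    make_trial,
    pooled_t,
    random_split,
    remove_treatment_effects,
    row_standardize,
    sample_correlation,
    simulate_gaussian,
    spike_in,
)
from corrank.evaluation import score_list
from corrank.reranker import rank_by_abs_desc
from corrank.simdata import (
    CASE1_SPIKE,
    CASE2_SPIKE,
    GAUSSIAN_EXPERIMENT,
    GAUSSIAN_SPIKE,
)

from conftest import make_em, rand_em, split_labels


class TestParams:
    def test_spike_params_counts(self):
        sp = SpikeParams(G_plus=200, G_minus=100, x_plus=0.1, x_minus=-0.1)
        assert sp.G_delta == 300

    def test_spike_params_sign_validation(self):
        with pytest.raises(ValidationError):
            SpikeParams(G_plus=1, G_minus=1, x_plus=-0.1, x_minus=-0.1)

    def test_zero_offsets_allowed(self):
        assert SpikeParams(2, 2, 0.0, 0.0).G_delta == 4

    def test_experiment_params_g_star_bound(self):
        with pytest.raises(ValidationError, match="G_star"):
            ExperimentParams(p0=0.5, G=100, G_star=60, M1=5, M2=5)

    def test_presets_match_benchmark_settings(self):
        assert (CASE1_SPIKE.G_plus, CASE1_SPIKE.G_minus) == (200, 100)
        assert CASE1_SPIKE.x_plus == 0.1 and CASE1_SPIKE.p_delta == 0.025
        assert (CASE2_SPIKE.G_plus, CASE2_SPIKE.G_minus) == (600, 600)
        assert CASE2_SPIKE.x_plus == 0.02
        assert (GAUSSIAN_SPIKE.G_plus, GAUSSIAN_SPIKE.G_minus) == (50, 50)
        assert GAUSSIAN_SPIKE.x_plus == 1.0 and GAUSSIAN_SPIKE.p_delta == 0.031
        assert (GAUSSIAN_EXPERIMENT.G, GAUSSIAN_EXPERIMENT.M1,
                GAUSSIAN_EXPERIMENT.M2) == (3226, 10, 10)


class TestRowStandardize:
    def test_forced_small_example(self, tiny_X, tiny_labels):
        Xs = row_standardize(tiny_X, tiny_labels)
        np.testing.assert_allclose(Xs.values[0], [-1.0, 1.0, -1.0, 1.0])

    def test_postconditions(self):
        X = rand_em(40, 24, seed=1)
        labels = split_labels(14, 10)
        Xs = row_standardize(X, labels)
        for cols in (slice(0, 14), slice(14, 24)):
            block = Xs.values[:, cols]
            assert np.abs(block.mean(axis=1)).max() < 1e-12
            np.testing.assert_allclose((block**2).mean(axis=1), 1.0, atol=1e-12)

    def test_per_group_correlation_preserved(self):
        X = rand_em(15, 30, seed=2)
        labels = split_labels(16, 14)
        Xc = remove_treatment_effects(X, labels)
        Xs = row_standardize(X, labels)
        for cols in (slice(0, 16), slice(16, 30)):
            np.testing.assert_allclose(
                sample_correlation(Xs.values[:, cols]),
                sample_correlation(Xc[:, cols]),
                atol=1e-10,
            )

    def test_pooled_correlation_preserved_for_balanced_energy(self):
        # when each gene has identical within-group scale in both groups, the
        # pooled correlation matrix is preserved exactly
        rng = np.random.default_rng(3)
        half = rng.standard_normal((12, 10))
        X = make_em(np.hstack([half, half[:, rng.permutation(10)]]))
        labels = split_labels(10, 10)
        Xc = remove_treatment_effects(X, labels)
        Xs = row_standardize(X, labels)
        np.testing.assert_allclose(
            sample_correlation(Xs.values), sample_correlation(Xc), atol=1e-10
        )

    def test_constant_gene_dropped_with_logged_warning(self, caplog):
        values = np.vstack([np.ones(8), np.random.default_rng(4).standard_normal((3, 8))])
        X = make_em(values)
        with caplog.at_level(logging.WARNING, logger="corrank.simdata"):
            Xs = row_standardize(X, split_labels(4, 4))
        assert Xs.n_genes == 3
        assert "g0" not in set(Xs.gene_ids)
        assert "dropped 1 constant gene" in caplog.text


class TestRandomSplit:
    def test_sizes(self):
        labels = random_split(102, 50, 52, seed=0)
        assert (labels.M1, labels.M2) == (50, 52)

    def test_determinism(self):
        assert random_split(102, 50, 52, seed=5) == random_split(102, 50, 52, seed=5)
        assert random_split(102, 50, 52, seed=5) != random_split(102, 50, 52, seed=6)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="M1"):
            random_split(10, 5, 6, seed=0)

    def test_uniformity_across_seeds(self):
        # each column should land in group 1 with frequency ~ 50/102
        n, M, M1 = 400, 102, 50
        counts = np.zeros(M)
        for seed in range(n):
            labels = random_split(M, M1, 52, seed=seed)
            groups = labels.groups_for([f"s{j + 1}" for j in range(M)])
            counts += groups == 1
        freq = counts / n
        p = M1 / M
        assert np.allclose(freq.mean(), p, atol=1e-12)  # exact by construction
        sd = np.sqrt(p * (1 - p) / n)
        assert np.abs(freq - p).max() < 5 * sd


class TestSpikeIn:
    def test_case1_truth_size(self):
        Xs = rand_em(12000, 8, seed=0)
        labels = split_labels(4, 4)
        td = spike_in(Xs, labels, CASE1_SPIKE, seed=1)
        assert len(td.truth) == 300
        assert sum(1 for v in td.truth.values() if v == +1) == 200
        assert sum(1 for v in td.truth.values() if v == -1) == 100

    def test_case2_truth_size(self):
        Xs = rand_em(12000, 8, seed=0)
        td = spike_in(Xs, split_labels(4, 4), CASE2_SPIKE, seed=2)
        assert len(td.truth) == 1200

    def test_zero_offset_leaves_matrix_unchanged(self):
        Xs = rand_em(50, 8, seed=3)
        sp = SpikeParams(3, 2, 0.0, 0.0)
        td = spike_in(Xs, split_labels(4, 4), sp, seed=4)
        np.testing.assert_array_equal(td.X.values, Xs.values)
        assert len(td.truth) == 5

    def test_conservation_outside_spiked_cells(self):
        Xs = rand_em(100, 10, seed=5)
        labels = split_labels(5, 5)
        sp = SpikeParams(10, 5, 0.7, -0.7)
        td = spike_in(Xs, labels, sp, seed=6)
        spiked_rows = np.array([gid in td.truth for gid in Xs.gene_ids.astype(str)])
        # untouched genes: all columns bit-identical
        np.testing.assert_array_equal(td.X.values[~spiked_rows], Xs.values[~spiked_rows])
        # spiked genes: group-1 columns bit-identical, group-2 shifted by x
        np.testing.assert_array_equal(
            td.X.values[spiked_rows][:, :5], Xs.values[spiked_rows][:, :5]
        )
        for gid, direction in td.truth.items():
            i = int(np.flatnonzero(Xs.gene_ids.astype(str) == gid)[0])
            np.testing.assert_allclose(
                td.X.values[i, 5:] - Xs.values[i, 5:], 0.7 * direction
            )

    def test_overfull_spike_rejected(self):
        Xs = rand_em(10, 8, seed=7)
        with pytest.raises(ValidationError, match="spike"):
            spike_in(Xs, split_labels(4, 4), SpikeParams(8, 8, 1.0, -1.0), seed=0)


class TestSimulateGaussian:
    def test_benchmark_shape(self):
        X = simulate_gaussian(3226, 10, 10, "identity", seed=0)
        assert X.values.shape == (3226, 20)
        assert len(set(X.gene_ids)) == 3226

    def test_identity_correlations_near_zero(self):
        G, M = 150, 60
        X = simulate_gaussian(G, 30, 30, IdentityCov(), seed=1)
        R = np.corrcoef(X.values)
        off = R[np.triu_indices(G, k=1)]
        assert abs(off.mean()) < 3.0 / np.sqrt(G * M)

    def test_block_within_block_correlation(self):
        X = simulate_gaussian(20, 5000, 5000, BlockCov(0.5, 10), seed=2)
        R = np.corrcoef(X.values)
        within = R[:10, :10][np.triu_indices(10, k=1)]
        across = R[:10, 10:]
        assert abs(within.mean() - 0.5) < 0.03
        assert abs(across.mean()) < 0.03

    @pytest.mark.parametrize(
        "cov",
        [BlockCov(0.4, 7), AR1Cov(0.6), FactorCov(4, 0.5, loading_seed=3)],
    )
    def test_sampler_matches_declared_matrix(self, cov):
        G = 30
        X = simulate_gaussian(G, 4000, 4000, cov, seed=4)
        emp = np.cov(X.values)
        np.testing.assert_allclose(emp, cov.matrix(G), atol=0.08)

    def test_dense_cov_roundtrip_and_psd_check(self):
        rng = np.random.default_rng(5)
        L = rng.standard_normal((8, 3))
        A = L @ L.T + np.eye(8)
        X = simulate_gaussian(8, 3000, 3000, DenseCov(A), seed=6)
        np.testing.assert_allclose(np.cov(X.values), A, atol=0.25)
        bad = np.eye(4)
        bad[0, 0] = -1.0
        with pytest.raises(ValidationError, match="positive semi-definite"):
            DenseCov(bad)

    def test_as_cov_spec_coercion(self):
        assert isinstance(as_cov_spec("identity"), IdentityCov)
        assert isinstance(as_cov_spec(np.eye(3)), DenseCov)
        with pytest.raises(ValidationError):
            as_cov_spec("nope")

    def test_brca_like_preset_correlation_strength(self):
        Lam = brca_like_cov().matrix(400)
        off = Lam[np.triu_indices(400, k=1)]
        rms = np.sqrt((off**2).mean())
        assert 0.1 < rms < 0.25  # microarray-strength linear dependence


class TestMakeTrial:
    sp = SpikeParams(5, 5, 0.5, -0.5)
    ep = ExperimentParams(p0=0.5, G=200, G_star=10, M1=10, M2=10)

    def test_bit_identical_reproducibility(self):
        for source in (rand_em(200, 20, seed=0), BlockCov(0.3, 10)):
            a = make_trial(source, self.sp, self.ep, seed=42)
            b = make_trial(source, self.sp, self.ep, seed=42)
            np.testing.assert_array_equal(a.X.values, b.X.values)
            assert a.truth == b.truth and a.labels == b.labels
            c = make_trial(source, self.sp, self.ep, seed=43)
            assert not np.array_equal(a.X.values, c.X.values)

    def test_template_column_subsampling(self):
        # small-sample robustness trials draw a column subset from the template
        template = rand_em(200, 102, seed=1)
        ep = ExperimentParams(p0=0.5, G=200, G_star=10, M1=20, M2=20)
        td = make_trial(template, self.sp, ep, seed=7)
        assert td.X.n_samples == 40
        assert set(td.X.sample_ids) <= set(template.sample_ids)
        assert (td.labels.M1, td.labels.M2) == (20, 20)

    def test_template_gene_count_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="genes"):
            make_trial(rand_em(100, 20, seed=2), self.sp, self.ep, seed=0)

    def test_template_too_few_samples_rejected(self):
        with pytest.raises(ValidationError, match="samples"):
            make_trial(rand_em(200, 10, seed=3), self.sp, self.ep, seed=0)

    def test_trial_is_standardized_wrt_template_groups_not_trial_groups(self):
        # within-trial-group means must NOT all be zero (that would make every
        # null t-statistic exactly zero and trivialize the benchmark)
        td = make_trial(rand_em(200, 20, seed=4), self.sp, self.ep, seed=11)
        groups = td.labels.groups_for(td.X.sample_ids)
        null_rows = ~np.isin(td.X.gene_ids.astype(str), list(td.truth))
        m1 = td.X.values[np.ix_(null_rows, groups == 1)].mean(axis=1)
        m2 = td.X.values[np.ix_(null_rows, groups == 2)].mean(axis=1)
        assert np.abs(m2 - m1).max() > 1e-3

    def test_signal_recovery_independent_genes(self):
        # near-oracle regime: huge effects, independent genes, plain t recovers
        sp = SpikeParams(10, 10, 1.0, -1.0)
        ep = ExperimentParams(p0=0.5, G=500, G_star=20, M1=50, M2=50)
        recovered = []
        for seed in range(20):
            td = make_trial(IdentityCov(), sp, ep, seed=seed)
            t = pooled_t(td.X, td.labels)
            _, order = rank_by_abs_desc(t)
            reported = [str(td.X.gene_ids[i]) for i in order[:20]]
            recovered.append(20 - score_list(reported, td.truth)[0])
        assert np.mean(recovered) >= 18.0

    def test_pure_null_trial_has_fdr_one(self):
        sp = SpikeParams(0, 0, 0.0, 0.0)
        td = make_trial(IdentityCov(), sp, self.ep, seed=5)
        t = pooled_t(td.X, td.labels)
        _, order = rank_by_abs_desc(t)
        reported = [str(td.X.gene_ids[i]) for i in order[:10]]
        F, Fbar = score_list(reported, td.truth)
        assert (F, Fbar) == (10, 1.0)
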