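import numpy as np
import pytest

from sigdecon.matrices import l1_normalize_columns
from sigdecon.simulate import (
    SimulationSpec,
    add_gaussian_noise,
    average_precision,
    flat_signature,
    max_epsilon_scores,
    random_separated_signatures,
    simulate_count_matrix,
    simulate_lda,
    sparsify_exposures,
    spike_in,
    support_auprc,
    support_pr,
)


class TestSimulateLDA:
    def test_relative_exposures_and_burden_law(self):
        W = random_separated_signatures(20, 4, seed=0, sparsity=2.0)
        spec = SimulationSpec(W, n_samples=1000, alpha=0.1, mean_burden=800, seed=1)
        X, H = simulate_lda(spec)
        # mean burden within 3 standard errors of the Poisson mean
        se = np.sqrt(800 / 1000)
        assert abs(X.sum(axis=0).mean() - 800) < 3 * se + 1  # +1 for multinomial rounding
        # absolute exposures per sample sum to the realized burden scale
        np.testing.assert_allclose(H.sum(axis=0), H.sum(axis=0).round(), atol=1e-6)

    def test_invalid_spec(self):
        W = np.eye(3)
        with pytest.raises(ValueError):
            SimulationSpec(W, alpha=0.0)
        with pytest.raises(ValueError):
            SimulationSpec(W, mean_burden=0.0)


class TestSparsify:
    def test_small_entries_zeroed_and_renormalized(self):
        H = np.array([[0.995, 0.6], [0.005, 0.4]])
        out = sparsify_exposures(H, cutoff=0.01)
        np.testing.assert_allclose(out[:, 0], [1.0, 0.0])
        np.testing.assert_allclose(out[:, 1], [0.6, 0.4])

    def test_cutoff_zero_identity(self, rng):
        H = rng.dirichlet([1, 1, 1], size=5).T
        np.testing.assert_allclose(sparsify_exposures(H, 0.0), H)

    def test_all_below_cutoff_errors(self):
        with pytest.raises(ValueError):
            sparsify_exposures(np.full((4, 1), 0.25), cutoff=0.5)


class TestNoise:
    def test_level_zero_identity(self, rng):
        X = rng.poisson(30, (5, 4)).astype(float)
        np.testing.assert_array_equal(add_gaussian_noise(X, 0.0), X)

    def test_empirical_sd_matches_level(self):
        """At level 0.1 a count of 100 is resampled with SD ~ 10."""
        X = np.full((1, 10000), 100.0)
        noisy = add_gaussian_noise(X, 0.1, seed=0)
        assert noisy.std() == pytest.approx(10.0, rel=0.05)
        assert noisy.min() >= 0
        np.testing.assert_array_equal(noisy, np.round(noisy))


class TestSpikeIn:
    def test_fraction_zero_identity(self, rng):
        X = rng.poisson(30, (6, 4)).astype(float)
        np.testing.assert_array_equal(spike_in(X, np.ones(6), 0.0), X)

    def test_added_totals_and_profile(self):
        X = np.full((4, 3), 500.0)
        s = np.array([1.0, 0, 0, 0])
        out = spike_in(X, s, fraction=0.05, seed=0)
        np.testing.assert_array_equal(out.sum(axis=0) - X.sum(axis=0),
                                      np.round(0.05 * X.sum(axis=0)))
        # one-hot spike lands entirely on its channel
        np.testing.assert_array_equal(out[1:], X[1:])


class TestSupportPR:
    def test_perfect(self):
        H = np.array([[1.0, 0], [0, 2]])
        assert support_pr(H, H) == (1.0, 1.0, 1.0)

    def test_half_true_all_predicted(self):
        true = np.array([[1.0, 0], [1, 0]])
        est = np.ones((2, 2))
        p, r, f1 = support_pr(true, est)
        assert (p, r) == (0.5, 1.0)
        assert f1 == pytest.approx(2 / 3)

    def test_nothing_predicted_convention(self):
        true = np.array([[1.0, 0]])
        p, r, f1 = support_pr(true, np.zeros((1, 2)))
        assert (p, r, f1) == (1.0, 0.0, 0.0)


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision([0.9, 0.8, 0.1], [1, 1, 0]) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        """scores [0.9, 0.8, 0.7], labels [1, 0, 1]:
        AP = 0.5*1 + 0.5*(2/3) = 0.8333."""
        assert average_precision([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(
            0.8333, abs=5e-5
        )

    def test_monotone_transform_invariance(self, rng):
        scores = rng.random(12)
        labels = rng.random(12) > 0.5
        if not labels.any():
            labels[0] = True
        a = average_precision(scores, labels)
        b = average_precision(np.exp(5 * scores), labels)
        assert a == pytest.approx(b)

    def test_no_positives_errors(self):
        with pytest.raises(ValueError):
            average_precision([0.5], [0])


class TestDenovoBenchmark:
    def test_oracle_discovery_scores_perfectly(self, toy_catalog):
        """Feeding the true signatures as the de novo set gives precision =
        recall = 1 over a proper threshold range and auPRC 1, with ~zero
        cosine reconstruction error onto the true set."""
        from sigdecon.simulate import denovo_benchmark

        true_ids = ["0", "2", "4"]
        W_denovo = toy_catalog[:, [0, 2, 4]]
        result = denovo_benchmark(true_ids, toy_catalog, W_denovo,
                                  epsilon_grid=np.geomspace(1e-4, 1e-2, 6))
        perfect = (result.precision == 1.0) & (result.recall == 1.0)
        assert perfect.sum() >= 3
        assert result.auprc == pytest.approx(1.0)
        assert np.all(result.denovo_cosine_errors < 1e-10)


class TestNoiseRobustness:
    def test_rank_selection_stable_under_10pct_noise(self):
        """Multiplicative Gaussian count noise at the highest benchmark level
        does not change the selected number of signatures on a
        well-separated cohort."""
        from sigdecon.discovery import select_rank

        W = random_separated_signatures(20, 3, seed=8, sparsity=2.0)
        spec = SimulationSpec(W, n_samples=120, alpha=0.1, mean_burden=2000, seed=4)
        X, _ = simulate_lda(spec)
        kwargs = dict(n_rep=6, lambda_grid=[1e-10, 1e-2, 0.1], seed=0,
                      tol=1e-7, max_iter=2000, gap_n_reference=20)
        clean_r = select_rank(X, range(2, 5), **kwargs).selected_r
        noisy_r = select_rank(
            add_gaussian_noise(X, 0.10, seed=9), range(2, 5), **kwargs
        ).selected_r
        assert clean_r == noisy_r == 3


class TestThresholdSweeps:
    def test_max_epsilon_scores_rank_planted_signatures_highest(self, toy_catalog):
        x = np.round(4000 * (0.7 * toy_catalog[:, 0] + 0.3 * toy_catalog[:, 2]))
        scores = max_epsilon_scores(x, toy_catalog, np.geomspace(1e-4, 1e-1, 8))
        assert scores[0] > 0 and scores[2] > 0
        assert min(scores[0], scores[2]) >= max(np.delete(scores, [0, 2]))

    def test_sparse_auprc_beats_thresholded_on_flat_cohort(self):
        """Cohorts containing two flat-ish signatures: support recovery by the
        likelihood-based stepwise NNLS dominates the thresholded-NNLS
        baseline in auPRC."""
        from sigdecon.simulate import correlated_flat_signatures

        peaked = random_separated_signatures(96, 10, seed=2, sparsity=3.0)
        flats = correlated_flat_signatures(96, 4, seed=3, wobble=0.9)
        W = np.column_stack([peaked, flats])
        spec = SimulationSpec(W, n_samples=40, alpha=0.1, mean_burden=5000,
                              exposure_cutoff=0.01, seed=0)
        X, H_true = simulate_lda(spec)
        eps_grid = np.geomspace(1e-5, 1e-1, 10)
        frac_grid = np.linspace(0.01, 0.3, 10)
        au_sparse = support_auprc(H_true, X, W, eps_grid, "sparse")
        au_thr = support_auprc(H_true, X, W, frac_grid, "thresholded")
        assert au_sparse > au_thr
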