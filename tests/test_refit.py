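import itertools

import numpy as np
import pytest

from sigdecon.matrices import l1_normalize_columns
from sigdecon.refit import (
    clean_matches,
    match_signature,
    nnls,
    per_mutation_loglik,
    sparse_nnls,
    thresholded_nnls,
)
from sigdecon.simulate import flat_signature


def brute_force_nnls(x, W):
    """Exhaustive active-set oracle: best least-squares fit over all supports
    whose unconstrained solution is nonnegative."""
    r = W.shape[1]
    best, best_res = np.zeros(r), float(np.sum(x**2))
    for size in range(1, r + 1):
        for subset in itertools.combinations(range(r), size):
            sub = W[:, subset]
            coef, *_ = np.linalg.lstsq(sub, x, rcond=None)
            if np.all(coef >= -1e-12):
                resid = float(np.sum((x - sub @ np.maximum(coef, 0)) ** 2))
                if resid < best_res - 1e-12:
                    best_res = resid
                    best = np.zeros(r)
                    best[list(subset)] = np.maximum(coef, 0)
    return best


def penalized_support_oracle(x, W, epsilon):
    """Global maximizer of per-mutation log likelihood minus epsilon times the
    support size, by exhaustive support enumeration (independent of the
    stepwise path)."""
    r = W.shape[1]
    best_support, best_score = (), -np.inf
    for size in range(1, r + 1):
        for subset in itertools.combinations(range(r), size):
            h = nnls(x, W, support_mask=subset)
            if h.sum() == 0:
                continue
            score = per_mutation_loglik(x, W, h) - epsilon * np.sum(h > 0)
            if score > best_score + 1e-12:
                best_score = score
                best_support = tuple(sorted(np.flatnonzero(h > 0)))
    return best_support, best_score


class TestNNLS:
    def test_identity_catalog(self):
        h = nnls(np.array([5.0, 3, 2]), np.eye(3))
        np.testing.assert_allclose(h, [5, 3, 2], atol=1e-12)

    def test_consistency_full_rank(self, rng):
        W = rng.random((6, 3)) + 0.1
        h0 = rng.random(3) * 10
        h = nnls(W @ h0, W)
        np.testing.assert_allclose(h, h0, atol=1e-8)

    def test_matches_exhaustive_active_set_oracle(self, rng):
        for _ in range(10):
            W = rng.random((5, 3))
            x = rng.random(5) * 5
            expected = brute_force_nnls(x, W)
            np.testing.assert_allclose(nnls(x, W), expected, atol=1e-8)

    def test_support_mask_forces_zeros(self, rng):
        W = rng.random((5, 4)) + 0.1
        x = rng.random(5)
        h = nnls(x, W, support_mask=[1, 3])
        assert h[0] == 0 and h[2] == 0

    def test_zero_input(self):
        np.testing.assert_array_equal(nnls(np.zeros(3), np.eye(3)), np.zeros(3))


class TestPerMutationLoglik:
    def test_direct_value(self):
        """x=[2,1,1] under w=[0.5,0.25,0.25]:
        (2 log 0.5 + 2 log 0.25) / 4 = -1.0397."""
        val = per_mutation_loglik([2, 1, 1], np.array([[0.5], [0.25], [0.25]]), [4.0])
        assert val == pytest.approx(-1.0397, abs=5e-5)

    def test_invariant_under_exposure_scaling(self, rng):
        W = l1_normalize_columns(rng.random((6, 3)))
        x = rng.poisson(20, 6).astype(float)
        h = rng.random(3)
        base = per_mutation_loglik(x, W, h)
        for c in (0.1, 7.3, 1000.0):
            assert per_mutation_loglik(x, W, c * h) == pytest.approx(base, rel=1e-12)

    def test_equals_negative_kl_minus_entropy(self, rng):
        """Per-mutation log likelihood = -KL(x_hat || w) - H(x_hat)."""
        W = l1_normalize_columns(rng.random((8, 2)) + 0.05)
        x = rng.poisson(30, 8).astype(float) + 1
        h = rng.random(2) + 0.1
        w = W @ h / (W @ h).sum()
        xh = x / x.sum()
        expected = -np.sum(xh * np.log(xh / w)) - (-np.sum(xh * np.log(xh)))
        assert per_mutation_loglik(x, W, h) == pytest.approx(expected, rel=1e-10)


class TestSparseNNLS:
    def test_pure_sample_drops_flat_confounder(self):
        """1000 mutations exactly on e1 against {e1, e2, flat}: the flat
        signature is excluded and the exposure equals the burden."""
        W = np.column_stack([np.eye(3)[:, 0], np.eye(3)[:, 1], np.full(3, 1 / 3)])
        res = sparse_nnls(1000 * np.eye(3)[:, 0], W, epsilon=0.01)
        assert res.support == (0,)
        np.testing.assert_allclose(res.h, [1000, 0, 0], atol=1e-9)

    def test_agrees_with_penalized_support_oracle(self, toy_catalog, rng):
        """On planted mixtures the stepwise fixed point matches the global
        optimum of (log likelihood - epsilon * support size) found by
        exhaustive enumeration."""
        W = toy_catalog
        for seed in range(4):
            g = np.random.default_rng(seed)
            true = g.choice(W.shape[1], size=2, replace=False)
            x = np.round(2000 * W[:, true] @ np.array([0.7, 0.3]))
            res = sparse_nnls(x, W, epsilon=0.005)
            oracle_support, _ = penalized_support_oracle(x, W, 0.005)
            assert res.support == oracle_support

    def test_support_monotone_in_epsilon(self, toy_catalog):
        W = toy_catalog
        x = np.round(3000 * W @ np.array([0.4, 0.3, 0.2, 0.05, 0.04, 0.01]))
        sizes = [
            len(sparse_nnls(x, W, float(e)).support)
            for e in np.geomspace(1e-5, 1e-1, 12)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_self_fit(self, toy_catalog):
        W = toy_catalog
        x = np.round(5000 * W[:, 2])
        res = sparse_nnls(x, W, epsilon=0.01)
        assert res.support == (2,)
        # least-squares exposure approximates the burden (exact only before
        # the integer rounding of the counts)
        assert res.h[2] == pytest.approx(x.sum(), rel=1e-3)

    def test_step_log_respects_threshold(self, toy_catalog, rng):
        """Additions gain more than epsilon; removals cost less than epsilon."""
        W = toy_catalog
        x = rng.poisson(l1_normalize_columns(W @ np.array([[1, 2, 0.5, 0, 0, 0.2]]).T)[:, 0] * 3000)
        res = sparse_nnls(x.astype(float), W, epsilon=0.003)
        for action, j, delta in res.step_log:
            if action == "add":
                assert delta > 0.003
            else:
                assert -delta < 0.003

    def test_requires_positive_epsilon(self):
        with pytest.raises(ValueError):
            sparse_nnls(np.ones(3), np.eye(3), 0.0)


class TestThresholdedNNLS:
    def test_frac_zero_equals_nnls(self, toy_catalog, rng):
        x = rng.poisson(50, toy_catalog.shape[0]).astype(float)
        np.testing.assert_allclose(
            thresholded_nnls(x, toy_catalog, 0.0), nnls(x, toy_catalog)
        )

    def test_minor_signature_zeroed(self):
        W = np.column_stack([np.eye(4)[:, 0], np.eye(4)[:, 1]])
        x = np.array([960.0, 40.0, 0, 0])
        h = thresholded_nnls(x, W, 0.05)
        assert h[1] == 0
        assert h[0] == pytest.approx(960)


class TestMatching:
    def test_catalog_entry_matches_itself(self, toy_catalog):
        weights, res = match_signature(toy_catalog[:, 1], toy_catalog, 0.01)
        assert np.flatnonzero(weights).tolist() == [1]
        assert weights[1] == pytest.approx(1.0)

    def test_planted_mixture_weights(self):
        A = np.eye(6)[:, 0] * 0.9 + 0.02
        B = np.eye(6)[:, 3] * 0.9 + 0.02
        catalog = l1_normalize_columns(np.column_stack([A, B, np.full(6, 1 / 6)]))
        s = 0.5 * catalog[:, 0] + 0.5 * catalog[:, 1]
        weights, _ = match_signature(s, catalog, 0.001)
        assert weights.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(weights[:2], [0.5, 0.5], atol=0.01)
        assert weights[2] == 0

    def test_probability_count_equivalence(self, toy_catalog):
        """Matching a spectrum and refitting a large count vector drawn from
        it produce the same support."""
        s = l1_normalize_columns(
            (0.6 * toy_catalog[:, 0] + 0.4 * toy_catalog[:, 3])[:, None]
        )[:, 0]
        w_match, _ = match_signature(s, toy_catalog, 0.005)
        res_counts = sparse_nnls(np.round(1e6 * s), toy_catalog, 0.005)
        assert tuple(np.flatnonzero(w_match)) == res_counts.support


class TestCleanMatches:
    def test_no_removal_when_conditions_unmet(self, toy_catalog):
        s = toy_catalog[:, 0]
        weights, _ = match_signature(s, toy_catalog, 0.001)
        cleaned = clean_matches(weights, toy_catalog, s)
        np.testing.assert_allclose(cleaned, weights, atol=1e-9)

    def test_flat_background_overfit_removed(self):
        """A sharply peaked de novo spectrum with a tiny flat admixture: the
        matched flat signature fails both rule conditions and is dropped."""
        p = 96
        peak = np.zeros(p)
        peak[:4] = [0.5, 0.3, 0.15, 0.05]
        flat = flat_signature(p)
        catalog = np.column_stack([peak, flat])
        s = l1_normalize_columns((0.97 * peak + 0.03 * flat)[:, None])[:, 0]
        weights = np.array([0.97, 0.03])
        cleaned = clean_matches(weights, catalog, s)
        assert cleaned[1] == 0
        assert cleaned[0] == pytest.approx(1.0)

    def test_own_mass_interpretation_switch(self):
        """Under the alternative 'own-mass' reading a 96-channel flat spectrum
        exceeds 1% at every channel, so condition (1) cannot fire and the flat
        match survives."""
        p = 96
        peak = np.zeros(p)
        peak[:2] = [0.7, 0.3]
        flat = flat_signature(p)
        catalog = np.column_stack([peak, flat])
        s = l1_normalize_columns((0.96 * peak + 0.04 * flat)[:, None])[:, 0]
        out = clean_matches(np.array([0.96, 0.04]), catalog, s, contribution="own")
        assert out[1] > 0
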