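"""Gaussian graphical model estimation: partials, GLASSO path, EBIC."""

import numpy as np
import pytest

import egakit as ek
from egakit.glasso import EstimationSettings

from conftest import random_correlation


def residual_partials(x: np.ndarray) -> np.ndarray:
    """Oracle: partial correlations as correlations of OLS residuals after
    regressing each pair of variables on all remaining ones."""
    n, p = x.shape
    x = x - x.mean(axis=0)
    out = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            rest = [k for k in range(p) if k not in (i, j)]
            z = x[:, rest]
            ri = x[:, i] - z @ np.linalg.lstsq(z, x[:, i], rcond=None)[0]
            rj = x[:, j] - z @ np.linalg.lstsq(z, x[:, j], rcond=None)[0]
            out[i, j] = out[j, i] = np.corrcoef(ri, rj)[0, 1]
    return out


class TestPartialCorrelations:
    def test_identity_gives_zero_partials(self):
        corr = ek.LabeledCorrelationMatrix(tuple("abcd"), np.eye(4), 100)
        np.testing.assert_allclose(ek.partial_correlations(corr), 0.0)

    def test_exchangeable_three_variable_closed_form(self):
        # first-order partial: (0.5 - 0.25) / (1 - 0.25) = 1/3
        vals = np.full((3, 3), 0.5)
        np.fill_diagonal(vals, 1.0)
        corr = ek.LabeledCorrelationMatrix(("a", "b", "c"), vals, 100)
        np.testing.assert_allclose(ek.partial_correlations(corr), (1 / 3) * (1 - np.eye(3)))

    def test_matches_regression_residual_oracle(self):
        rng = np.random.default_rng(42)
        for p in (4, 5, 6):
            x = rng.standard_normal((80, p)) + 0.7 * rng.standard_normal((80, 1))
            corr = ek.LabeledCorrelationMatrix.from_scores(x)
            got = ek.partial_correlations(corr)
            want = residual_partials(x)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_singular_input_raises_with_eigenvalue(self):
        vals = np.ones((3, 3))
        corr = ek.LabeledCorrelationMatrix(("a", "b", "c"), vals, 100)
        with pytest.raises(ek.EstimationError, match="eigenvalue"):
            ek.partial_correlations(corr)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        vals = random_correlation(rng, 5)
        labels = tuple("abcde")
        corr = ek.LabeledCorrelationMatrix(labels, vals, 200)
        perm = [3, 0, 4, 1, 2]
        corr_p = ek.LabeledCorrelationMatrix(
            tuple(labels[i] for i in perm), vals[np.ix_(perm, perm)], 200
        )
        rho = ek.partial_correlations(corr)
        rho_p = ek.partial_correlations(corr_p)
        np.testing.assert_allclose(rho[np.ix_(perm, perm)], rho_p, atol=1e-12)


class TestGlassoFit:
    def test_full_shrinkage_gives_empty_network(self, clean_corr):
        lam_max = np.max(np.abs(clean_corr.values - np.eye(clean_corr.p)))
        net = ek.glasso_fit(clean_corr, lam_max * 1.01)
        assert net.edge_count == 0

    def test_zero_penalty_matches_unregularized_partials(self):
        rng = np.random.default_rng(8)
        vals = random_correlation(rng, 6)
        corr = ek.LabeledCorrelationMatrix(tuple("abcdef"), vals, 300)
        net = ek.glasso_fit(corr, 0.0)
        np.testing.assert_allclose(net.weights, ek.partial_correlations(corr), atol=1e-4)

    def test_block_diagonal_population_has_no_cross_block_edges(self):
        # two orthogonal factors -> exactly zero cross-block partials
        spec = ek.FactorModelSpec.simple(2, 3, 0.7, 0.0)
        corr = ek.implied_correlation(spec).with_n(1000)
        net = ek.glasso_fit(corr, 0.01)
        cross = net.weights[:3, 3:]
        np.testing.assert_allclose(cross, 0.0, atol=1e-6)
        assert np.all(np.abs(net.weights[np.triu_indices(3, 1)]) > 0.1)

    def test_negative_penalty_rejected(self, clean_corr):
        with pytest.raises(ValueError, match="lambda"):
            ek.glasso_fit(clean_corr, -0.1)


class TestEbic:
    def test_gamma_zero_reduces_to_bic(self, clean_corr):
        net = ek.glasso_fit(clean_corr, 0.05)
        theta = net.precision
        n, p = clean_corr.n, clean_corr.p
        ll = (n / 2) * (np.linalg.slogdet(theta)[1] - np.sum(clean_corr.values * theta))
        bic = -2 * ll + net.edge_count * np.log(n)
        assert ek.ebic_score(net, clean_corr, gamma=0.0) == pytest.approx(bic)

    def test_penalty_monotone_in_gamma(self, clean_corr):
        net = ek.glasso_fit(clean_corr, 0.05)
        assert net.edge_count > 0
        assert ek.ebic_score(net, clean_corr, 1.0) > ek.ebic_score(net, clean_corr, 0.5)

    def test_sparser_true_model_wins_on_its_own_data(self):
        # data generated from two orthogonal blocks: the sparse fit that
        # keeps the blocks beats the dense unregularized fit
        spec = ek.FactorModelSpec.simple(2, 3, 0.7, 0.0)
        corr = ek.sample_scores(spec, 2000, 9).correlation()
        dense = ek.glasso_fit(corr, 0.0)
        sparse = ek.glasso_fit(corr, 0.05)
        assert sparse.edge_count < dense.edge_count
        assert ek.ebic_score(sparse, corr) < ek.ebic_score(dense, corr)


class TestEstimateNetwork:
    def test_identity_input_selects_empty_network(self):
        corr = ek.LabeledCorrelationMatrix(tuple("abcde"), np.eye(5), 500)
        assert ek.estimate_network(corr).edge_count == 0

    def test_orthogonal_block_population_recovers_blocks(self):
        spec = ek.FactorModelSpec.simple(3, 4, 0.7, 0.0)
        corr = ek.implied_correlation(spec).with_n(1000)
        net = ek.estimate_network(corr)
        w = net.weights
        for b in range(3):
            blk = slice(4 * b, 4 * b + 4)
            inside = w[blk, blk][np.triu_indices(4, 1)]
            assert np.all(np.abs(inside) > 1e-3)
        assert np.allclose(w[:4, 4:], 0.0, atol=1e-6)

    def test_deterministic(self, clean_corr):
        a = ek.estimate_network(clean_corr)
        b = ek.estimate_network(clean_corr)
        assert a.lam == b.lam
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_selected_model_minimizes_ebic_over_path(self, clean_corr):
        settings = EstimationSettings(n_lambda=25)
        best = ek.estimate_network(clean_corr, settings)
        lam_max = np.max(np.abs(clean_corr.values - np.eye(clean_corr.p)))
        for lam in settings.lambda_grid(lam_max):
            net = ek.glasso_fit(clean_corr, float(lam), settings)
            assert best.ebic <= net.ebic + 1e-9

    def test_edge_count_non_increasing_along_path(self, clean_corr):
        # the glasso active set is not strictly nested: an edge's
        # coefficient can cross zero as lambda decreases, transiently
        # dipping any fixed-threshold count near the crossing.  On the
        # smooth population matrix the exact-zero count is monotone; on
        # sampled data the robust form holds: every clearly present edge
        # stays at least weakly present at the next smaller penalty.
        settings = EstimationSettings(n_lambda=40)
        pop = ek.implied_correlation(ek.wisc_like_preset("three_dim")).with_n(1000)
        lam_max = np.max(np.abs(pop.values - np.eye(pop.p)))
        counts = [
            ek.glasso_fit(pop, float(lam), settings).edge_count
            for lam in settings.lambda_grid(lam_max)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

        iu = np.triu_indices(clean_corr.p, 1)
        lam_max = np.max(np.abs(clean_corr.values - np.eye(clean_corr.p)))
        hi, lo = [], []
        for lam in settings.lambda_grid(lam_max):
            net = ek.glasso_fit(clean_corr, float(lam), settings)
            hi.append(int(np.sum(np.abs(net.weights[iu]) > 5e-3)))
            lo.append(int(np.sum(np.abs(net.weights[iu]) > 5e-4)))
        assert all(hi[i] <= lo[i + 1] for i in range(len(hi) - 1))

    def test_too_few_variables_rejected(self):
        corr = ek.LabeledCorrelationMatrix(("a", "b"), np.eye(2), 50)
        with pytest.raises(ek.EstimationError, match="p >= 3"):
            ek.estimate_network(corr)

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            EstimationSettings(gamma=-0.1)
        with pytest.raises(ValueError):
            EstimationSettings(n_lambda=1)
        with pytest.raises(ValueError):
            EstimationSettings(lambda_min_ratio=1.5)
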