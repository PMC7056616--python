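import numpy as np
import pytest

from copulagraph import (
    FitConfig,
    bootstrap_stability,
    ebic_score,
    estimate_all_cutpoints,
    fit_network,
    fit_path,
    graph_sparsity,
    mixed_specs,
    partial_correlations,
    penalty_grid,
    random_sparse_precision,
    sample_copula_data,
    select_model,
)


class TestEbicScore:
    def test_empty_graph_is_minus_two_loglik(self):
        assert ebic_score(-123.4, 0, 100, 10) == pytest.approx(246.8)

    def test_gamma_zero_reduces_to_bic(self):
        n, df = 250, 7
        assert ebic_score(-50.0, df, n, 20, gamma=0.0) == \
            pytest.approx(100.0 + np.log(n) * df)

    def test_hand_computed_value(self):
        # -2(-500) + (ln 662 + 2 ln 33) * 10
        expected = 1000.0 + (np.log(662) + 2 * np.log(33)) * 10
        assert ebic_score(-500.0, 10, 662, 33, 0.5) == \
            pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(1134.88, abs=0.01)

    def test_increasing_in_df_and_gamma(self):
        base = ebic_score(-100.0, 5, 300, 12, 0.5)
        assert ebic_score(-100.0, 6, 300, 12, 0.5) > base
        assert ebic_score(-100.0, 5, 300, 12, 0.9) > base
        # gamma has no effect on the empty graph
        assert ebic_score(-100.0, 0, 300, 12, 0.9) == \
            ebic_score(-100.0, 0, 300, 12, 0.0)

    def test_double_count_convention(self):
        single = ebic_score(-10.0, 4, 50, 8, 0.5)
        double = ebic_score(-10.0, 4, 50, 8, 0.5, double_count_offdiag=True)
        assert double - 20.0 == pytest.approx(2 * (single - 20.0))

    def test_out_of_range_gamma_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            ebic_score(-1.0, 1, 10, 5, 1.5)


class TestPartialCorrelations:
    def test_identity_gives_zero_partials(self):
        P = partial_correlations(np.eye(4))
        assert np.count_nonzero(P - np.eye(4)) == 0

    def test_two_by_two_hand_value(self):
        omega = np.array([[2.0, -1.0], [-1.0, 2.0]])
        P = partial_correlations(omega)
        assert P[0, 1] == pytest.approx(0.5)

    def test_matches_residual_regression_oracle(self):
        # rho_ij|rest equals the correlation of residuals from regressing
        # i and j on all remaining variables
        rng = np.random.default_rng(314)
        truth = random_sparse_precision(5, 0.4, (0.3, 0.45), "random", seed=6)
        sigma = np.linalg.inv(truth.omega_true)
        X = rng.multivariate_normal(np.zeros(5), sigma, size=4000)
        omega_hat = np.linalg.inv(np.cov(X.T))
        P = partial_correlations(omega_hat)
        for i in range(5):
            for j in range(i + 1, 5):
                rest = [k for k in range(5) if k not in (i, j)]
                A = np.column_stack([X[:, rest], np.ones(len(X))])
                ri = X[:, i] - A @ np.linalg.lstsq(A, X[:, i], rcond=None)[0]
                rj = X[:, j] - A @ np.linalg.lstsq(A, X[:, j], rcond=None)[0]
                assert P[i, j] == pytest.approx(
                    np.corrcoef(ri, rj)[0, 1], abs=1e-6)

    def test_zero_pattern_preserved_exactly(self):
        omega = np.array([[1.0, 0.0, -0.3],
                          [0.0, 1.0, 0.2],
                          [-0.3, 0.2, 1.0]])
        P = partial_correlations(omega)
        assert P[0, 1] == 0.0

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError, match="positive diagonal"):
            partial_correlations(np.diag([1.0, -2.0]))


class TestSignEquivariance:
    def test_reversing_one_ordinal_scale_negates_its_partials(
            self, ordinal_dataset):
        # reversing a variable's level order flips its latent sign, so on
        # refit exactly that row/column of off-diagonal partials negates
        from copulagraph import MixedDataset, em_fit
        data, _ = ordinal_dataset
        flipped_vals = data.values.copy()
        k = data.specs[0].n_levels
        flipped_vals[:, 0] = (k - 1) - flipped_vals[:, 0]
        flipped = MixedDataset(flipped_vals, data.specs, data.missing_mask)
        lam = 0.05
        net_a = partial_correlations(
            em_fit(data, estimate_all_cutpoints(data), lam).omega)
        net_b = partial_correlations(
            em_fit(flipped, estimate_all_cutpoints(flipped), lam).omega)
        flip = np.diag([-1.0, 1.0, 1.0])
        expected = flip @ net_a @ flip
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(net_b, expected, atol=1e-7)


class TestGraphSparsity:
    @pytest.mark.parametrize("omega,expected", [
        (np.eye(4), 0.0),
        (np.ones((4, 4)), 1.0),
        (np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1.0]]), 2 / 3),
    ])
    def test_counting(self, omega, expected):
        assert graph_sparsity(omega) == pytest.approx(expected)


@pytest.fixture(scope="module")
def fitted_path():
    specs = mixed_specs(6, "ordinal", 3)
    truth = random_sparse_precision(6, 0.3, (0.3, 0.4), "random",
                                    seed=41, specs=specs)
    data = sample_copula_data(truth, 500, seed=42)
    cps = estimate_all_cutpoints(data)
    grid = penalty_grid(data, cps, n_lambda=8, min_ratio=0.05)
    return fit_path(data, cps, grid)


@pytest.fixture(scope="module")
def small_fit():
    specs = mixed_specs(5, "ordinal", 3)
    truth = random_sparse_precision(5, 1.0, (0.35, 0.45), "chain",
                                    seed=51, specs=specs)
    data = sample_copula_data(truth, 400, seed=52)
    cfg = FitConfig(n_lambda=8, min_ratio=0.1, seed=53)
    _, net = fit_network(data, cfg)
    return data, cfg, net, truth


class TestSelectModel:
    def test_single_model_path_selects_it(self, continuous_dataset):
        data, _ = continuous_dataset
        cps = estimate_all_cutpoints(data)
        path = fit_path(data, cps, np.array([0.2]))
        net = select_model(path)
        assert net.lam_hat == pytest.approx(0.2)

    def test_tie_broken_toward_sparser_model(self, fitted_path):
        path = fitted_path
        ebic = path.ebic.copy()
        k = int(np.argmin(ebic))
        ebic[min(k + 1, len(path) - 1)] = ebic[k]  # forge an exact tie
        path.ebic = ebic
        net = select_model(path)
        assert net.lam_hat == pytest.approx(path.grid[k])

    def test_selected_sparsity_nonincreasing_in_gamma(self, fitted_path):
        sparsities = [select_model(fitted_path, gamma=g).sparsity
                      for g in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(a >= b for a, b in zip(sparsities, sparsities[1:]))

    def test_partials_zero_exactly_on_missing_edges(self, fitted_path):
        net = select_model(fitted_path, gamma=0.5)
        off = ~np.eye(net.omega.shape[0], dtype=bool)
        assert np.array_equal(net.partials[off] == 0.0,
                              net.omega[off] == 0.0)
        assert np.all(np.abs(net.partials[off]) <= 1.0)

    def test_gamma_half_beats_bic_on_false_edges(self):
        # eBIC (gamma = 1/2) should produce fewer false edges than plain
        # BIC (gamma = 0) on sparse truth, aggregated over seeds
        fp_ebic = fp_bic = 0
        for s in range(8):
            specs = mixed_specs(8, "continuous")
            truth = random_sparse_precision(8, 0.25, (0.3, 0.45), "random",
                                            seed=700 + s, specs=specs)
            data = sample_copula_data(truth, 2000, seed=800 + s)
            cps = estimate_all_cutpoints(data)
            grid = penalty_grid(data, cps, n_lambda=10, min_ratio=0.05)
            path = fit_path(data, cps, grid)
            for gamma, acc in ((0.5, "e"), (0.0, "b")):
                net = select_model(path, gamma=gamma)
                fp = int(np.count_nonzero(
                    np.triu(net.support & ~truth.support, 1)))
                if acc == "e":
                    fp_ebic += fp
                else:
                    fp_bic += fp
        assert fp_ebic <= fp_bic


class TestBootstrapStability:
    def test_same_seed_reproduces_frequencies(self, small_fit):
        data, cfg, net, _ = small_fit
        r1 = bootstrap_stability(data, cfg, B=5, seed=99, original=net)
        r2 = bootstrap_stability(data, cfg, B=5, seed=99, original=net)
        np.testing.assert_array_equal(r1.frequency, r2.frequency)

    def test_frequencies_cover_exactly_original_edges(self, small_fit):
        data, cfg, net, _ = small_fit
        rep = bootstrap_stability(data, cfg, B=4, seed=7, original=net)
        assert np.all(np.isfinite(rep.frequency[net.support]))
        off = ~np.eye(data.p, dtype=bool)
        assert np.all(np.isnan(rep.frequency[off & ~net.support]))
        vals = rep.frequency[net.support]
        assert np.all((vals >= 0) & (vals <= 1))

    def test_two_replicates_give_half_integer_frequencies(self, small_fit):
        data, cfg, net, _ = small_fit
        rep = bootstrap_stability(data, cfg, B=2, seed=11, original=net)
        vals = rep.frequency[net.support]
        assert set(np.round(vals * 2).astype(int)) <= {0, 1, 2}
        np.testing.assert_allclose(vals * 2, np.round(vals * 2), atol=1e-12)

    def test_invalid_b_rejected(self, small_fit):
        data, cfg, net, _ = small_fit
        with pytest.raises(ValueError, match="B"):
            bootstrap_stability(data, cfg, B=0, original=net)

    def test_true_edges_outrank_false_edges(self, small_fit):
        data, cfg, net, truth = small_fit
        rep = bootstrap_stability(data, cfg, B=12, seed=21, original=net)
        full = rep.full_frequency
        iu = np.triu_indices(data.p, 1)
        true_mask = truth.support[iu]
        assert full[iu][true_mask].mean() > full[iu][~true_mask].mean()
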