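"""The nCREANN estimator: lagged design, training, extraction, surrogates."""

import numpy as np
import pytest

from ncreann import (
    NCREANN,
    NMVARSpec,
    build_lagged_dataset,
    select_model_order,
    simulate_nmvar,
    validate_model,
)
from ncreann.model import FoldModel, _lc_from_map, _stack_lags


class TestLaggedDataset:
    def test_row_counting_single_trial(self):
        rng = np.random.default_rng(0)
        ds = build_lagged_dataset(rng.standard_normal((2, 12, 1)), p=10)
        assert ds.n_obs == 2
        assert ds.X.shape == (2, 20)

    def test_rows_never_cross_trial_boundaries(self):
        rng = np.random.default_rng(1)
        ds = build_lagged_dataset(rng.standard_normal((2, 12, 2)), p=10)
        assert ds.n_obs == 4

    def test_columns_exactly_standardized(self):
        rng = np.random.default_rng(2)
        ds = build_lagged_dataset(rng.standard_normal((3, 100, 4)), p=3)
        np.testing.assert_allclose(ds.X.mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(ds.X.std(axis=0), 1, atol=1e-8)
        np.testing.assert_allclose(ds.Y.mean(axis=0), 0, atol=1e-8)

    def test_lag_ordering_node_major(self):
        """Column i*p + (d-1) must hold node i at lag d."""
        x = np.arange(20.0).reshape(1, 20, 1)
        ds = build_lagged_dataset(x, p=3, standardize=False)
        # row r corresponds to time n = p + r; X[r, d-1] = x(n-d)
        assert ds.X[0, 0] == 2.0   # lag 1 of sample 3
        assert ds.X[0, 2] == 0.0   # lag 3
        assert ds.Y[0, 0] == 3.0

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            build_lagged_dataset(np.ones((2, 50, 1)), p=2)

    def test_short_trials_warn_then_error_when_none_usable(self):
        rng = np.random.default_rng(3)
        tcs = rng.standard_normal((2, 5, 2))
        with pytest.warns(UserWarning, match="skipped"):
            with pytest.raises(ValueError, match="no trial long enough"):
                build_lagged_dataset(tcs, p=10)


class TestOrderSelection:
    def test_known_order_recovered(self):
        A = np.zeros((3, 3, 3))
        for i in range(3):
            A[0, i, i] = 0.4
            A[2, i, i] = -0.3
        A[0, 1, 0] = 0.4
        A[2, 2, 1] = 0.3
        hits = 0
        for seed in range(5):
            spec = NMVARSpec(M=3, p=3, A=A, n_samples=20000, seed=seed)
            data, _ = simulate_nmvar(spec)
            sel = select_model_order(data.transpose(1, 2, 0), p_max=6)
            hits += (sel.aic_order == 3) + (sel.bic_order == 3)
        assert hits >= 8

    def test_white_noise_selects_one(self):
        rng = np.random.default_rng(4)
        sel = select_model_order(rng.standard_normal((3, 5000, 1)), p_max=5)
        assert sel.bic_order == 1

    def test_singleton_pmax(self):
        rng = np.random.default_rng(5)
        sel = select_model_order(rng.standard_normal((2, 500, 1)), p_max=1)
        assert sel.selected == 1


class TestLinearExtraction:
    def test_hand_set_network_arithmetic(self):
        """H=1, tanh, b1=0: the first-order map is W2 * g'(0) * W1 and
        the lag-mean absolute coefficient follows directly."""
        fm = FoldModel(W1=np.array([[0.5, -0.3]]), b1=np.zeros(1),
                       W2=np.array([[1.0]]), b2=np.zeros(1),
                       train_idx=None, val_idx=None, test_idx=None,
                       n_epochs=0)
        A_full = fm.linear_map()
        np.testing.assert_allclose(A_full, [[0.5, -0.3]])
        A = _stack_lags(A_full, M=1, p=2)
        assert A[0, 0, 0] == 0.5 and A[1, 0, 0] == -0.3
        lC = _lc_from_map(A_full, M=1, p=2)
        assert lC[0, 0] == pytest.approx(0.4)

    def test_zero_output_weights_zero_lc(self):
        fm = FoldModel(W1=np.ones((4, 6)), b1=np.zeros(4),
                       W2=np.zeros((3, 4)), b2=np.zeros(3),
                       train_idx=None, val_idx=None, test_idx=None,
                       n_epochs=0)
        np.testing.assert_array_equal(_lc_from_map(fm.linear_map(), 3, 2),
                                      np.zeros((3, 3)))

    def test_directed_asymmetry_on_unidirectional_coupling(self):
        """VAR(1) with a_21=0.8, a_12=0: extracted coefficients match
        OLS and the 1->2 connection dominates 2->1."""
        A = np.array([[[0.5, 0.0], [0.8, 0.3]]])
        spec = NMVARSpec(M=2, p=1, A=A, noise_sd=0.5, n_samples=20000,
                         seed=6)
        data, _ = simulate_nmvar(spec)
        mod = NCREANN.from_trials(data, order=1, hidden=10)
        res = mod.fit(folds=3, seed=0)
        coefs, *_ = np.linalg.lstsq(mod.data.X, mod.data.Y, rcond=None)
        A_net = np.mean([fm.linear_map() for fm in res.fold_models], axis=0)
        assert np.abs(A_net - coefs.T).max() < 0.1
        assert res.lC[1, 0] > 5 * res.lC[0, 1]


class TestTraining:
    def test_bit_reproducible_given_seed(self, dense_var_data):
        _, data, _ = dense_var_data
        short = data[:, :, :3000]
        r1 = NCREANN.from_trials(short, order=2).fit(folds=2, max_epochs=20,
                                                     seed=9)
        r2 = NCREANN.from_trials(short, order=2).fit(folds=2, max_epochs=20,
                                                     seed=9)
        for f1, f2 in zip(r1.fold_models, r2.fold_models):
            np.testing.assert_array_equal(f1.W1, f2.W1)
            np.testing.assert_array_equal(f1.W2, f2.W2)

    def test_shuffled_targets_have_no_predictable_signal(self, dense_var_data):
        _, data, _ = dense_var_data
        mod = NCREANN.from_trials(data[:, :, :6000], order=2)
        rng = np.random.default_rng(10)
        mod.data.Y = mod.data.Y[rng.permutation(mod.data.n_obs)]
        res = mod.fit(folds=2, max_epochs=40, seed=1)
        assert res.r2_test.mean() <= 0.05

    def test_amplitude_scaling_invariance(self, dense_var_data):
        """Doubling all node amplitudes changes nothing after z-scoring."""
        _, data, _ = dense_var_data
        short = data[:, :, :3000]
        r1 = NCREANN.from_trials(short, order=2).fit(folds=2, max_epochs=25,
                                                     seed=3)
        r2 = NCREANN.from_trials(2.0 * short, order=2).fit(
            folds=2, max_epochs=25, seed=3)
        np.testing.assert_allclose(r1.lC, r2.lC, atol=1e-12)
        np.testing.assert_allclose(r1.NC, r2.NC, atol=1e-12)

    def test_node_relabeling_equivariance(self, dense_var_data):
        """Permuting node labels permutes lC rows/columns (up to
        training noise, since RNG streams differ per layout)."""
        _, data, _ = dense_var_data
        short = data[:, :, :12000]
        perm = [2, 0, 1]
        r1 = NCREANN.from_trials(short, order=2).fit(folds=3, seed=4)
        r2 = NCREANN.from_trials(short[:, perm], order=2).fit(folds=3, seed=4)
        lC_perm = r1.lC[np.ix_(perm, perm)]
        assert np.abs(r2.lC - lC_perm).max() < 0.08


class TestNonlinearConnectivity:
    def test_restricting_disconnected_node_gives_zero(self):
        """If node i has zero weights into the network, linearizing it
        changes nothing: its NC column is exactly ln(1) = 0."""
        rng = np.random.default_rng(11)
        data, _ = simulate_nmvar(NMVARSpec(
            M=2, p=1, A=np.array([[[0.5, 0.0], [0.0, 0.5]]]),
            n_samples=500, seed=12))
        mod = NCREANN.from_trials(data, order=1, hidden=4)
        W1 = rng.uniform(-0.5, 0.5, (4, 2))
        W1[:, 1] = 0.0  # node 1 (its only lag column) disconnected
        fm = FoldModel(W1, rng.uniform(-0.5, 0.5, 4),
                       rng.uniform(-0.5, 0.5, (2, 4)),
                       rng.uniform(-0.5, 0.5, 2),
                       train_idx=np.arange(10), val_idx=np.arange(10),
                       test_idx=np.arange(mod.data.n_obs), n_epochs=0)
        from ncreann.model import _nc_from_fold
        NC = _nc_from_fold(fm, mod.data, fm.linear_map())
        np.testing.assert_allclose(NC[:, 1], 0.0, atol=1e-12)


class TestValidation:
    def test_perfect_predictor(self):
        y = np.random.default_rng(0).standard_normal((50, 2))
        mse, r2 = validate_model(y.copy(), y)
        assert mse == 0 and r2 == 1

    def test_mean_predictor_r2_zero(self):
        y = np.random.default_rng(1).standard_normal((50, 2))
        pred = np.tile(y.mean(axis=0), (50, 1))
        _, r2 = validate_model(pred, y)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_targets_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            validate_model(np.ones((10, 1)), np.ones((10, 1)))

    def test_network_mse_close_to_ols_floor_on_linear_data(self,
                                                           dense_var_data):
        _, data, _ = dense_var_data
        mod = NCREANN.from_trials(data, order=2)
        res = mod.fit(folds=2, seed=5)
        coefs, *_ = np.linalg.lstsq(mod.data.X, mod.data.Y, rcond=None)
        resid = mod.data.Y - mod.data.X @ coefs
        ols_mse = float((resid ** 2).mean())
        assert res.mse_test.mean() <= 1.1 * ols_mse


class TestSurrogates:
    def test_few_surrogates_warn(self):
        rng = np.random.default_rng(13)
        tcs = rng.standard_normal((2, 200, 1))
        from ncreann.model import surrogate_significance
        with pytest.warns(UserWarning, match="unstable"):
            surrogate_significance(tcs, 1, hidden=3,
                                   fit_kwargs=dict(folds=1, max_epochs=3),
                                   n_surrogates=3, seed=0)

    def test_time_shift_preserves_marginals(self):
        from ncreann.model import _time_shift
        rng = np.random.default_rng(14)
        tcs = rng.standard_normal((3, 100, 2))
        shifted = _time_shift(tcs, rng)
        for i in range(3):
            for tr in range(2):
                np.testing.assert_allclose(
                    np.sort(shifted[i, :, tr]), np.sort(tcs[i, :, tr]))


class TestAgainstStatsmodels:
    def test_ols_var_step_matches_statsmodels(self):
        """The OLS VAR underlying order selection and oracle
        comparisons agrees with statsmodels' independent VAR fit."""
        from statsmodels.tsa.api import VAR
        A = np.array([[[0.5, 0.2], [-0.3, 0.4]]])
        data, _ = simulate_nmvar(NMVARSpec(M=2, p=1, A=A, n_samples=5000,
                                           seed=0))
        sm = VAR(data[0].T).fit(maxlags=1, trend="n")
        ds = build_lagged_dataset(data.transpose(1, 2, 0), 1,
                                  standardize=False)
        ours, *_ = np.linalg.lstsq(ds.X, ds.Y, rcond=None)
        np.testing.assert_allclose(ours.T, sm.coefs[0], atol=1e-8)
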