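"""Ground-truth generators: statistical structure and reproducibility."""

import numpy as np
import pytest

from ncreann import (
    BandEffectSpec,
    EpochedData,
    NMVARSpec,
    make_grid_source_model,
    simulate_band_trials,
    simulate_behavior,
    simulate_condition_study,
    simulate_nmvar,
    simulate_source_projection,
)
from ncreann.simulate import companion_spectral_radius


class TestNMVAR:
    def test_ar1_lag_autocorrelation(self, ar1_data):
        x = ar1_data[0, 0]
        r = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r == pytest.approx(0.5, abs=0.05)

    def test_edge_list_matches_construction(self):
        A = np.zeros((1, 2, 2))
        A[0, 1, 0] = 0.8
        spec = NMVARSpec(M=2, p=1, A=A, n_samples=50, seed=0)
        _, edges = simulate_nmvar(spec)
        assert edges == [(0, 1, "linear")]

    def test_nonstationary_rejected(self):
        A = np.full((1, 2, 2), 0.9)
        with pytest.raises(ValueError, match="spectral radius"):
            NMVARSpec(M=2, p=1, A=A, n_samples=50)

    def test_quadratic_regressor_reduces_residual_variance(self):
        """Brute-force OLS: adding the known square regressor must
        explain variance of the nonlinear target node."""
        A = np.zeros((1, 3, 3))
        for i in range(3):
            A[0, i, i] = 0.4
        spec = NMVARSpec(M=3, p=1, A=A,
                         nonlinear_terms=[(2, 1, 1, "square", 0.5)],
                         n_samples=5000, seed=3)
        data, edges = simulate_nmvar(spec)
        assert (1, 2, "nonlinear") in edges
        x = data[0]
        Y = x[2, 1:]
        Xlin = x[:, :-1].T
        Xnl = np.column_stack([Xlin, x[1, :-1] ** 2])
        rv = []
        for X in (Xlin, Xnl):
            c, *_ = np.linalg.lstsq(X, Y, rcond=None)
            rv.append(np.var(Y - X @ c))
        assert rv[1] < 0.9 * rv[0]

    def test_bit_reproducible(self):
        spec = NMVARSpec(M=2, p=1, A=np.array([[[0.3, 0.0], [0.4, 0.3]]]),
                         n_samples=200, n_trials=3, seed=42)
        d1, _ = simulate_nmvar(spec)
        d2, _ = simulate_nmvar(spec)
        np.testing.assert_array_equal(d1, d2)

    def test_ols_recovers_coefficients_when_linear(self):
        """With all nonlinear gains zero, OLS VAR recovers each a_ij^d
        within +-0.05 at large n (averaged over seeds)."""
        A = np.array([[[0.5, 0.2], [-0.3, 0.4]], [[-0.2, 0.0], [0.1, -0.1]]])
        errs = []
        for seed in range(4):
            spec = NMVARSpec(M=2, p=2, A=A, n_samples=20000, seed=seed)
            data, _ = simulate_nmvar(spec)
            x = data[0]
            Y = x[:, 2:].T
            X = np.column_stack([x[:, 1:-1].T, x[:, :-2].T])
            c, *_ = np.linalg.lstsq(X, Y, rcond=None)
            A_hat = np.stack([c[:2].T, c[2:].T])
            errs.append(np.abs(A_hat - A).max())
        assert np.mean(errs) < 0.05

    def test_companion_radius_known_case(self):
        assert companion_spectral_radius(
            np.array([[[0.5]]])) == pytest.approx(0.5)


class TestBandTrials:
    def test_positive_effect_direction(self, grid_positions):
        spec = BandEffectSpec(
            bands={"theta": (4, 7)}, channel_groups={"theta": [0, 1, 2]},
            effect_size_d={"theta": 1.0}, n_subjects=6,
            n_trials_per_condition=6, trial_window=(-1, 1),
            n_channels=16, seed=5)
        subs = simulate_band_trials(spec, grid_positions(16))
        from ncreann.spectral import BANDS, band_power_welch
        diffs = [band_power_welch(a, BANDS["theta"])[:3].mean()
                 - band_power_welch(b, BANDS["theta"])[:3].mean()
                 for a, b in subs]
        assert all(d > 0 for d in diffs)

    def test_invalid_srate_rejected(self):
        with pytest.raises(ValueError):
            BandEffectSpec(bands={"theta": (4, 7)}, channel_groups={},
                           effect_size_d={}, srate=float("nan"))

    def test_effect_channels_validated(self):
        with pytest.raises(ValueError, match="outside"):
            BandEffectSpec(bands={"theta": (4, 7)},
                           channel_groups={"theta": [99]},
                           effect_size_d={"theta": 1.0}, n_channels=8)


class TestSourceProjection:
    def test_single_source_zero_noise_rank_one(self):
        model = make_grid_source_model((4, 4, 4), n_channels=12, seed=0)
        tc = np.sin(np.linspace(0, 20, 256))
        ep, truth = simulate_source_projection(tc[None], [10], model,
                                               sensor_noise_sd=0.0, seed=0)
        s = np.linalg.svd(ep.data[0], compute_uv=False)
        assert s[1] < 1e-10 * s[0]
        assert truth["voxel_indices"][0] == 10

    def test_out_of_grid_voxel_rejected(self):
        model = make_grid_source_model((3, 3, 3), n_channels=8, seed=0)
        with pytest.raises(ValueError, match="outside the grid"):
            simulate_source_projection(np.ones((1, 10)), [27], model, 0.1)


class TestBehavior:
    def test_r_target_zero_null(self):
        rng = np.random.default_rng(0)
        rs = []
        for seed in range(30):
            x = rng.standard_normal(100)
            y = simulate_behavior(x, 0.0, seed=seed)
            rs.append(np.corrcoef(x, y)[0, 1])
        assert abs(np.mean(rs)) < 2 / np.sqrt(100)

    def test_high_r_recovered(self):
        rng = np.random.default_rng(1)
        ok = 0
        for seed in range(40):
            x = rng.standard_normal(79)
            y = simulate_behavior(x, 0.9, seed=seed)
            ok += 0.8 <= np.corrcoef(x, y)[0, 1] <= 0.96
        assert ok >= 36  # Fisher-z 95% interval

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            simulate_behavior(np.ones(10), 0.5)
        with pytest.raises(ValueError, match="r_target"):
            simulate_behavior(np.arange(10.0), 1.0)


class TestConditionStudy:
    def test_planted_contrast_direction(self):
        study = simulate_condition_study(n_subjects=12, n_trials=4,
                                         n_samples=64, seed=0)
        diffs = []
        for coup in study["couplings"]:
            for (src, tgt) in study["edges"]:
                diffs.append(coup[(src, tgt, "A")] - coup[(src, tgt, "B")])
        assert np.mean(diffs) > 0

    def test_container_roundtrip(self, tmp_path, grid_positions):
        ep = EpochedData(np.random.default_rng(0).standard_normal((3, 4, 16)),
                         srate=128.0, ch_names=[f"c{i}" for i in range(4)],
                         ch_pos=grid_positions(4), tmin=-0.5,
                         condition=np.array(["A", "B", "A"]))
        path = tmp_path / "e.h5"
        ep.to_hdf5(path)
        back = EpochedData.from_hdf5(path)
        np.testing.assert_array_equal(back.data, ep.data)
        assert back.ch_names == ep.ch_names
        assert back.tmin == ep.tmin
        assert list(back.condition) == ["A", "B", "A"]
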