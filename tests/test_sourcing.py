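"""LCMV beamforming, NAI and DBSCAN source clustering."""

import numpy as np
import pytest

from ncreann import make_grid_source_model, simulate_source_projection
from ncreann.sourcing import (
    NAIVolume,
    apply_filters,
    cluster_timecourses,
    compute_nai,
    dbscan_source_clusters,
    lcmv_common_filter,
)


@pytest.fixture(scope="module")
def model():
    return make_grid_source_model((8, 8, 8), edge_mm=5.0, n_channels=24,
                                  seed=1)


@pytest.fixture(scope="module")
def two_source_fixture(model):
    """Two orthogonal (uncorrelated) sources at separated voxels."""
    T = 512
    t = np.arange(T) / 256.0
    tcs = np.stack([np.sin(2 * np.pi * 8 * t),
                    np.sign(np.sin(2 * np.pi * 5 * t + 1.0))])
    tcs -= tcs.mean(axis=1, keepdims=True)
    vox = np.array([100, 400])
    ep, truth = simulate_source_projection(tcs, vox, model,
                                           sensor_noise_sd=1e-6,
                                           n_trials=3, seed=2)
    return ep, truth, vox, tcs


class TestLCMV:
    def test_unit_gain_constraint(self, model, two_source_fixture):
        ep, *_ = two_source_fixture
        avg = ep.data.mean(axis=0)
        filters = lcmv_common_filter(avg, avg, model)
        for v in [0, 17, 311, model.n_voxels - 1]:
            l = model.leadfield[:, v, :] @ filters.orientations[v]
            assert filters.weights[v] @ l == pytest.approx(1.0, abs=1e-6)

    def test_reconstruction_correlates_with_truth(self, model,
                                                  two_source_fixture):
        ep, truth, vox, tcs = two_source_fixture
        avg = ep.data.mean(axis=0)
        filters = lcmv_common_filter(avg, avg, model)
        rec = apply_filters(filters, ep, voxels=vox)
        for k in range(2):
            r_own = abs(np.corrcoef(rec[k, :, 0], tcs[k])[0, 1])
            r_other = abs(np.corrcoef(rec[k, :, 0], tcs[1 - k])[0, 1])
            assert r_own > 0.99
            assert r_other < 0.2

    def test_leadfield_scaling_halves_weights(self, model,
                                              two_source_fixture):
        ep, *_ = two_source_fixture
        avg = ep.data.mean(axis=0)
        f1 = lcmv_common_filter(avg, avg, model)
        from ncreann import SourceModel
        model2 = SourceModel(2.0 * model.leadfield, model.coords,
                             model.edge_mm, model.labels)
        f2 = lcmv_common_filter(avg, avg, model2)
        np.testing.assert_allclose(f2.weights, 0.5 * f1.weights, atol=1e-9)

    def test_singular_covariance_needs_regularization(self, model):
        avg = np.outer(np.arange(model.n_channels, dtype=float),
                       np.ones(64))  # rank 1
        with pytest.raises(np.linalg.LinAlgError, match="reg_fraction"):
            lcmv_common_filter(avg, avg, model, reg_fraction=0.0)


class TestNAI:
    def test_equal_covariances_give_unity(self, model, two_source_fixture):
        ep, *_ = two_source_fixture
        avg = ep.data.mean(axis=0)
        filters = lcmv_common_filter(avg, avg, model)
        C = np.eye(model.n_channels)
        nai = compute_nai(filters, C, C)
        np.testing.assert_allclose(nai.nai, 1.0, atol=1e-9)

    def test_linearity_in_data_covariance(self, model, two_source_fixture):
        ep, *_ = two_source_fixture
        avg = ep.data.mean(axis=0)
        filters = lcmv_common_filter(avg, avg, model)
        cat = avg - avg.mean(axis=1, keepdims=True)
        C = cat @ cat.T / cat.shape[1]
        n1 = compute_nai(filters, C)
        n2 = compute_nai(filters, 2.0 * C)
        np.testing.assert_allclose(n2.nai, 2.0 * n1.nai, rtol=1e-9)

    def test_argmax_at_planted_source(self, model):
        T = 512
        tc = np.sin(2 * np.pi * 9 * np.arange(T) / 256.0)
        vox = 237
        clean, _ = simulate_source_projection(tc[None], [vox], model,
                                              sensor_noise_sd=0.0, seed=3)
        sd = clean.data.std() / np.sqrt(10)  # SNR 10
        ep, _ = simulate_source_projection(tc[None], [vox], model,
                                           sensor_noise_sd=sd, n_trials=5,
                                           seed=3)
        avg = ep.data.mean(axis=0)
        filters = lcmv_common_filter(avg, avg, model)
        cat = avg - avg.mean(axis=1, keepdims=True)
        nai = compute_nai(filters, cat @ cat.T / cat.shape[1])
        err = np.linalg.norm(model.coords[int(np.argmax(nai.nai))]
                             - model.coords[vox])
        assert err <= model.edge_mm


class TestDBSCANClusters:
    def make_volume(self, model, hot):
        nai = np.ones(model.n_voxels)
        for v in hot:
            nai[v] = 50.0
        return NAIVolume(nai, model.coords, model.labels)

    def test_two_separated_blobs(self, model):
        blob1, blob2 = [0, 1], [5 * 64, 5 * 64 + 1]  # 25 mm apart in x
        vol = self.make_volume(model, blob1 + blob2)
        cl = dbscan_source_clusters(vol, top_fraction=4 / model.n_voxels,
                                    voxel_edge=5.0)
        assert sorted(tuple(c.voxels) for c in cl.clusters) == [
            tuple(blob1), tuple(blob2)]

    def test_isolated_voxel_is_noise(self, model):
        vol = self.make_volume(model, [100])
        cl = dbscan_source_clusters(vol, top_fraction=1 / model.n_voxels,
                                    voxel_edge=5.0)
        assert len(cl) == 0

    def test_uniform_map_candidate_count(self, model):
        """With constant NAI, candidate selection keeps exactly
        ceil(top_fraction * n_labeled) voxels, lowest indices first."""
        vol = NAIVolume(np.ones(model.n_voxels), model.coords, model.labels)
        frac = 0.013
        cl = dbscan_source_clusters(vol, top_fraction=frac, voxel_edge=5.0)
        n_labeled = int((model.labels > 0).sum())
        expected = int(np.ceil(frac * n_labeled))
        got = sorted(v for c in cl.clusters for v in c.voxels)
        assert got == list(range(expected))

    def test_voxel_order_independence(self, model):
        rng = np.random.default_rng(7)
        nai = np.ones(model.n_voxels)
        hot = [0, 1, 2, 200, 201]
        for v in hot:
            nai[v] = 50.0
        vol = NAIVolume(nai, model.coords, model.labels)
        c1 = dbscan_source_clusters(vol, top_fraction=5 / model.n_voxels,
                                    voxel_edge=5.0)
        perm = rng.permutation(model.n_voxels)
        vol2 = NAIVolume(nai[perm], vol.coords[perm], vol.labels[perm])
        c2 = dbscan_source_clusters(vol2, top_fraction=5 / model.n_voxels,
                                    voxel_edge=5.0)
        sets1 = sorted(tuple(sorted(c.voxels)) for c in c1.clusters)
        sets2 = sorted(tuple(sorted(int(perm[v]) for v in c.voxels))
                       for c in c2.clusters)
        assert sets1 == sets2


class TestClusterTimecourses:
    def test_single_voxel_identity(self, model):
        from ncreann.sourcing import SourceCluster, SourceClusterSet
        tcs = np.random.default_rng(8).standard_normal((10, 64, 3))
        cl = SourceClusterSet([SourceCluster(np.array([4]), np.zeros(3), 1,
                                             1.0)])
        out = cluster_timecourses(tcs, cl)
        np.testing.assert_array_equal(out[0], tcs[4])

    def test_opposite_timecourses_cancel(self, model):
        from ncreann.sourcing import SourceCluster, SourceClusterSet
        x = np.random.default_rng(9).standard_normal((1, 64, 2))
        tcs = np.concatenate([x, -x], axis=0)
        cl = SourceClusterSet([SourceCluster(np.array([0, 1]), np.zeros(3),
                                             1, 1.0)])
        np.testing.assert_allclose(cluster_timecourses(tcs, cl), 0.0,
                                   atol=1e-12)
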