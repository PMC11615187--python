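"""LCMV beamforming, neural activity index maps and source clustering.

A common spatial filter is computed per voxel from the covariance of
the concatenated time-locked condition averages:
w = (l' C^-1 l)^-1 l' C^-1 with C the regularized data covariance and
l the leadfield column at the filter's fixed orientation (the
max-power direction).  The filter has unit gain toward its voxel
(w'l = 1).  Applying the fixed filter to single trials yields source
time courses; the neural activity index NAI(v) = (w' C_d w)/(w' C_n w)
ranks voxels by source power normalized by projected noise power.
High-NAI voxels (top fraction within atlas-labeled regions) are
grouped by DBSCAN into spatial clusters whose mean time courses feed
the connectivity stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

from .containers import EpochedData, SourceModel

__all__ = ["SpatialFilterSet", "NAIVolume", "SourceCluster",
           "SourceClusterSet", "lcmv_common_filter", "compute_nai",
           "apply_filters", "dbscan_source_clusters", "cluster_timecourses"]


@dataclass
class SpatialFilterSet:
    """Per-voxel LCMV weights and fixed orientations.

    weights : (n_voxels, n_channels); orientations : (n_voxels, 3),
    unit vectors; ``cov`` is the regularized covariance the filters
    were derived from.
    """

    weights: np.ndarray
    orientations: np.ndarray
    reg_fraction: float
    cov: np.ndarray
    model: SourceModel


@dataclass
class NAIVolume:
    nai: np.ndarray        # (n_voxels,), nonnegative
    coords: np.ndarray     # mm
    labels: np.ndarray     # atlas label per voxel

    def __post_init__(self):
        if not np.all(np.isfinite(self.nai)) or np.any(self.nai < 0):
            raise ValueError("NAI must be finite and nonnegative")


@dataclass
class SourceCluster:
    voxels: np.ndarray       # voxel indices
    centroid: np.ndarray     # mm
    label: int               # dominant atlas label
    mean_nai: float


@dataclass
class SourceClusterSet:
    clusters: list

    def __len__(self):
        return len(self.clusters)


def lcmv_common_filter(avg_A: np.ndarray, avg_B: np.ndarray,
                       model: SourceModel, reg_fraction: float = 0.05
                       ) -> SpatialFilterSet:
    """LCMV filters from the concatenated condition averages.

    ``avg_A``/``avg_B`` are time-locked averages (channels x samples);
    their concatenation defines the common covariance so both
    conditions are reconstructed through identical filters.
    Regularization adds ``reg_fraction * mean(eigenvalues) * I``.
    """
    data = np.concatenate([np.asarray(avg_A, float),
                           np.asarray(avg_B, float)], axis=1)
    if data.shape[0] != model.n_channels:
        raise ValueError("averages do not match the leadfield channel count")
    data = data - data.mean(axis=1, keepdims=True)
    C = data @ data.T / data.shape[1]
    eig = np.linalg.eigvalsh(C)
    if reg_fraction > 0:
        C = C + reg_fraction * eig.mean() * np.eye(C.shape[0])
    elif eig.min() <= 1e-12 * max(eig.max(), 1.0):
        raise np.linalg.LinAlgError(
            "covariance of the concatenated averages is singular; "
            "set reg_fraction > 0")
    Cinv = np.linalg.inv(C)
    n_vox = model.n_voxels
    weights = np.empty((n_vox, model.n_channels))
    orientations = np.empty((n_vox, 3))
    for v in range(n_vox):
        L = model.leadfield[:, v, :]                     # channels x 3
        G = L.T @ Cinv @ L                                # 3 x 3
        # max-power orientation: dominant eigenvector of the source
        # covariance pinv(G) == minimum eigenvector of G
        w_eig, V = np.linalg.eigh(G)
        u = V[:, np.argmin(w_eig)]
        l = L @ u                                         # scalar leadfield
        Cinv_l = Cinv @ l
        denom = l @ Cinv_l
        if denom <= 0:
            raise np.linalg.LinAlgError(f"degenerate leadfield at voxel {v}")
        weights[v] = Cinv_l / denom
        orientations[v] = u
    return SpatialFilterSet(weights, orientations, reg_fraction, C, model)


def compute_nai(filters: SpatialFilterSet, data_cov: np.ndarray,
                noise_cov: np.ndarray | None = None) -> NAIVolume:
    """Neural activity index per voxel: source power over projected noise power.

    ``noise_cov`` defaults to the identity scaled by the smallest
    eigenvalue of the filter covariance (unit-noise floor estimate).
    """
    W = filters.weights
    if noise_cov is None:
        lam = float(np.linalg.eigvalsh(filters.cov).min())
        noise_cov = lam * np.eye(W.shape[1])
    num = np.einsum("vc,cd,vd->v", W, data_cov, W)
    den = np.einsum("vc,cd,vd->v", W, noise_cov, W)
    if np.any(den <= 0):
        raise ZeroDivisionError("zero noise projection for some voxel; "
                                "noise covariance is degenerate")
    nai = np.maximum(num / den, 0.0)
    return NAIVolume(nai, filters.model.coords, filters.model.labels)


def apply_filters(filters: SpatialFilterSet, epochs: EpochedData,
                  voxels=None) -> np.ndarray:
    """Single-trial source time courses (n_voxels_sel, n_samples, n_trials)."""
    W = filters.weights if voxels is None else filters.weights[voxels]
    return np.einsum("vc,tcs->vst", W, epochs.data)


def dbscan_source_clusters(nai: NAIVolume, top_fraction: float = 0.01,
                           min_size: int = 2, eps_factor: float = 1.5,
                           voxel_edge: float | None = None,
                           min_report_size: int | None = None,
                           merge_distance: float = 0.0) -> SourceClusterSet:
    """DBSCAN clusters of the highest-NAI voxels within labeled regions.

    The candidate set is the top ``top_fraction`` of the NAI
    distribution among atlas-labeled voxels — exactly
    ceil(top_fraction * n_labeled) voxels, ties broken by voxel index.
    DBSCAN runs on candidate coordinates with
    eps = eps_factor * voxel_edge and minPts = min_size; noise points
    are discarded.  Two deterministic post-rules replace manual
    curation: clusters smaller than ``min_report_size`` are dropped,
    and clusters sharing a dominant label with centroids closer than
    ``merge_distance`` (mm) are merged (0 disables merging).
    """
    labeled = np.where(nai.labels > 0)[0]
    if labeled.size == 0:
        raise ValueError("no atlas-labeled voxels")
    k = int(np.ceil(top_fraction * labeled.size))
    order = labeled[np.argsort(-nai.nai[labeled], kind="stable")]
    cand = np.sort(order[:k])
    if cand.size == 0:
        return SourceClusterSet([])
    edge = voxel_edge
    if edge is None:
        edge = _infer_edge(nai.coords)
    db = DBSCAN(eps=eps_factor * edge, min_samples=min_size).fit(
        nai.coords[cand])
    clusters = []
    for lab in sorted(set(db.labels_) - {-1}):
        members = cand[db.labels_ == lab]
        vals, counts = np.unique(nai.labels[members], return_counts=True)
        clusters.append(SourceCluster(
            members, nai.coords[members].mean(axis=0),
            int(vals[np.argmax(counts)]), float(nai.nai[members].mean())))
    if merge_distance > 0:
        clusters = _merge_close(clusters, nai, merge_distance)
    if min_report_size:
        clusters = [c for c in clusters if c.voxels.size >= min_report_size]
    clusters.sort(key=lambda c: tuple(c.voxels))
    return SourceClusterSet(clusters)


def _infer_edge(coords: np.ndarray) -> float:
    d = np.unique(np.abs(np.diff(np.unique(coords[:, 0]))))
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("cannot infer voxel edge length; pass voxel_edge")
    return float(d.min())


def _merge_close(clusters, nai: NAIVolume, merge_distance: float):
    merged = True
    clusters = list(clusters)
    while merged:
        merged = False
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca, cb = clusters[a], clusters[b]
                if (ca.label == cb.label and
                        np.linalg.norm(ca.centroid - cb.centroid)
                        <= merge_distance):
                    vox = np.sort(np.concatenate([ca.voxels, cb.voxels]))
                    clusters[a] = SourceCluster(
                        vox, nai.coords[vox].mean(axis=0), ca.label,
                        float(nai.nai[vox].mean()))
                    del clusters[b]
                    merged = True
                    break
            if merged:
                break
    return clusters


def cluster_timecourses(single_trial_source_tcs: np.ndarray,
                        clusters: SourceClusterSet,
                        voxel_index_map=None) -> np.ndarray:
    """Mean voxel time course per cluster: (n_clusters, n_samples, n_trials).

    ``single_trial_source_tcs`` is (n_voxels, n_samples, n_trials) as
    returned by :func:`apply_filters` over all voxels; pass
    ``voxel_index_map`` (voxel id -> row) when it covers a subset.
    """
    tcs = np.asarray(single_trial_source_tcs, dtype=float)
    out = np.empty((len(clusters), tcs.shape[1], tcs.shape[2]))
    for k, c in enumerate(clusters.clusters):
        if c.voxels.size == 0:
            raise ValueError(f"cluster {k} is empty")
        rows = (c.voxels if voxel_index_map is None
                else np.array([voxel_index_map[v] for v in c.voxels]))
        out[k] = tcs[rows].mean(axis=0)
    return out
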