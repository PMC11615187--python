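"""Sensor-level cluster-based permutation test for two paired conditions.

Channels whose paired t statistic crosses the two-tailed threshold are
grouped into spatial clusters of adjacent channels (separately for
positive and negative t); the cluster statistic is the within-cluster
t-sum ("maxsum") and clusters need at least two channels.  The null
distribution is the maximum absolute cluster mass under random
within-subject condition sign flips, and p-values use the +1-smoothed
Monte Carlo estimator, which is valid at any permutation count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["build_adjacency", "cluster_permutation_test", "Cluster",
           "ClusterStatResult"]


def build_adjacency(positions: np.ndarray, neighbor_distance: float
                    ) -> np.ndarray:
    """Boolean channel adjacency from pairwise distances.

    ``adjacency[i, j]`` is True when 0 < dist(i, j) <= neighbor_distance.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite channel positions")
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    off = ~np.eye(pos.shape[0], dtype=bool)
    if np.any(d[off] == 0):
        warnings.warn("duplicate channel positions detected")
    return (d > 0) & (d <= neighbor_distance)


@dataclass
class Cluster:
    channels: np.ndarray      # channel indices, sorted
    sign: int                 # +1 or -1
    statistic: float          # sum of t over the cluster
    p: float


@dataclass
class ClusterStatResult:
    clusters: list            # of Cluster, any sign
    t_values: np.ndarray      # per-channel paired t
    t_threshold: float
    n_perm: int

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p <= alpha]

    def to_report(self, ch_names=None) -> list:
        out = []
        for c in self.clusters:
            names = (list(np.asarray(ch_names)[c.channels])
                     if ch_names is not None else c.channels.tolist())
            out.append({"channels": names, "sign": c.sign,
                        "statistic": float(c.statistic), "p": float(c.p)})
        return out


def _clusters_from_t(t: np.ndarray, thr: float, indptr, indices,
                     min_size: int):
    """Signed supra-threshold clusters; returns list of (mask, sum_t)."""
    out = []
    for sign in (1, -1):
        supra = (sign * t) > thr
        idx = np.where(supra)[0]
        if idx.size == 0:
            continue
        # connected components on the subgraph induced by supra channels
        sub = {c: k for k, c in enumerate(idx)}
        rows, cols = [], []
        for c in idx:
            for nb in indices[indptr[c]:indptr[c + 1]]:
                if supra[nb]:
                    rows.append(sub[c])
                    cols.append(sub[nb])
        g = csr_matrix((np.ones(len(rows)), (rows, cols)),
                       shape=(idx.size, idx.size))
        n_comp, lab = connected_components(g, directed=False)
        for k in range(n_comp):
            members = idx[lab == k]
            if members.size >= min_size:
                out.append((sign, members, float(t[members].sum())))
    return out


def _paired_t(diff: np.ndarray) -> np.ndarray:
    """Vectorized paired t over axis 0 (subjects) for each channel."""
    n = diff.shape[0]
    m = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    return t


def cluster_permutation_test(values_A: np.ndarray, values_B: np.ndarray,
                             adjacency: np.ndarray,
                             alpha_cluster: float = 0.05,
                             n_perm: int = 500, min_size: int = 2,
                             seed: int = 0, exhaustive: bool = False
                             ) -> ClusterStatResult:
    """Cluster-based permutation test on paired per-channel values.

    Parameters
    ----------
    values_A, values_B : (n_subjects, n_channels)
        Per-subject band-power (or any paired scalar) per channel.
    adjacency : boolean (n_channels, n_channels)
    alpha_cluster : two-tailed per-channel t threshold for cluster
        formation (default 0.05).
    n_perm : Monte-Carlo sign-flip draws (ignored with ``exhaustive``).
    exhaustive : enumerate all 2^n_subjects sign flips instead of
        sampling (feasible only for small n; p then has no +1 term).
    """
    A = np.asarray(values_A, dtype=float)
    B = np.asarray(values_B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("condition arrays must have identical shape "
                         "(same subjects in both conditions)")
    n_sub, n_ch = A.shape
    if n_sub < 3:
        raise ValueError("need at least 3 subjects")
    if adjacency.shape != (n_ch, n_ch):
        raise ValueError("adjacency shape does not match channel count")
    adj = csr_matrix(adjacency)
    indptr, indices = adj.indptr, adj.indices
    diff = A - B
    thr = stats.t.ppf(1 - alpha_cluster / 2, df=n_sub - 1)
    t_obs = _paired_t(diff)
    obs = _clusters_from_t(t_obs, thr, indptr, indices, min_size)

    if exhaustive:
        if n_sub > 20:
            raise ValueError("exhaustive enumeration infeasible for n > 20")
        flips = ((np.arange(2 ** n_sub)[:, None] >> np.arange(n_sub)) & 1)
        signs_iter = 1 - 2 * flips.astype(float)
        denom = signs_iter.shape[0]
        add = 0
    else:
        rng = np.random.default_rng(seed)
        signs_iter = 1 - 2 * rng.integers(0, 2, size=(n_perm, n_sub)).astype(float)
        denom = n_perm + 1
        add = 1

    null_max = np.empty(signs_iter.shape[0])
    for k, s in enumerate(signs_iter):
        t_p = _paired_t(diff * s[:, None])
        cl = _clusters_from_t(t_p, thr, indptr, indices, min_size)
        null_max[k] = max((abs(st) for _, _, st in cl), default=0.0)

    clusters = []
    for sign, members, statistic in obs:
        count = int(np.sum(null_max >= abs(statistic)))
        clusters.append(Cluster(np.sort(members), sign, statistic,
                                (count + add) / denom))
    clusters.sort(key=lambda c: c.p)
    return ClusterStatResult(clusters, t_obs, thr, signs_iter.shape[0])
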