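"""Group-level connectivity contrasts and brain-behavior correlation.

Per-edge and network-mean condition contrasts use one-sided paired t
tests with Cohen's d on the paired differences; per-edge tests honor
the surrogate-based inclusion mask (a subject enters an edge's
contrast only when that edge was significant in both conditions), so
degrees of freedom vary across edges.  No multiple-comparison
correction is applied by default; Holm correction is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupConnectivity", "paired_t_one_sided",
           "edge_and_mean_contrasts", "brain_behavior_correlation"]


@dataclass
class GroupConnectivity:
    """Per-subject connectivity matrices for two conditions.

    values : dict condition -> ndarray (n_subjects, M, M), edge
    convention mat[j, i] = i -> j.  ``inclusion`` maps each condition
    to a boolean (n_subjects, M, M) mask from the surrogate tests
    (True = that subject's edge estimate is significant); None means
    include everyone.
    """

    values: dict
    inclusion: dict | None = None

    def __post_init__(self):
        conds = list(self.values)
        if len(conds) != 2:
            raise ValueError("exactly two conditions required")
        a, b = (np.asarray(self.values[c], float) for c in conds)
        if a.shape != b.shape:
            raise ValueError("condition arrays must share (n_subjects, M, M)")
        self.conditions = conds
        self.n_subjects, self.M = a.shape[0], a.shape[1]

    def included(self, cond_a: str, cond_b: str, j: int, i: int) -> np.ndarray:
        """Subjects whose (i -> j) edge is significant in both conditions."""
        if self.inclusion is None:
            return np.ones(self.n_subjects, dtype=bool)
        return (np.asarray(self.inclusion[cond_a])[:, j, i]
                & np.asarray(self.inclusion[cond_b])[:, j, i])


def paired_t_one_sided(values_A, values_B, direction: str = "greater"
                       ) -> dict:
    """One-sided paired t test with Cohen's d on the paired differences.

    ``direction='greater'`` tests mean(A - B) > 0.  d = mean(diff)/sd(diff).
    """
    a = np.asarray(values_A, float)
    b = np.asarray(values_B, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired 1-D vectors required")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("zero-variance paired differences")
    t = diff.mean() / (sd / np.sqrt(n))
    df = n - 1
    if direction == "greater":
        p = stats.t.sf(t, df)
    elif direction == "less":
        p = stats.t.cdf(t, df)
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    return {"t": float(t), "df": df, "p": float(p),
            "cohens_d": float(diff.mean() / sd), "n": n}


def edge_and_mean_contrasts(group: GroupConnectivity, direction: str,
                            scope: str = "per-edge",
                            holm: bool = False) -> pd.DataFrame:
    """Condition contrasts of connectivity, per edge or on the network mean.

    Per-edge rows test each non-self edge on the subjects included
    (surrogate-significant in both conditions) for that edge; edges
    with fewer than 3 included subjects are skipped with a notice row.
    ``scope='network-mean'`` tests each subject's mean over included
    non-self edges.
    """
    ca, cb = group.conditions
    A = np.asarray(group.values[ca], float)
    B = np.asarray(group.values[cb], float)
    M = group.M
    rows = []
    if scope == "per-edge":
        for i in range(M):
            for j in range(M):
                if i == j:
                    continue
                inc = group.included(ca, cb, j, i)
                if inc.sum() < 3:
                    rows.append({"edge": f"{i}->{j}", "n": int(inc.sum()),
                                 "df": np.nan, "t": np.nan, "p": np.nan,
                                 "cohens_d": np.nan, "note": "skipped (<3 subjects)"})
                    continue
                r = paired_t_one_sided(A[inc, j, i], B[inc, j, i], direction)
                rows.append({"edge": f"{i}->{j}", "n": r["n"], "df": r["df"],
                             "t": r["t"], "p": r["p"],
                             "cohens_d": r["cohens_d"], "note": ""})
    elif scope == "network-mean":
        off = ~np.eye(M, dtype=bool)
        mean_a = np.empty(group.n_subjects)
        mean_b = np.empty(group.n_subjects)
        keep = np.ones(group.n_subjects, dtype=bool)
        for s in range(group.n_subjects):
            if group.inclusion is None:
                m = off
            else:
                m = off & (np.asarray(group.inclusion[ca])[s]
                           & np.asarray(group.inclusion[cb])[s])
            if not m.any():
                keep[s] = False
                continue
            mean_a[s] = A[s][m].mean()
            mean_b[s] = B[s][m].mean()
        r = paired_t_one_sided(mean_a[keep], mean_b[keep], direction)
        rows.append({"edge": "network-mean", "n": r["n"], "df": r["df"],
                     "t": r["t"], "p": r["p"], "cohens_d": r["cohens_d"],
                     "note": "" if keep.all() else
                     f"{int((~keep).sum())} subjects without included edges"})
    else:
        raise ValueError("scope must be 'per-edge' or 'network-mean'")
    table = pd.DataFrame(rows)
    if holm and scope == "per-edge":
        ok = table["p"].notna()
        p = table.loc[ok, "p"].to_numpy()
        orderd = np.argsort(p)
        m = p.size
        adj = np.empty(m)
        running = 0.0
        for rank, k in enumerate(orderd):
            running = max(running, (m - rank) * p[k])
            adj[k] = min(1.0, running)
        table.loc[ok, "p_holm"] = adj
    return table


def brain_behavior_correlation(connectivity_summary, behavior) -> dict:
    """Pearson correlation between a per-subject connectivity summary
    and a behavioral score, with two-sided p from the t transform."""
    x = np.asarray(connectivity_summary, float)
    y = np.asarray(behavior, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-D vectors required")
    if x.size < 4:
        raise ValueError("need at least 4 subjects")
    if x.std() == 0 or y.std() == 0:
        raise ZeroDivisionError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": x.size}
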