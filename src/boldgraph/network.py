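"""Atlas-based connectivity and the network-based statistic (NBS).

ROI time courses are voxel averages within a labeled parcellation; pairwise
Pearson correlations are Fisher-z transformed into a symmetric connectivity
matrix per subject. Edge-wise two-sample t tests (pooled variance, plain
group comparison, df = n1 + n2 - 2) feed the NBS: edges surviving a stringent
primary threshold form a graph whose connected components are tested by
permuting group labels and recording the maximal component extent (edge
count), giving family-wise-error-corrected component p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

__all__ = [
    "ConnectivityMatrix",
    "EdgeTest",
    "NBSResult",
    "extract_roi_series",
    "connectivity_matrix",
    "edgewise_ttest",
    "nbs",
    "export_edges",
]

Z_CAP = 1.0 - 1e-7  # |r| cap before atanh, keeps Fisher z finite


@dataclass
class ConnectivityMatrix:
    z: np.ndarray                    # ROI x ROI Fisher-z, zero diagonal
    n_timepoints_used: int
    roi_labels: pd.DataFrame | None = None


@dataclass
class EdgeTest:
    t: np.ndarray                    # ROI x ROI symmetric, zero diagonal
    df: int
    p: np.ndarray                    # two-sided
    undefined: np.ndarray            # edges with zero pooled variance


@dataclass
class NBSResult:
    components: list[dict]           # {"edges": [(i,j)...], "extent": int, "p_fwer": float}
    null_max_extents: np.ndarray
    primary_p: float
    tail: str                        # "greater" | "less"
    t_threshold: float
    df: int


def extract_roi_series(volume4d: np.ndarray, parcellation: np.ndarray) -> np.ndarray:
    """Average voxel time courses within each parcellation label.

    Returns a time x ROI matrix whose column order follows the sorted positive
    labels. Empty labels (present in the label range but absent from the
    image) raise.
    """
    vol = np.asarray(volume4d, dtype=float)
    parc = np.asarray(parcellation)
    if vol.shape[:3] != parc.shape:
        raise ValueError("parcellation grid does not match the volume")
    labels = np.unique(parc[parc > 0])
    if labels.size == 0:
        raise ValueError("parcellation has no positive labels")
    full = np.arange(1, labels.max() + 1)
    empty = sorted(int(l) for l in set(full) - set(labels))
    if empty:
        raise ValueError(f"empty ROI labels: {empty}")
    n_t = vol.shape[-1]
    out = np.empty((n_t, len(labels)))
    flat = vol.reshape(-1, n_t)
    lab_flat = parc.ravel()
    for k, lab in enumerate(labels):
        out[:, k] = flat[lab_flat == lab].mean(axis=0)
    return out


def connectivity_matrix(roi_series: np.ndarray,
                        roi_labels: pd.DataFrame | None = None,
                        z_cap: float = Z_CAP) -> ConnectivityMatrix:
    """Fisher-z Pearson connectivity of a time x ROI matrix.

    ``z(i, j) = atanh(r_ij)`` with |r| capped at ``z_cap`` so perfectly
    correlated series give a large finite value; the diagonal is set to zero
    and excluded from all downstream statistics.
    """
    x = np.asarray(roi_series, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need >= 3 time points")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError(f"zero-variance ROIs: {np.flatnonzero(sd == 0).tolist()}")
    r = np.corrcoef(x, rowvar=False)
    r = (r + r.T) / 2  # exact symmetry despite float round-off
    r = np.clip(r, -z_cap, z_cap)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z=z, n_timepoints_used=x.shape[0], roi_labels=roi_labels)


def _stack_z(matrices: list[ConnectivityMatrix] | np.ndarray) -> np.ndarray:
    if isinstance(matrices, np.ndarray):
        return matrices
    return np.asarray([m.z for m in matrices])


def _pooled_t(data: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t for each column of subjects x features data."""
    n1, n2 = len(g1), len(g2)
    x1, x2 = data[g1], data[g2]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    ss = ((x1 - m1) ** 2).sum(axis=0) + ((x2 - m2) ** 2).sum(axis=0)
    sp2 = ss / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / se, np.nan)
    return t


def edgewise_ttest(matrices: list[ConnectivityMatrix] | np.ndarray,
                   group: np.ndarray) -> EdgeTest:
    """Pooled two-sample t per edge; group coded 1 (first group) vs 0.

    t is for group-1 minus group-0 on the Fisher-z scale. Edges with zero
    pooled variance get t = NaN and are flagged in ``undefined``.
    """
    z = _stack_z(matrices)
    group = np.asarray(group)
    g1, g2 = np.flatnonzero(group == 1), np.flatnonzero(group == 0)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >= 2 subjects per group")
    n_roi = z.shape[1]
    iu = np.triu_indices(n_roi, k=1)
    edges = z[:, iu[0], iu[1]]
    t_flat = _pooled_t(edges, g1, g2)
    df = len(g1) + len(g2) - 2
    p_flat = 2 * stats.t.sf(np.abs(t_flat), df)
    t = np.zeros((n_roi, n_roi))
    p = np.ones((n_roi, n_roi))
    und = np.zeros((n_roi, n_roi), dtype=bool)
    t[iu], p[iu], und[iu] = t_flat, p_flat, ~np.isfinite(t_flat)
    t, p, und = t + t.T, p + p.T - np.ones_like(p), und | und.T
    np.fill_diagonal(p, 1.0)
    t = np.nan_to_num(t, nan=0.0)
    t[und] = 0.0
    return EdgeTest(t=t, df=df, p=p, undefined=und)


def _components(t_flat: np.ndarray, iu: tuple, n_roi: int, thr: float,
                sign: int) -> list[list[tuple[int, int]]]:
    hits = np.flatnonzero(sign * t_flat > thr)
    if hits.size == 0:
        return []
    g = nx.Graph()
    g.add_edges_from(zip(iu[0][hits].tolist(), iu[1][hits].tolist()))
    comps = []
    for nodes in nx.connected_components(g):
        sub = g.subgraph(nodes)
        comps.append(sorted(tuple(sorted(e)) for e in sub.edges))
    return comps


def nbs(matrices: list[ConnectivityMatrix] | np.ndarray, group: np.ndarray,
        primary_p: float = 0.0001, tail: str = "greater",
        n_perm: int = 5000, seed: int | None = None) -> NBSResult:
    """Network-based statistic with component-extent FWER control.

    Edge-wise pooled t statistics are thresholded at the |t| corresponding to
    the two-sided ``primary_p`` at df = n1 + n2 - 2; for ``tail='greater'``
    only positive (group 1 > group 0) edges enter the suprathreshold graph,
    for ``'less'`` only negative ones. Component extent is the edge count.
    The null of maximal extents comes from ``n_perm`` random relabelings of
    the groups; ``p_fwer = (1 + #{null >= extent}) / (1 + n_perm)``, the +1
    standing for the observed (identity) relabeling.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'greater' or 'less'")
    z = _stack_z(matrices)
    group = np.asarray(group)
    g1, g2 = np.flatnonzero(group == 1), np.flatnonzero(group == 0)
    n = len(group)
    n_roi = z.shape[1]
    df = len(g1) + len(g2) - 2
    thr = stats.t.isf(primary_p / 2, df)
    sign = 1 if tail == "greater" else -1
    iu = np.triu_indices(n_roi, k=1)
    edges = z[:, iu[0], iu[1]]

    t_obs = _pooled_t(edges, g1, g2)
    t_obs = np.nan_to_num(t_obs, nan=0.0)
    comps = _components(t_obs, iu, n_roi, thr, sign)

    rng = np.random.default_rng(seed)
    perm_ind = np.empty((n_perm, n), dtype=bool)
    for b in range(n_perm):
        perm_ind[b] = rng.permutation(group) == 1
    null_max = np.zeros(n_perm, dtype=int)
    e2 = edges**2
    tot = edges.sum(axis=0)
    tot2 = e2.sum(axis=0)
    n1, n2 = len(g1), len(g2)
    # group-sum formulation, chunked so the perm x edge temporaries stay small
    chunk = max(1, int(2**25 / max(1, edges.shape[1])))
    for lo in range(0, n_perm, chunk):
        ind = perm_ind[lo:lo + chunk].astype(float)
        s1 = ind @ edges                   # chunk x edges
        s1sq = ind @ e2
        m1 = s1 / n1
        m2 = (tot - s1) / n2
        ss = (s1sq - n1 * m1**2) + ((tot2 - s1sq) - n2 * m2**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = (m1 - m2) / np.sqrt(ss / df * (1 / n1 + 1 / n2))
        t_perm = np.nan_to_num(t_perm, nan=0.0)
        supra = sign * t_perm > thr
        for b in np.flatnonzero(supra.any(axis=1)):
            c = _components(t_perm[b], iu, n_roi, thr, sign)
            if c:
                null_max[lo + b] = max(len(e) for e in c)

    components = []
    for e in comps:
        extent = len(e)
        p_fwer = float((1 + (null_max >= extent).sum()) / (1 + n_perm))
        components.append({"edges": e, "extent": extent, "p_fwer": p_fwer})
    components.sort(key=lambda c: (-c["extent"], c["p_fwer"]))
    return NBSResult(components=components, null_max_extents=null_max,
                     primary_p=primary_p, tail=tail, t_threshold=float(thr), df=df)


def export_edges(results: list[NBSResult] | NBSResult, edge_test: EdgeTest,
                 labels: pd.DataFrame) -> pd.DataFrame:
    """Undirected edge list for chord-diagram rendering (CIRCOS link track).

    One record per undirected edge across all NBS results, with node names
    resolved from the label table (columns ``label_id``, ``name``), the edge
    t value, the component FWER p, and the sign of the group difference.
    Deterministic ordering: by (node1, node2).
    """
    if isinstance(results, NBSResult):
        results = [results]
    name_of = dict(zip(labels["label_id"].astype(int), labels["name"]))
    records = {}
    for res in results:
        edge_sign = 1 if res.tail == "greater" else -1
        for comp in res.components:
            for i, j in comp["edges"]:
                a, b = sorted((int(i), int(j)))
                records[(a, b)] = {
                    "node1": name_of[a + 1],
                    "node2": name_of[b + 1],
                    "t": float(edge_test.t[a, b]),
                    "p_fwer": comp["p_fwer"],
                    "sign": edge_sign,
                }
    rows = [records[k] for k in sorted(records)]
    return pd.DataFrame(rows, columns=["node1", "node2", "t", "p_fwer", "sign"])


def write_circos_links(edges: pd.DataFrame, labels: pd.DataFrame, path) -> None:
    """Write a CIRCOS-style link file: node1 node2 t p sign, tab separated."""
    edges.to_csv(path, sep="\t", index=False, float_format="%.6g")
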