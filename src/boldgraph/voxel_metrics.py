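"""Voxel-wise graph metrics: binarized degree centrality and regional homogeneity.

Degree centrality of a voxel is the number of other in-mask voxels whose time
series correlate with it above a threshold (default Pearson r > 0.25, positive
tail only). Regional homogeneity (ReHo) is Kendall's coefficient of concordance
W between a voxel's time series and those of its cubic neighborhood, normalized
by the whole-brain mean W.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import itertools

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "DegreeMap",
    "ReHoMap",
    "degree_centrality",
    "z_transform_map",
    "reho",
    "kendalls_w",
    "cluster_mean",
    "NEIGHBORHOOD_OFFSETS",
]


def _cube_offsets(n: int) -> np.ndarray:
    """Offsets (center included) for the standard 7/19/27-voxel neighborhoods."""
    offs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        manhattan = sum(abs(v) for v in d)
        if n == 7 and manhattan > 1:
            continue
        if n == 19 and manhattan > 2:
            continue
        offs.append(d)
    return np.array(offs, dtype=int)


NEIGHBORHOOD_OFFSETS = {n: _cube_offsets(n) for n in (7, 19, 27)}


@dataclass
class DegreeMap:
    """Per-voxel connection counts over the in-mask voxel graph."""

    degree: np.ndarray       # float map, NaN outside mask if volumetric
    z_degree: np.ndarray
    mask: np.ndarray
    r_threshold: float = 0.25


@dataclass
class ReHoMap:
    w: np.ndarray
    w_normalized: np.ndarray
    mask: np.ndarray          # valid voxels actually entering the normalization
    neighborhood_size: int = 27


def degree_centrality(series: np.ndarray, mask: np.ndarray | None = None,
                      r_threshold: float = 0.25, absolute: bool = False,
                      block_size: int = 2048) -> DegreeMap:
    """Binarized degree centrality from a time x voxels matrix.

    ``mask`` selects the columns forming the graph (default: all). A pair of
    voxels is connected when their Pearson correlation is strictly above
    ``r_threshold`` (or |r| above it with ``absolute=True``). The map is
    z-transformed (standardized over the mask). Computation is blocked so the
    full voxel-by-voxel correlation matrix is never materialized.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] < 3:
        raise ValueError("series must be time x voxels with >= 3 time points")
    n_t, n_v = series.shape
    if mask is None:
        mask = np.ones(n_v, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    cols = np.flatnonzero(mask)
    x = series[:, cols]
    sd = x.std(axis=0)
    dead = cols[sd == 0]
    if dead.size:
        raise ValueError(f"zero-variance voxels in mask: {dead.tolist()}")
    u = (x - x.mean(axis=0)) / (sd * np.sqrt(n_t))  # corr = u.T @ u
    m = len(cols)
    deg = np.zeros(m, dtype=np.int64)
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        r = u[:, start:stop].T @ u
        if absolute:
            r = np.abs(r)
        hits = r > r_threshold
        # exclude self-connections (r = 1 on the diagonal of the full matrix)
        hits[np.arange(stop - start), np.arange(start, stop)] = False
        deg[start:stop] = hits.sum(axis=1)
    degree = np.zeros(n_v, dtype=float)
    degree[cols] = deg
    z = np.zeros(n_v, dtype=float)
    if deg.std() > 0:
        z[cols] = z_transform_map(deg.astype(float))
    return DegreeMap(degree=degree, z_degree=z, mask=mask, r_threshold=r_threshold)


def z_transform_map(values: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Standardize a map over its mask: (x - mean) / sd, population-sd convention.

    Out-of-mask entries are returned as zero.
    """
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    v = values[mask]
    sd = v.std()  # population convention (ddof=0)
    if sd == 0:
        raise ValueError("cannot z-transform a constant map")
    out = np.zeros_like(values)
    out[mask] = (v - v.mean()) / sd
    return out


def kendalls_w(series: np.ndarray, tie_correction: bool = False) -> float:
    """Kendall's coefficient of concordance among the columns of a time x m matrix.

    W = 12 * sum_t (R_t - Rbar)^2 / (m^2 (n^3 - n)), with R_t the rank sum of
    time point t across the m series (midranks for ties). The tie-correction
    denominator term is off by default; continuous BOLD-like data make ties
    measure-zero.
    """
    series = np.asarray(series, dtype=float)
    n, m = series.shape
    if n < 2 or m < 2:
        raise ValueError("need >= 2 time points and >= 2 series")
    ranks = rankdata(series, axis=0)
    r_t = ranks.sum(axis=1)
    s = ((r_t - m * (n + 1) / 2.0) ** 2).sum()
    denom = m**2 * (n**3 - n)
    if tie_correction:
        correction = 0.0
        for j in range(m):
            _, counts = np.unique(series[:, j], return_counts=True)
            correction += (counts**3 - counts).sum()
        denom -= m * correction
    if denom <= 0:
        return np.nan
    return float(12.0 * s / denom)


def reho(volume4d: np.ndarray, mask: np.ndarray,
         neighborhood: int | np.ndarray = 27,
         tie_correction: bool = False) -> ReHoMap:
    """Regional homogeneity map over a 4D volume.

    For each in-mask voxel, Kendall's W is computed across the voxel and its
    in-mask neighbors (cubic 7/19/27 scheme or custom offset array). Voxels
    whose neighborhood retains fewer than 2 in-mask members are marked invalid
    (NaN) and excluded from the whole-brain mean used for normalization.
    """
    vol = np.asarray(volume4d, dtype=float)
    if vol.ndim != 4 or vol.shape[-1] < 4:
        raise ValueError("volume4d must be x,y,z,t with >= 4 time points")
    mask = np.asarray(mask, dtype=bool)
    if isinstance(neighborhood, (int, np.integer)):
        if neighborhood not in NEIGHBORHOOD_OFFSETS:
            raise ValueError("neighborhood must be 7, 19, 27 or an offset array")
        offsets = NEIGHBORHOOD_OFFSETS[int(neighborhood)]
        nsize = int(neighborhood)
    else:
        offsets = np.asarray(neighborhood, dtype=int)
        nsize = len(offsets)
    n_t = vol.shape[-1]

    # rank within each voxel's time series, vectorized over space
    flat = vol.reshape(-1, n_t)
    in_mask = mask.ravel()
    ranks = np.zeros_like(flat)
    ranks[in_mask] = rankdata(flat[in_mask], axis=1)
    ranks3 = ranks.reshape(vol.shape)

    shape = mask.shape
    w = np.full(shape, np.nan)
    idx = np.argwhere(mask)
    for (i, j, k) in idx:
        coords = offsets + (i, j, k)
        ok = np.all((coords >= 0) & (coords < shape), axis=1)
        coords = coords[ok]
        member = mask[coords[:, 0], coords[:, 1], coords[:, 2]]
        coords = coords[member]
        m = len(coords)
        if m < 2:
            continue
        r = ranks3[coords[:, 0], coords[:, 1], coords[:, 2], :]  # m x t
        r_t = r.sum(axis=0)
        s = ((r_t - m * (n_t + 1) / 2.0) ** 2).sum()
        denom = m**2 * (n_t**3 - n_t)
        if tie_correction:
            corr = 0.0
            for row in r:
                _, counts = np.unique(row, return_counts=True)
                corr += (counts**3 - counts).sum()
            denom -= m * corr
        w[i, j, k] = 12.0 * s / denom if denom > 0 else np.nan
    valid = np.isfinite(w) & mask
    w_norm = np.full(shape, np.nan)
    mean_w = w[valid].mean()
    if mean_w > 0:
        w_norm[valid] = w[valid] / mean_w
    return ReHoMap(w=w, w_normalized=w_norm, mask=valid, neighborhood_size=nsize)


def cluster_mean(values: np.ndarray, cluster_mask: np.ndarray) -> float:
    """Arithmetic mean of a map over a nonempty cluster."""
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    if not cluster_mask.any():
        raise ValueError("empty cluster")
    return float(np.asarray(values, dtype=float)[cluster_mask].mean())
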