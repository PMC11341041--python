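"""Group-level inference on voxel maps.

Voxel-wise two-sample comparison with age and gender covariates (OLS GLM),
cluster formation at a cluster-defining threshold (default one-sided p = 0.001),
and cluster-level multiple-comparison correction by a permutation cluster-extent
null combined with Benjamini-Hochberg across observed clusters. A seed-based
connectivity group map (descriptively thresholded at |t| > 2) is also provided.

The permutation-based cluster correction replaces the random-field-theory
"topological FDR" used by classical SPM analyses: the cluster-defining
threshold and the FDR-across-clusters structure are identical, but the
cluster-extent null distribution is estimated by relabeling groups rather
than by random-field theory. This changes the calibration mechanism, not the
form of the inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "GroupDesign",
    "ClusterResult",
    "voxelwise_glm",
    "form_clusters",
    "cluster_fdr",
    "seed_connectivity",
    "residualize_scores",
    "design_matrix",
    "connectivity_structure",
]


@dataclass
class GroupDesign:
    """Subjects' group membership and covariates.

    ``group`` is coded 1 for the first (e.g. patient) group and 0 for the
    second; the reported t is for group 1 minus group 2.
    """

    group: np.ndarray
    age: np.ndarray
    gender: np.ndarray  # numeric coding, e.g. f=0, m=1

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.gender = np.asarray(self.gender, dtype=float)
        n1, n0 = (self.group == 1).sum(), (self.group == 0).sum()
        if n1 < 2 or n0 < 2:
            raise ValueError("need >= 2 subjects per group")

    @classmethod
    def from_phenotype(cls, pheno: pd.DataFrame, patient_label: str = "patient") -> "GroupDesign":
        return cls(
            group=(pheno["group"] == patient_label).to_numpy(dtype=float),
            age=pheno["age"].to_numpy(dtype=float),
            gender=(pheno["gender"] == "m").to_numpy(dtype=float),
        )


@dataclass
class ClusterResult:
    voxels: np.ndarray            # (k, 3) voxel indices
    extent: int
    peak_t: float                 # signed value of max |t| in the cluster
    peak_index: tuple[int, int, int]
    peak_coordinate: tuple[float, float, float] | None = None  # mm via affine
    sign: int = 1
    p_uncorrected: float | None = None
    q_fdr: float | None = None


def design_matrix(design: GroupDesign) -> np.ndarray:
    x = np.column_stack([
        np.ones(len(design.group)), design.group, design.age, design.gender,
    ])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # find which added columns are collinear
        names = ["intercept", "group", "age", "gender"]
        bad = [names[c] for c in range(1, 4)
               if np.linalg.matrix_rank(np.delete(x, c, axis=1)) == np.linalg.matrix_rank(x)]
        raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")
    return x


def _glm_t(x: np.ndarray, maps: np.ndarray, coef: int = 1) -> tuple[np.ndarray, int]:
    """t statistic of column ``coef`` for every column of ``maps`` (subjects x voxels)."""
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ maps
    resid = maps - x @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * xtx_inv[coef, coef])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[coef] / se, 0.0)
    return t, df


def voxelwise_glm(maps: np.ndarray, design: GroupDesign) -> tuple[np.ndarray, int]:
    """Per-voxel OLS of map value on (intercept, group, age, gender).

    Returns the group-coefficient t map and its residual degrees of freedom
    ``n_subjects - 4``.
    """
    maps = np.asarray(maps, dtype=float)
    x = design_matrix(design)
    if maps.shape[0] != x.shape[0]:
        raise ValueError("maps must be subjects x voxels")
    return _glm_t(x, maps)


def connectivity_structure(connectivity: int = 18) -> np.ndarray:
    """3D binary structure for 6 (face), 18 (face+edge) or 26 (full) connectivity."""
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def form_clusters(t_map: np.ndarray, df: int, cluster_p: float = 0.001,
                  connectivity: int = 18,
                  affine: np.ndarray | None = None) -> list[ClusterResult]:
    """Suprathreshold connected components, positive and negative tails separately.

    The cluster-defining threshold is the one-sided t quantile for
    ``cluster_p`` at ``df``. Components use face+edge (18) connectivity by
    default. ``affine`` maps voxel indices to world mm for peak coordinates.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t_map = np.asarray(t_map, dtype=float)
    thr = stats.t.isf(cluster_p, df)
    structure = connectivity_structure(connectivity)
    results: list[ClusterResult] = []
    for sign in (1, -1):
        supra = (sign * t_map) > thr
        labeled, n = ndimage.label(supra, structure=structure)
        for lab in range(1, n + 1):
            vox = np.argwhere(labeled == lab)
            vals = t_map[tuple(vox.T)]
            peak_k = int(np.argmax(np.abs(vals)))
            peak_index = tuple(int(v) for v in vox[peak_k])
            coord = None
            if affine is not None:
                coord = tuple(float(c) for c in (affine @ np.append(vox[peak_k], 1.0))[:3])
            results.append(ClusterResult(
                voxels=vox, extent=len(vox), peak_t=float(vals[peak_k]),
                peak_index=peak_index, peak_coordinate=coord, sign=sign,
            ))
    results.sort(key=lambda c: -c.extent)
    return results


def cluster_fdr(maps4d: np.ndarray, design: GroupDesign,
                cluster_p: float = 0.001, connectivity: int = 18,
                n_perm: int = 1000, seed: int | None = None,
                mask: np.ndarray | None = None,
                affine: np.ndarray | None = None) -> tuple[list[ClusterResult], np.ndarray]:
    """Cluster-level inference with a permutation extent null and BH across clusters.

    ``maps4d`` is subjects x (x, y, z). Group labels are permuted ``n_perm``
    times with covariates fixed; for each permutation the full GLM + clustering
    pipeline is rerun and the maximal cluster extent over both tails recorded.
    Each observed cluster's ``p_uncorrected`` is the permutation tail
    probability of its extent, and ``q_fdr`` the Benjamini-Hochberg adjusted
    value across all observed clusters (both tails pooled).

    Returns ``(clusters, null_max_extents)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    maps4d = np.asarray(maps4d, dtype=float)
    n = maps4d.shape[0]
    shape3 = maps4d.shape[1:]
    if mask is None:
        mask = np.ones(shape3, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    flat = maps4d.reshape(n, -1)[:, mask.ravel()]

    from math import comb
    n1 = int((design.group == 1).sum())
    if comb(n, n1) - 1 < n_perm:
        raise ValueError(
            f"only {comb(n, n1) - 1} distinct relabelings exist for n={n}, n1={n1}; "
            "reduce n_perm or enumerate exactly")

    def run(groups: np.ndarray) -> list[ClusterResult]:
        d = GroupDesign(group=groups, age=design.age, gender=design.gender)
        t_flat, df = _glm_t(design_matrix(d), flat)
        t_map = np.zeros(shape3)
        t_map[mask] = t_flat
        return form_clusters(t_map, df, cluster_p, connectivity, affine), df

    observed, df = run(design.group)
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm, dtype=int)
    for b in range(n_perm):
        perm = rng.permutation(design.group)
        clusters, _ = run(perm)
        null_max[b] = clusters[0].extent if clusters else 0

    for c in observed:
        c.p_uncorrected = float((1 + (null_max >= c.extent).sum()) / (1 + n_perm))
    if observed:
        p = np.array([c.p_uncorrected for c in observed])
        q = stats.false_discovery_control(p, method="bh")
        for c, qv in zip(observed, q):
            c.q_fdr = float(qv)
    return observed, null_max


def residualize_scores(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of per-subject values on covariates plus intercept."""
    values = np.asarray(values, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] == 1:
        cov = cov.T
    x = np.column_stack([np.ones(cov.shape[0]), cov])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariate matrix rank deficient")
    beta, *_ = np.linalg.lstsq(x, values, rcond=None)
    return values - x @ beta


def seed_connectivity(seed_mask: np.ndarray, subject_volumes: list[np.ndarray],
                      design: GroupDesign, t_threshold: float = 2.0,
                      z_cap: float = 1.0 - 1e-7) -> tuple[np.ndarray, np.ndarray, int]:
    """Seed-based group-difference connectivity map (descriptive).

    For each subject, the mean seed time course is correlated with every voxel,
    Fisher-z transformed (|r| capped below 1), and the per-subject z maps are
    compared with the covariate-adjusted GLM. Returns
    ``(t_map, supra_mask, df)`` where ``supra_mask`` marks |t| > t_threshold.
    The threshold is descriptive, not an inferential cutoff.
    """
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    z_maps = []
    shape3 = subject_volumes[0].shape[:3]
    for vol in subject_volumes:
        seed_ts = vol[seed_mask].mean(axis=0)
        if seed_ts.std() == 0:
            raise ValueError("seed time course has zero variance")
        flat = vol.reshape(-1, vol.shape[-1])
        sd = flat.std(axis=1)
        seed_z = (seed_ts - seed_ts.mean()) / (seed_ts.std() * np.sqrt(len(seed_ts)))
        with np.errstate(invalid="ignore", divide="ignore"):
            centered = (flat - flat.mean(axis=1, keepdims=True)) / (sd * np.sqrt(flat.shape[1]))[:, None]
        r = np.where(sd > 0, centered @ seed_z, 0.0)
        r = np.clip(r, -z_cap, z_cap)
        z_maps.append(np.arctanh(r))
    z_maps = np.asarray(z_maps)
    t_flat, df = voxelwise_glm(z_maps, design)
    t_map = t_flat.reshape(shape3)
    return t_map, np.abs(t_map) > t_threshold, df
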