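"""Synthetic multi-subject resting-state BOLD data with known ground truth.

Generates two-group datasets that emulate the structure of a case-control
resting-state study: block-structured inter-regional correlations with
group differences planted on chosen edges (on the Fisher-z scale), AR(1)
temporal autocorrelation, head-motion traces with scrubbing-triggering
spikes, voxel volumes rendered from ROI time courses, and a phenotype
table with ADHD symptom scores.

Every generator is a pure function of (spec, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationSpec",
    "SubjectDataset",
    "GroundTruth",
    "build_group_covariances",
    "simulate_subject",
    "simulate_motion",
    "render_volumes",
    "simulate_phenotype",
    "make_parcellation",
    "simulate_dataset",
]

# Phenotype defaults: patient/control mean (sd) for the ADHD scales, BDI and age,
# matching the demographic table of the emulated study design.
PHENOTYPE_DEFAULTS = {
    "adhd_rs4": {"patient": (35.82, 10.58), "control": (26.11, 7.65)},
    "adhd_asrs": {"patient": (96.82, 42.15), "control": (64.17, 23.21)},
    "bdi": {"patient": (9.24, 7.42), "control": (7.83, 6.67)},
    "age": {"patient": (36.5, 13.3), "control": (35.2, 14.0)},
}


@dataclass
class SimulationSpec:
    """Parameters of a two-group synthetic resting-state dataset.

    ``planted_edges`` holds ``(roi_i, roi_j, delta_z)`` triples: the group-1
    minus group-2 connectivity difference on the Fisher-z (atanh r) scale.
    """

    n_group1: int = 17
    n_group2: int = 18
    n_volumes: int = 330
    n_initial_dropped: int = 10
    tr: float = 1.46
    n_rois: int = 20
    block_assignment: dict[int, str] | None = None
    baseline_correlation_within: float = 0.3
    baseline_correlation_between: float = 0.05
    planted_edges: list[tuple[int, int, float]] = field(default_factory=list)
    ar_coefficient: float = 0.3
    voxel_noise_sd: float = 1.0
    motion_spike_rate: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group1 < 2 or self.n_group2 < 2:
            raise ValueError("group sizes must be >= 2")
        for r in (self.baseline_correlation_within, self.baseline_correlation_between):
            if not abs(r) < 1:
                raise ValueError(f"baseline correlation {r} must satisfy |r| < 1")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        for i, j, dz in self.planted_edges:
            if not np.isfinite(dz):
                raise ValueError(f"delta_z on edge ({i},{j}) is not finite")
            if i == j or not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                raise ValueError(f"planted edge ({i},{j}) outside the ROI graph")
        if self.block_assignment is None:
            # default: four equal networks
            labels = ["net%d" % (k % 4) for k in range(self.n_rois)]
            self.block_assignment = dict(enumerate(labels))
        missing = set(range(self.n_rois)) - set(self.block_assignment)
        if missing:
            raise ValueError(f"block_assignment missing ROIs {sorted(missing)}")
        # fail fast on a non-PD implied correlation structure
        build_group_covariances(self)


@dataclass
class SubjectDataset:
    """One subject's simulated data and phenotype row."""

    subject_id: str
    group: str  # "patient" | "control"
    roi_series: np.ndarray  # time x ROI
    motion: np.ndarray  # time x 6 (trans mm, rot rad)
    wm_signal: np.ndarray
    csf_signal: np.ndarray
    age: float
    gender: str  # "f" | "m"
    adhd_asrs: float
    adhd_rs4: float
    bdi: float
    volume_series: np.ndarray | None = None  # x,y,z,t
    spike_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = self.roi_series.shape[0]
        if self.motion.shape != (t, 6):
            raise ValueError("motion trace must have one 6-parameter row per volume")
        for name in ("wm_signal", "csf_signal"):
            if len(getattr(self, name)) != t:
                raise ValueError(f"{name} length differs from roi_series")
        if self.volume_series is not None and self.volume_series.shape[-1] != t:
            raise ValueError("volume_series time dimension differs from roi_series")


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    cov_group1: np.ndarray
    cov_group2: np.ndarray
    planted_edges: list[tuple[int, int, float]]
    realized_delta_z: list[tuple[int, int, float]]  # after PD repair
    spike_indices: dict[str, list[int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cov_group1": self.cov_group1.tolist(),
            "cov_group2": self.cov_group2.tolist(),
            "planted_edges": [list(e) for e in self.planted_edges],
            "realized_delta_z": [list(e) for e in self.realized_delta_z],
            "spike_indices": {k: list(map(int, v)) for k, v in self.spike_indices.items()},
        }


def _nearest_correlation(c: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Repair a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the result rescaled to unit
    diagonal. A no-op for matrices that are already valid correlations.
    """
    c = (c + c.T) / 2
    w, v = np.linalg.eigh(c)
    if w.min() >= eig_floor:
        return c
    w = np.clip(w, eig_floor, None)
    c = (v * w) @ v.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def build_group_covariances(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Target correlation matrices for the two groups.

    The baseline is block structured: ``baseline_correlation_within`` inside a
    network, ``baseline_correlation_between`` across networks. Planted edges
    shift the baseline symmetrically on the Fisher-z scale: group 1 gets
    ``+delta_z/2``, group 2 ``-delta_z/2``, so the group difference
    ``atanh(r1) - atanh(r2)`` equals ``delta_z`` (up to the PD repair).
    """
    n = spec.n_rois
    nets = np.asarray([spec.block_assignment[i] for i in range(n)], dtype=object)
    same = nets[:, None] == nets[None, :]
    base = np.where(same, spec.baseline_correlation_within, spec.baseline_correlation_between)
    np.fill_diagonal(base, 1.0)

    def planted(sign: float) -> np.ndarray:
        c = base.copy()
        for i, j, dz in spec.planted_edges:
            r = np.tanh(np.arctanh(base[i, j]) + sign * dz / 2)
            c[i, j] = c[j, i] = r
        return _nearest_correlation(c)

    cov1, cov2 = planted(+1.0), planted(-1.0)
    for cov, name in ((cov1, "group 1"), (cov2, "group 2")):
        w = np.linalg.eigvalsh(cov)
        if w.min() <= 0:
            raise ValueError(
                f"implied {name} correlation matrix is not positive definite "
                f"(min eigenvalue {w.min():.3g}) — reduce planted effects or baseline correlations"
            )
    return cov1, cov2


def realized_deltas(cov1: np.ndarray, cov2: np.ndarray,
                    planted_edges: Sequence[tuple[int, int, float]]) -> list[tuple[int, int, float]]:
    """Post-repair Fisher-z group differences on the planted edges."""
    return [(i, j, float(np.arctanh(cov1[i, j]) - np.arctanh(cov2[i, j])))
            for i, j, _ in planted_edges]


def simulate_subject_series(cov: np.ndarray, n_volumes: int, ar_coefficient: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian AR(1) process with stationary cross-ROI covariance ``cov``.

    Innovations carry covariance ``(1 - phi^2) * cov``, so spatial mixing and
    temporal autocorrelation factorize and the stationary covariance is exactly
    the target.
    """
    w = np.linalg.eigvalsh(cov)
    if w.min() <= 0:
        raise ValueError("covariance must be positive definite")
    chol = np.linalg.cholesky(cov)
    phi = ar_coefficient
    n = cov.shape[0]
    innov = rng.standard_normal((n_volumes, n)) @ chol.T
    series = np.empty((n_volumes, n))
    series[0] = innov[0]  # stationary start: x0 ~ N(0, cov)
    scale = np.sqrt(1 - phi**2)
    for t in range(1, n_volumes):
        series[t] = phi * series[t - 1] + scale * innov[t]
    return series


def simulate_subject(cov: np.ndarray, spec: SimulationSpec, seed: int, *,
                     subject_id: str = "sub-01", group: str = "patient") -> SubjectDataset:
    """Simulate one subject: ROI series, motion, nuisance signals, phenotype row."""
    ss = np.random.SeedSequence([int(seed), spec.rng_seed])
    r_series, r_motion, r_nuis, r_pheno = [np.random.default_rng(s) for s in ss.spawn(4)]

    roi_series = simulate_subject_series(cov, spec.n_volumes, spec.ar_coefficient, r_series)
    motion, spikes = simulate_motion(spec, rng=r_motion)
    wm = r_nuis.standard_normal(spec.n_volumes) * 0.5
    csf = r_nuis.standard_normal(spec.n_volumes) * 0.5

    mcol = "patient" if group == "patient" else "control"
    age = float(np.clip(r_pheno.normal(*PHENOTYPE_DEFAULTS["age"][mcol]), 18, 75))
    gender = "f" if r_pheno.random() < 0.5 else "m"
    scores = {k: float(r_pheno.normal(*PHENOTYPE_DEFAULTS[k][mcol]))
              for k in ("adhd_asrs", "adhd_rs4", "bdi")}
    return SubjectDataset(
        subject_id=subject_id, group=group, roi_series=roi_series, motion=motion,
        wm_signal=wm, csf_signal=csf, age=age, gender=gender,
        spike_indices=spikes, **scores,
    )


def simulate_motion(spec: SimulationSpec, seed: int | None = None, *,
                    rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Six-parameter motion trace: small random walk plus scrubbing-triggering spikes.

    Baseline framewise displacement (Power convention, 50 mm rotation radius)
    stays strictly below 0.5 mm; each spike is a sustained step whose FD at the
    spike index exceeds 0.5 mm. Returns ``(motion, spike_indices)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    t = spec.n_volumes
    steps = np.column_stack([
        rng.normal(0.0, 0.01, size=(t, 3)),      # translations, mm
        rng.normal(0.0, 2e-4, size=(t, 3)),      # rotations, rad (~0.01 mm arc)
    ])
    steps[0] = 0.0
    # keep baseline FD < 0.4 mm with margin
    fd_step = np.abs(steps[:, :3]).sum(axis=1) + 50.0 * np.abs(steps[:, 3:]).sum(axis=1)
    over = fd_step > 0.4
    steps[over] *= (0.4 / fd_step[over])[:, None]

    n_spikes = rng.poisson(spec.motion_spike_rate)
    candidates = np.arange(1, t)
    n_spikes = min(n_spikes, len(candidates))
    spikes = np.sort(rng.choice(candidates, size=n_spikes, replace=False))
    offset = np.zeros(3)  # running spike displacement per axis
    for idx in spikes:
        axis = rng.integers(0, 3)
        step = rng.uniform(0.7, 1.2)
        # sustained step (FD > 0.5 only at idx), signed toward zero offset so
        # spikes do not accumulate into a whole-run exclusion
        sign = -np.sign(offset[axis]) if offset[axis] != 0 else (1 if rng.random() < 0.5 else -1)
        steps[idx, axis] += sign * step
        offset[axis] += sign * step
    motion = np.cumsum(steps, axis=0)
    return motion, spikes


def make_parcellation(shape: tuple[int, int, int] = (24, 24, 24),
                      n_rois: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Compact box-shaped parcellation covering a cuboid grid.

    The grid is split into near-equal boxes along each axis; labels are
    1..n_rois. Returns ``(labels, mask)`` with mask = labels > 0.
    """
    # factor n_rois into three near-cubic counts
    best = None
    for a in range(1, n_rois + 1):
        if n_rois % a:
            continue
        for b in range(1, n_rois // a + 1):
            if (n_rois // a) % b:
                continue
            c = n_rois // (a * b)
            dims = sorted((a, b, c))
            score = dims[2] - dims[0]
            if best is None or score < best[0]:
                best = (score, (a, b, c))
    splits = best[1]
    labels = np.zeros(shape, dtype=np.int32)
    xs = [np.array_split(np.arange(shape[d]), splits[d]) for d in range(3)]
    lab = 1
    for ix in xs[0]:
        for iy in xs[1]:
            for iz in xs[2]:
                labels[np.ix_(ix, iy, iz)] = lab
                lab += 1
    return labels, labels > 0


def render_volumes(roi_series: np.ndarray, parcellation: np.ndarray,
                   voxel_noise_sd: float, seed: int | None = None, *,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Expand a time x ROI matrix into a 4D volume over a labeled parcellation.

    Each voxel's time course is its ROI's series plus independent Gaussian
    noise; voxels outside the parcellation (label 0) are zero.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = np.unique(parcellation[parcellation > 0])
    n_t, n_roi = roi_series.shape
    missing = [int(l) for l in labels if not (1 <= l <= n_roi)]
    if missing:
        raise ValueError(f"parcellation labels missing from roi_series columns: {missing}")
    vol = np.zeros(parcellation.shape + (n_t,), dtype=np.float64)
    inside = parcellation > 0
    # label l -> column l-1
    vol[inside] = roi_series.T[parcellation[inside] - 1]
    if voxel_noise_sd > 0:
        vol[inside] += rng.normal(0.0, voxel_noise_sd, size=(inside.sum(), n_t))
    return vol


def simulate_phenotype(spec: SimulationSpec, seed: int, *,
                       effect_magnitude: np.ndarray | None = None,
                       coupling: float = 0.0,
                       means: dict | None = None) -> pd.DataFrame:
    """Phenotype table for all subjects of a simulated study.

    Scores are Gaussian with group-specific means/SDs (defaults follow the
    emulated study's demographics). If ``effect_magnitude`` (one value per
    subject) is given, ``coupling`` in [0, 1] mixes a rank-preserving signal
    into the ADHD-RS-IV score: at 1 the score is a strictly increasing
    function of the magnitude, enabling Spearman-recovery tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), spec.rng_seed, 7]))
    defaults = means or PHENOTYPE_DEFAULTS
    n = spec.n_group1 + spec.n_group2
    groups = ["patient"] * spec.n_group1 + ["control"] * spec.n_group2
    rows = []
    for k, g in enumerate(groups):
        age = float(np.clip(rng.normal(*defaults["age"][g]), 18, 75))
        rows.append({
            "subject_id": f"sub-{k + 1:02d}",
            "group": g,
            "age": age,
            "gender": "f" if rng.random() < 0.5 else "m",
            "adhd_asrs": float(rng.normal(*defaults["adhd_asrs"][g])),
            "adhd_rs4": float(rng.normal(*defaults["adhd_rs4"][g])),
            "bdi": float(rng.normal(*defaults["bdi"][g])),
        })
    table = pd.DataFrame(rows)
    if effect_magnitude is not None and coupling > 0:
        mag = np.asarray(effect_magnitude, dtype=float)
        if len(mag) != n:
            raise ValueError("effect_magnitude needs one value per subject")
        from scipy.stats import rankdata, norm
        if coupling >= 1.0:
            # degenerate rank-preserving mode: the drawn scores are reassigned
            # so the score is a strictly increasing function of the magnitude
            scores = np.sort(table["adhd_rs4"].to_numpy())
            order = rankdata(mag, method="ordinal").astype(int) - 1
            table["adhd_rs4"] = scores[order]
        else:
            z_sig = norm.ppf((rankdata(mag) - 0.375) / (n + 0.25))  # Blom scores
            z_noise = rng.standard_normal(n)
            z = coupling * z_sig + np.sqrt(1 - coupling**2) * z_noise
            for k, g in enumerate(groups):
                m, s = defaults["adhd_rs4"][g]
                table.loc[k, "adhd_rs4"] = m + s * z[k]
    return table


def simulate_dataset(spec: SimulationSpec, seed: int | None = None,
                     parcellation: np.ndarray | None = None,
                     render: bool = False) -> tuple[list[SubjectDataset], GroundTruth]:
    """Full two-group dataset: per-subject series (optionally rendered volumes),
    phenotype merged into each subject, and the ground truth record."""
    if seed is None:
        seed = spec.rng_seed
    cov1, cov2 = build_group_covariances(spec)
    truth = GroundTruth(cov1, cov2, list(spec.planted_edges),
                        realized_deltas(cov1, cov2, spec.planted_edges))
    pheno = simulate_phenotype(spec, seed)
    subjects = []
    n = spec.n_group1 + spec.n_group2
    child_seeds = np.random.SeedSequence([int(seed), spec.rng_seed, 11]).generate_state(n)
    for k in range(n):
        group = "patient" if k < spec.n_group1 else "control"
        cov = cov1 if group == "patient" else cov2
        sub = simulate_subject(cov, spec, int(child_seeds[k] % (2**31)),
                               subject_id=pheno.subject_id[k], group=group)
        for col in ("age", "gender", "adhd_asrs", "adhd_rs4", "bdi"):
            setattr(sub, col, pheno[col][k])
        if render:
            if parcellation is None:
                raise ValueError("render=True requires a parcellation")
            sub.volume_series = render_volumes(
                sub.roi_series, parcellation, spec.voxel_noise_sd,
                int(child_seeds[k] % (2**31)) ^ 0x5EED)
        truth.spike_indices[sub.subject_id] = list(map(int, sub.spike_indices))
        subjects.append(sub)
    return subjects, truth
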