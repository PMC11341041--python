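"""End-to-end orchestration: simulate (or load) -> preprocess -> voxel metrics
-> group inference -> atlas network analysis -> behavioral statistics.

``run_pipeline`` executes the stages in dependency order on a synthetic
dataset, drops subjects failing the motion-exclusion rule, and writes the
stage outputs (cluster table, edge table, CIRCOS link file, manifest) under
``config.output_dir``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import network, voxel_metrics
from .group_inference import GroupDesign, cluster_fdr, voxelwise_glm
from .io import PipelineConfig, write_json, write_nifti, write_tsv
from .preprocess import motion_exclusion_flag, preprocess_series
from .simulate import (SimulationSpec, make_parcellation, render_volumes,
                       simulate_dataset)

log = logging.getLogger("boldgraph")

__all__ = ["RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    excluded_subjects: list = field(default_factory=list)
    censored_volumes: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "excluded_subjects": self.excluded_subjects,
            "censored_volumes": self.censored_volumes,
            "stages": self.stages,
            "outputs": self.outputs,
        }


def _hash_config(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, spec: SimulationSpec | None = None,
                 grid: tuple[int, int, int] = (24, 24, 24),
                 output_dir: str | Path | None = None) -> RunManifest:
    """Simulate a two-group study and run every analysis stage on it.

    Stages: simulate volumes on a labeled grid; per-subject preprocessing
    (drop, nuisance regression, smoothing, bandpass, scrubbing) with motion
    exclusion; degree-centrality and ReHo maps; voxel-wise GLM with
    permutation cluster correction; ROI connectivity, edge-wise tests and NBS
    for both tails; behavioral summary table. Outputs are written as TSV /
    NIfTI / JSON under the output directory and recorded in the manifest.
    """
    from . import __version__
    from .behavior import group_summary_table

    config.validate()
    if spec is None:
        spec = SimulationSpec(rng_seed=config.rng_seed)
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_hash_config(config), seed=config.rng_seed,
                           version=__version__)

    def stage(name):
        t0 = time.time()
        log.info("stage %s", name)
        manifest.stages.append({"name": name, "started": t0})
        return t0

    def done(t0):
        manifest.stages[-1]["seconds"] = round(time.time() - t0, 3)

    rng_root = np.random.SeedSequence(config.rng_seed)

    t0 = stage("simulate")
    parcellation, mask = make_parcellation(grid, spec.n_rois)
    subjects, truth = simulate_dataset(spec, seed=config.rng_seed)
    write_json(out / "ground_truth.json", truth.to_dict())
    labels = pd.DataFrame({
        "label_id": np.arange(1, spec.n_rois + 1),
        "name": [f"roi{k:03d}" for k in range(1, spec.n_rois + 1)],
        "network": [spec.block_assignment[k] for k in range(spec.n_rois)],
    })
    write_tsv(out / "roi_labels.tsv", labels)
    write_nifti(out / "parcellation.nii.gz", parcellation.astype(np.int16),
                np.diag([3.0, 3.0, 3.0, 1.0]))
    done(t0)

    # subject-level work is streamed: each subject's volumes are rendered,
    # preprocessed and reduced to maps/matrices before the next is touched,
    # so peak memory stays at one subject's 4D data
    t0 = stage("subject_level")
    kept, deg_maps, reho_maps, conn = [], [], [], []
    affine = np.diag([3.0, 3.0, 3.0, 1.0])  # 3 mm isotropic synthetic grid
    render_seeds = np.random.SeedSequence([config.rng_seed, 23]).generate_state(len(subjects))
    for k, sub in enumerate(subjects):
        try:
            if motion_exclusion_flag(sub.motion, config.preprocess):
                manifest.excluded_subjects.append(
                    {"subject_id": sub.subject_id, "reason": "head motion"})
                log.info("excluding %s (head motion)", sub.subject_id)
                continue
            raw = render_volumes(sub.roi_series, parcellation, spec.voxel_noise_sd,
                                 int(render_seeds[k] % (2**31)))
            vol, censor, fd = preprocess_series(
                None, sub.motion, config.tr,
                nuisance=np.column_stack([sub.wm_signal, sub.csf_signal]),
                config=config.preprocess, volume4d=raw, voxel_size=3.0)
            del raw
            manifest.censored_volumes[sub.subject_id] = censor.n_censored
            flat = vol.reshape(-1, vol.shape[-1]).T  # time x voxels
            dm = voxel_metrics.degree_centrality(flat, mask.ravel(), config.r_threshold)
            deg_maps.append(dm.z_degree.reshape(mask.shape))
            rh = voxel_metrics.reho(vol, mask, config.reho_neighborhood)
            reho_maps.append(rh.w_normalized)
            roi_series = network.extract_roi_series(vol, parcellation)
            conn.append(network.connectivity_matrix(roi_series, labels))
        except Exception as err:
            raise RuntimeError(f"stage subject_level failed for {sub.subject_id}") from err
        kept.append(sub)
    if len(kept) < 4:
        raise RuntimeError("stage subject_level: too few subjects survived exclusion")
    deg_maps = np.asarray(deg_maps)
    done(t0)

    pheno = pd.DataFrame([{
        "subject_id": s.subject_id, "group": s.group, "age": s.age,
        "gender": s.gender, "adhd_asrs": s.adhd_asrs, "adhd_rs4": s.adhd_rs4,
        "bdi": s.bdi} for s in kept])
    write_tsv(out / "phenotype.tsv", pheno)
    design = GroupDesign.from_phenotype(pheno)

    t0 = stage("cluster_inference")
    sub_seed = int(rng_root.generate_state(1)[0] % (2**31))
    clusters, null_ext = cluster_fdr(
        deg_maps, design, cluster_p=config.cluster_p,
        connectivity=config.connectivity, n_perm=config.n_perm_cluster,
        seed=sub_seed, mask=mask, affine=affine)
    cluster_rows = []
    for c in clusters:
        roi_at_peak = int(parcellation[c.peak_index])
        cluster_rows.append({
            "region": labels.loc[roi_at_peak - 1, "name"] if roi_at_peak else "outside",
            "direction": "group1>group2" if c.sign > 0 else "group1<group2",
            "q_fdr": c.q_fdr, "k": c.extent,
            "peak_x_mm": c.peak_coordinate[0], "peak_y_mm": c.peak_coordinate[1],
            "peak_z_mm": c.peak_coordinate[2], "peak_t": c.peak_t,
        })
    cluster_table = pd.DataFrame(
        cluster_rows, columns=["region", "direction", "q_fdr", "k",
                               "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_t"])
    write_tsv(out / "cluster_table.tsv", cluster_table)
    write_json(out / "cluster_null_extents.json",
               {"null_max_extents": null_ext, "n_perm": config.n_perm_cluster})
    log.info("clusters found: %d", len(clusters))
    done(t0)

    t0 = stage("reho_group")
    reho_t, reho_df = voxelwise_glm(
        np.asarray([np.nan_to_num(m, nan=1.0) for m in reho_maps]).reshape(len(kept), -1),
        design)
    write_nifti(out / "reho_group_t.nii.gz", reho_t.reshape(mask.shape), affine)
    done(t0)

    t0 = stage("network")
    edge_test = network.edgewise_ttest(conn, design.group)
    seeds = rng_root.generate_state(3)
    results = []
    for tail, s in zip(("greater", "less"), seeds[1:]):
        results.append(network.nbs(conn, design.group, config.nbs_primary_p,
                                   tail, config.n_perm_nbs, int(s % (2**31))))
    edge_rows = []
    iu = np.triu_indices(spec.n_rois, k=1)
    thr = results[0].t_threshold
    for i, j in zip(*iu):
        if abs(edge_test.t[i, j]) > thr:
            edge_rows.append({
                "node1": labels.loc[i, "name"], "node2": labels.loc[j, "name"],
                "t": edge_test.t[i, j], "df": edge_test.df, "p": edge_test.p[i, j]})
    write_tsv(out / "edge_table.tsv",
              pd.DataFrame(edge_rows, columns=["node1", "node2", "t", "df", "p"]))
    link_df = network.export_edges(results, edge_test, labels)
    network.write_circos_links(link_df, labels, out / "circos_links.tsv")
    write_json(out / "nbs_results.json", {
        r.tail: {"components": [{"edges": c["edges"], "extent": c["extent"],
                                 "p_fwer": c["p_fwer"]} for c in r.components],
                 "t_threshold": r.t_threshold, "df": r.df}
        for r in results})
    log.info("NBS components: %s",
             {r.tail: len(r.components) for r in results})
    done(t0)

    t0 = stage("behavior")
    from .behavior import spearman_with_residualization
    write_tsv(out / "behavior_table.tsv", group_summary_table(pheno))
    # brain-behavior: per-subject mean z-degree in each cluster, and the
    # residualized Spearman correlation with the ADHD score in the patient group
    if clusters:
        rows = []
        for ci, c in enumerate(clusters):
            cmask = np.zeros(mask.shape, dtype=bool)
            cmask[tuple(c.voxels.T)] = True
            for s, m in zip(kept, deg_maps):
                rows.append({"subject_id": s.subject_id, "cluster": ci,
                             "mean_z_degree": voxel_metrics.cluster_mean(m, cmask)})
        means = pd.DataFrame(rows)
        write_tsv(out / "cluster_means.tsv", means)
        top = means[means.cluster == 0].reset_index(drop=True)
        pat = pheno["group"] == "patient"
        if pat.sum() >= 4:
            cov = np.column_stack([pheno.loc[pat, "age"],
                                   (pheno.loc[pat, "gender"] == "m").astype(float)])
            try:
                rho, p = spearman_with_residualization(
                    top.loc[pat.to_numpy(), "mean_z_degree"].to_numpy(), cov,
                    pheno.loc[pat, "adhd_rs4"].to_numpy())
                write_json(out / "brain_behavior.json", {
                    "cluster": 0, "rho": rho, "p": p, "n": int(pat.sum()),
                    "covariates": ["age", "gender"], "score": "adhd_rs4"})
            except ValueError as err:
                log.info("brain-behavior correlation skipped: %s", err)
    done(t0)

    manifest.outputs = {p.name: _sha256(p) for p in sorted(out.iterdir())
                        if p.name != "manifest.json"}
    write_json(out / "manifest.json", manifest.to_dict())
    return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]
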