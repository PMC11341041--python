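"""End-to-end run: simulate, preprocess, voxel metrics, inference, network, export.

Uses a reduced grid (14^3, 24 ROIs, 12 + 12 subjects) so the whole pipeline
finishes in well under a minute; the study-scale configuration (35 subjects,
392 ROIs, 330 volumes) is what scripts/acceptance.py runs.
"""

from pathlib import Path

from boldgraph.io import PipelineConfig, read_tsv
from boldgraph.pipeline import run_pipeline
from boldgraph.simulate import SimulationSpec

spec = SimulationSpec(n_group1=12, n_group2=12, n_volumes=180, n_rois=24,
                      planted_edges=[(0, 6, 0.6), (0, 12, 0.6), (6, 12, 0.6)],
                      motion_spike_rate=2.0, rng_seed=9)
cfg = PipelineConfig(n_perm_cluster=200, n_perm_nbs=500, rng_seed=9,
                     output_dir="boldgraph_example_out")
manifest = run_pipeline(cfg, spec, grid=(14, 14, 14))

out = Path(cfg.output_dir)
print("stages run:", [s["name"] for s in manifest.stages])
print("subjects excluded for motion:", len(manifest.excluded_subjects))
print("volumes censored per subject:", dict(list(manifest.censored_volumes.items())[:4]), "...")

clusters = read_tsv(out / "cluster_table.tsv")
print(f"\ncluster table ({len(clusters)} clusters): columns {list(clusters.columns)}")
edges = read_tsv(out / "edge_table.tsv")
print(f"edge table: {len(edges)} suprathreshold edges")
links = read_tsv(out / "circos_links.tsv")
print(f"CIRCOS link file: {len(links)} undirected links from suprathreshold NBS components")
# every output (tables, NIfTI maps, manifest with per-file checksums) is under
print("outputs in:", out)
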