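"""File formats and configuration: NIfTI, TSV, JSON, YAML.

Thin wrappers over nibabel and pandas so the rest of the package never touches
file handles directly; plus validated loading of the pipeline configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .preprocess import PreprocessConfig

__all__ = [
    "PipelineConfig",
    "read_nifti",
    "write_nifti",
    "read_tsv",
    "write_tsv",
    "read_config",
    "write_json",
]


@dataclass
class PipelineConfig:
    """Nested configuration for a full pipeline run."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    r_threshold: float = 0.25
    reho_neighborhood: int = 27
    cluster_p: float = 0.001
    nbs_primary_p: float = 0.0001
    n_perm_cluster: int = 1000
    n_perm_nbs: int = 5000
    connectivity: int = 18
    tr: float = 1.46
    rng_seed: int = 0
    output_dir: str = "boldgraph_out"

    def validate(self) -> None:
        self.preprocess.validate(tr=self.tr)
        if not 0 < self.r_threshold < 1:
            raise ValueError("r_threshold must lie in (0, 1)")
        if self.reho_neighborhood not in (7, 19, 27):
            raise ValueError("reho_neighborhood must be 7, 19 or 27")
        for name in ("cluster_p", "nbs_primary_p"):
            v = getattr(self, name)
            if not 0 < v < 0.5:
                raise ValueError(f"{name} must lie in (0, 0.5)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        for name in ("n_perm_cluster", "n_perm_nbs"):
            if getattr(self, name) < 100:
                raise ValueError(f"{name} must be >= 100")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        pp = data.pop("preprocess", {})
        known_pp = set(PreprocessConfig.__dataclass_fields__)
        unknown = set(pp) - known_pp
        if unknown:
            raise ValueError(f"unknown preprocess keys: {sorted(unknown)}")
        known = set(cls.__dataclass_fields__) - {"preprocess"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(preprocess=PreprocessConfig(**pp), **data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def read_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON pipeline configuration; defaults fill missing keys."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return PipelineConfig.from_dict(data or {})


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Return (data, affine) from a NIfTI file."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_nifti(path: str | Path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_tsv(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"TSV {path} missing required columns: {missing}")
    return df


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_json(path: str | Path, data: dict) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
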