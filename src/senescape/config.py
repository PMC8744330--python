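"""Pipeline configuration: flat key-value YAML with strict key checking.

Every threshold is exposed with its conventional default (edge FDR 0.05,
module q 0.05, consensus k-means k=4 with 100 runs, conservation weight
cutoff 5, 3-layer neighborhoods, LogNormalize scale 10,000, marker filters
FDR<0.05 / lfc 0.25 / fraction 0.25, 1,000 GSEA permutations, 10,000
ligand-receptor permutations, voxel calling at p<0.01).  One master seed
deterministically derives per-stage seeds via SHA-256 of
``"<master>:<stage>"`` so any stage can be re-run in isolation.
Unknown configuration keys are errors, not warnings.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # cohort simulation (bundled small cohort)
    simulate: bool = True
    inputs_dir: str | None = None
    n_tissues: int = 3
    n_genes: int = 300
    n_samples_per_tissue: int = 40
    module_size: int = 50
    module_correlation: float = 0.7
    n_modules_per_tissue: int = 2
    n_sngs_planted: int = 30
    n_sngs_decoy: int = 30
    n_cells: int = 800
    n_sc_genes: int = 1000
    spatial_side: int = 20
    # analysis thresholds (conventional defaults)
    adjust_age: bool = False
    edge_fdr: float = 0.05
    module_q: float = 0.05
    min_module_size: int = 10
    max_module_depth: int = 4
    module_rewires: int = 100
    kmeans_k: int = 4
    kmeans_runs: int = 100
    min_conservation_weight: int = 5
    neighborhood_layers: int = 3
    sc_scale: float = 10_000.0
    marker_fdr: float = 0.05
    marker_lfc: float = 0.25
    marker_min_frac: float = 0.25
    gsea_permutations: int = 1000
    lr_permutations: int = 10_000
    coexistence_background: int = 1000
    voxel_p: float = 0.01
    cell_p: float = 0.01
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config; every key must be a PipelineConfig field."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key-value mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return PipelineConfig(**raw)


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2 ** 31)
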