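"""Synthetic cohorts with the statistical structure the pipeline assumes.

Each generator is a pure function of its spec (seed included): bulk tissues
with block-correlated gene modules and planted senescence genes (SnGs),
single-cell datasets with cell-type-specific markers and dropout, a
ligand-receptor table with pairs planted in marker sets, and spatial voxels
as cell-type mixtures with an expression-elevated region.

Count model throughout: lognormal latent expression -> Poisson counts.
This yields overdispersed counts while the downstream statistics only rely
on rank/correlation structure. Dropout in single cells is Bernoulli
thinning independent of expression level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

AGE_BIN_MIDPOINTS = np.array([25.0, 35.0, 45.0, 55.0, 65.0, 75.0])
#: Donor ages are recorded in ten-year bins; the bin midpoint is used.

COVARIATE_COLUMNS = ["site", "rin", "ischemic_time", "exonic_rate",
                     "rrna_rate", "intergenic_rate", "sex", "age"]


# --------------------------------------------------------------------------
# Bulk cohort
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BulkCohortSpec:
    """Parameters of a multi-tissue bulk RNA-seq cohort.

    ``modules_per_tissue`` lists ``(module_size, within_correlation)`` blocks;
    the same block layout is used in every tissue, but the latent module
    factors are independent across tissues.  ``sng_planting`` maps a tissue
    name to the module index whose membership is forced to contain
    ``sng_genes``.  ``covariate_effects`` are global technical effects in
    log-expression units per covariate SD.  ``age_effect_modules`` get a
    linear trend of ``age_slope`` log-expression units per decade.
    """

    n_tissues: int = 3
    n_genes: int = 300
    n_samples_per_tissue: int = 60
    modules_per_tissue: Sequence[tuple[int, float]] = ((50, 0.7), (50, 0.7))
    sng_genes: Sequence[str] = ()
    sng_planting: Mapping[str, int] = field(default_factory=dict)
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"rin": 0.3, "exonic_rate": 0.2, "site": 0.2})
    age_effect_modules: frozenset[int] = frozenset()
    age_slope: float = 0.3
    base_mean: float = 150.0
    noise_sd: float = 0.6
    depth_sd: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if sum(size for size, _ in self.modules_per_tissue) > self.n_genes:
            raise ValueError("module sizes sum exceeds n_genes")
        for _, rho in self.modules_per_tissue:
            if not (0.0 <= rho < 1.0):
                raise ValueError(f"within_correlation {rho} outside [0, 1)")
        if self.n_samples_per_tissue < 2:
            raise ValueError("need at least 2 samples per tissue")

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i + 1}" for i in range(self.n_tissues)]

    @property
    def genes(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]


@dataclass
class BulkTissue:
    """One tissue's raw counts (gene x sample) plus its sample covariates."""

    counts: pd.DataFrame
    covariates: pd.DataFrame


def _gen_covariates(rng: np.random.Generator, n: int, tissue: str) -> pd.DataFrame:
    return pd.DataFrame({
        "site": rng.choice(["B1", "C1", "D1"], size=n),
        "rin": rng.normal(7.5, 0.8, size=n),
        "ischemic_time": rng.normal(600.0, 150.0, size=n),
        "exonic_rate": rng.normal(0.80, 0.05, size=n),
        "rrna_rate": rng.normal(0.05, 0.02, size=n),
        "intergenic_rate": rng.normal(0.10, 0.03, size=n),
        "sex": rng.choice(["M", "F"], size=n),
        "age": rng.choice(AGE_BIN_MIDPOINTS, size=n),
    }, index=[f"{tissue}_s{j + 1}" for j in range(n)])


def _covariate_design(covars: pd.DataFrame) -> pd.DataFrame:
    """Standardized numeric columns plus standardized category indicators."""
    cols = {}
    for name in covars.columns:
        col = covars[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True)
            for dcol in dummies.columns:
                cols[dcol] = dummies[dcol].astype(float)
        else:
            cols[name] = col.astype(float)
    design = pd.DataFrame(cols, index=covars.index)
    sd = design.std(ddof=0).replace(0.0, 1.0)
    return (design - design.mean()) / sd


def _module_memberships(spec: BulkCohortSpec, tissue: str) -> list[list[str]]:
    """Assign genes to this tissue's modules; SnGs forced into the planted one."""
    genes = spec.genes
    planted = spec.sng_planting.get(tissue)
    sngs = [g for g in spec.sng_genes if g in set(genes)]
    if len(sngs) != len(spec.sng_genes):
        missing = set(spec.sng_genes) - set(genes)
        raise ValueError(f"sng_genes not in universe: {sorted(missing)}")
    pool = [g for g in genes if g not in set(sngs)]
    members: list[list[str]] = []
    cursor = 0
    for idx, (size, _rho) in enumerate(spec.modules_per_tissue):
        if planted is not None and idx == planted:
            if len(sngs) > size:
                raise ValueError("planted module smaller than SnG list")
            fill = pool[cursor:cursor + (size - len(sngs))]
            cursor += size - len(sngs)
            members.append(sorted(sngs + fill))
        else:
            members.append(pool[cursor:cursor + size])
            cursor += size
    return members


def gen_bulk_cohort(spec: BulkCohortSpec) -> tuple[dict[str, BulkTissue], dict]:
    """Generate raw counts per tissue plus a ground-truth record.

    Latent log-expression of gene g in sample j:

        mu_g + noise_sd * (sqrt(rho) * f_module + sqrt(1-rho) * eps)
             + covariate effects + age trend

    where ``f_module`` is one factor per (tissue, module) so that any two
    genes of a module have latent correlation ``rho``.  Counts are Poisson
    draws of ``exp(latent) * sample_depth``.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.genes
    n_genes, n = spec.n_genes, spec.n_samples_per_tissue
    # gene-level base abundance, shared across tissues
    mu = np.log(spec.base_mean) + rng.normal(0.0, 0.4, size=n_genes)

    tissues: dict[str, BulkTissue] = {}
    truth: dict = {"modules": {}, "sng_modules": {}, "genes": list(genes)}
    gene_pos = {g: i for i, g in enumerate(genes)}

    for tissue in spec.tissues:
        covars = _gen_covariates(rng, n, tissue)
        members = _module_memberships(spec, tissue)
        latent = mu[:, None] + spec.noise_sd * rng.normal(size=(n_genes, n))
        for idx, ((_, rho), mem) in enumerate(zip(spec.modules_per_tissue, members)):
            rows = [gene_pos[g] for g in mem]
            f = rng.normal(size=n)
            eps = rng.normal(size=(len(rows), n))
            latent[rows] = (mu[rows, None]
                            + spec.noise_sd * (np.sqrt(rho) * f
                                               + np.sqrt(1.0 - rho) * eps))
            if idx in spec.age_effect_modules:
                trend = spec.age_slope * (covars["age"].to_numpy() - 50.0) / 10.0
                latent[rows] += trend[None, :]
        design = _covariate_design(covars.drop(columns=["age"]))
        for cov, beta in spec.covariate_effects.items():
            cols = [c for c in design.columns if c == cov or c.startswith(f"{cov}_")]
            for c in cols:
                latent += beta * design[c].to_numpy()[None, :]
        depth = np.exp(rng.normal(0.0, spec.depth_sd, size=n))
        counts = rng.poisson(np.exp(latent) * depth[None, :])
        tissues[tissue] = BulkTissue(
            counts=pd.DataFrame(counts, index=genes, columns=covars.index),
            covariates=covars)
        truth["modules"][tissue] = [list(m) for m in members]
        if tissue in spec.sng_planting:
            truth["sng_modules"][tissue] = spec.sng_planting[tissue]
    return tissues, truth


# --------------------------------------------------------------------------
# SnG annotation
# --------------------------------------------------------------------------

def gen_sng_annotation(n_total: int, universe: Sequence[str], seed: int = 0,
                       inducer_fraction: float = 153 / 279) -> pd.DataFrame:
    """Draw a stand-in senescence-gene annotation from ``universe``.

    Returns a table with columns ``gene`` and ``role`` (inducer/inhibitor).
    The default inducer share mirrors the 153-of-279 inducer split of the
    CellAge-style annotation the pipeline is designed around.
    """
    if n_total > len(universe):
        raise ValueError("n_total exceeds universe size")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(list(universe), size=n_total, replace=False))
    n_inducers = int(round(inducer_fraction * n_total))
    roles = np.array(["inhibitor"] * n_total, dtype=object)
    inducer_idx = rng.choice(n_total, size=n_inducers, replace=False) if n_total else []
    roles[list(inducer_idx)] = "inducer"
    return pd.DataFrame({"gene": chosen, "role": roles})


# --------------------------------------------------------------------------
# Single-cell cohort
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CellTypeSpec:
    name: str
    proportion: float
    n_marker_genes: int
    marker_log_fold_change: float = 2.0


@dataclass(frozen=True)
class ScCohortSpec:
    """Parameters of a synthetic scRNA-seq dataset.

    Marker genes are disjoint gene blocks per cell type, elevated by
    ``marker_log_fold_change`` (natural-log scale) in their own type.
    ``planted_sng_celltypes`` additionally elevates given genes (typically
    SnGs) in given types by ``sng_log_fold_change``.
    """

    n_cells: int = 800
    n_genes: int = 1000
    cell_types: Sequence[CellTypeSpec] = (
        CellTypeSpec("typeA", 0.4, 50), CellTypeSpec("typeB", 0.35, 50),
        CellTypeSpec("typeC", 0.25, 50))
    base_mean: float = 1.0
    dropout_rate: float = 0.3
    planted_sng_celltypes: Mapping[str, Sequence[str]] = field(default_factory=dict)
    sng_log_fold_change: float = 2.0
    genes: Sequence[str] | None = None
    cell_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        total = sum(ct.proportion for ct in self.cell_types)
        if abs(total - 1.0) > 1e-8:
            raise ValueError("cell type proportions must sum to 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if sum(ct.n_marker_genes for ct in self.cell_types) > self.n_genes:
            raise ValueError("marker gene blocks exceed n_genes")
        if self.genes is not None and len(self.genes) != self.n_genes:
            raise ValueError("genes list length must equal n_genes")


def gen_scrna(spec: ScCohortSpec) -> ad.AnnData:
    """Generate a cells x genes AnnData with raw counts and truth record.

    ``obs['cell_type']`` carries the true labels; ``uns['truth']`` records
    the planted marker genes per type and the dropout mask statistics.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.genes is not None:
        genes = list(spec.genes)
    else:
        width = len(str(spec.n_genes))
        genes = [f"G{i + 1:0{width}d}" for i in range(spec.n_genes)]
    gene_pos = {g: i for i, g in enumerate(genes)}

    # cell labels: deterministic blocks by proportion, in spec order
    counts_per_type = [int(round(ct.proportion * spec.n_cells)) for ct in spec.cell_types]
    counts_per_type[-1] = spec.n_cells - sum(counts_per_type[:-1])
    labels = np.repeat([ct.name for ct in spec.cell_types], counts_per_type)

    mu = np.log(spec.base_mean) + rng.normal(0.0, 0.3, size=spec.n_genes)
    type_mu = {ct.name: mu.copy() for ct in spec.cell_types}
    truth_markers: dict[str, list[str]] = {}
    cursor = 0
    for ct in spec.cell_types:
        block = genes[cursor:cursor + ct.n_marker_genes]
        cursor += ct.n_marker_genes
        truth_markers[ct.name] = block
        rows = [gene_pos[g] for g in block]
        type_mu[ct.name][rows] += ct.marker_log_fold_change
    for name, elevated in spec.planted_sng_celltypes.items():
        rows = [gene_pos[g] for g in elevated]
        type_mu[name][rows] += spec.sng_log_fold_change
        # genes elevated in one type are markers of that type by construction
        truth_markers[name] = sorted(set(truth_markers[name]) | set(elevated))

    latent = np.empty((spec.n_cells, spec.n_genes))
    for i, lab in enumerate(labels):
        latent[i] = type_mu[lab] + spec.cell_noise_sd * rng.normal(size=spec.n_genes)
    counts = rng.poisson(np.exp(latent)).astype(np.int64)
    pre_dropout_nonzero = int((counts > 0).sum())
    if spec.dropout_rate > 0:
        keep = rng.random(counts.shape) >= spec.dropout_rate
        counts = counts * keep
    adata = ad.AnnData(
        X=counts.astype(np.float64),
        obs=pd.DataFrame({"cell_type": pd.Categorical(labels)},
                         index=[f"cell{i + 1}" for i in range(spec.n_cells)]),
        var=pd.DataFrame(index=genes))
    adata.uns["truth"] = {
        "markers": truth_markers,
        "pre_dropout_nonzero": pre_dropout_nonzero,
        "dropout_rate": spec.dropout_rate,
    }
    return adata


# --------------------------------------------------------------------------
# Ligand-receptor table
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LRSpec:
    """Planted ligand-receptor pairs plus decoys from non-marker genes."""

    planted_pairs: Sequence[tuple[str, str]]
    n_decoys: int
    universe: Sequence[str]
    marker_genes: frozenset[str] = frozenset()
    seed: int = 0

    def __post_init__(self):
        pool = set(self.universe)
        for lig, rec in self.planted_pairs:
            if lig == rec:
                raise ValueError(f"ligand equals receptor: {lig}")
            if lig not in pool or rec not in pool:
                raise ValueError(f"pair ({lig}, {rec}) outside gene universe")


def gen_lr_db(spec: LRSpec) -> pd.DataFrame:
    """Two-column (ligand, receptor) table: planted pairs then decoys."""
    rng = np.random.default_rng(spec.seed)
    rows = [(l, r) for l, r in spec.planted_pairs]
    decoy_pool = sorted(set(spec.universe) - set(spec.marker_genes))
    for _ in range(spec.n_decoys):
        lig, rec = rng.choice(decoy_pool, size=2, replace=False)
        rows.append((str(lig), str(rec)))
    return pd.DataFrame(rows, columns=["ligand", "receptor"])


# --------------------------------------------------------------------------
# Spatial slide
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpatialSpec:
    """A grid of voxels, each a simplex mixture of cell-type profiles.

    ``cell_type_profiles`` is a genes x types table of mean expression.
    ``compositions`` (voxels x types) may be supplied; otherwise Dirichlet
    weights are drawn, biased toward the first type inside
    ``enriched_region`` so the planted region has a distinct composition.
    Voxels in ``enriched_region`` have ``module_genes`` multiplied by
    exp(module_log_offset).
    """

    n_side: int = 20
    cell_type_profiles: pd.DataFrame = None  # genes x types
    compositions: pd.DataFrame | None = None
    enriched_region: frozenset[int] = frozenset()
    module_genes: Sequence[str] = ()
    module_log_offset: float = 1.0
    dirichlet_alpha: float = 1.0
    region_bias: float = 4.0
    noise_sd: float = 0.1
    depth: float = 1.0
    seed: int = 0

    @property
    def n_voxels(self) -> int:
        return self.n_side ** 2


def gen_spatial(spec: SpatialSpec) -> ad.AnnData:
    """Generate a voxels x genes AnnData slide.

    ``layers['expected']`` holds the noise-free composition-weighted mixture
    (before the lognormal noise and Poisson sampling), ``obs`` the grid
    coordinates, and ``obsm['composition']`` the simplex weights.
    """
    rng = np.random.default_rng(spec.seed)
    profiles = spec.cell_type_profiles
    if profiles is None:
        raise ValueError("cell_type_profiles is required")
    genes = list(profiles.index)
    types = list(profiles.columns)
    n_vox = spec.n_voxels
    if spec.compositions is not None:
        comp = spec.compositions.to_numpy(dtype=float)
        if comp.shape != (n_vox, len(types)):
            raise ValueError("compositions shape mismatch")
    else:
        alphas = np.full(len(types), spec.dirichlet_alpha)
        comp = rng.dirichlet(alphas, size=n_vox)
        if spec.enriched_region:
            region = sorted(spec.enriched_region)
            biased = np.full(len(types), spec.dirichlet_alpha)
            biased[0] *= spec.region_bias
            comp[region] = rng.dirichlet(biased, size=len(region))
    if np.any(comp < 0) or not np.allclose(comp.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("compositions must be nonnegative and sum to 1 per voxel")

    expected = comp @ profiles.to_numpy(dtype=float).T  # voxels x genes
    gene_pos = {g: i for i, g in enumerate(genes)}
    module_cols = [gene_pos[g] for g in spec.module_genes]
    region = sorted(spec.enriched_region)
    if region and module_cols:
        expected[np.ix_(region, module_cols)] *= np.exp(spec.module_log_offset)

    noisy = expected * np.exp(rng.normal(0.0, spec.noise_sd, size=expected.shape)) \
        if spec.noise_sd > 0 else expected
    counts = rng.poisson(spec.depth * noisy).astype(np.float64)

    side = spec.n_side
    coords = pd.DataFrame({
        "x": np.repeat(np.arange(side), side),
        "y": np.tile(np.arange(side), side),
    }, index=[f"voxel{i + 1}" for i in range(n_vox)])
    adata = ad.AnnData(X=counts, obs=coords, var=pd.DataFrame(index=genes))
    adata.layers["expected"] = expected
    adata.obsm["composition"] = pd.DataFrame(comp, index=coords.index, columns=types)
    adata.uns["truth"] = {"enriched_region": [int(i) for i in region],
                          "module_genes": list(spec.module_genes)}
    return adata


def profiles_from_scrna(adata: ad.AnnData, label_key: str = "cell_type") -> pd.DataFrame:
    """Mean raw-count profile per cell type (genes x types), for gen_spatial."""
    out = {}
    for name, idx in adata.obs.groupby(label_key, observed=True).groups.items():
        out[str(name)] = np.asarray(adata[idx].X).mean(axis=0)
    return pd.DataFrame(out, index=adata.var_names)
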