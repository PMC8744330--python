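"""End-to-end orchestration of the senescence-landscape analysis.

``run_pipeline`` executes the stages in dependency order — preprocess ->
networks -> module enrichment -> SnG landscape -> aggregation ->
single-cell -> interactions -> spatial — reading every input from plain
text files (generated by :func:`generate_inputs` when simulating), writing
every output as a TSV with a metadata header, and finishing with a
machine-readable manifest (config, per-stage seeds, SHA-256 checksums).
Identical config and inputs give byte-identical manifests.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from . import __version__, aggregation, bulk_preprocess, cell_interactions
from . import io as sio
from . import module_stats, network, single_cell, sng_landscape, spatial
from . import synthetic_data as syn
from .config import PipelineConfig, derive_seed


# --------------------------------------------------------------------------
# Input generation (the bundled synthetic cohort)
# --------------------------------------------------------------------------

def build_cohort_specs(cfg: PipelineConfig) -> dict:
    """Derive all generator specs (bulk, SnG set, sc, LR, spatial) from config."""
    rng = np.random.default_rng(derive_seed(cfg.seed, "cohort"))
    width = len(str(cfg.n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(cfg.n_genes)]
    picked = sorted(rng.choice(genes, size=cfg.n_sngs_planted + cfg.n_sngs_decoy,
                               replace=False))
    planted = sorted(rng.choice(picked, size=cfg.n_sngs_planted, replace=False))
    decoys = sorted(set(picked) - set(planted))
    sng_table = pd.DataFrame({
        "gene": planted + decoys,
        "role": ["inducer"] * len(planted) + ["inhibitor"] * len(decoys),
    }).sort_values("gene").reset_index(drop=True)

    modules = tuple((cfg.module_size, cfg.module_correlation)
                    for _ in range(cfg.n_modules_per_tissue))
    bulk = syn.BulkCohortSpec(
        n_tissues=cfg.n_tissues, n_genes=cfg.n_genes,
        n_samples_per_tissue=cfg.n_samples_per_tissue,
        modules_per_tissue=modules, sng_genes=planted,
        sng_planting={t: 0 for t in
                      [f"tissue{i + 1}" for i in range(cfg.n_tissues)]},
        age_effect_modules=frozenset({1}),
        seed=derive_seed(cfg.seed, "bulk"))

    non_sng = [g for g in genes if g not in set(picked)]
    extras = [f"SC{i + 1:04d}" for i in range(cfg.n_sc_genes - cfg.n_genes)]
    sc_genes = non_sng + picked + extras
    sc = syn.ScCohortSpec(
        n_cells=cfg.n_cells, n_genes=len(sc_genes), genes=sc_genes,
        planted_sng_celltypes={"typeA": planted},
        seed=derive_seed(cfg.seed, "scrna"))
    return {"genes": genes, "sng_table": sng_table, "planted_sngs": planted,
            "bulk": bulk, "sc": sc}


def generate_inputs(cfg: PipelineConfig, inputs_dir: str | Path) -> Path:
    """Write the synthetic cohort to ``inputs_dir`` as plain-text files."""
    inputs_dir = Path(inputs_dir)
    inputs_dir.mkdir(parents=True, exist_ok=True)
    specs = build_cohort_specs(cfg)

    tissues, bulk_truth = syn.gen_bulk_cohort(specs["bulk"])
    for tissue, data in tissues.items():
        sio.write_matrix_tsv(data.counts, inputs_dir / f"counts_{tissue}.tsv")
        data.covariates.to_csv(inputs_dir / f"covariates_{tissue}.tsv",
                               sep="\t", index_label="sample")
    specs["sng_table"].to_csv(inputs_dir / "sng_annotation.tsv", sep="\t",
                              index=False)
    sio.write_gmt({"SnG_all": specs["sng_table"]["gene"].tolist(),
                   "SnG_inducers": specs["sng_table"].query(
                       "role == 'inducer'")["gene"].tolist()},
                  inputs_dir / "sng.gmt")

    adata = syn.gen_scrna(specs["sc"])
    counts = pd.DataFrame(np.asarray(adata.X).T, index=adata.var_names,
                          columns=adata.obs_names)
    sio.write_mtx(counts, inputs_dir / "sc")
    adata.obs[["cell_type"]].to_csv(inputs_dir / "sc_labels.tsv", sep="\t",
                                    index_label="cell_id")
    markers = adata.uns["truth"]["markers"]
    sio.write_gmt({f"markers_{t}": g for t, g in markers.items()},
                  inputs_dir / "sc_marker_truth.gmt")

    # ligand-receptor pairs: planted between typeA and typeB marker blocks
    marker_union = frozenset(g for gl in markers.values() for g in gl)
    type_names = sorted(markers)
    n_planted = min(12, len(markers[type_names[0]]), len(markers[type_names[1]]))
    planted_pairs = list(zip(markers[type_names[0]][:n_planted],
                             markers[type_names[1]][:n_planted]))
    lr = syn.gen_lr_db(syn.LRSpec(planted_pairs=planted_pairs, n_decoys=100,
                                  universe=list(adata.var_names),
                                  marker_genes=marker_union,
                                  seed=derive_seed(cfg.seed, "lr")))
    lr.to_csv(inputs_dir / "lr_pairs.tsv", sep="\t", index=False)

    # spatial slide: tissue1's planted module is elevated in a corner
    # region where the SnG-bearing cell type (typeA) also concentrates,
    # mirroring the colocalization the composition contrast should detect
    profiles = syn.profiles_from_scrna(adata)
    module_genes = [g for g in bulk_truth["modules"]["tissue1"][0]
                    if g in profiles.index]
    side = cfg.spatial_side
    block = min(6, max(2, side // 2))  # ~9% of voxels on the default slide
    region = frozenset(x * side + y for x in range(block) for y in range(block))
    comp_rng = np.random.default_rng(derive_seed(cfg.seed, "spatial_comp"))
    n_types = profiles.shape[1]
    alphas_out = np.full(n_types, 2.0)
    alphas_out[0] = 0.5
    comp = comp_rng.dirichlet(alphas_out, size=side * side)
    alphas_in = np.ones(n_types)
    alphas_in[0] = 8.0
    comp[sorted(region)] = comp_rng.dirichlet(alphas_in, size=len(region))
    compositions = pd.DataFrame(
        comp, index=[f"voxel{i + 1}" for i in range(side * side)],
        columns=profiles.columns)
    slide = syn.gen_spatial(syn.SpatialSpec(
        n_side=side, cell_type_profiles=profiles, compositions=compositions,
        enriched_region=region, module_genes=module_genes, depth=5.0,
        seed=derive_seed(cfg.seed, "spatial")))
    sio.write_matrix_tsv(pd.DataFrame(np.asarray(slide.X).T,
                                      index=slide.var_names,
                                      columns=slide.obs_names),
                         inputs_dir / "spatial_counts.tsv")
    slide.obs.to_csv(inputs_dir / "spatial_coords.tsv", sep="\t",
                     index_label="voxel_id")
    slide.obsm["composition"].to_csv(inputs_dir / "spatial_composition.tsv",
                                     sep="\t", index_label="voxel_id")
    sio.write_json({"bulk": bulk_truth,
                    "planted_sngs": specs["planted_sngs"],
                    "sc_markers": markers,
                    "lr_planted_pairs": planted_pairs,
                    "spatial_region": sorted(region),
                    "spatial_module_genes": module_genes},
                   inputs_dir / "truth.json")
    return inputs_dir


# --------------------------------------------------------------------------
# Output helpers
# --------------------------------------------------------------------------

def _write_output(df: pd.DataFrame, path: Path, stage: str, cfg: PipelineConfig,
                  seed: int | None = None, index: bool = False,
                  index_label: str | None = None, **params) -> None:
    lines = [f"# stage: {stage}", f"# senescape_version: {__version__}",
             f"# master_seed: {cfg.seed}"]
    if seed is not None:
        lines.append(f"# stage_seed: {seed}")
    for key, value in sorted(params.items()):
        lines.append(f"# {key}: {value}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def read_output(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _required(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    return path


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# --------------------------------------------------------------------------
# The run
# --------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig, run_dir: str | Path) -> dict:
    """Execute all stages; return the manifest (also written to disk)."""
    run_dir = Path(run_dir)
    out = run_dir / "outputs"
    out.mkdir(parents=True, exist_ok=True)
    if cfg.inputs_dir is not None:
        inputs = Path(cfg.inputs_dir)
        if not inputs.exists():
            raise FileNotFoundError(f"missing inputs directory: {inputs}")
    elif cfg.simulate:
        inputs = generate_inputs(cfg, run_dir / "inputs")
    else:
        raise ValueError("config needs inputs_dir or simulate: true")

    tissues = sorted(p.stem.removeprefix("counts_")
                     for p in inputs.glob("counts_*.tsv"))
    if not tissues:
        raise FileNotFoundError(f"no counts_<tissue>.tsv files in {inputs}")
    sng_table = pd.read_csv(_required(inputs / "sng_annotation.tsv"), sep="\t")
    sng_all = set(sng_table["gene"])
    sng_inducers = set(sng_table.query("role == 'inducer'")["gene"])

    # --- bulk preprocess + networks -------------------------------------
    pfns: dict[str, "network.nx.Graph"] = {}
    hierarchies: dict[str, network.ModuleHierarchy] = {}
    universes: dict[str, set] = {}
    residuals: dict[str, pd.DataFrame] = {}
    ages: dict[str, pd.Series] = {}
    for tissue in tissues:
        counts = sio.read_matrix_tsv(_required(inputs / f"counts_{tissue}.tsv"))
        covars = pd.read_csv(_required(inputs / f"covariates_{tissue}.tsv"),
                             sep="\t", index_col=0)
        norm = bulk_preprocess.preprocess_tissue(
            counts, covars, include_age_adjustment=cfg.adjust_age)
        residuals[tissue] = norm.values
        ages[tissue] = covars["age"]
        _write_output(norm.values, out / f"residuals_{tissue}.tsv",
                      "preprocess", cfg, index=True, index_label="gene",
                      age_adjusted=cfg.adjust_age)
        pfn = network.build_tissue_network(norm.values, alpha=cfg.edge_fdr,
                                           tissue=tissue)
        pfns[tissue] = pfn
        universes[tissue] = set(norm.values.index)
        _write_output(network.edges_frame(pfn), out / f"network_{tissue}.tsv",
                      "network", cfg, edge_fdr=cfg.edge_fdr)
        mod_seed = derive_seed(cfg.seed, f"modules:{tissue}")
        hierarchy = network.detect_modules(
            pfn, min_module_size=cfg.min_module_size,
            max_depth=cfg.max_module_depth, n_rewires=cfg.module_rewires,
            seed=mod_seed)
        network.detect_hubs(pfn, hierarchy)
        hierarchies[tissue] = hierarchy
        sio.write_json(network.hierarchy_to_json(hierarchy),
                       out / f"modules_{tissue}.json")

    # --- enrichment + eigengene age correlation -------------------------
    flagged = module_stats.flag_sng_modules(hierarchies, sng_all, universes,
                                            alpha_q=cfg.module_q)
    _write_output(flagged.assign(members=flagged["members"].map(",".join))
                  if not flagged.empty else flagged,
                  out / "sng_enriched_modules.tsv", "enrichment", cfg,
                  module_q=cfg.module_q, bh_scope="per-tissue")
    age_rows = []
    for row in flagged.itertuples(index=False):
        eig = module_stats.module_eigengene(residuals[row.tissue], row.members,
                                            module_id=row.module_id)
        rho, p = module_stats.age_correlation(eig.scores, ages[row.tissue])
        age_rows.append({"tissue": row.tissue, "module_id": row.module_id,
                         "variance_explained": eig.variance_explained,
                         "spearman_rho": rho, "p": p})
    age_table = pd.DataFrame(age_rows)
    _write_output(age_table, out / "module_age_correlation.tsv",
                  "enrichment", cfg)

    # --- SnG landscape ---------------------------------------------------
    landscape_seed = derive_seed(cfg.seed, "landscape")
    presence = sng_landscape.build_presence_matrix(flagged, sng_all)
    _write_output(presence, out / "presence_matrix.tsv", "landscape", cfg,
                  index=True, index_label="gene")
    k_rows = min(cfg.kmeans_k, presence.shape[0])
    k_cols = min(cfg.kmeans_k, presence.shape[1])
    row_clusters = sng_landscape.consensus_kmeans(
        presence, k=k_rows, runs=cfg.kmeans_runs, axis="rows",
        seed=landscape_seed)
    col_clusters = sng_landscape.consensus_kmeans(
        presence, k=k_cols, runs=cfg.kmeans_runs, axis="cols",
        seed=landscape_seed + 1)
    _write_output(row_clusters.labels.rename_axis("gene").reset_index(),
                  out / "sng_clusters.tsv", "landscape", cfg, k=k_rows,
                  runs=cfg.kmeans_runs, seed=landscape_seed)
    _write_output(col_clusters.labels.rename_axis("module").reset_index(),
                  out / "module_clusters.tsv", "landscape", cfg, k=k_cols,
                  runs=cfg.kmeans_runs)
    tissue_of = {col: col.split(":")[0] for col in presence.columns}
    n_surveyed = len({tissue_of[c] for c in presence.columns})
    conserved, breadth = sng_landscape.select_conserved_sngs(
        row_clusters, presence, tissue_of, n_tissues_surveyed=n_surveyed)
    _write_output(breadth, out / "cluster_tissue_breadth.tsv", "landscape",
                  cfg, n_tissues_surveyed=n_surveyed)
    _write_output(pd.DataFrame({"gene": conserved}),
                  out / "conserved_sngs.tsv", "landscape", cfg)

    # --- aggregation ------------------------------------------------------
    subnets = aggregation.tissue_subnetworks(pfns, flagged)
    agg = aggregation.aggregate(subnets,
                                min_node_weight=cfg.min_conservation_weight)
    _write_output(aggregation.node_table(agg), out / "aggregate_nodes.tsv",
                  "aggregation", cfg,
                  min_node_weight=cfg.min_conservation_weight)
    _write_output(aggregation.edge_table(agg), out / "aggregate_edges.tsv",
                  "aggregation", cfg)
    seed_gene = sorted(sng_inducers)[0] if sng_inducers else sorted(sng_all)[0]
    try:
        hood = aggregation.consensus_neighborhood(
            pfns, seed_gene, layers=cfg.neighborhood_layers,
            min_node_weight=cfg.min_conservation_weight)
        hood_nodes = aggregation.node_table(hood)
    except ValueError:
        hood_nodes = pd.DataFrame(columns=["gene", "weight", "n_tissues",
                                           "tissues"])
    _write_output(hood_nodes, out / "consensus_neighborhood.tsv",
                  "aggregation", cfg, seed_gene=seed_gene,
                  layers=cfg.neighborhood_layers)

    # --- single cell ------------------------------------------------------
    sc_counts = sio.read_mtx(inputs / "sc")
    labels_df = pd.read_csv(_required(inputs / "sc_labels.tsv"), sep="\t",
                            index_col=0)
    adata = ad.AnnData(X=sc_counts.to_numpy().T.astype(float),
                       obs=labels_df.loc[sc_counts.columns],
                       var=pd.DataFrame(index=sc_counts.index))
    single_cell.lognormalize(adata, scale=cfg.sc_scale)
    sc_seed = derive_seed(cfg.seed, "single_cell")
    clusters = single_cell.cluster_cells(adata, seed=sc_seed)
    _write_output(clusters.rename_axis("cell_id").reset_index(),
                  out / "sc_clusters.tsv", "single_cell", cfg, seed=sc_seed)
    markers = single_cell.find_markers(adata, "cell_type",
                                       lfc_min=cfg.marker_lfc,
                                       min_frac=cfg.marker_min_frac,
                                       q_max=cfg.marker_fdr)
    _write_output(markers, out / "sc_markers.tsv", "single_cell", cfg,
                  lfc_min=cfg.marker_lfc, min_frac=cfg.marker_min_frac,
                  q_max=cfg.marker_fdr)
    gsea_set = sng_inducers & set(adata.var_names) or sng_all & set(adata.var_names)
    scores = single_cell.cell_gsea(adata, gsea_set,
                                   n_perm=cfg.gsea_permutations,
                                   seed=derive_seed(cfg.seed, "cell_gsea"),
                                   alpha=cfg.cell_p)
    _write_output(scores.reset_index(), out / "sc_sng_scores.tsv",
                  "single_cell", cfg, n_perm=cfg.gsea_permutations,
                  alpha=cfg.cell_p, null="gene-label permutation")
    fractions = single_cell.sng_cell_fractions(scores, adata.obs["cell_type"])
    _write_output(fractions, out / "sc_sng_fractions.tsv", "single_cell", cfg)

    # --- interactions -----------------------------------------------------
    marker_sng = sorted(sng_inducers & set(adata.var_names))
    coexist_marker = marker_sng[0] if marker_sng else str(adata.var_names[0])
    agg_genes = [g for g in aggregation.node_table(agg)["gene"]
                 if g in set(adata.var_names) and g != coexist_marker]
    if agg_genes:
        coexist = cell_interactions.coexistence_test(
            adata, coexist_marker, agg_genes,
            labels="cell_type", n_background=cfg.coexistence_background,
            seed=derive_seed(cfg.seed, "coexistence"))
    else:
        coexist = pd.DataFrame(columns=["cell_type", "n_cells",
                                        "median_query_proportion",
                                        "median_background_proportion", "p"])
    _write_output(coexist, out / "coexistence.tsv", "interactions", cfg,
                  marker_gene=coexist_marker)
    lr_db = pd.read_csv(_required(inputs / "lr_pairs.tsv"), sep="\t")
    pool = cell_interactions.expressed_gene_pool(adata)
    comm = cell_interactions.lr_communication(
        markers, lr_db, pool, n_perm=cfg.lr_permutations,
        seed=derive_seed(cfg.seed, "lr"))
    comm_out = comm.assign(pairs=comm["pairs"].map(
        lambda ps: ";".join(f"{l}-{r}" for l, r in ps)))
    _write_output(comm_out, out / "lr_communication.tsv", "interactions", cfg,
                  n_perm=cfg.lr_permutations)

    # --- spatial ----------------------------------------------------------
    sp_counts = sio.read_matrix_tsv(_required(inputs / "spatial_counts.tsv"))
    coords = pd.read_csv(_required(inputs / "spatial_coords.tsv"), sep="\t",
                         index_col=0)
    comp = pd.read_csv(_required(inputs / "spatial_composition.tsv"),
                       sep="\t", index_col=0)
    slide = ad.AnnData(X=sp_counts.to_numpy().T.astype(float),
                       obs=coords.loc[sp_counts.columns],
                       var=pd.DataFrame(index=sp_counts.index))
    module_genes = _spatial_module(flagged, inputs)
    vox = spatial.voxel_gsea(slide, module_genes,
                             n_perm=cfg.gsea_permutations,
                             seed=derive_seed(cfg.seed, "voxel_gsea"),
                             alpha=cfg.voxel_p)
    _write_output(vox.reset_index(), out / "voxel_scores.tsv", "spatial", cfg,
                  n_perm=cfg.gsea_permutations, alpha=cfg.voxel_p)
    comp_cmp = spatial.compare_compositions(vox, comp)
    _write_output(comp_cmp, out / "voxel_composition_comparison.tsv",
                  "spatial", cfg)

    # --- manifest ---------------------------------------------------------
    manifest = {
        "senescape_version": __version__,
        "config": cfg.to_dict(),
        "inputs_dir": str(inputs),
        "stage_seeds": {s: derive_seed(cfg.seed, s) for s in
                        ["cohort", "bulk", "scrna", "lr", "spatial",
                         "landscape", "single_cell", "cell_gsea",
                         "coexistence", "voxel_gsea"]},
        "input_checksums": {p.name: _checksum(p)
                            for p in sorted(inputs.rglob("*")) if p.is_file()},
        "output_checksums": {p.name: _checksum(p)
                             for p in sorted(out.iterdir()) if p.is_file()},
    }
    sio.write_json(manifest, run_dir / "manifest.json")
    return manifest


def _spatial_module(flagged: pd.DataFrame, inputs: Path) -> list[str]:
    """Module gene set scored on the slide: the planted truth if present,
    else the most SnG-enriched flagged module."""
    truth_path = inputs / "truth.json"
    if truth_path.exists():
        truth = sio.read_json(truth_path)
        if "spatial_module_genes" in truth:
            return list(truth["spatial_module_genes"])
    top = flagged.sort_values("p").iloc[0]
    return list(top["members"])
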