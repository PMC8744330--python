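"""Generators: determinism, planted structure, and mixture oracles."""

import numpy as np
import pandas as pd
import pytest

from senescape import synthetic_data as syn
from conftest import log_cpm


class TestBulkCohort:
    def test_deterministic_given_seed(self):
        spec = syn.BulkCohortSpec(n_tissues=2, n_genes=60,
                                  n_samples_per_tissue=20,
                                  modules_per_tissue=((20, 0.5),), seed=7)
        a, _ = syn.gen_bulk_cohort(spec)
        b, _ = syn.gen_bulk_cohort(spec)
        for tissue in a:
            pd.testing.assert_frame_equal(a[tissue].counts, b[tissue].counts)
            pd.testing.assert_frame_equal(a[tissue].covariates,
                                          b[tissue].covariates)

    def test_counts_are_nonnegative_integers(self, bulk_tissue):
        counts = bulk_tissue[0].counts
        assert (counts.to_numpy() >= 0).all()
        assert np.allclose(counts.to_numpy() % 1, 0)

    def test_zero_correlation_gives_uncorrelated_genes(self):
        spec = syn.BulkCohortSpec(n_tissues=1, n_genes=100,
                                  n_samples_per_tissue=80,
                                  modules_per_tissue=((40, 0.0),), seed=3)
        tissues, truth = syn.gen_bulk_cohort(spec)
        expr = log_cpm(tissues["tissue1"].counts)
        module = truth["modules"]["tissue1"][0]
        r = np.corrcoef(expr.loc[module].to_numpy())
        iu = np.triu_indices(len(module), k=1)
        assert abs(r[iu].mean()) < 0.06

    def test_planted_module_correlation_near_target(self):
        # brute-force pairwise correlation over all module pairs
        spec = syn.BulkCohortSpec(n_tissues=1, n_genes=500,
                                  n_samples_per_tissue=100,
                                  modules_per_tissue=((50, 0.7),), seed=9)
        tissues, truth = syn.gen_bulk_cohort(spec)
        expr = log_cpm(tissues["tissue1"].counts)
        module = truth["modules"]["tissue1"][0]
        r = np.corrcoef(expr.loc[module].to_numpy())
        iu = np.triu_indices(len(module), k=1)
        assert abs(np.abs(r[iu]).mean() - 0.7) < 0.1

    def test_age_is_decade_midpoint(self, bulk_tissue):
        ages = bulk_tissue[0].covariates["age"]
        assert set(ages).issubset(set(syn.AGE_BIN_MIDPOINTS))

    def test_oversized_modules_rejected(self):
        with pytest.raises(ValueError, match="module sizes"):
            syn.BulkCohortSpec(n_genes=30, modules_per_tissue=((20, 0.5),
                                                               (20, 0.5)))

    def test_sngs_planted_into_designated_module(self):
        sngs = ["G010", "G020", "G030"]
        spec = syn.BulkCohortSpec(n_tissues=2, n_genes=100,
                                  n_samples_per_tissue=20,
                                  modules_per_tissue=((30, 0.5), (30, 0.5)),
                                  sng_genes=sngs,
                                  sng_planting={"tissue1": 0, "tissue2": 1},
                                  seed=4)
        _, truth = syn.gen_bulk_cohort(spec)
        assert set(sngs) <= set(truth["modules"]["tissue1"][0])
        assert set(sngs) <= set(truth["modules"]["tissue2"][1])


class TestSngAnnotation:
    def test_requested_count_and_uniqueness(self):
        universe = [f"G{i}" for i in range(400)]
        table = syn.gen_sng_annotation(279, universe, seed=1)
        assert len(table) == 279
        assert table["gene"].is_unique
        assert set(table["role"]) == {"inducer", "inhibitor"}

    def test_empty_and_deterministic(self):
        universe = [f"G{i}" for i in range(50)]
        assert len(syn.gen_sng_annotation(0, universe, seed=1)) == 0
        a = syn.gen_sng_annotation(10, universe, seed=2)
        b = syn.gen_sng_annotation(10, universe, seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_sng_annotation(10, ["G1", "G2"], seed=0)


class TestScrna:
    def test_deterministic_given_seed(self):
        spec = syn.ScCohortSpec(
            n_cells=60, n_genes=100, seed=11,
            cell_types=(syn.CellTypeSpec("A", 0.5, 10),
                        syn.CellTypeSpec("B", 0.5, 10)))
        a, b = syn.gen_scrna(spec), syn.gen_scrna(spec)
        np.testing.assert_array_equal(np.asarray(a.X), np.asarray(b.X))

    def test_single_type_no_dropout_shares_profile(self):
        spec = syn.ScCohortSpec(
            n_cells=400, n_genes=80, dropout_rate=0.0,
            cell_types=(syn.CellTypeSpec("only", 1.0, 0),), seed=2)
        adata = syn.gen_scrna(spec)
        X = np.asarray(adata.X)
        # no type structure: per-gene means in two random halves agree
        half = X[:200].mean(axis=0), X[200:].mean(axis=0)
        assert np.corrcoef(half[0], half[1])[0, 1] > 0.95

    def test_marker_elevated_in_own_type_across_seeds(self):
        hits = 0
        for seed in range(20):
            spec = syn.ScCohortSpec(
                n_cells=100, n_genes=60, dropout_rate=0.0,
                cell_types=(syn.CellTypeSpec("A", 0.5, 5, 3.0),
                            syn.CellTypeSpec("B", 0.5, 0)), seed=seed)
            adata = syn.gen_scrna(spec)
            marker = adata.uns["truth"]["markers"]["A"][0]
            col = adata[:, marker].X.ravel()
            in_a = adata.obs["cell_type"].to_numpy() == "A"
            hits += col[in_a].mean() > col[~in_a].mean()
        assert hits >= 19

    def test_dropout_removes_expected_fraction_of_nonzeros(self):
        spec = syn.ScCohortSpec(n_cells=300, n_genes=200, dropout_rate=0.9,
                                base_mean=5.0, seed=3)
        adata = syn.gen_scrna(spec)
        nonzero_after = int((np.asarray(adata.X) > 0).sum())
        nonzero_before = adata.uns["truth"]["pre_dropout_nonzero"]
        removed = 1.0 - nonzero_after / nonzero_before
        assert removed == pytest.approx(0.9, abs=0.02)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            syn.ScCohortSpec(cell_types=(syn.CellTypeSpec("A", 0.5, 5),))


class TestLrDb:
    def test_no_decoys_gives_exactly_planted_pairs(self):
        pairs = [("G1", "G2"), ("G3", "G4")]
        db = syn.gen_lr_db(syn.LRSpec(planted_pairs=pairs, n_decoys=0,
                                      universe=["G1", "G2", "G3", "G4"]))
        assert list(map(tuple, db.to_numpy())) == pairs

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError, match="ligand equals receptor"):
            syn.LRSpec(planted_pairs=[("G1", "G1")], n_decoys=0,
                       universe=["G1"])

    def test_decoys_avoid_marker_genes(self):
        db = syn.gen_lr_db(syn.LRSpec(
            planted_pairs=[], n_decoys=30,
            universe=[f"G{i}" for i in range(40)],
            marker_genes=frozenset({"G0", "G1"}), seed=1))
        assert not ({"G0", "G1"} & set(db.to_numpy().ravel()))


class TestSpatial:
    def _profiles(self):
        genes = [f"G{i}" for i in range(30)]
        rng = np.random.default_rng(0)
        return pd.DataFrame(rng.uniform(1, 10, size=(30, 3)), index=genes,
                            columns=["A", "B", "C"])

    def test_pure_composition_zero_noise_equals_profile(self):
        profiles = self._profiles()
        comp = pd.DataFrame(0.0, index=[f"voxel{i + 1}" for i in range(4)],
                            columns=profiles.columns)
        comp["A"] = 1.0
        slide = syn.gen_spatial(syn.SpatialSpec(
            n_side=2, cell_type_profiles=profiles, compositions=comp,
            noise_sd=0.0, seed=1))
        for i in range(4):
            np.testing.assert_allclose(slide.layers["expected"][i],
                                       profiles["A"].to_numpy())

    def test_mixture_matches_brute_force_weighted_sum(self, rng):
        profiles = self._profiles()
        comp_raw = rng.dirichlet(np.ones(3), size=9)
        comp = pd.DataFrame(comp_raw,
                            index=[f"voxel{i + 1}" for i in range(9)],
                            columns=profiles.columns)
        slide = syn.gen_spatial(syn.SpatialSpec(
            n_side=3, cell_type_profiles=profiles, compositions=comp,
            noise_sd=0.0, seed=2))
        P = profiles.to_numpy()
        for v in range(9):
            expected = sum(comp_raw[v, t] * P[:, t] for t in range(3))
            np.testing.assert_allclose(slide.layers["expected"][v], expected,
                                       rtol=1e-12)

    def test_compositions_are_simplex_weights(self):
        profiles = self._profiles()
        slide = syn.gen_spatial(syn.SpatialSpec(
            n_side=4, cell_type_profiles=profiles, seed=3))
        w = slide.obsm["composition"].to_numpy()
        assert (w >= 0).all()
        np.testing.assert_allclose(w.sum(axis=1), 1.0)

    def test_enriched_region_elevates_module_genes(self):
        profiles = self._profiles()
        region = frozenset(range(8))
        module = ["G0", "G1", "G2"]
        slide = syn.gen_spatial(syn.SpatialSpec(
            n_side=4, cell_type_profiles=profiles, enriched_region=region,
            module_genes=module, module_log_offset=1.0, noise_sd=0.0, seed=4))
        exp = slide.layers["expected"]
        cols = [list(slide.var_names).index(g) for g in module]
        in_region = exp[sorted(region)][:, cols].mean()
        outside = exp[8:][:, cols].mean()
        assert in_region > outside * 1.5
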