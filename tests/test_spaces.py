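"""Ancestry spaces: SUGIBS, PCA, UPCA, MDS, randomized SVD, serialization."""

import numpy as np
import pytest
from scipy.linalg import eigh

from sugibs.genotype_io import MISSING, filter_maf
from sugibs.similarity import ibs_degrees, ibs_matrix, ug_relationship
from sugibs.simulate import simulate_admixed, simulate_drift
from sugibs.spaces import (
    load_model,
    mds_fit,
    pca_fit,
    pca_project,
    randomized_svd,
    save_model,
    suggest_component_count,
    sugibs_fit,
    sugibs_project,
    upca_fit,
    upca_project,
)

from conftest import make_panel


@pytest.fixture(scope="module")
def two_pop_cohort():
    """Admixed two-population cohort at Fst=0.1 (strong structure)."""
    drift = simulate_drift(3200, 0.1, 20, rng_seed=101)
    return simulate_admixed(drift, 200, rng_seed=102)


class TestRandomizedSVD:
    def test_diagonal_matrix_exact(self):
        a = np.zeros((5, 5))
        np.fill_diagonal(a, [5, 4, 3, 2, 1])
        _, s, _ = randomized_svd(a, 2, oversample=3)
        np.testing.assert_allclose(s, [5, 4])

    def test_matches_dense_svd(self, rng):
        a = rng.standard_normal((100, 80))
        _, s, _ = randomized_svd(a, 5, rng_seed=3)
        s_dense = np.linalg.svd(a, compute_uv=False)[:5]
        np.testing.assert_allclose(s, s_dense, rtol=1e-6)

    def test_deterministic_given_seed(self, rng):
        a = rng.standard_normal((2100, 1100))  # large enough for the
        # randomized range-finder path
        u1, s1, v1 = randomized_svd(a, 3, rng_seed=7)
        u2, s2, v2 = randomized_svd(a, 3, rng_seed=7)
        assert (u1 == u2).all() and (s1 == s2).all() and (v1 == v2).all()

    def test_dimension_violation(self, rng):
        with pytest.raises(ValueError, match="oversample"):
            randomized_svd(rng.standard_normal((8, 8)), 5, oversample=10)


class TestSugibs:
    def test_generalized_eigen_oracle(self, rng):
        """(lambda, V) from a dense generalized symmetric eigensolver on
        (G, D) match the SVD route on a 30x40 panel."""
        g = make_panel(rng.choice(np.array([-1, 0, 1], dtype=np.int8), (30, 40)))
        model = sugibs_fit(g, k=3, rng_seed=1)
        G = ug_relationship(g).G
        d = ibs_degrees(g).astype(float)
        lam, vecs = eigh(G, np.diag(d))
        lam, vecs = lam[::-1], vecs[:, ::-1]
        np.testing.assert_allclose(
            model.singular_values, np.sqrt(30 * lam[1:4]), rtol=1e-8
        )
        for j in range(3):
            v1, v2 = model.reference_scores[:, j], vecs[:, j + 1]
            cos = abs(v1 @ (d * v2)) / np.sqrt((v1 @ (d * v1)) * (v2 @ (d * v2)))
            assert cos > 1 - 1e-8

    def test_generalized_orthonormality(self, rng):
        g = make_panel(rng.choice(np.array([-1, 0, 1], dtype=np.int8), (50, 20)))
        model = sugibs_fit(g, k=4, rng_seed=0)
        d = ibs_degrees(g).astype(float)
        vdv = model.reference_scores.T @ (d[:, None] * model.reference_scores)
        np.testing.assert_allclose(vdv, np.eye(4), atol=1e-8)

    def test_detects_structure_at_fst_01(self, two_pop_cohort):
        model = sugibs_fit(two_pop_cohort.genotypes, k=1, rng_seed=0)
        r = abs(np.corrcoef(model.reference_scores[:, 0], two_pop_cohort.alpha)[0, 1])
        assert r > 0.99

    def test_self_projection_identity(self, rng):
        vals = rng.choice(
            np.array([-1, 0, 1, MISSING], dtype=np.int8), (60, 25),
            p=[0.3, 0.3, 0.3, 0.1],
        )
        g = make_panel(vals)
        model = sugibs_fit(g, k=3, rng_seed=2)
        proj = sugibs_project(model, g, g)
        np.testing.assert_allclose(
            proj.scores, model.reference_scores, atol=1e-10
        )

    def test_duplicated_snps_preserve_score_directions(self, rng):
        """Doubling every SNP doubles G, W and the degrees together, so the
        generalized eigenvectors are unchanged; only the V'DV = I
        normalization rescales them (by 1/sqrt(2))."""
        vals = rng.choice(np.array([-1, 0, 1], dtype=np.int8), (40, 15))
        g1 = make_panel(vals)
        g2 = make_panel(np.vstack([vals, vals]))
        s1 = sugibs_fit(g1, k=2, rng_seed=0).reference_scores
        s2 = sugibs_fit(g2, k=2, rng_seed=0).reference_scores
        for j in range(2):
            a, b = s1[:, j], s2[:, j]
            cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos > 1 - 1e-8
        np.testing.assert_allclose(np.abs(s2), np.abs(s1) / np.sqrt(2), atol=1e-10)

    def test_duplicate_target_sample_identical_rows(self, rng):
        vals = rng.choice(np.array([-1, 0, 1], dtype=np.int8), (50, 12))
        g = make_panel(vals)
        model = sugibs_fit(g, k=2, rng_seed=0)
        from sugibs.genotype_io import GenotypeMatrix, SampleRecord

        tgt = GenotypeMatrix(
            np.repeat(vals[:, :1], 2, axis=1),
            list(g.variants),
            [SampleRecord("fam", "dup1"), SampleRecord("fam", "dup2")],
        )
        proj = sugibs_project(model, tgt, g)
        np.testing.assert_allclose(proj.scores[0], proj.scores[1])

    def test_k_too_large_rejected(self, rng):
        g = make_panel(rng.choice(np.array([-1, 0, 1], dtype=np.int8), (10, 5)))
        with pytest.raises(ValueError, match="k="):
            sugibs_fit(g, k=5)

    def test_all_missing_target_sample_rejected(self, rng):
        vals = rng.choice(np.array([-1, 0, 1], dtype=np.int8), (30, 10))
        g = make_panel(vals)
        model = sugibs_fit(g, k=2, rng_seed=0)
        tgt = g.take_samples([0])
        tgt.values[:] = MISSING
        with pytest.raises(ValueError, match="ind1"):
            sugibs_project(model, tgt, g)


class TestPCA:
    def test_dense_svd_oracle(self, rng):
        vals = rng.choice(np.array([-1, 0, 1], dtype=np.int8), (20, 25))
        g = filter_maf(make_panel(vals), 1e-9)
        model = pca_fit(g, k=3, rng_seed=0)
        p = np.array(
            [(row[row != MISSING] + 1).sum() / (2 * (row != MISSING).sum())
             for row in g.values]
        )
        z = (g.values - (2 * p - 1)[:, None]) / np.sqrt(2 * p * (1 - p))[:, None]
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        np.testing.assert_allclose(model.singular_values, s[:3], rtol=1e-10)
        for j in range(3):
            assert abs(np.dot(model.reference_scores[:, j], vt[j])) > 1 - 1e-8

    def test_detects_structure_at_fst_01(self, two_pop_cohort):
        g = filter_maf(two_pop_cohort.genotypes, 1e-9)
        model = pca_fit(g, k=1, rng_seed=0)
        r = abs(np.corrcoef(model.reference_scores[:, 0], two_pop_cohort.alpha)[0, 1])
        assert r > 0.99

    def test_score_columns_centered(self, observed_panel):
        g = filter_maf(observed_panel, 1e-9)
        model = pca_fit(g, k=2, rng_seed=0)
        np.testing.assert_allclose(
            model.reference_scores.mean(axis=0), 0, atol=1e-6
        )

    def test_monomorphic_snp_rejected(self):
        g = make_panel(np.ones((3, 8), dtype=np.int8))
        with pytest.raises(ValueError, match="MAF"):
            pca_fit(g, k=1)

    def test_all_missing_sample_projects_to_origin(self, observed_panel):
        g = filter_maf(observed_panel, 1e-9)
        model = pca_fit(g, k=2, rng_seed=0)
        tgt = g.take_samples([0])
        tgt.values[:] = MISSING
        proj = pca_project(model, tgt)
        np.testing.assert_array_equal(proj.scores, 0.0)

    def test_heavy_missingness_shrinks_projection(self, two_pop_cohort, rng):
        """Mean imputation pulls projected scores toward the origin."""
        g = filter_maf(two_pop_cohort.genotypes, 1e-9)
        model = pca_fit(g, k=1, rng_seed=0)
        clean = pca_project(model, g)
        corrupted = g.copy()
        mask = rng.random(corrupted.values.shape) < 0.5
        corrupted.values[mask] = MISSING
        shrunk = pca_project(model, corrupted)
        assert (
            np.abs(shrunk.scores).mean() < 0.75 * np.abs(clean.scores).mean()
        )


class TestUPCA:
    def test_equals_sugibs_when_degrees_equal(self):
        # crafted panel where all samples have identical similarity degrees:
        # every column is a permutation of the same multiset and pairwise
        # sharing is symmetric under the cyclic shift
        base = np.array(
            [[-1, 0, 1], [0, 1, -1], [1, -1, 0], [-1, 0, 1], [0, 1, -1], [1, -1, 0]],
            dtype=np.int8,
        )
        g = make_panel(base)
        d = ibs_degrees(g)
        assert (d == d[0]).all()
        su = sugibs_fit(g, k=1, rng_seed=0).reference_scores[:, 0]
        up = upca_fit(g, k=1, rng_seed=0).reference_scores[:, 0]
        su = su / np.linalg.norm(su)
        up = up / np.linalg.norm(up)
        assert min(np.abs(su - up).max(), np.abs(su + up).max()) < 1e-8

    def test_dense_svd_oracle(self, rng):
        vals = rng.choice(np.array([-1, 0, 1], dtype=np.int8), (20, 25))
        g = make_panel(vals)
        model = upca_fit(g, k=3, rng_seed=0)
        s_dense = np.linalg.svd(vals.astype(float), compute_uv=False)
        np.testing.assert_allclose(model.singular_values, s_dense[1:4], rtol=1e-10)

    def test_component_one_separates_populations(self, two_pop_cohort):
        model = upca_fit(two_pop_cohort.genotypes, k=1, rng_seed=0)
        r = abs(np.corrcoef(model.reference_scores[:, 0], two_pop_cohort.alpha)[0, 1])
        assert r > 0.99

    def test_projection_is_plain_dosage_product(self, rng):
        vals = rng.choice(np.array([-1, 0, 1], dtype=np.int8), (30, 10))
        g = make_panel(vals)
        model = upca_fit(g, k=2, rng_seed=0)
        proj = upca_project(model, g)
        np.testing.assert_allclose(
            proj.scores, vals.T.astype(float) @ model.loadings
        )


class TestMDS:
    def test_identical_samples_coincide(self, rng):
        col = rng.choice(np.array([-1, 0, 1], dtype=np.int8), size=40)
        other = rng.choice(np.array([-1, 0, 1], dtype=np.int8), size=(40, 3))
        g = make_panel(np.column_stack([col, col, other]))
        res = mds_fit(g, k=2)
        np.testing.assert_allclose(
            res.coordinates[0], res.coordinates[1], atol=1e-10
        )

    def test_dimension_one_separates_populations(self, two_pop_cohort):
        res = mds_fit(two_pop_cohort.genotypes, k=1)
        r = abs(np.corrcoef(res.coordinates[:, 0], two_pop_cohort.alpha)[0, 1])
        assert r > 0.99

    def test_gram_reconstruction(self, rng):
        """With k = N-1 the coordinates reproduce the pairwise distances."""
        vals = rng.choice(np.array([-1, 0, 1], dtype=np.int8), (200, 10))
        g = make_panel(vals)
        res = mds_fit(g, k=9)
        w = ibs_matrix(g).W
        dist = 1.0 - w / (2.0 * g.n_variants)
        np.fill_diagonal(dist, 0.0)
        coords = res.coordinates[:, res.eigenvalues > 1e-10]
        recon = np.sqrt(
            np.maximum(
                ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1), 0
            )
        )
        np.testing.assert_allclose(recon, dist, atol=1e-6)

    def test_coordinates_centered(self, two_pop_cohort):
        res = mds_fit(two_pop_cohort.genotypes, k=3)
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0, atol=1e-8)


class TestComponentCountSuggestion:
    def test_homogeneous_panel_suggests_zero(self, rng):
        """A structureless panel should essentially never clear the null
        spectrum; the parallel-analysis rule has a ~5% per-dataset false
        alarm rate by construction, so check the rate, not one draw."""
        counts = []
        for seed in range(6):
            r = np.random.default_rng(1000 + seed)
            p = r.uniform(0.2, 0.8, 300)
            vals = (r.binomial(2, p[:, None], (300, 60)) - 1).astype(np.int8)
            g = make_panel(vals)
            counts.append(suggest_component_count(g, max_k=5, n_null=19, rng_seed=seed))
        assert sum(c > 0 for c in counts) <= 1

    def test_two_populations_suggest_at_least_one(self):
        drift = simulate_drift(500, 0.1, 20, rng_seed=5)
        cohort = simulate_admixed(drift, 80, rng_seed=6)
        k = suggest_component_count(cohort.genotypes, max_k=5, n_null=19, rng_seed=1)
        assert k >= 1

    def test_three_populations_suggest_at_least_two(self, rng):
        drift_a = simulate_drift(600, 0.2, 20, rng_seed=7)
        drift_b = simulate_drift(600, 0.2, 20, rng_seed=8)
        # three pure populations from two independent drift pairs sharing SNPs
        cols = []
        for p in (drift_a.p1, drift_a.p2, drift_b.p1):
            cols.append((rng.binomial(2, p[:, None], (600, 30)) - 1).astype(np.int8))
        g = make_panel(np.concatenate(cols, axis=1))
        k = suggest_component_count(g, max_k=5, n_null=19, rng_seed=1)
        assert k >= 2


class TestSignConventionAndSerialization:
    def test_largest_loading_positive(self, two_pop_cohort):
        for model in (
            sugibs_fit(two_pop_cohort.genotypes, k=3, rng_seed=0),
            upca_fit(two_pop_cohort.genotypes, k=3, rng_seed=0),
            pca_fit(filter_maf(two_pop_cohort.genotypes, 1e-9), k=3, rng_seed=0),
        ):
            for j in range(model.k):
                col = model.loadings[:, j]
                assert col[np.argmax(np.abs(col))] > 0

    @pytest.mark.parametrize("method", ["sugibs", "pca", "upca"])
    def test_round_trip(self, tmp_path, two_pop_cohort, method):
        g = two_pop_cohort.genotypes
        if method == "pca":
            g = filter_maf(g, 1e-9)
        fit = {"sugibs": sugibs_fit, "pca": pca_fit, "upca": upca_fit}[method]
        model = fit(g, k=2, rng_seed=3)
        save_model(model, tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        assert loaded.method == model.method
        np.testing.assert_allclose(loaded.loadings, model.loadings)
        np.testing.assert_allclose(loaded.reference_scores, model.reference_scores)
        assert loaded.variant_keys == model.variant_keys
        if method == "pca":
            np.testing.assert_allclose(loaded.mu, model.mu)
            np.testing.assert_allclose(loaded.sigma, model.sigma)
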