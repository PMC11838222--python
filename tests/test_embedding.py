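"""Class-specific PCA models and pathway-image assembly."""

import numpy as np
import pytest
from scipy import stats

from pathimage.data_io import ValidationError
from pathimage.embedding import (
    build_image,
    build_image_stack,
    fit_class_pca,
    fit_embedding_bank,
    isolate_pathway_matrices,
    split_by_class,
)


class TestSplitByClass:
    def test_counts_and_partition(self, small_cohort):
        ds = small_cohort["dataset"]
        blocks = split_by_class(ds)
        assert len(blocks) == 2
        assert all(len(per) == 3 for per in blocks.values())
        total = sum(next(iter(per.values())).shape[0] for per in blocks.values())
        assert total == len(ds.sample_ids)

    def test_class_sizes_propagate(self, small_cohort):
        ds = small_cohort["dataset"]
        blocks = split_by_class(ds)
        sizes = sorted(next(iter(per.values())).shape[0] for per in blocks.values())
        assert sizes == [20, 30]


class TestIsolatePathwayMatrices:
    def test_full_design_count(self, small_cohort):
        ds = small_cohort["dataset"]
        blocks = split_by_class(ds)
        out = list(isolate_pathway_matrices(blocks, small_cohort["pathways"], ds.gene_ids))
        assert len(out) == 2 * 3 * 10
        assert all(m is not None for *_, m in out)

    def test_unknown_genes_flagged_degenerate(self, small_cohort):
        ds = small_cohort["dataset"]
        pw = small_cohort["pathways"]
        pw2 = type(pw)(pw.pathways + [("GHOST", ["NOT_A_GENE"])])
        blocks = split_by_class(ds)
        out = list(isolate_pathway_matrices(blocks, pw2, ds.gene_ids))
        ghosts = [m for *_, pid, _, m in [(a, b, c, d, e) for a, b, c, d, e in out]
                  if pid == "GHOST"]
        ghost_entries = [e for e in out if e[2] == "GHOST"]
        assert len(ghost_entries) == 6
        assert all(e[4] is None for e in ghost_entries)


class TestFitClassPca:
    def test_diagonal_cloud_pc1(self, rng):
        t = rng.normal(size=200)
        m = np.column_stack([t, t]) + rng.normal(0, 0.01, size=(200, 2))
        model = fit_class_pca(m, ["a", "b"], 1, standardize=False)
        np.testing.assert_allclose(np.abs(model.loadings[:, 0]),
                                   [1 / np.sqrt(2)] * 2, atol=0.02)
        assert model.loadings[np.argmax(np.abs(model.loadings[:, 0])), 0] > 0

    def test_orthonormal_loadings(self, rng):
        m = rng.normal(size=(30, 8))
        model = fit_class_pca(m, [f"g{i}" for i in range(8)], 4)
        np.testing.assert_allclose(model.loadings.T @ model.loadings,
                                   np.eye(4), atol=1e-8)

    def test_matches_eigendecomposition_oracle(self, rng):
        """Explained-variance ratios equal covariance eigenvalues (brute force)."""
        m = rng.normal(size=(20, 8))
        model = fit_class_pca(m, [f"g{i}" for i in range(8)], 5, standardize=True)
        z = (m - m.mean(0)) / m.std(0)
        evals = np.sort(np.linalg.eigvalsh(np.cov(z.T, ddof=1)))[::-1]
        np.testing.assert_allclose(model.explained_variance_ratio,
                                   (evals / evals.sum())[:5], atol=1e-8)

    def test_rank_deficit_zero_pads(self, rng):
        m = rng.normal(size=(3, 10))  # feasible rank 2
        model = fit_class_pca(m, [f"g{i}" for i in range(10)], 5)
        assert model.n_fitted == 2
        scores = model.project(m[0])
        assert scores.shape == (5,)
        assert np.all(scores[2:] == 0)

    def test_constant_columns_dropped(self, rng):
        m = rng.normal(size=(20, 3))
        m[:, 1] = 7.0
        model = fit_class_pca(m, ["a", "b", "c"], 2)
        assert model.gene_ids == ["a", "c"]

    def test_all_constant_degenerate(self):
        m = np.full((10, 3), 2.0)
        model = fit_class_pca(m, ["a", "b", "c"], 2)
        assert model.degenerate
        assert np.all(model.project(m[0]) == 0)

    def test_class_mean_projects_to_zero(self, rng):
        m = rng.normal(size=(40, 6))
        model = fit_class_pca(m, [f"g{i}" for i in range(6)], 3)
        scores = model.project(m[:, [i for i, g in enumerate(model.gene_ids)
                                     for _ in [0]]])
        cloud = model.project(m)
        assert np.all(np.abs(cloud.mean(axis=0)) < 1e-8)

    def test_projection_matches_manual_linear_algebra(self):
        m = np.array([[1.0, 2.0, 0.0], [3.0, 0.0, 1.0], [2.0, 4.0, 5.0],
                      [0.0, 1.0, 2.0]])
        model = fit_class_pca(m, ["a", "b", "c"], 2, standardize=True)
        x = np.array([2.0, 2.0, 2.0])
        expected = ((x - model.mean) / model.scale) @ model.loadings
        np.testing.assert_allclose(model.project(x)[:2], expected, atol=1e-12)


class TestImageAssembly:
    def test_image_shape_and_column_order(self, small_cohort):
        ds, pw = small_cohort["dataset"], small_cohort["pathways"]
        bank = fit_embedding_bank(ds, pw, n_pcs=2)
        img = build_image(ds.sample_ids[0], ds, bank, "LTS")
        assert img.grid.shape == (10, 6)
        assert img.col_labels == [(o, pc) for o in ("CNV", "EXP", "MET")
                                  for pc in (1, 2)]

    def test_identical_samples_identical_images(self, small_cohort):
        ds, pw = small_cohort["dataset"], small_cohort["pathways"]
        bank = fit_embedding_bank(ds, pw, n_pcs=2)
        a = build_image(ds.sample_ids[3], ds, bank, "LTS")
        b = build_image(ds.sample_ids[3], ds, bank, "LTS")
        np.testing.assert_array_equal(a.grid, b.grid)

    def test_stack_modes_column_counts(self, small_cohort):
        ds, pw = small_cohort["dataset"], small_cohort["pathways"]
        paper, _ = build_image_stack(ds, pw, n_pcs=2, mode="paper-faithful")
        safe, _ = build_image_stack(ds, pw, n_pcs=2, mode="fold-safe",
                                    fold_train_samples=ds.sample_ids)
        assert paper.tensor.shape == (50, 10, 6)
        assert safe.tensor.shape == (50, 10, 12)

    def test_normalized_to_unit_interval(self, small_cohort):
        ds, pw = small_cohort["dataset"], small_cohort["pathways"]
        stack, _ = build_image_stack(ds, pw, n_pcs=2, mode="paper-faithful")
        assert stack.tensor.min() >= 0 and stack.tensor.max() <= 1

    def test_fold_safe_requires_folds(self, small_cohort):
        ds, pw = small_cohort["dataset"], small_cohort["pathways"]
        with pytest.raises(ValueError, match="fold_train_samples"):
            build_image_stack(ds, pw, n_pcs=2, mode="fold-safe")

    def test_planted_column_separates_classes(self, small_cohort):
        """The planted pathway's EXP cells separate classes on held-out
        samples (the plain out-of-fit path used for test images; images of
        training samples are cross-fitted half-mixtures and not comparable
        cell-for-cell)."""
        ds, pw = small_cohort["dataset"], small_cohort["pathways"]
        truth = small_cohort["truth"]
        by_class: dict[str, list[str]] = {}
        for s in ds.sample_ids:
            by_class.setdefault(ds.class_of(s), []).append(s)
        train = by_class["LTS"][:12] + by_class["non-LTS"][:18]
        stack, _ = build_image_stack(ds, pw, n_pcs=2, mode="fold-safe",
                                     fold_train_samples=train)
        held = np.array([s not in set(train) for s in ds.sample_ids])
        y = np.array([ds.class_of(s) == "non-LTS" for s in ds.sample_ids])
        row = truth.planted[0].pathway_index
        cols = [i for i, (tag, pc) in enumerate(stack.col_labels)
                if "EXP" in tag and pc == 1]
        pvals = [stats.ttest_ind(stack.tensor[held & y, row, c],
                                 stack.tensor[held & ~y, row, c]).pvalue
                 for c in cols]
        assert min(pvals) < 0.01

    def test_full_size_config_counts(self):
        """2 classes x 3 omics x 146 pathways yields 876 PCA models and a
        146 x 6 image at 2 PCs."""
        from pathimage.data_io import assign_survival_labels, harmonize
        from pathimage.synthetic import SyntheticConfig, generate_multiomics

        cfg = SyntheticConfig(n_samples_per_class=(15, 20), n_pathways=146,
                              genes_per_pathway=(4, 6), n_short_censored=0, seed=1)
        mats, pw, clin, _ = generate_multiomics(cfg)
        ds = harmonize(mats, assign_survival_labels(clin))
        bank = fit_embedding_bank(ds, pw, n_pcs=2)
        assert len(bank) == 876
        img = build_image(ds.sample_ids[0], ds, bank, "LTS")
        assert img.grid.shape == (146, 6)
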