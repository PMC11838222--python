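"""Gradient-SHAP estimator properties and pathway roll-up logic.

The estimator is validated three ways: exact closed forms (zero at the
baseline, w_i(x_i - x'_i) for a linear model), the completeness identity
sum(phi) ~= f(x) - E[f(x')], and agreement with an independent oracle that
integrates central-finite-difference gradients over a dense alpha grid.
"""

import numpy as np
import pytest

from pathimage.attribution import (
    AttributionMap,
    GradientShapConfig,
    aggregate_class_attributions,
    gradient_shap,
    pathway_set_analysis,
    top_k_features,
)


class LinearModel:
    """f(x) = sum(w * x) with constant gradient; target class ignored."""

    def __init__(self, w):
        self.w = w

    def value(self, x):
        return np.sum(self.w * x, axis=(-2, -1))

    def __call__(self, batch, target):
        return np.broadcast_to(self.w, batch.shape).copy()


class QuadraticModel:
    """f(x) = sum(a * x^2) — curvature exercises the path integral."""

    def __init__(self, a):
        self.a = a

    def value(self, x):
        return np.sum(self.a * x**2, axis=(-2, -1))

    def __call__(self, batch, target):
        return 2 * self.a * batch


def fd_path_integral_oracle(value_fn, x, baselines, n_alpha=101, eps=1e-5):
    """Independent estimator: dense trapezoid alpha grid, FD gradients,
    exact expectation over the given baselines (no sampling, no noise)."""
    phi = np.zeros_like(x)
    alphas = np.linspace(0, 1, n_alpha)
    for bl in baselines:
        g_acc = np.zeros_like(x)
        for a in alphas:
            pt = bl + a * (x - bl)
            g = np.zeros_like(x)
            for idx in np.ndindex(x.shape):
                p_plus, p_minus = pt.copy(), pt.copy()
                p_plus[idx] += eps
                p_minus[idx] -= eps
                g[idx] = (value_fn(p_plus) - value_fn(p_minus)) / (2 * eps)
            g_acc += g
        phi += (g_acc / n_alpha) * (x - bl)
    return phi / len(baselines)


class TestGradientShap:
    def test_zero_attribution_at_baseline(self):
        model = LinearModel(np.ones((3, 2)))
        x = np.full((3, 2), 0.7)
        cfg = GradientShapConfig(n_baselines=5, n_path_samples=3, noise_sd=0.0, seed=0)
        amap = gradient_shap(model, x, x[None], cfg)
        np.testing.assert_allclose(amap.phi, 0.0, atol=1e-12)

    def test_linear_model_closed_form(self, rng):
        w = rng.normal(size=(4, 3))
        model = LinearModel(w)
        x = rng.normal(size=(4, 3))
        bl = rng.normal(size=(4, 3))
        cfg = GradientShapConfig(n_baselines=1, n_path_samples=1, noise_sd=0.0, seed=1)
        amap = gradient_shap(model, x, bl[None], cfg)
        np.testing.assert_allclose(amap.phi, w * (x - bl), atol=1e-12)

    def test_completeness_quadratic(self, rng):
        a = rng.uniform(0.5, 1.5, size=(5, 4))
        model = QuadraticModel(a)
        x = rng.normal(size=(5, 4))
        baselines = rng.normal(size=(10, 5, 4))
        cfg = GradientShapConfig(n_baselines=100, n_path_samples=8,
                                 noise_sd=0.0, seed=2)
        amap = gradient_shap(model, x, baselines, cfg)
        expected = model.value(x) - model.value(baselines).mean()
        rel_err = abs(amap.phi.sum() - expected) / abs(expected)
        assert rel_err < 0.05

    def test_agrees_with_finite_difference_oracle(self, rng):
        a = rng.uniform(0.5, 1.5, size=(4, 3))
        model = QuadraticModel(a)
        x = rng.normal(size=(4, 3))
        baselines = rng.normal(size=(3, 4, 3))
        cfg = GradientShapConfig(n_baselines=600, n_path_samples=4,
                                 noise_sd=0.0, seed=3)
        amap = gradient_shap(model, x, baselines, cfg)
        oracle = fd_path_integral_oracle(model.value, x, baselines)
        r = np.corrcoef(amap.phi.ravel(), oracle.ravel())[0, 1]
        assert r > 0.95

    def test_seeded_determinism(self, rng):
        model = QuadraticModel(np.ones((3, 3)))
        x = rng.normal(size=(3, 3))
        baselines = rng.normal(size=(5, 3, 3))
        cfg = GradientShapConfig(n_baselines=20, n_path_samples=4, seed=9)
        a = gradient_shap(model, x, baselines, cfg)
        b = gradient_shap(model, x, baselines, cfg)
        np.testing.assert_array_equal(a.phi, b.phi)

    def test_symmetric_features_equal_attribution(self):
        """Two cells with identical roles get equal scores within MC error."""
        w = np.zeros((1, 2))
        w[0] = [1.0, 1.0]
        model = LinearModel(w)
        x = np.array([[0.8, 0.8]])
        rng = np.random.default_rng(4)
        baselines = np.zeros((20, 1, 2))
        cfg = GradientShapConfig(n_baselines=200, n_path_samples=4,
                                 noise_sd=0.1, seed=5)
        amap = gradient_shap(model, x, baselines, cfg)
        assert abs(amap.phi[0, 0] - amap.phi[0, 1]) < 0.05 * abs(amap.phi[0, 0] + 1e-9)

    def test_monte_carlo_error_shrinks(self, rng):
        """Estimator scatter decreases roughly like 1/sqrt(n_path_samples)."""
        a = rng.uniform(0.5, 1.5, size=(3, 3))
        model = QuadraticModel(a)
        x = rng.normal(size=(3, 3))
        baselines = rng.normal(size=(8, 3, 3))
        sds = []
        for n in (4, 16, 64):
            vals = []
            for seed in range(12):
                cfg = GradientShapConfig(n_baselines=n, n_path_samples=4,
                                         noise_sd=0.0, seed=seed)
                vals.append(gradient_shap(model, x, baselines, cfg).phi.sum())
            sds.append(np.std(vals))
        assert sds[0] > sds[1] > sds[2]

    def test_zero_baselines_rejected(self):
        model = LinearModel(np.ones((2, 2)))
        with pytest.raises(ValueError):
            gradient_shap(model, np.ones((2, 2)), np.empty((0, 2, 2)),
                          GradientShapConfig(seed=0))


def make_map(phi, cls=1):
    return AttributionMap("s", cls, np.asarray(phi, dtype=float),
                          [f"P{i}" for i in range(np.asarray(phi).shape[0])],
                          [("EXP", 1), ("EXP", 2)])


class TestAggregation:
    def test_single_sample_class_passthrough(self):
        m = make_map([[1.0, -2.0], [0.5, 0.0]])
        scores = aggregate_class_attributions([m], ["LTS"], ["LTS"])
        np.testing.assert_array_equal(scores["LTS"].signed_mean, m.phi)
        np.testing.assert_array_equal(scores["LTS"].abs_mean, np.abs(m.phi))

    def test_cancellation_signed_vs_absolute(self):
        v = np.array([[1.0, -3.0]])
        scores = aggregate_class_attributions(
            [make_map(v), make_map(-v)], ["LTS", "LTS"], ["LTS"])
        np.testing.assert_allclose(scores["LTS"].signed_mean, 0.0)
        np.testing.assert_allclose(scores["LTS"].abs_mean, np.abs(v))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            aggregate_class_attributions([make_map([[1.0, 1.0]])], ["LTS"],
                                         ["LTS", "non-LTS"])


class TestTopK:
    def _scores(self, values):
        arr = np.asarray(values, dtype=float)
        from pathimage.attribution import GlobalFeatureScores

        return GlobalFeatureScores(
            "LTS", arr, np.abs(arr),
            [f"P{i}" for i in range(arr.shape[0])],
            [("EXP", c + 1) for c in range(arr.shape[1])],
        )

    def test_ordering_and_k(self):
        s = self._scores([[3.0], [1.0], [2.0]])
        top = top_k_features(s, 2)
        assert [c["pathway"] for c in top] == ["P0", "P2"]

    def test_full_ranking(self):
        s = self._scores([[3.0, 0.5], [1.0, 2.0]])
        top = top_k_features(s, 4)
        assert [c["score"] for c in top] == [3.0, 2.0, 1.0, 0.5]

    def test_deterministic_tie_break(self):
        s = self._scores([[1.0, 1.0], [1.0, 1.0]])
        top = top_k_features(s, 4)
        assert [(c["row"], c["col"]) for c in top] == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_pathway_can_appear_twice(self):
        s = self._scores([[5.0, 4.0], [1.0, 0.5]])
        top = top_k_features(s, 2)
        assert [c["pathway"] for c in top] == ["P0", "P0"]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            top_k_features(self._scores([[1.0]]), 5)


class TestPathwaySets:
    def _cells(self, pathways):
        return [{"pathway": p, "omics": "EXP", "pc": 1, "score": 1.0} for p in pathways]

    def test_identical_sets_all_common(self):
        rep = pathway_set_analysis({
            "LTS": self._cells(["A", "B"]),
            "non-LTS": self._cells(["B", "A"]),
        })
        assert set(rep.common) == {"A", "B"}
        assert rep.unique == {"LTS": [], "non-LTS": []}

    def test_disjoint_sets_no_common(self):
        rep = pathway_set_analysis({
            "LTS": self._cells(["A"]), "non-LTS": self._cells(["B"])})
        assert rep.common == []
        assert rep.unique["LTS"] == ["A"]

    def test_six_common_two_unique_pattern(self):
        """Two 10-cell lists mapping to 8 pathways each, 6 shared."""
        shared = [f"S{i}" for i in range(6)]
        a = self._cells(shared + ["A1", "A2"] + shared[:2])  # 10 cells, 8 pathways
        b = self._cells(shared + ["B1", "B2"] + shared[2:4])
        rep = pathway_set_analysis({"LTS": a, "non-LTS": b})
        assert len(rep.common) == 6
        assert rep.unique["LTS"] == ["A1", "A2"]
        assert rep.unique["non-LTS"] == ["B1", "B2"]
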