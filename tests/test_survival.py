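"""Cox partial-likelihood estimation against closed properties and lifelines."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from pathimage.survival import (
    fit_coxph,
    run_pathway_survival,
    select_significant_genes,
    wald_test,
)
from pathimage.synthetic import generate_survival_data


def lifelines_fit(times, events, x):
    df = pd.DataFrame(x, columns=[f"x{j}" for j in range(x.shape[1])])
    df["T"] = times
    df["E"] = events
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E")
    return cph


class TestFitCoxph:
    def test_recovers_known_coefficients(self):
        clin, x = generate_survival_data(2000, np.array([0.7, -0.4]), seed=4)
        fit = fit_coxph(clin.time_years, clin.event, x, standardize=False)
        assert fit.converged
        assert abs(fit.beta[0] - 0.7) < 0.1
        assert abs(fit.beta[1] + 0.4) < 0.1

    def test_agrees_with_lifelines(self):
        clin, x = generate_survival_data(400, np.array([0.5, -0.3, 0.0]),
                                         censoring_rate=0.25, seed=7)
        fit = fit_coxph(clin.time_years, clin.event, x, standardize=False)
        ref = lifelines_fit(clin.time_years, clin.event, x)
        np.testing.assert_allclose(fit.beta, ref.params_.to_numpy(), atol=1e-4)
        np.testing.assert_allclose(fit.se, ref.standard_errors_.to_numpy(), atol=1e-4)

    def test_agreement_battery(self):
        """beta/SE/p match lifelines within 1e-4 across many simulated sets."""
        rng = np.random.default_rng(0)
        for rep in range(50):
            p = int(rng.integers(1, 4))
            betas = rng.normal(0, 0.5, size=p)
            clin, x = generate_survival_data(
                120, betas, censoring_rate=float(rng.uniform(0, 0.4)),
                seed=int(rng.integers(2**31)),
            )
            fit = fit_coxph(clin.time_years, clin.event, x, standardize=False)
            if not fit.converged:
                continue
            ref = lifelines_fit(clin.time_years, clin.event, x)
            np.testing.assert_allclose(fit.beta, ref.params_.to_numpy(), atol=1e-4)
            np.testing.assert_allclose(fit.se, ref.standard_errors_.to_numpy(), atol=1e-4)
            ref_p = ref.summary["p"].to_numpy()
            ours_p = np.array([r.p_value for r in wald_test(fit, alpha=0.01)])
            np.testing.assert_allclose(ours_p, ref_p, atol=1e-4)

    def test_score_norm_at_optimum(self):
        from pathimage.survival import _breslow_loglik

        clin, x = generate_survival_data(300, np.array([0.4, 0.2]), seed=3)
        fit = fit_coxph(clin.time_years, clin.event, x, standardize=False)
        order = np.argsort(clin.time_years)
        _, grad, _ = _breslow_loglik(fit.beta, x[order],
                                     clin.time_years[order], clin.event[order])
        assert np.linalg.norm(grad) < 1e-8

    def test_constant_covariate_untestable(self):
        clin, x = generate_survival_data(100, np.array([0.3]), seed=5)
        x2 = np.column_stack([x, np.ones(100)])
        fit = fit_coxph(clin.time_years, clin.event, x2, ["g1", "const"])
        records = wald_test(fit)
        assert [r.gene for r in records] == ["g1"]

    def test_requirements(self):
        with pytest.raises(ValueError):
            fit_coxph(np.ones(5), np.ones(5, dtype=int), np.ones((5, 1)))
        with pytest.raises(ValueError):
            fit_coxph(np.ones(20), np.zeros(20, dtype=int), np.ones((20, 1)))


class TestWaldRecords:
    def test_hr_ci_algebra(self):
        clin, x = generate_survival_data(500, np.array([0.6, -0.2]), seed=8)
        fit = fit_coxph(clin.time_years, clin.event, x)
        for r in wald_test(fit, alpha=0.05):
            assert r.ci_low < r.hr < r.ci_high
            # log-CI symmetric about beta
            assert np.log(r.ci_high) - r.beta == pytest.approx(
                r.beta - np.log(r.ci_low), abs=1e-12)
            assert r.hr == pytest.approx(np.exp(r.beta))
            assert r.significant == (r.p_value < 0.05)

    def test_wald_threshold_quantile(self):
        # beta = 1.96 SE gives p close to 0.05
        from scipy.stats import norm

        assert 2 * norm.sf(1.96) == pytest.approx(0.05, abs=1e-3)

    def test_type_i_error_calibration(self):
        """Null simulation: fraction of p < 0.01 is 0.01 within MC bounds."""
        hits, n_rep = 0, 1000
        for rep in range(n_rep):
            clin, x = generate_survival_data(200, np.array([0.0]), seed=10_000 + rep)
            fit = fit_coxph(clin.time_years, clin.event, x, standardize=False)
            (rec,) = wald_test(fit, alpha=0.01)
            hits += rec.p_value < 0.01
        assert abs(hits / n_rep - 0.01) <= 0.01


class TestSelection:
    def test_threshold_edges(self):
        from pathimage.survival import GeneSurvivalRecord

        def rec(gene, p):
            return GeneSurvivalRecord(gene, 0.1, 0.1, 1.0, p, 1.1, 1.0, 1.2,
                                      p < 0.01)

        table = select_significant_genes([rec("a", 0.009), rec("b", 0.011)])
        assert table["gene"].tolist() == ["a"]

    def test_empty_table_allowed(self):
        assert len(select_significant_genes([])) == 0

    def test_power_on_planted_effects(self):
        """3 true-effect genes (|beta|=0.8) among 20 nulls at n=500: at
        least 2 recovered, false positives rare."""
        betas = np.zeros(23)
        betas[:3] = [0.8, -0.8, 0.8]
        clin, x = generate_survival_data(500, betas, seed=12)
        fit = fit_coxph(clin.time_years, clin.event, x,
                        [f"g{j}" for j in range(23)], standardize=False)
        table = select_significant_genes(wald_test(fit), alpha=0.01)
        found = set(table["gene"]) & {"g0", "g1", "g2"}
        false_pos = set(table["gene"]) - {"g0", "g1", "g2"}
        assert len(found) >= 2
        assert len(false_pos) <= 1


class TestPathwaySurvival:
    def test_planted_genes_dominate(self, small_cohort):
        ds = small_cohort["dataset"]
        truth = small_cohort["truth"]
        pw = small_cohort["pathways"]
        # gene G00000 carries beta 0.7 in the generator (first omics layer)
        pid = pw.pathway_ids[0]
        per_pathway, table = run_pathway_survival(
            ds, [pid], pw, small_cohort["clinical"],
            omics_for_cox=ds.omics_names[0], alpha=0.05,
        )
        assert pid in per_pathway
        recs = {r.gene: r for r in per_pathway[pid]}
        assert "G00000" in recs
        assert recs["G00000"].beta > 0  # sign matches planted effect

    def test_deterministic(self, small_cohort):
        ds, pw = small_cohort["dataset"], small_cohort["pathways"]
        args = (ds, [pw.pathway_ids[0]], pw, small_cohort["clinical"])
        _, a = run_pathway_survival(*args, omics_for_cox=ds.omics_names[0])
        _, b = run_pathway_survival(*args, omics_for_cox=ds.omics_names[0])
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_layer_rejected(self, small_cohort):
        ds, pw = small_cohort["dataset"], small_cohort["pathways"]
        with pytest.raises(ValueError, match="omics"):
            run_pathway_survival(ds, [pw.pathway_ids[0]], pw,
                                 small_cohort["clinical"], omics_for_cox="NOPE")
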