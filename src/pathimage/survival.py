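"""Cox proportional-hazards gene selection within significant pathways.

The hazard for covariates X is h(t|X) = h0(t) exp(beta . X); the baseline
hazard h0 cancels in the partial likelihood, so beta is estimated alone.
Fitting maximizes the Breslow partial log-likelihood by Newton iteration;
standard errors come from the inverse observed information.  Each gene gets
a Wald statistic W = beta / SE(beta), a two-sided normal p-value, a hazard
ratio HR = exp(beta) and a 95% CI exp(beta +/- 1.96 SE); genes with p below
a threshold (default 0.01) are reported as significant — the rows of a
forest plot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class CoxFit:
    gene_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int
    pathway_id: str = ""


@dataclass
class GeneSurvivalRecord:
    gene: str
    beta: float
    se: float
    wald: float
    p_value: float
    hr: float
    ci_low: float
    ci_high: float
    significant: bool
    pathway_id: str = ""


def _breslow_loglik(beta, x, times, events):
    """Breslow partial log-likelihood, gradient and Hessian.

    Samples are pre-sorted by ascending time; tied event times share one
    risk set (every subject with time >= t).
    """
    eta = x @ beta
    # Guard against overflow in exp for wild Newton steps.
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    # Suffix sums over the risk sets.
    s0 = np.cumsum(w[::-1])[::-1]                       # (n,)
    s1 = np.cumsum((w[:, None] * x)[::-1], axis=0)[::-1]  # (n, p)
    xxw = w[:, None, None] * (x[:, :, None] * x[:, None, :])
    s2 = np.cumsum(xxw[::-1], axis=0)[::-1]             # (n, p, p)
    # Map each index to the first position of its tied-time group.
    first = np.zeros(len(times), dtype=int)
    for i in range(1, len(times)):
        first[i] = first[i - 1] if times[i] == times[i - 1] else i
    ev = events.astype(bool)
    k = first[ev]
    ll = float(np.sum(eta[ev]) - np.sum(np.log(s0[k])))
    mu = s1[k] / s0[k, None]                            # (d, p)
    grad = x[ev].sum(axis=0) - mu.sum(axis=0)
    v = s2[k] / s0[k, None, None] - mu[:, :, None] * mu[:, None, :]
    hess = -v.sum(axis=0)
    return ll, grad, hess


def fit_coxph(
    times: np.ndarray,
    events: np.ndarray,
    covariates: np.ndarray,
    gene_ids: list[str] | None = None,
    standardize: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
    pathway_id: str = "",
) -> CoxFit:
    """Fit a Cox model by Newton iteration on the Breslow partial likelihood.

    Covariates are z-scored before the fit (constant columns are dropped with
    a warning and reported with beta = 0, SE = inf).  Convergence requires
    gradient norm below ``tol``; non-convergence or a singular information
    matrix flags the fit as failed.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    if x.shape[0] != times.size:
        x = x.T
    n, p = x.shape
    if n < 10:
        raise ValueError("need >= 10 samples")
    if events.sum() < 1:
        raise ValueError("need >= 1 observed event")
    gene_ids = list(gene_ids) if gene_ids is not None else [f"X{j}" for j in range(p)]

    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = [g for g, k in zip(gene_ids, keep) if not k]
    if dropped:
        logger.warning("dropping constant covariates: %s", dropped)
    xk = x[:, keep]
    if standardize and xk.shape[1]:
        xk = (xk - xk.mean(axis=0)) / xk.std(axis=0, ddof=0)

    order = np.argsort(times, kind="stable")
    ts, es, xs = times[order], events[order], xk[order]

    q = xk.shape[1]
    beta = np.zeros(q)
    converged = False
    ll, grad, hess = _breslow_loglik(beta, xs, ts, es)
    it = 0
    for it in range(1, max_iter + 1):
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            break
        # Step-halving to keep the likelihood non-decreasing.
        t_step = 1.0
        for _ in range(30):
            cand = beta + t_step * step
            ll_new, grad_new, hess_new = _breslow_loglik(cand, xs, ts, es)
            if ll_new >= ll - 1e-12:
                beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
                break
            t_step *= 0.5
        else:
            break
    if not converged and np.linalg.norm(grad) < tol:
        converged = True

    se = np.full(q, np.inf)
    cov = np.full((q, q), np.nan)
    if converged and q:
        try:
            cov = np.linalg.inv(-hess)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            converged = False
    if not converged:
        logger.warning("Cox fit failed to converge (pathway %s)", pathway_id or "-")

    # Re-inflate dropped constant columns.
    beta_full = np.zeros(p)
    se_full = np.full(p, np.inf)
    beta_full[keep] = beta
    se_full[keep] = se
    return CoxFit(gene_ids, beta_full, se_full, cov, ll, converged, it, pathway_id)


def wald_test(fit: CoxFit, alpha: float = 0.01) -> list[GeneSurvivalRecord]:
    """Per-gene Wald statistics W = beta/SE with two-sided normal p-values."""
    if not fit.converged:
        raise ValueError("Wald test requires a converged fit")
    records = []
    for g, b, s in zip(fit.gene_ids, fit.beta, fit.se):
        if not np.isfinite(s):
            continue  # constant covariate, untestable
        w = b / s
        p = 2 * norm.sf(abs(w))
        records.append(GeneSurvivalRecord(
            gene=g, beta=float(b), se=float(s), wald=float(w), p_value=float(p),
            hr=float(np.exp(b)),
            ci_low=float(np.exp(b - Z_95 * s)),
            ci_high=float(np.exp(b + Z_95 * s)),
            significant=bool(p < alpha),
            pathway_id=fit.pathway_id,
        ))
    return records


def select_significant_genes(
    records: list[GeneSurvivalRecord], alpha: float = 0.01
) -> pd.DataFrame:
    """Forest-plot table of genes with p < alpha, sorted by p-value."""
    rows = [
        {"pathway_id": r.pathway_id, "gene": r.gene, "beta": r.beta, "se": r.se,
         "wald": r.wald, "p": r.p_value, "hr": r.hr, "ci_low": r.ci_low,
         "ci_high": r.ci_high}
        for r in records if r.p_value < alpha
    ]
    df = pd.DataFrame(rows, columns=["pathway_id", "gene", "beta", "se", "wald",
                                     "p", "hr", "ci_low", "ci_high"])
    return df.sort_values("p").reset_index(drop=True) if len(df) else df


def run_pathway_survival(
    dataset,
    pathway_ids: list[str],
    pathways,
    clinical,
    omics_for_cox: str = "EXP",
    mode: str = "multivariate-per-pathway",
    alpha: float = 0.01,
    include_censored_short: bool = True,
) -> tuple[dict[str, list[GeneSurvivalRecord]], pd.DataFrame]:
    """Cox fits over each significant pathway's genes in one omics layer.

    ``mode`` fits either one multivariate model per pathway (default) or one
    univariate model per gene.  By default every clinical sample present in
    the dataset enters the fit — censoring is handled natively, so the
    short-follow-up samples excluded from classification remain eligible.
    """
    if mode not in ("multivariate-per-pathway", "univariate-per-gene"):
        raise ValueError(f"unknown mode {mode!r}")
    if omics_for_cox not in dataset.omics_names:
        raise ValueError(f"omics layer {omics_for_cox!r} not in dataset")
    om = dataset.omics[dataset.omics_names.index(omics_for_cox)]
    clin = clinical.to_frame()
    if include_censored_short:
        usable = [s for s in om.sample_ids if s in clin.index]
    else:
        labelled = set(dataset.labels.classified_samples)
        usable = [s for s in om.sample_ids if s in clin.index and s in labelled]
    rows = [om.sample_ids.index(s) for s in usable]
    times = clin.loc[usable, "time_years"].to_numpy()
    events = clin.loc[usable, "event"].to_numpy(dtype=int)
    gene_index = {g: i for i, g in enumerate(om.gene_ids)}

    per_pathway: dict[str, list[GeneSurvivalRecord]] = {}
    for pid in pathway_ids:
        genes = [g for g in pathways.genes(pid) if g in gene_index]
        if not genes:
            logger.warning("pathway %s has no genes in the universe; skipped", pid)
            continue
        xmat = om.values[np.ix_(rows, [gene_index[g] for g in genes])]
        records: list[GeneSurvivalRecord] = []
        if mode == "multivariate-per-pathway":
            fit = fit_coxph(times, events, xmat, genes, pathway_id=pid)
            if fit.converged:
                records = wald_test(fit, alpha)
        else:
            for j, g in enumerate(genes):
                fit = fit_coxph(times, events, xmat[:, [j]], [g], pathway_id=pid)
                if fit.converged:
                    records.extend(wald_test(fit, alpha))
        per_pathway[pid] = records
    all_records = [r for recs in per_pathway.values() for r in recs]
    return per_pathway, select_significant_genes(all_records, alpha)
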