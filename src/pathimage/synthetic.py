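"""Synthetic multi-omics cohorts with known ground truth.

Emulates the structure of TCGA-style survival cohorts: two survival classes,
several omics layers over a shared gene universe, pathway gene sets that
partition that universe, a configurable set of "planted" discriminative
pathways whose genes carry a class-dependent mean shift, and survival times
with known log-hazard coefficients for designated genes.  Every downstream
stage of the pipeline is testable against this generator's bookkeeping.

All randomness flows through a single ``numpy.random.Generator`` (PCG64)
seeded from the config, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import (
    LTS,
    NON_LTS,
    ClinicalTable,
    OmicsMatrix,
    PathwayCollection,
)


@dataclass
class PlantedEffect:
    """A class-2 mean shift of ``delta`` (in noise-SD units) on the genes of
    one (pathway, omics) pair."""

    pathway_index: int
    omics_index: int
    delta: float


@dataclass
class SyntheticConfig:
    n_samples_per_class: tuple[int, int] = (60, 90)  # (LTS, non-LTS)
    n_omics: int = 3
    n_pathways: int = 146
    genes_per_pathway: tuple[int, int] = (10, 30)
    planted: list[PlantedEffect] = field(default_factory=list)
    noise_sd: float = 1.0
    survival_betas: dict[int, float] = field(default_factory=dict)  # gene index -> beta
    censoring_rate: float = 0.0
    n_short_censored: int = 10  # extra samples censored below threshold ("excluded")
    threshold_years: float = 2.0
    omics_names: tuple[str, ...] = ("CNV", "EXP", "MET")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")
        for eff in self.planted:
            if not np.isfinite(eff.delta):
                raise ValueError("planted effect size must be finite")
            if not (0 <= eff.pathway_index < self.n_pathways):
                raise ValueError(f"planted pathway index {eff.pathway_index} out of range")
            if not (0 <= eff.omics_index < self.n_omics):
                raise ValueError(f"planted omics index {eff.omics_index} out of range")
        if len(self.omics_names) < self.n_omics:
            self.omics_names = tuple(
                list(self.omics_names) + [f"OMICS{i}" for i in range(len(self.omics_names), self.n_omics)]
            )


@dataclass
class SyntheticTruth:
    """Ground truth the generator knows: class per sample, planted cells,
    per-pathway gene index ranges, and true log-hazard coefficients."""

    classes: dict[str, str]
    planted: list[PlantedEffect]
    pathway_gene_slices: list[tuple[int, int]]
    survival_betas: dict[int, float]
    gene_ids: list[str]
    pathway_ids: list[str]


def _truncated_exponential(rng, rate, low, high, size):
    """Inverse-CDF sample of Exp(rate) conditioned on (low, high]."""
    rate = np.broadcast_to(rate, size).astype(float)
    u = rng.uniform(size=size)
    cl = -np.expm1(-rate * low)   # CDF at low
    ch = -np.expm1(-rate * high) if np.isfinite(high) else 1.0
    return -np.log1p(-(cl + u * (ch - cl))) / rate


def generate_multiomics(
    config: SyntheticConfig,
) -> tuple[list[OmicsMatrix], PathwayCollection, ClinicalTable, SyntheticTruth]:
    """Draw a full synthetic cohort.

    Background values are Normal(0, noise_sd).  For each planted
    (pathway, omics, delta), the non-LTS class's genes in that pathway are
    shifted by +delta * noise_sd.  Pathway gene lists partition the gene
    universe.  Survival times follow an exponential proportional-hazards
    model on the designated genes with a class-specific baseline hazard,
    sampled conditionally so that thresholding reproduces the planted
    classes exactly; an extra block of samples censored below the threshold
    exercises the exclusion rule.
    """
    rng = np.random.default_rng(config.seed)
    n1, n2 = config.n_samples_per_class
    n_classified = n1 + n2
    n_total = n_classified + config.n_short_censored

    sizes = rng.integers(config.genes_per_pathway[0], config.genes_per_pathway[1] + 1,
                         size=config.n_pathways)
    n_genes = int(sizes.sum())
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    slices: list[tuple[int, int]] = []
    pathways: list[tuple[str, list[str]]] = []
    start = 0
    for p, sz in enumerate(sizes):
        stop = start + int(sz)
        slices.append((start, stop))
        pathways.append((f"PW{p:04d}", gene_ids[start:stop]))
        start = stop
    collection = PathwayCollection(pathways)

    sample_ids = [f"S{i:04d}" for i in range(n_total)]
    classes = {sid: (LTS if i < n1 else NON_LTS) for i, sid in enumerate(sample_ids[:n_classified])}

    matrices: list[OmicsMatrix] = []
    for o in range(config.n_omics):
        vals = rng.normal(0.0, config.noise_sd, size=(n_total, n_genes))
        for eff in config.planted:
            if eff.omics_index != o:
                continue
            lo, hi = slices[eff.pathway_index]
            vals[n1:n_classified, lo:hi] += eff.delta * config.noise_sd
        matrices.append(OmicsMatrix(config.omics_names[o], list(sample_ids), list(gene_ids), vals))

    # Survival: exponential PH with gene effects from the first omics layer,
    # conditionally sampled within each class's time window.
    thr = config.threshold_years
    lin = np.zeros(n_total)
    if config.survival_betas:
        x0 = matrices[0].values
        for gi, beta in config.survival_betas.items():
            lin += beta * x0[:, gi]
    base_rate = np.where(
        np.arange(n_total) < n1, 0.15, 1.2
    )  # low hazard for LTS, high for non-LTS
    rate = base_rate * np.exp(lin)
    times = np.empty(n_total)
    events = np.empty(n_total, dtype=int)
    # LTS: time beyond threshold; censor a fraction of them.
    times[:n1] = thr + _truncated_exponential(rng, rate[:n1], 0.0, np.inf, n1)
    events[:n1] = (rng.uniform(size=n1) >= config.censoring_rate).astype(int)
    # non-LTS: observed death at or before threshold.
    times[n1:n_classified] = _truncated_exponential(rng, rate[n1:n_classified], 0.0, thr,
                                                    n_classified - n1)
    events[n1:n_classified] = 1
    # short-follow-up censored samples (excluded downstream).
    if config.n_short_censored:
        times[n_classified:] = rng.uniform(0.05, thr, size=config.n_short_censored)
        events[n_classified:] = 0
    clinical = ClinicalTable(list(sample_ids), times, events)

    truth = SyntheticTruth(
        classes=classes,
        planted=list(config.planted),
        pathway_gene_slices=slices,
        survival_betas=dict(config.survival_betas),
        gene_ids=gene_ids,
        pathway_ids=collection.pathway_ids,
    )
    return matrices, collection, clinical, truth


def generate_survival_data(
    n: int,
    betas: np.ndarray,
    baseline_rate: float = 0.5,
    censoring_rate: float = 0.0,
    seed: int = 0,
) -> tuple[ClinicalTable, np.ndarray]:
    """Clean exponential proportional-hazards data for estimator calibration.

    Covariates are iid standard normal; event times are Exp(baseline_rate *
    exp(X beta)); censoring times are drawn uniform on (0, c_max] with c_max
    tuned so the expected censored fraction matches ``censoring_rate``.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, betas.size))
    rate = baseline_rate * np.exp(x @ betas)
    t_event = rng.exponential(1.0 / rate)
    if censoring_rate > 0:
        # Calibrate a uniform censoring horizon by bisection on the empirical
        # censored fraction (deterministic given the drawn times).
        u = rng.uniform(size=n)
        lo_c, hi_c = 1e-3, float(np.quantile(t_event, 0.999)) * 10
        for _ in range(60):
            mid = 0.5 * (lo_c + hi_c)
            frac = np.mean(u * mid < t_event)
            if frac > censoring_rate:
                lo_c = mid  # longer horizon -> less censoring
            else:
                hi_c = mid
        t_cens = u * 0.5 * (lo_c + hi_c)
        events = (t_event <= t_cens).astype(int)
        times = np.minimum(t_event, t_cens)
    else:
        events = np.ones(n, dtype=int)
        times = t_event
    clinical = ClinicalTable([f"S{i:05d}" for i in range(n)], times, events)
    return clinical, x
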