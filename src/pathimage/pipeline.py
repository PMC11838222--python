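"""End-to-end orchestration: data -> images -> CNN CV -> attribution -> Cox.

A single ``RunConfig`` (YAML-serializable) drives the whole run.  One master
seed fans out to per-stage seeds through named ``numpy.random.SeedSequence``
derivations, so stages are individually reproducible and never share RNG
streams.  Every artifact directory carries the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attribution as attr
from . import classifier as clf
from . import data_io, embedding, survival, synthetic

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "prepare", "embed", "cv", "explain", "cox", "sweep")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master."""
    idx = _STAGES.index(stage) if stage in _STAGES else len(_STAGES)
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class CoxSettings:
    omics: str = "EXP"
    mode: str = "multivariate-per-pathway"
    alpha: float = 0.01
    include_censored_short: bool = True


@dataclass
class RunConfig:
    # data source: "synthetic" or "files"
    source: str = "synthetic"
    # synthetic source
    n_samples_per_class: tuple[int, int] = (60, 90)
    n_omics: int = 3
    n_pathways: int = 146
    genes_per_pathway: tuple[int, int] = (10, 30)
    planted: list[tuple[int, int, float]] = field(default_factory=list)
    noise_sd: float = 1.0
    survival_betas: dict[int, float] = field(default_factory=dict)
    censoring_rate: float = 0.1
    n_short_censored: int = 10
    # file source
    omics_paths: dict[str, str] = field(default_factory=dict)
    omics_orientation: str = "samples-as-rows"
    gmt_path: str = ""
    clinical_path: str = ""
    exclusion_path: str = ""
    time_unit: str = "years"
    # shared settings
    threshold_years: float = 2.0
    n_pcs: int = 2
    mode: str = "fold-safe"
    k_folds: int = 5
    top_k: int = 10
    cnn: clf.CnnConfig = field(default_factory=clf.CnnConfig)
    # Per-sample attribution budget: class-level scores average over all of a
    # class's samples, so a modest per-sample Monte-Carlo budget suffices.
    shap: attr.GradientShapConfig = field(
        default_factory=lambda: attr.GradientShapConfig(n_baselines=25, n_path_samples=2))
    cox: CoxSettings = field(default_factory=CoxSettings)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cnn"] = self.cnn.to_dict()
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cnn" in d and isinstance(d["cnn"], dict):
            c = dict(d["cnn"])
            for k in ("kernel_sizes", "pool_sizes"):
                if k in c:
                    c[k] = tuple(tuple(v) for v in c[k])
            if "filters" in c:
                c["filters"] = tuple(c["filters"])
            d["cnn"] = clf.CnnConfig(**c)
        if "shap" in d and isinstance(d["shap"], dict):
            d["shap"] = attr.GradientShapConfig(**d["shap"])
        if "cox" in d and isinstance(d["cox"], dict):
            d["cox"] = CoxSettings(**d["cox"])
        if "planted" in d:
            d["planted"] = [tuple(p) for p in d["planted"]]
        if "n_samples_per_class" in d:
            d["n_samples_per_class"] = tuple(d["n_samples_per_class"])
        if "genes_per_pathway" in d:
            d["genes_per_pathway"] = tuple(d["genes_per_pathway"])
        if "survival_betas" in d:
            d["survival_betas"] = {int(k): float(v) for k, v in d["survival_betas"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def synthetic_config(cfg: RunConfig) -> synthetic.SyntheticConfig:
    return synthetic.SyntheticConfig(
        n_samples_per_class=cfg.n_samples_per_class,
        n_omics=cfg.n_omics,
        n_pathways=cfg.n_pathways,
        genes_per_pathway=cfg.genes_per_pathway,
        planted=[synthetic.PlantedEffect(*p) for p in cfg.planted],
        noise_sd=cfg.noise_sd,
        survival_betas=cfg.survival_betas,
        censoring_rate=cfg.censoring_rate,
        n_short_censored=cfg.n_short_censored,
        threshold_years=cfg.threshold_years,
        seed=stage_seed(cfg.seed, "simulate"),
    )


def load_inputs(cfg: RunConfig):
    """Stage 1: produce (omics list, pathways, clinical) from config source."""
    if cfg.source == "synthetic":
        matrices, pathways, clinical, _truth = synthetic.generate_multiomics(synthetic_config(cfg))
        return matrices, pathways, clinical
    if cfg.source != "files":
        raise ValueError(f"unknown source {cfg.source!r}")
    matrices = [
        data_io.read_omics_matrix(path, name, cfg.omics_orientation)
        for name, path in cfg.omics_paths.items()
    ]
    exclusions: list[str] = []
    if cfg.exclusion_path:
        exclusions = [l.strip() for l in open(cfg.exclusion_path) if l.strip()]
    pathways = data_io.read_gene_sets(cfg.gmt_path, exclusions)
    clinical = data_io.read_clinical_table(cfg.clinical_path, cfg.time_unit)
    return matrices, pathways, clinical


def prepare(cfg: RunConfig):
    """Stages 1-2: inputs, survival labels and harmonization."""
    matrices, pathways, clinical = load_inputs(cfg)
    labels = data_io.assign_survival_labels(clinical, cfg.threshold_years)
    dataset = data_io.harmonize(matrices, labels)
    return dataset, pathways, clinical


@dataclass
class PipelineResult:
    cv: clf.CrossValidationResult
    scores: dict[str, attr.GlobalFeatureScores]
    report: attr.SignificantPathwayReport
    gene_table: pd.DataFrame
    config_hash: str


def explain_cv(
    cv_result: clf.CrossValidationResult,
    stacks: list[embedding.ImageStack],
    dataset: data_io.HarmonizedDataset,
    shap_cfg: attr.GradientShapConfig,
    top_k: int = 10,
) -> tuple[dict[str, attr.GlobalFeatureScores], attr.SignificantPathwayReport]:
    """Attribution over the cohort using each fold's model on its test samples.

    Every sample is attributed by the one model that never saw it in
    training, with that fold's training images as the baseline pool; maps are
    averaged per class into global scores, then rolled up to pathway sets.
    """
    y, class_order = cv_result.y_true, cv_result.fold_models[0].class_order
    maps: list[attr.AttributionMap] = []
    sample_classes: list[str] = []
    for i, sid in enumerate(dataset.sample_ids):
        fold = int(cv_result.fold_of_sample[i])
        model = cv_result.fold_models[fold]
        stack = stacks[fold]
        train_rows = np.flatnonzero(cv_result.fold_of_sample != fold)
        baselines = stack.tensor[train_rows]
        target = int(y[i])  # own-class attribution
        cfg_i = attr.GradientShapConfig(
            n_baselines=shap_cfg.n_baselines,
            n_path_samples=shap_cfg.n_path_samples,
            noise_sd=shap_cfg.noise_sd,
            seed=(shap_cfg.seed * 1_000_003 + i) % (2**31),
        )
        amap = attr.gradient_shap(
            model.input_gradient, stack.tensor[i], baselines, cfg_i,
            sample_id=sid, target_class=target,
            row_labels=stack.row_labels, col_labels=stack.col_labels,
        )
        maps.append(amap)
        sample_classes.append(class_order[target])
    scores = attr.aggregate_class_attributions(maps, sample_classes, class_order)
    per_class_cells = {cls: attr.top_k_features(s, top_k) for cls, s in scores.items()}
    report = attr.pathway_set_analysis(per_class_cells)
    return scores, report


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute every stage and (optionally) write artifacts to ``outdir``."""
    chash = cfg.config_hash()
    dataset, pathways, clinical = prepare(cfg)
    cv_seed = stage_seed(cfg.seed, "cv")
    cnn_cfg = dataclasses.replace(cfg.cnn, seed=stage_seed(cfg.seed, "embed"))
    cv_result = clf.cross_validate(
        dataset, pathways, cnn_cfg, n_pcs=cfg.n_pcs, k=cfg.k_folds,
        mode=cfg.mode, seed=cv_seed,
    )
    stacks = cv_result.fold_stacks
    shap_cfg = dataclasses.replace(cfg.shap, seed=stage_seed(cfg.seed, "explain"))
    scores, report = explain_cv(cv_result, stacks, dataset, shap_cfg, cfg.top_k)
    sig_pathways = sorted(set(report.common) | {p for u in report.unique.values() for p in u})
    _, gene_table = survival.run_pathway_survival(
        dataset, sig_pathways, pathways, clinical,
        omics_for_cox=cfg.cox.omics if cfg.cox.omics in dataset.omics_names
        else dataset.omics_names[0],
        mode=cfg.cox.mode, alpha=cfg.cox.alpha,
        include_censored_short=cfg.cox.include_censored_short,
    )
    result = PipelineResult(cv_result, scores, report, gene_table, chash)
    if outdir is not None:
        write_artifacts(result, cfg, Path(outdir))
    return result


def write_artifacts(result: PipelineResult, cfg: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    (outdir / "config_hash.txt").write_text(result.config_hash + "\n")
    metrics = {
        "config_hash": result.config_hash,
        "pooled": result.cv.pooled.to_dict(),
        "folds": [r.to_dict() for r in result.cv.fold_reports],
    }
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, default=float)
    pd.DataFrame([{"fold": i, **r.to_dict()} for i, r in enumerate(result.cv.fold_reports)]
                 + [{"fold": "pooled", **result.cv.pooled.to_dict()}]).to_csv(
        outdir / "metrics.tsv", sep="\t", index=False)
    result.report.to_frame().to_csv(outdir / "significant_pathways.tsv", sep="\t", index=False)
    result.gene_table.to_csv(outdir / "significant_genes.tsv", sep="\t", index=False)
    logger.info("artifacts written to %s (config %s)", outdir, result.config_hash)


def sweep_n_pcs(cfg: RunConfig, pc_values: list[int]) -> pd.DataFrame:
    """Full CV at each PC count; returns (n_pcs, pooled AUC, accuracy) table."""
    if not pc_values:
        raise ValueError("pc_values must be non-empty")
    rows = []
    for n_pcs in sorted(pc_values):
        sub = dataclasses.replace(cfg, n_pcs=n_pcs)
        dataset, pathways, _ = prepare(sub)
        cnn_cfg = dataclasses.replace(sub.cnn, seed=stage_seed(sub.seed, "embed"))
        cv_result = clf.cross_validate(
            dataset, pathways, cnn_cfg, n_pcs=n_pcs, k=sub.k_folds,
            mode=sub.mode, seed=stage_seed(sub.seed, "cv"),
        )
        rows.append({
            "n_pcs": n_pcs,
            "image_width": int(cv_result.fold_models[0].input_shape[1]),
            "pooled_auc": cv_result.pooled.auc_roc,
            "pooled_accuracy": cv_result.pooled.accuracy,
        })
    df = pd.DataFrame(rows)
    best = df.loc[df["pooled_auc"].idxmax()]
    logger.info("best n_pcs = %d (AUC %.3f)", int(best["n_pcs"]), best["pooled_auc"])
    return df
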