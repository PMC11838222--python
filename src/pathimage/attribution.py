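"""Gradient-SHAP feature attribution over pathway images.

The attribution of image cell i for target class c is the Monte-Carlo
estimate of

    phi_i = E_{x' ~ P(x')} [ integral_0^1 d f_c(x' + a (x - x')) / d x_i da ]
            * (x_i - x'_i)

where P(x') draws baselines from the training images plus Gaussian noise and
a is sampled uniformly on [0, 1] per path sample.  Summed over cells, the
attributions satisfy completeness: sum phi ~= f_c(x) - E[f_c(x')].

Per-cell attributions are averaged over all samples of a class (targeted at
that class) to give global scores; the top-k cells roll back to significant
(pathway, omics, PC) triples, and pathway sets are compared across classes
for common/unique membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GradientShapConfig:
    n_baselines: int = 50
    n_path_samples: int = 4   # interpolation points per baseline
    noise_sd: float | None = None  # default: 0.1 * per-cell training SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_baselines < 1 or self.n_path_samples < 1:
            raise ValueError("baseline and path-sample counts must be >= 1")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class AttributionMap:
    sample_id: str
    target_class: int
    phi: np.ndarray  # same shape as the image
    row_labels: list[str]
    col_labels: list[tuple[str, int]]


@dataclass
class GlobalFeatureScores:
    class_label: str
    signed_mean: np.ndarray
    abs_mean: np.ndarray
    row_labels: list[str]
    col_labels: list[tuple[str, int]]
    ranking_key: str = "abs"  # "abs" or "signed"

    def ranking(self) -> list[tuple[int, int]]:
        """All (row, col) cells ordered by decreasing score; ties break by
        (pathway order, column order)."""
        score = self.abs_mean if self.ranking_key == "abs" else self.signed_mean
        n_rows, n_cols = score.shape
        cells = [(r, c) for r in range(n_rows) for c in range(n_cols)]
        return sorted(cells, key=lambda rc: (-score[rc], rc[0], rc[1]))


@dataclass
class SignificantPathwayReport:
    per_class_cells: dict[str, list[dict]]
    per_class_pathways: dict[str, list[str]]
    common: list[str]
    unique: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls, cells in self.per_class_cells.items():
            for cell in cells:
                rows.append({
                    "class": cls,
                    "pathway": cell["pathway"],
                    "omics": cell["omics"],
                    "pc": cell["pc"],
                    "score": cell["score"],
                    "shared": cell["pathway"] in self.common,
                })
        return pd.DataFrame(rows)


def gradient_shap(
    value_and_grad,
    x: np.ndarray,
    baselines: np.ndarray,
    config: GradientShapConfig,
    sample_id: str = "",
    target_class: int = 1,
    row_labels: list[str] | None = None,
    col_labels: list[tuple[str, int]] | None = None,
) -> AttributionMap:
    """Estimate per-cell attributions for one input image.

    ``value_and_grad(batch, target)`` must return the gradient of the target
    output w.r.t. each input in the batch, shape-matched to the batch.
    ``baselines`` is a (m, h, w) pool (typically training images); each of
    ``n_baselines`` draws picks one pool image, perturbs it with Gaussian
    noise, and contributes ``n_path_samples`` uniformly-placed interpolation
    points.  Deterministic for a fixed seed.
    """
    x = np.asarray(x, dtype=float)
    baselines = np.asarray(baselines, dtype=float)
    if baselines.ndim == 2:
        baselines = baselines[None]
    if baselines.shape[0] == 0:
        raise ValueError("need at least one baseline image")
    rng = np.random.default_rng(config.seed)
    noise_sd = config.noise_sd
    if noise_sd is None:
        noise_sd = 0.1 * float(baselines.std(axis=0).mean()) if baselines.shape[0] > 1 else 0.0

    # Cycle through a permuted baseline pool (lower variance than drawing
    # with replacement) and stratify the alpha draws along the path.
    perm = rng.permutation(baselines.shape[0])
    picks = np.resize(perm, config.n_baselines)
    total = config.n_baselines * config.n_path_samples
    bl = baselines[np.repeat(picks, config.n_path_samples)]
    if noise_sd > 0:
        bl = bl + rng.normal(0.0, noise_sd, size=bl.shape)
    strata = np.tile(np.arange(config.n_path_samples), config.n_baselines)
    alpha = ((strata + rng.uniform(size=total)) / config.n_path_samples)[:, None, None]
    points = bl + alpha * (x[None] - bl)
    grads = value_and_grad(points, target_class)
    phi = np.mean(grads * (x[None] - bl), axis=0)
    return AttributionMap(sample_id, target_class, phi,
                          row_labels or [], col_labels or [])


def attribute_model(model, x, baselines, config, **kw) -> AttributionMap:
    """gradient_shap using a TrainedModel's probability gradient."""
    return gradient_shap(model.input_gradient, x, baselines, config, **kw)


def aggregate_class_attributions(
    maps: list[AttributionMap],
    sample_classes: list[str],
    class_labels: list[str],
    ranking_key: str = "abs",
) -> dict[str, GlobalFeatureScores]:
    """Global per-cell scores: mean over each class's own-class attributions.

    Both the signed mean and the mean of absolute values are stored; the
    configured key (default absolute) drives the ranking.
    """
    out: dict[str, GlobalFeatureScores] = {}
    for cls in class_labels:
        members = [m for m, c in zip(maps, sample_classes) if c == cls]
        if not members:
            raise ValueError(f"no attribution maps for class {cls}")
        stackd = np.stack([m.phi for m in members])
        out[cls] = GlobalFeatureScores(
            class_label=cls,
            signed_mean=stackd.mean(axis=0),
            abs_mean=np.abs(stackd).mean(axis=0),
            row_labels=members[0].row_labels,
            col_labels=members[0].col_labels,
            ranking_key=ranking_key,
        )
    return out


def top_k_features(scores: GlobalFeatureScores, k: int = 10) -> list[dict]:
    """The k highest-ranked cells as (pathway, omics, PC, score) records.

    A pathway may legitimately appear more than once through different cells;
    de-duplication happens only at the pathway-set level.
    """
    n_cells = scores.abs_mean.size
    if k > n_cells:
        raise ValueError(f"k={k} exceeds {n_cells} cells")
    key = scores.abs_mean if scores.ranking_key == "abs" else scores.signed_mean
    cells = []
    for r, c in scores.ranking()[:k]:
        omics, pc = scores.col_labels[c] if scores.col_labels else (str(c), c + 1)
        pathway = scores.row_labels[r] if scores.row_labels else str(r)
        cells.append({"pathway": pathway, "omics": omics, "pc": pc,
                      "score": float(key[r, c]), "row": r, "col": c})
    return cells


def pathway_set_analysis(per_class_cells: dict[str, list[dict]]) -> SignificantPathwayReport:
    """Common/unique pathway sets across classes from top-k cell lists."""
    if len(per_class_cells) < 2:
        raise ValueError("need top-k lists for at least 2 classes")
    per_class_pathways = {
        cls: list(dict.fromkeys(cell["pathway"] for cell in cells))
        for cls, cells in per_class_cells.items()
    }
    sets = [set(p) for p in per_class_pathways.values()]
    common_set = set.intersection(*sets)
    # Preserve first-class ordering for the common list.
    first = next(iter(per_class_pathways.values()))
    common = [p for p in first if p in common_set]
    unique = {
        cls: [p for p in paths if p not in common_set]
        for cls, paths in per_class_pathways.items()
    }
    return SignificantPathwayReport(per_class_cells, per_class_pathways, common, unique)
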