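"""Pathway-PC image construction.

The embedding turns a harmonized multi-omics cohort into one small 2-D
"image" per sample: rows are pathways, columns are (omics layer x principal
component) in omics-major order.  PCA is fitted separately for every
(survival class, omics layer, pathway) triple — class-specific embedding —
so each pathway's dominant within-class variation becomes a pixel.

Two assembly modes are provided:

``paper-faithful``
    Each class's PCA is fitted on all samples of that class and every sample
    is embedded with its own class's models.  This reproduces the original
    procedure but uses the label at embedding time (label leakage when the
    images later feed a classifier).

``fold-safe``
    PCA is fitted only on training-fold samples per class, and every sample
    (train and test) is embedded under BOTH classes' models, doubling the
    column count.  No label information enters a test sample's image.
    Training images are additionally *cross-fitted*: each training half is
    embedded with models fitted on the other half, so training projections
    are out-of-fit just like test projections.  Without this, in-fit
    projections carry systematically larger variance than out-of-fit ones
    and a classifier learns that artifact instead of the biology.  The
    half-fit PCA bases are Procrustes-rotated onto the full-fold bank's so
    all samples share one column coordinate system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .data_io import HarmonizedDataset, PathwayCollection, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PcaModel:
    """A fitted per-(class, omics, pathway) PCA with deterministic signs.

    ``loadings`` is genes x n_fitted columns, column-orthonormal; the sign of
    each component is fixed so its largest-magnitude loading is positive.
    Projections are zero-padded to ``n_pcs`` when the feasible rank is lower.
    """

    class_label: str
    omics_name: str
    pathway_id: str
    gene_ids: list[str]
    mean: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # (n_genes_used, n_fitted)
    explained_variance_ratio: np.ndarray
    n_pcs: int
    degenerate: bool = False

    @property
    def n_fitted(self) -> int:
        return self.loadings.shape[1]

    def project(self, sample_values: np.ndarray) -> np.ndarray:
        """Scores for one sample vector or a (n, genes) block, zero-padded."""
        x = np.atleast_2d(np.asarray(sample_values, dtype=float))
        if x.shape[1] != len(self.gene_ids):
            raise ValueError(
                f"sample has {x.shape[1]} genes, model expects {len(self.gene_ids)}"
            )
        if self.degenerate or self.n_fitted == 0:
            out = np.zeros((x.shape[0], self.n_pcs))
        else:
            z = (x - self.mean) / self.scale
            scores = z @ self.loadings
            out = np.zeros((x.shape[0], self.n_pcs))
            out[:, : self.n_fitted] = scores
        return out[0] if np.ndim(sample_values) == 1 else out


@dataclass
class PcaEmbeddingBank:
    """All fitted PCA models keyed by (class, omics, pathway), plus layout."""

    models: dict[tuple[str, str, str], PcaModel]
    class_labels: list[str]
    omics_names: list[str]
    pathway_ids: list[str]
    n_pcs: int
    degenerate_keys: list[tuple[str, str, str]] = field(default_factory=list)

    def __getitem__(self, key: tuple[str, str, str]) -> PcaModel:
        return self.models[key]

    def __len__(self) -> int:
        return len(self.models)


@dataclass
class PathwayPCImage:
    """One sample's pathway x (omics x PC) score grid."""

    sample_id: str
    grid: np.ndarray
    row_labels: list[str]
    col_labels: list[tuple[str, int]]  # (column tag, pc index), omics-major

    def __post_init__(self) -> None:
        if self.grid.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("image shape does not match labels")


@dataclass
class ImageStack:
    """A cohort's images sharing one row/column labelling, as a 3-D tensor."""

    sample_ids: list[str]
    tensor: np.ndarray  # (n_samples, n_pathways, n_cols)
    row_labels: list[str]
    col_labels: list[tuple[str, int]]
    norm_min: np.ndarray | None = None
    norm_range: np.ndarray | None = None

    def image(self, i: int) -> PathwayPCImage:
        return PathwayPCImage(self.sample_ids[i], self.tensor[i], self.row_labels, self.col_labels)

    def __len__(self) -> int:
        return len(self.sample_ids)


def split_by_class(dataset: HarmonizedDataset) -> dict[str, dict[str, np.ndarray]]:
    """Per-class, per-omics sample blocks: class -> omics name -> matrix.

    For an n-class, t-omics problem this yields n*t matrices whose sample
    sets partition the cohort.
    """
    classes = dataset.class_labels
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes present")
    out: dict[str, dict[str, np.ndarray]] = {}
    sample_index = {s: i for i, s in enumerate(dataset.sample_ids)}
    for c in classes:
        members = [s for s in dataset.sample_ids if dataset.class_of(s) == c]
        if len(members) < 3:
            raise ValidationError(f"class {c} has {len(members)} samples; PCA needs >= 3")
        rows = [sample_index[s] for s in members]
        out[c] = {om.omics_name: om.values[rows] for om in dataset.omics}
    return out


def isolate_pathway_matrices(
    class_matrices: dict[str, dict[str, np.ndarray]],
    pathways: PathwayCollection,
    gene_ids: list[str],
):
    """Iterate (class, omics, pathway_id, gene columns, matrix) blocks.

    Pathway genes are intersected with the dataset's gene universe; a pathway
    with no overlapping genes is emitted with ``matrix=None`` (degenerate).
    Total non-degenerate count is n_classes * n_omics * n_pathways minus the
    flagged empties.
    """
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    pathway_cols = []
    for pid, genes in pathways.pathways:
        cols = [gene_index[g] for g in genes if g in gene_index]
        used = [g for g in genes if g in gene_index]
        pathway_cols.append((pid, cols, used))
    for c, per_omics in class_matrices.items():
        for omics_name, mat in per_omics.items():
            for pid, cols, used in pathway_cols:
                if not cols:
                    yield c, omics_name, pid, [], None
                else:
                    yield c, omics_name, pid, used, mat[:, cols]


def fit_class_pca(
    matrix: np.ndarray,
    gene_ids: list[str],
    n_pcs: int,
    class_label: str = "",
    omics_name: str = "",
    pathway_id: str = "",
    standardize: bool = True,
) -> PcaModel:
    """Fit PCA on one (class, omics, pathway) sample block.

    Constant-variance gene columns are dropped before the fit.  If the
    requested component count exceeds the feasible rank
    min(n_samples - 1, n_genes), the model stores the feasible count and
    projections are zero-padded.  Component signs are fixed so the
    largest-|loading| entry of each component is positive.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 1:
        raise ValidationError("PCA needs >= 2 samples and >= 1 gene")
    sd = matrix.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        logger.warning("all-constant matrix for (%s, %s, %s); degenerate",
                       class_label, omics_name, pathway_id)
        return PcaModel(class_label, omics_name, pathway_id, list(gene_ids),
                        np.zeros(len(gene_ids)), np.ones(len(gene_ids)),
                        np.zeros((len(gene_ids), 0)), np.zeros(0), n_pcs, degenerate=True)
    if not keep.all():
        logger.warning("dropping %d constant gene columns in (%s, %s, %s)",
                       int((~keep).sum()), class_label, omics_name, pathway_id)
    sub = matrix[:, keep]
    used_genes = [g for g, k in zip(gene_ids, keep) if k]
    mean = sub.mean(axis=0)
    scale = sub.std(axis=0, ddof=0) if standardize else np.ones(sub.shape[1])
    z = (sub - mean) / scale
    feasible = min(n_pcs, sub.shape[0] - 1, sub.shape[1])
    pca = PCA(n_components=feasible, svd_solver="full")
    pca.fit(z)
    loadings = pca.components_.T.copy()  # genes x comps
    # Deterministic sign: largest-|loading| entry of each component positive.
    for j in range(loadings.shape[1]):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
    return PcaModel(class_label, omics_name, pathway_id, used_genes,
                    mean, scale, loadings, pca.explained_variance_ratio_.copy(), n_pcs)


def project_sample(model: PcaModel, sample_values: np.ndarray) -> np.ndarray:
    """PC scores for one sample: loadings^T ((x - mu) / sigma), zero-padded."""
    return model.project(sample_values)


def fit_embedding_bank(
    dataset: HarmonizedDataset,
    pathways: PathwayCollection,
    n_pcs: int,
    sample_subset: list[str] | None = None,
    standardize: bool = True,
) -> PcaEmbeddingBank:
    """Fit all (class, omics, pathway) PCA models on a sample subset."""
    if sample_subset is None:
        sub = dataset
    else:
        keep = [s for s in dataset.sample_ids if s in set(sample_subset)]
        sub = HarmonizedDataset(
            [om.reindex(keep, om.gene_ids) for om in dataset.omics],
            type(dataset.labels)({s: dataset.labels.labels[s] for s in keep},
                                 dataset.labels.threshold_years),
        )
    class_matrices = split_by_class(sub)
    models: dict[tuple[str, str, str], PcaModel] = {}
    degenerate: list[tuple[str, str, str]] = []
    for c, omics_name, pid, used_genes, block in isolate_pathway_matrices(
        class_matrices, pathways, sub.gene_ids
    ):
        key = (c, omics_name, pid)
        if block is None:
            logger.warning("pathway %s has no genes in universe; degenerate", pid)
            models[key] = PcaModel(c, omics_name, pid, [], np.zeros(0), np.ones(0),
                                   np.zeros((0, 0)), np.zeros(0), n_pcs, degenerate=True)
            degenerate.append(key)
            continue
        m = fit_class_pca(block, used_genes, n_pcs, c, omics_name, pid, standardize)
        models[key] = m
        if m.degenerate:
            degenerate.append(key)
    return PcaEmbeddingBank(
        models=models,
        class_labels=sub.class_labels,
        omics_names=sub.omics_names,
        pathway_ids=pathways.pathway_ids,
        n_pcs=n_pcs,
        degenerate_keys=degenerate,
    )


def _gene_cols_cache(bank: PcaEmbeddingBank, dataset: HarmonizedDataset):
    gene_index = {g: i for i, g in enumerate(dataset.gene_ids)}
    cache = {}
    for key, m in bank.models.items():
        cache[key] = [gene_index[g] for g in m.gene_ids]
    return cache


def build_image(
    sample_id: str,
    dataset: HarmonizedDataset,
    bank: PcaEmbeddingBank,
    embed_class: str,
) -> PathwayPCImage:
    """Assemble one sample's image under a single embedding class."""
    if sample_id not in dataset.sample_ids:
        raise KeyError(f"unknown sample {sample_id!r}")
    i = dataset.sample_ids.index(sample_id)
    grid = np.zeros((len(bank.pathway_ids), len(bank.omics_names) * bank.n_pcs))
    col_labels: list[tuple[str, int]] = []
    for o, omics_name in enumerate(bank.omics_names):
        om = dataset.omics[dataset.omics_names.index(omics_name)]
        for pc in range(bank.n_pcs):
            col_labels.append((omics_name, pc + 1))
        for p, pid in enumerate(bank.pathway_ids):
            model = bank[(embed_class, omics_name, pid)]
            cols = [dataset.gene_ids.index(g) for g in model.gene_ids]
            scores = model.project(om.values[i, cols]) if cols else np.zeros(bank.n_pcs)
            grid[p, o * bank.n_pcs : (o + 1) * bank.n_pcs] = scores
    return PathwayPCImage(sample_id, grid, list(bank.pathway_ids), col_labels)


def _assemble(dataset, bank, embed_classes, col_cache):
    """Vectorized image assembly for all samples under the given class list.

    Columns are ordered embedding-class-major, then omics-major, then PC.
    """
    n = len(dataset.sample_ids)
    n_path = len(bank.pathway_ids)
    width = len(embed_classes) * len(bank.omics_names) * bank.n_pcs
    tensor = np.zeros((n, n_path, width))
    col_labels: list[tuple[str, int]] = []
    col = 0
    for c in embed_classes:
        for omics_name in bank.omics_names:
            om = dataset.omics[dataset.omics_names.index(omics_name)]
            for pc in range(bank.n_pcs):
                tag = omics_name if len(embed_classes) == 1 else f"{c}:{omics_name}"
                col_labels.append((tag, pc + 1))
            for p, pid in enumerate(bank.pathway_ids):
                key = (c, omics_name, pid)
                model = bank[key]
                cols = col_cache[key]
                if cols:
                    scores = model.project(om.values[:, cols])
                else:
                    scores = np.zeros((n, bank.n_pcs))
                tensor[:, p, col : col + bank.n_pcs] = scores
            col += bank.n_pcs
    return tensor, col_labels


def _align_bank(bank: PcaEmbeddingBank, reference: PcaEmbeddingBank) -> None:
    """Rotate each model's loadings to best match the reference bank's.

    PCA bases fitted on different sample subsets can disagree by component
    sign flips or PC swaps/rotations within the retained subspace.  When one
    bank embeds some samples and another bank embeds the rest, such
    disagreements scramble the shared column coordinates.  For each
    (class, omics, pathway) model this applies the orthogonal Procrustes
    rotation (computed on the genes common to both fits) that maps the
    model's component basis closest to the reference's, preserving
    orthonormality and the spanned subspace.  Modifies ``bank`` in place.
    """
    for key, m in bank.models.items():
        ref = reference.models.get(key)
        if ref is None or m.degenerate or ref.degenerate:
            continue
        if m.n_fitted == 0 or ref.n_fitted == 0:
            continue
        ref_row = {g: r for r, g in enumerate(ref.gene_ids)}
        common = [g for g in m.gene_ids if g in ref_row]
        if not common:
            continue
        rows_m = [m.gene_ids.index(g) for g in common]
        rows_r = [ref_row[g] for g in common]
        k = min(m.n_fitted, ref.n_fitted)
        cross = m.loadings[rows_m, :k].T @ ref.loadings[rows_r, :k]
        u, _, vt = np.linalg.svd(cross)
        m.loadings[:, :k] = m.loadings[:, :k] @ (u @ vt)


def build_image_stack(
    dataset: HarmonizedDataset,
    pathways: PathwayCollection,
    n_pcs: int = 2,
    mode: str = "paper-faithful",
    fold_train_samples: list[str] | None = None,
    standardize: bool = True,
    normalize: bool = True,
) -> tuple[ImageStack, PcaEmbeddingBank]:
    """Embed the whole cohort into an ImageStack.

    In ``paper-faithful`` mode the bank is fitted per class on all samples of
    that class and each sample is embedded with its own class's models
    (n_omics * n_pcs columns).  In ``fold-safe`` mode the bank is fitted on
    ``fold_train_samples`` only and every sample is embedded under both
    classes' models (columns doubled, labelled by embedding class).  After
    assembly each column is min-max scaled to [0, 1] using statistics from
    the fitting samples; out-of-range values are clipped.
    """
    if mode not in ("paper-faithful", "fold-safe"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "fold-safe" and fold_train_samples is None:
        raise ValueError("fold-safe mode requires fold_train_samples")
    fit_subset = list(fold_train_samples) if mode == "fold-safe" else None
    bank = fit_embedding_bank(dataset, pathways, n_pcs, fit_subset, standardize)
    col_cache = _gene_cols_cache(bank, dataset)

    if mode == "paper-faithful":
        # One pass per class's models; pick each sample's own-class columns.
        tensors = {}
        for c in bank.class_labels:
            tensors[c], col_labels = _assemble(dataset, bank, [c], col_cache)
        tensor = np.zeros_like(next(iter(tensors.values())))
        for i, s in enumerate(dataset.sample_ids):
            tensor[i] = tensors[dataset.class_of(s)][i]
        col_labels = [(om, pc) for om in bank.omics_names for pc in range(1, n_pcs + 1)]
        train_rows = np.arange(len(dataset.sample_ids))
    else:
        tensor, col_labels = _assemble(dataset, bank, bank.class_labels, col_cache)
        train_set = set(fold_train_samples)
        train_rows = np.array([i for i, s in enumerate(dataset.sample_ids) if s in train_set])
        # Cross-fit the training images: split the training fold per class
        # into two halves (by position parity, deterministic); embed each
        # half with a bank fitted on the other half.  Skipped when a half
        # would fall below the 3-sample PCA minimum.
        halves: tuple[list[str], list[str]] = ([], [])
        by_class: dict[str, list[str]] = {}
        for s in fold_train_samples:
            by_class.setdefault(dataset.class_of(s), []).append(s)
        for members in by_class.values():
            halves[0].extend(members[0::2])
            halves[1].extend(members[1::2])
        min_half = min(
            sum(1 for s in half if dataset.class_of(s) == c)
            for half in halves for c in by_class
        )
        if min_half >= 3:
            for emb_half, fit_half in ((0, 1), (1, 0)):
                half_bank = fit_embedding_bank(
                    dataset, pathways, n_pcs, halves[fit_half], standardize
                )
                # Rotate the half-fit bases onto the full-fold bank's so the
                # cross-fitted training columns share the test columns'
                # coordinates (otherwise subset-dependent sign flips / PC
                # swaps scramble them).
                _align_bank(half_bank, bank)
                half_cache = _gene_cols_cache(half_bank, dataset)
                half_tensor, _ = _assemble(dataset, half_bank, half_bank.class_labels,
                                           half_cache)
                rows = [i for i, s in enumerate(dataset.sample_ids)
                        if s in set(halves[emb_half])]
                tensor[rows] = half_tensor[rows]
        else:
            logger.warning(
                "training fold too small for cross-fit embedding; "
                "training images remain in-fit"
            )

    norm_min = norm_range = None
    if normalize:
        flat_train = tensor[train_rows]
        norm_min = flat_train.min(axis=0)
        norm_range = flat_train.max(axis=0) - norm_min
        norm_range = np.where(norm_range > 0, norm_range, 1.0)
        tensor = np.clip((tensor - norm_min) / norm_range, 0.0, 1.0)

    stack = ImageStack(
        sample_ids=list(dataset.sample_ids),
        tensor=tensor,
        row_labels=list(bank.pathway_ids),
        col_labels=col_labels,
        norm_min=norm_min,
        norm_range=norm_range,
    )
    return stack, bank
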