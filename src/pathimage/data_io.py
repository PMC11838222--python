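"""Reading, validation and harmonization of multi-omics inputs.

Handles three kinds of input: per-omics numeric matrices (samples x genes,
TSV/CSV), pathway gene sets (GMT), and a clinical table with overall-survival
time and vital status.  Samples are partitioned into long-term survivors
(LTS, survival beyond a threshold), non-long-term survivors (non-LTS, death
observed at or before the threshold) and excluded samples (censored at or
before the threshold, uninformative for the two-class problem).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LTS = "LTS"
NON_LTS = "non-LTS"
EXCLUDED = "excluded"


class ValidationError(ValueError):
    """Raised when an input violates a structural contract."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed, with location information."""


def _normalize_gene(g: str) -> str:
    return g.strip().upper()


@dataclass
class OmicsMatrix:
    """One omics layer: a samples x genes numeric matrix with identifiers.

    Units depend on the layer (copy-number ratio for CNV, expression for
    EXP, beta-value for MET); the container is unit-agnostic.
    """

    omics_name: str
    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError(f"{self.omics_name}: duplicate sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError(f"{self.omics_name}: duplicate gene ids")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValidationError(
                f"{self.omics_name}: shape {self.values.shape} != "
                f"({len(self.sample_ids)}, {len(self.gene_ids)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.omics_name}: non-finite values after imputation")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def reindex(self, sample_ids: list[str], gene_ids: list[str]) -> "OmicsMatrix":
        df = self.to_frame().loc[sample_ids, gene_ids]
        return OmicsMatrix(self.omics_name, list(sample_ids), list(gene_ids), df.to_numpy())

    def write_tsv(self, path) -> None:
        """Write samples-as-rows TSV with %.10g floats (round-trip precision)."""
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.10g")


@dataclass
class PathwayCollection:
    """Ordered pathway gene sets; order fixes the image row order."""

    pathways: list[tuple[str, list[str]]]
    exclusion_list: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p for p, _ in self.pathways]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate pathway ids")
        for pid, genes in self.pathways:
            if not genes:
                raise ValidationError(f"pathway {pid} has an empty gene list")

    @property
    def pathway_ids(self) -> list[str]:
        return [p for p, _ in self.pathways]

    def genes(self, pathway_id: str) -> list[str]:
        for pid, genes in self.pathways:
            if pid == pathway_id:
                return genes
        raise KeyError(pathway_id)

    def __len__(self) -> int:
        return len(self.pathways)

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for pid, genes in self.pathways:
                fh.write("\t".join([pid, "na", *genes]) + "\n")


@dataclass
class ClinicalTable:
    """Per-sample survival time (years) and event flag (1 = death observed)."""

    sample_ids: list[str]
    time_years: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time_years = np.asarray(self.time_years, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in clinical table")
        if np.any(self.time_years < 0):
            raise ValidationError("negative survival time")
        if not np.all(np.isin(self.event, [0, 1])):
            raise ValidationError("event flag must be 0 or 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_years": self.time_years, "event": self.event}, index=self.sample_ids
        )

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.10g")


@dataclass
class CohortLabels:
    """Three-way survival partition: sample id -> LTS / non-LTS / excluded."""

    labels: dict[str, str]
    threshold_years: float

    def samples_with_label(self, label: str) -> list[str]:
        return [s for s, lab in self.labels.items() if lab == label]

    @property
    def classified_samples(self) -> list[str]:
        return [s for s, lab in self.labels.items() if lab != EXCLUDED]

    def counts(self) -> dict[str, int]:
        out = {LTS: 0, NON_LTS: 0, EXCLUDED: 0}
        for lab in self.labels.values():
            out[lab] += 1
        return out


@dataclass
class HarmonizedDataset:
    """Omics layers aligned to one sample ordering and one gene universe."""

    omics: list[OmicsMatrix]
    labels: CohortLabels

    def __post_init__(self) -> None:
        ref = self.omics[0]
        for om in self.omics[1:]:
            if om.sample_ids != ref.sample_ids:
                raise ValidationError("omics layers have differing sample orderings")
            if om.gene_ids != ref.gene_ids:
                raise ValidationError("omics layers have differing gene sets")

    @property
    def sample_ids(self) -> list[str]:
        return self.omics[0].sample_ids

    @property
    def gene_ids(self) -> list[str]:
        return self.omics[0].gene_ids

    @property
    def omics_names(self) -> list[str]:
        return [om.omics_name for om in self.omics]

    def class_of(self, sample_id: str) -> str:
        return self.labels.labels[sample_id]

    @property
    def class_labels(self) -> list[str]:
        """Distinct non-excluded classes present, in canonical (LTS first) order."""
        present = {self.labels.labels[s] for s in self.sample_ids}
        order = [LTS, NON_LTS]
        return [c for c in order if c in present] + sorted(present - set(order))


def _detect_sep(path) -> str:
    with open(path) as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def _read_table(path) -> pd.DataFrame:
    """TSV/CSV with auto-detected delimiter, first column = row identifier.

    The header is parsed by hand so duplicate column names survive (pandas
    would mangle them to "name.1").
    """
    sep = _detect_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    df = pd.read_csv(path, sep=sep, header=None, skiprows=1, index_col=0, dtype=str)
    df.columns = header[1:]
    return df


def read_omics_matrix(
    path,
    omics_name: str,
    orientation: str = "samples-as-rows",
    max_missing_frac: float = 0.2,
) -> OmicsMatrix:
    """Read an omics matrix from TSV/CSV and clean it.

    ``orientation`` declares the file layout; the result is always samples x
    genes.  Duplicate gene columns are collapsed by mean.  Rows and columns
    with more than ``max_missing_frac`` missing entries are dropped, then
    remaining missing entries are imputed with the per-gene median.
    """
    if orientation not in ("samples-as-rows", "genes-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = _read_table(path)
    df = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    # Cells that are non-empty text but fail numeric conversion are parse errors.
    bad = df.isna() & raw.notna() & (raw.astype(str).apply(lambda c: c.str.strip()) != "")
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {raw.iat[i, j]!r} at row "
            f"{raw.index[i]!r}, column {raw.columns[j]!r}"
        )
    if orientation == "genes-as-rows":
        df = df.T
    df.columns = [_normalize_gene(g) for g in df.columns]
    df.index = [str(s).strip() for s in df.index]
    if df.columns.has_duplicates:
        n_dup = int(df.columns.duplicated().sum())
        logger.info("%s: collapsing %d duplicate gene columns by mean", omics_name, n_dup)
        df = df.T.groupby(level=0, sort=False).mean().T
    # Drop high-missingness genes first, then samples, then impute by
    # per-gene median.
    col_keep = df.isna().mean(axis=0) <= max_missing_frac
    if (~col_keep).any():
        logger.info("%s: dropping %d genes >%g%% missing", omics_name,
                    int((~col_keep).sum()), 100 * max_missing_frac)
    df = df.loc[:, col_keep]
    row_keep = df.isna().mean(axis=1) <= max_missing_frac
    if (~row_keep).any():
        logger.info("%s: dropping %d samples >%g%% missing", omics_name,
                    int((~row_keep).sum()), 100 * max_missing_frac)
    df = df.loc[row_keep]
    if df.empty:
        raise ValidationError(f"{path}: no samples/genes left after missingness filter")
    n_missing = int(df.isna().to_numpy().sum())
    if n_missing:
        logger.info("%s: imputing %d missing cells with per-gene median", omics_name, n_missing)
        df = df.fillna(df.median(axis=0))
    return OmicsMatrix(omics_name, list(df.index), list(df.columns), df.to_numpy())


def read_gene_sets(path, exclusions: list[str] | None = None) -> PathwayCollection:
    """Parse a GMT file (id, description, genes...) minus an exclusion list.

    Pathways keep file order; duplicate genes within a set are de-duplicated
    preserving first occurrence.
    """
    exclusions = list(exclusions or [])
    excl = set(exclusions)
    pathways: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            pid = fields[0].strip()
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                g = _normalize_gene(g)
                if g and g not in seen:
                    seen.add(g)
                    genes.append(g)
            if pid in excl:
                continue
            pathways.append((pid, genes))
    return PathwayCollection(pathways, exclusion_list=exclusions)


def read_clinical_table(path, time_unit: str = "years") -> ClinicalTable:
    """Read sample_id / time / event TSV; ``time_unit`` is 'years' or 'days'."""
    if time_unit not in ("years", "days"):
        raise ValueError(f"unknown time unit {time_unit!r}")
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    time_col = next((cols[c] for c in cols if "time" in c or "survival" in c), df.columns[0])
    event_col = next((cols[c] for c in cols if "event" in c or "status" in c), df.columns[1])
    t = pd.to_numeric(df[time_col], errors="raise").to_numpy(dtype=float)
    if time_unit == "days":
        t = t / 365.25
    e = pd.to_numeric(df[event_col], errors="raise").to_numpy(dtype=int)
    return ClinicalTable([str(s).strip() for s in df.index], t, e)


def assign_survival_labels(clinical: ClinicalTable, threshold_years: float = 2.0) -> CohortLabels:
    """Three-way LTS / non-LTS / excluded partition at a survival threshold.

    LTS: survival beyond the threshold (event or censored).  non-LTS: death
    observed at or before the threshold.  Excluded: censored at or before the
    threshold (class unknowable).
    """
    if threshold_years <= 0:
        raise ValueError("threshold must be positive")
    labels: dict[str, str] = {}
    for sid, t, e in zip(clinical.sample_ids, clinical.time_years, clinical.event):
        if t > threshold_years:
            labels[sid] = LTS
        elif e == 1:
            labels[sid] = NON_LTS
        else:
            labels[sid] = EXCLUDED
    out = CohortLabels(labels, threshold_years)
    counts = out.counts()
    logger.info("survival labels: %s", counts)
    if counts[LTS] + counts[NON_LTS] == 0:
        logger.warning("all samples excluded at threshold %g years", threshold_years)
    return out


def harmonize(omics: list[OmicsMatrix], labels: CohortLabels) -> HarmonizedDataset:
    """Restrict all layers to common samples/genes and non-excluded labels.

    Sample set = intersection of per-layer samples and labelled, non-excluded
    clinical samples; gene set = intersection across layers.  All matrices are
    re-indexed to identical sorted orderings.
    """
    if len(omics) < 2:
        raise ValidationError("harmonize requires at least 2 omics layers")
    sample_sets = [set(om.sample_ids) for om in omics]
    common_samples = set.intersection(*sample_sets) & set(labels.classified_samples)
    gene_sets = [set(om.gene_ids) for om in omics]
    common_genes = set.intersection(*gene_sets)
    if not common_samples or not common_genes:
        per_layer = ", ".join(
            f"{om.omics_name}: {len(s)} samples / {len(g)} genes"
            for om, s, g in zip(omics, sample_sets, gene_sets)
        )
        raise ValidationError(
            f"empty intersection after harmonization ({per_layer}; "
            f"{len(labels.classified_samples)} labelled samples)"
        )
    sample_order = sorted(common_samples)
    gene_order = sorted(common_genes)
    aligned = [om.reindex(sample_order, gene_order) for om in omics]
    kept_labels = CohortLabels(
        {s: labels.labels[s] for s in sample_order}, labels.threshold_years
    )
    logger.info(
        "harmonized: %d common samples, %d common genes across %d layers",
        len(sample_order), len(gene_order), len(omics),
    )
    return HarmonizedDataset(aligned, kept_labels)
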