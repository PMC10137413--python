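"""Core expression containers and per-tissue summaries.

The central object is :class:`ExpressionMatrix`: a genes × samples table of
TPM (transcripts per million) values together with per-sample metadata
(species and tissue labels).  From it the pipeline derives per-tissue
*median profiles* — the working representation of a tissue's expression
state — and everything downstream (tissue-specific gene calling,
housekeeping classification, cross-species comparison) operates on either
the matrix or the profile.

Conventions used throughout the package:

* "expressed" means per-tissue median TPM strictly greater than the
  ``expressed_tpm`` cutoff (default 0.1); the boundary value is excluded.
* log transformation is ``log2(TPM + pseudocount)`` with pseudocount 0.25.
* cross-species sample-level comparisons are performed on quantile-
  normalized log values of one-to-one orthologs (see
  :func:`normalize_cross_species`), a deterministic substitute for
  anchor-based batch integration.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Thresholds",
    "ExpressionMatrix",
    "TissueProfile",
    "CorrelationStructure",
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
    "median_profile",
    "median_profiles",
    "split_by_species",
    "count_expressed",
    "log_transform",
    "quantile_normalize",
    "normalize_cross_species",
    "correlation_structure",
]

#: A per-tissue median-TPM profile: genes in rows, tissues in columns.
TissueProfile = pd.DataFrame

REQUIRED_METADATA_COLUMNS = ("species", "tissue")


@dataclasses.dataclass(frozen=True)
class Thresholds:
    """Analysis cutoffs, collected in one place.

    Attributes
    ----------
    expressed_tpm
        Expression-presence cutoff on per-tissue median TPM (strict ``>``).
    log_pseudocount
        Additive constant before log2.
    tsg_log2fc
        Minimum one-vs-rest log2 fold change for a tissue-specific gene.
    deg_log2fc
        Minimum between-species log2 fold change for a cross-species DEG.
    fdr
        Benjamini–Hochberg significance level for TSG/DEG calls.
    phkg_tpm
        Per-tissue median TPM that a preliminary housekeeping gene must
        exceed in every tissue.
    hkg_level_low_max, hkg_level_medium_max
        Upper bounds (inclusive) of the low and medium expression-level
        tiers for housekeeping genes.
    divergence_fraction
        Fraction of orthologs taken as most divergent / most conserved.
    """

    expressed_tpm: float = 0.1
    log_pseudocount: float = 0.25
    tsg_log2fc: float = 1.5
    deg_log2fc: float = 1.2
    fdr: float = 0.05
    phkg_tpm: float = 1.0
    hkg_level_low_max: float = 10.0
    hkg_level_medium_max: float = 50.0
    divergence_fraction: float = 0.10

    def __post_init__(self) -> None:
        for name in (
            "expressed_tpm",
            "log_pseudocount",
            "tsg_log2fc",
            "deg_log2fc",
            "fdr",
            "phkg_tpm",
            "hkg_level_low_max",
            "hkg_level_medium_max",
            "divergence_fraction",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"threshold {name!r} must be strictly positive")
        if not 0 < self.divergence_fraction <= 0.5:
            raise ValueError("divergence_fraction must lie in (0, 0.5]")
        if self.hkg_level_low_max >= self.hkg_level_medium_max:
            raise ValueError("hkg_level_low_max must be below hkg_level_medium_max")


@dataclasses.dataclass
class ExpressionMatrix:
    """Genes × samples TPM values plus per-sample species/tissue labels.

    ``values`` is a DataFrame indexed by gene id with sample ids as
    columns; ``metadata`` is indexed by sample id with ``species`` and
    ``tissue`` columns.  On construction the metadata is validated against
    the matrix and reordered to the matrix's column order; metadata rows
    for samples absent from the matrix are dropped, whereas samples
    missing from the metadata are an error.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        arr = v.to_numpy()
        if np.isnan(arr).any():
            raise ValueError("missing values in expression matrix")
        if (arr < 0).any():
            raise ValueError("negative TPM values in expression matrix")
        meta = self.metadata
        for col in REQUIRED_METADATA_COLUMNS:
            if col not in meta.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        if meta.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        missing = v.columns.difference(meta.index)
        if len(missing):
            raise ValueError(
                f"samples missing from metadata: {sorted(missing)[:5]}"
            )
        if meta[list(REQUIRED_METADATA_COLUMNS)].isna().any().any():
            raise ValueError("missing species or tissue labels in metadata")
        # keep only samples present in the matrix, in matrix column order
        self.metadata = meta.loc[v.columns]

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def species_labels(self) -> list[str]:
        return sorted(self.metadata["species"].unique())

    @property
    def tissue_labels(self) -> list[str]:
        return sorted(self.metadata["tissue"].unique())

    def samples_of(self, tissue: str) -> list[str]:
        """Sample ids belonging to one tissue (all species)."""
        mask = self.metadata["tissue"] == tissue
        return list(self.metadata.index[mask])

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        """Restrict (and reorder) to the given genes; values untouched."""
        idx = pd.Index(gene_ids)
        missing = idx.difference(self.values.index)
        if len(missing):
            raise KeyError(f"genes absent from matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.values.loc[idx], self.metadata.copy())


# -- I/O ----------------------------------------------------------------------

def read_matrix(matrix_path, metadata_path) -> ExpressionMatrix:
    """Read a TPM matrix TSV (first column gene id) plus a metadata TSV.

    Gzip compression is inferred from the file suffix.  The metadata file
    must contain ``sample_id``, ``species`` and ``tissue`` columns.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    meta = read_metadata(metadata_path)
    return ExpressionMatrix(values, meta)


def read_metadata(metadata_path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValueError("metadata must have a 'sample_id' column")
    return meta.set_index("sample_id")


def write_matrix(em: ExpressionMatrix, path) -> None:
    out = em.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_metadata(em: ExpressionMatrix, path) -> None:
    out = em.metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# -- per-tissue summaries -----------------------------------------------------

def split_by_species(em: ExpressionMatrix) -> dict[str, ExpressionMatrix]:
    """Partition the samples of a mixed matrix into one matrix per species."""
    out = {}
    for sp in em.species_labels:
        cols = em.metadata.index[em.metadata["species"] == sp]
        out[sp] = ExpressionMatrix(em.values[list(cols)], em.metadata.loc[cols])
    return out


def median_profile(em: ExpressionMatrix) -> TissueProfile:
    """Per-tissue median TPM: entry (g, t) is the median over samples of t.

    Samples of all species present in ``em`` are pooled; split with
    :func:`split_by_species` first for per-species profiles.  The median
    of an even sample count is the midpoint of the two central order
    statistics.  Tissue columns are sorted lexicographically.
    """
    if em.values.shape[1] == 0:
        raise ValueError("matrix has no samples")
    cols = {}
    for tissue in em.tissue_labels:
        samples = em.samples_of(tissue)
        if not samples:
            raise ValueError(f"tissue {tissue!r} has no samples")
        cols[tissue] = em.values[samples].median(axis=1)
    return pd.DataFrame(cols)


def median_profiles(em: ExpressionMatrix) -> dict[str, TissueProfile]:
    """One median profile per species label found in the metadata."""
    return {sp: median_profile(m) for sp, m in split_by_species(em).items()}


def count_expressed(profile: TissueProfile, thr: Thresholds | None = None) -> pd.Series:
    """Number of expressed genes (median TPM strictly above the cutoff) per tissue."""
    thr = thr or Thresholds()
    return (profile > thr.expressed_tpm).sum(axis=0)


def log_transform(values, thr: Thresholds | None = None):
    """Elementwise ``log2(x + pseudocount)``; raises on negative input."""
    thr = thr or Thresholds()
    arr = values.to_numpy() if hasattr(values, "to_numpy") else np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("log_transform requires non-negative input")
    out = np.log2(arr + thr.log_pseudocount)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index)
    return out


# -- cross-species normalization ----------------------------------------------

def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean empirical distribution.

    Classical quantile normalization: the reference is the across-column
    mean of the sorted values; each entry is replaced by the reference
    value at its within-column rank, with tied ranks (``method='average'``)
    interpolated linearly between adjacent reference values.
    """
    arr = df.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    ranks = df.rank(axis=0, method="average").to_numpy()  # 1..n, ties averaged
    grid = np.arange(1, arr.shape[0] + 1, dtype=float)
    out = np.interp(ranks, grid, ref)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def normalize_cross_species(
    em_a: ExpressionMatrix,
    em_b: ExpressionMatrix,
    thr: Thresholds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-transform two ortholog-aligned matrices and quantile-normalize
    all sample columns of both species jointly.

    Returns the two log-scale normalized value tables (same row order as
    the inputs).  Input matrices must already be restricted to one-to-one
    orthologs and share row order (see ``orthology.align_one_to_one``).
    """
    thr = thr or Thresholds()
    if em_a.values.shape[0] != em_b.values.shape[0]:
        raise ValueError("matrices must be ortholog-aligned (equal gene counts)")
    la = log_transform(em_a.values, thr)
    lb = log_transform(em_b.values, thr)
    lb_stacked = lb.copy()
    lb_stacked.index = la.index  # align paired ortholog rows positionally
    combined = pd.concat([la, lb_stacked], axis=1)
    qn = quantile_normalize(combined)
    out_a = qn[la.columns]
    out_b = qn[lb.columns].copy()
    out_b.index = lb.index
    return out_a, out_b


# -- correlation structure ----------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CorrelationStructure:
    """Tissue × tissue correlation matrix across two species plus the
    summary comparison motivating it: mean same-tissue *cross-species*
    correlation versus mean different-tissue *within-species* correlation.

    ``matrix`` has a two-level (species, tissue) index on both axes.
    """

    matrix: pd.DataFrame
    same_tissue_cross_species: float
    cross_tissue_within_species: float


def correlation_structure(
    profile_a: TissueProfile,
    profile_b: TissueProfile,
    thr: Thresholds | None = None,
    method: str = "pearson",
    labels: tuple[str, str] = ("species_a", "species_b"),
) -> CorrelationStructure:
    """Correlate log-transformed median profiles within and across species.

    Profiles must share (ortholog-aligned) gene order.  A tissue column
    with zero variance after log transformation is an error.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if profile_a.shape[0] != profile_b.shape[0]:
        raise ValueError("profiles must be ortholog-aligned (equal gene counts)")
    thr = thr or Thresholds()
    la = log_transform(profile_a, thr)
    lb = log_transform(profile_b, thr)
    lb.index = la.index
    combined = pd.concat({labels[0]: la, labels[1]: lb}, axis=1)
    std = combined.std(axis=0, ddof=0)
    if (std == 0).any():
        bad = list(combined.columns[std == 0])[:5]
        raise ValueError(f"zero-variance tissue column(s): {bad}")
    corr = combined.corr(method=method)

    shared = sorted(set(profile_a.columns) & set(profile_b.columns))
    same_cross = [corr.loc[(labels[0], t), (labels[1], t)] for t in shared]
    within = []
    for lab, prof in ((labels[0], profile_a), (labels[1], profile_b)):
        tissues = list(prof.columns)
        for i, t1 in enumerate(tissues):
            for t2 in tissues[i + 1 :]:
                within.append(corr.loc[(lab, t1), (lab, t2)])
    return CorrelationStructure(
        matrix=corr,
        same_tissue_cross_species=float(np.mean(same_cross)) if same_cross else float("nan"),
        cross_tissue_within_species=float(np.mean(within)) if within else float("nan"),
    )
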