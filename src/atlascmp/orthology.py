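"""Orthology table handling and homology-category accounting.

The orthology table is an *input* produced upstream (e.g. by an
orthogroup-inference tool); this module consumes it.  Genes fall into four
homology categories: ``one2one`` (a unique ortholog pair), ``complex``
(one-to-many / many-to-one / many-to-many), ``none`` (no homolog) and
``nonprotein``.  Cross-species quantitative comparisons are restricted to
one-to-one pairs; the other categories exist for the per-tissue accounting
of expressed-gene counts and expression mass.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, Thresholds, TissueProfile, log_transform

__all__ = [
    "CATEGORIES",
    "OrthologyMap",
    "read_orthology",
    "align_one_to_one",
    "category_accounting",
]

CATEGORIES = ("one2one", "complex", "none", "nonprotein")


@dataclasses.dataclass
class OrthologyMap:
    """Records of (gene_a, gene_b, category); empty string for an absent partner.

    Invariant: a gene labelled ``one2one`` appears in exactly one record
    and its partner is present.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        rec = self.records
        for col in ("gene_a", "gene_b", "category"):
            if col not in rec.columns:
                raise ValueError(f"orthology records lack column {col!r}")
        bad = set(rec["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown homology categories: {sorted(bad)}")
        rec = rec.fillna({"gene_a": "", "gene_b": ""})
        one = rec[rec["category"] == "one2one"]
        if ((one["gene_a"] == "") | (one["gene_b"] == "")).any():
            raise ValueError("one2one records must name both partners")
        for col in ("gene_a", "gene_b"):
            genes = one[col]
            if genes.duplicated().any():
                raise ValueError(f"a one2one gene appears in multiple records ({col})")
            multi = rec.loc[rec["category"] != "one2one", col]
            clash = set(genes) & set(multi) - {""}
            if clash:
                raise ValueError(
                    f"gene(s) labelled one2one also appear in other records: {sorted(clash)[:5]}"
                )
        self.records = rec.reset_index(drop=True)

    def one_to_one_pairs(self) -> pd.DataFrame:
        """The (gene_a, gene_b) pairs of the one2one category, in record order."""
        one = self.records[self.records["category"] == "one2one"]
        return one[["gene_a", "gene_b"]].reset_index(drop=True)

    def category_of(self, species: str) -> pd.Series:
        """gene id → category for one species (``'a'`` or ``'b'``).

        Genes occurring in several complex records keep a single,
        consistent category label.
        """
        col = {"a": "gene_a", "b": "gene_b"}[species]
        rec = self.records[self.records[col] != ""]
        out = rec.drop_duplicates(subset=col).set_index(col)["category"]
        out.index.name = "gene_id"
        return out


def read_orthology(path) -> OrthologyMap:
    """Read an orthology TSV.

    Two dialects are accepted: the three-column form
    (``gene_a  gene_b  category``) and a headerless-category "pairs only"
    two-column form in which every listed pair is taken as one2one.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "category" not in df.columns:
        if df.shape[1] != 2:
            raise ValueError("pairs-only orthology dialect must have exactly two columns")
        df.columns = ["gene_a", "gene_b"]
        df["category"] = "one2one"
    return OrthologyMap(df)


def align_one_to_one(
    em_a: ExpressionMatrix,
    em_b: ExpressionMatrix,
    omap: OrthologyMap,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to one-to-one ortholog pairs, rows ordered
    identically by pair.  Values are copied untouched (no re-scaling).

    Raises if the map has no one-to-one pairs or a mapped gene is missing
    from either matrix.  Idempotent: aligning aligned matrices returns
    them unchanged.
    """
    pairs = omap.one_to_one_pairs()
    if pairs.empty:
        raise ValueError("orthology map contains no one-to-one pairs")
    pairs = pairs[
        pairs["gene_a"].isin(em_a.values.index) | pairs["gene_b"].isin(em_b.values.index)
    ]
    missing_a = set(pairs["gene_a"]) - set(em_a.values.index)
    missing_b = set(pairs["gene_b"]) - set(em_b.values.index)
    if missing_a or missing_b:
        raise KeyError(
            "one2one genes missing from matrix: "
            f"{sorted(missing_a)[:3]} / {sorted(missing_b)[:3]}"
        )
    if pairs.empty:
        raise ValueError("no one-to-one pair is present in the matrices")
    return em_a.subset_genes(pairs["gene_a"]), em_b.subset_genes(pairs["gene_b"])


class CategoryAccounting(NamedTuple):
    """Per-tissue homology-category proportions (tissues × categories)."""

    expressed_proportion: pd.DataFrame
    expression_mass_proportion: pd.DataFrame


def category_accounting(
    profile: TissueProfile,
    omap: OrthologyMap,
    species: str,
    thr: Thresholds | None = None,
) -> CategoryAccounting:
    """Homology-category share of expressed genes and of expression mass.

    For each tissue, among genes with median TPM above the presence cutoff:
    the fraction of expressed genes per category, and the fraction of
    summed log2(TPM + pseudocount) per category.  Expression mass is summed
    over expressed genes only, which keeps every summand above
    log2(cutoff + pseudocount).  Both proportion sets sum to 1 per tissue.

    A tissue with no expressed genes yields NaN proportions and a warning.
    Every profiled gene must be categorized.
    """
    thr = thr or Thresholds()
    cat = omap.category_of(species)
    uncategorized = profile.index.difference(cat.index)
    if len(uncategorized):
        raise KeyError(f"uncategorized gene(s): {sorted(uncategorized)[:5]}")
    gene_cat = cat.loc[profile.index]

    counts = pd.DataFrame(index=profile.columns, columns=list(CATEGORIES), dtype=float)
    mass = counts.copy()
    for tissue in profile.columns:
        col = profile[tissue]
        expressed = col > thr.expressed_tpm
        n_expr = int(expressed.sum())
        if n_expr == 0:
            warnings.warn(f"tissue {tissue!r} has no expressed genes; proportions undefined")
            continue
        sub_cat = gene_cat[expressed]
        counts.loc[tissue] = (
            sub_cat.value_counts().reindex(CATEGORIES).fillna(0.0) / n_expr
        )
        logs = pd.Series(
            log_transform(col[expressed], thr), index=col.index[expressed]
        )
        total = logs.sum()
        mass.loc[tissue] = (
            logs.groupby(sub_cat).sum().reindex(CATEGORIES).fillna(0.0) / total
        )
    counts.index.name = mass.index.name = "tissue"
    return CategoryAccounting(counts, mass)
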