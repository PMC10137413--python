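"""Housekeeping-gene identification and cross-species consistency.

Preliminary housekeeping genes (pHKGs) are genes whose per-tissue median
TPM exceeds 1 in every tissue.  Their expression stability is measured by
the coefficient of variation (CV = sd / mean, n−1 denominator) of the
per-tissue medians, and pHKGs are tiered by the quartiles of the CV
distribution: low (CV ≤ Q1), medium (Q1 < CV < Q3), high (CV ≥ Q3).
Low-variability pHKGs are the housekeeping genes proper and are further
tiered by mean expression: low (1 < TPM ≤ 10), medium (10 < TPM ≤ 50),
high (TPM > 50).  Cross-species conservation is summarized by 3×3 tier
contingency tables and their diagonal fractions.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import Thresholds, TissueProfile

__all__ = [
    "VARIABILITY_TIERS",
    "LEVEL_TIERS",
    "call_phkg",
    "compute_cv",
    "cv_series",
    "classify_variability",
    "classify_level",
    "hkg_records",
    "consistency_table",
]

VARIABILITY_TIERS = ("low", "medium", "high")
LEVEL_TIERS = ("low", "medium", "high")


def call_phkg(
    profile: TissueProfile, thr: Thresholds | None = None, rule: str = "median_all"
) -> set[str]:
    """Preliminary housekeeping genes.

    ``rule='median_all'`` (default): per-tissue median TPM strictly above
    ``phkg_tpm`` in *every* tissue.  ``rule='mean'``: mean of the
    per-tissue medians above the threshold (a laxer, mean-based variant).
    """
    thr = thr or Thresholds()
    if profile.shape[1] < 2:
        raise ValueError("pHKG calling needs at least two tissues")
    if rule == "median_all":
        mask = (profile > thr.phkg_tpm).all(axis=1)
    elif rule == "mean":
        mask = profile.mean(axis=1) > thr.phkg_tpm
    else:
        raise ValueError("rule must be 'median_all' or 'mean'")
    return set(profile.index[mask])


def compute_cv(values) -> float:
    """Coefficient of variation of one gene's per-tissue medians:
    sample standard deviation (n−1) divided by the mean.  Scale-invariant;
    requires a positive mean."""
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(arr.std(ddof=1) / mean)


def cv_series(profile: TissueProfile) -> pd.Series:
    """Per-gene CV over tissue columns (vectorized :func:`compute_cv`)."""
    mean = profile.mean(axis=1)
    if (mean <= 0).any():
        raise ValueError("CV undefined for non-positive mean")
    return profile.std(axis=1, ddof=1) / mean


def classify_variability(cvs: pd.Series) -> pd.Series:
    """Tier pHKGs by CV quartiles (linear-interpolation quantiles).

    low iff CV ≤ Q1, high iff CV ≥ Q3, medium otherwise.  When the CV
    distribution is degenerate (Q1 = Q3) every gene satisfies both bounds;
    the low tier takes precedence (documented, deterministic) and a
    warning is issued.
    """
    if len(cvs) < 4:
        raise ValueError("quartile tiering needs at least four genes")
    q1, q3 = np.quantile(cvs.to_numpy(dtype=float), [0.25, 0.75])
    if q1 == q3:
        warnings.warn("degenerate CV distribution (Q1 = Q3); all genes tiered low")
    tier = np.where(cvs <= q1, "low", np.where(cvs >= q3, "high", "medium"))
    return pd.Series(tier, index=cvs.index, name="variability_tier")


def classify_level(mean_tpm: float, thr: Thresholds | None = None) -> str:
    """Expression-level tier of a housekeeping gene from its mean TPM:
    low (1 < TPM ≤ 10), medium (10 < TPM ≤ 50), high (TPM > 50)."""
    thr = thr or Thresholds()
    if mean_tpm <= thr.phkg_tpm:
        raise ValueError("expression level tiers require mean TPM above the pHKG cutoff")
    if mean_tpm <= thr.hkg_level_low_max:
        return "low"
    if mean_tpm <= thr.hkg_level_medium_max:
        return "medium"
    return "high"


def hkg_records(
    profile: TissueProfile,
    genes=None,
    thr: Thresholds | None = None,
) -> pd.DataFrame:
    """Per-gene housekeeping record table for one species.

    Restricted to ``genes`` when given (typically the cross-species shared
    pHKG set — quartiles are then taken over exactly that set).  Columns:
    ``mean_tpm`` (mean of per-tissue medians), ``cv``, ``variability_tier``
    and, for low-variability genes only, ``level_tier``.
    """
    thr = thr or Thresholds()
    if genes is not None:
        idx = pd.Index(sorted(genes))
        missing = idx.difference(profile.index)
        if len(missing):
            raise KeyError(f"genes absent from profile: {sorted(missing)[:5]}")
        profile = profile.loc[idx]
    rec = pd.DataFrame(
        {
            "mean_tpm": profile.mean(axis=1),
            "cv": cv_series(profile),
        }
    )
    rec["variability_tier"] = classify_variability(rec["cv"])
    low = rec["variability_tier"] == "low"
    rec["level_tier"] = pd.NA
    rec.loc[low, "level_tier"] = [
        classify_level(v, thr) for v in rec.loc[low, "mean_tpm"]
    ]
    rec.index.name = "gene_id"
    return rec


class ConsistencyTable(NamedTuple):
    """Cross-species tier contingency: counts (species A rows × species B
    columns) and the diagonal (consistent) fraction."""

    counts: pd.DataFrame
    consistent_fraction: float


def consistency_table(
    tiers_a: pd.Series, tiers_b: pd.Series, categories=VARIABILITY_TIERS
) -> ConsistencyTable:
    """Tier agreement between two species on a shared gene set.

    Both series must be keyed on exactly the same genes.  Returns the
    k × k contingency table (ordered by ``categories``) and the fraction
    of genes on the diagonal.
    """
    if set(tiers_a.index) != set(tiers_b.index):
        raise ValueError("tier series must cover the same shared gene set")
    tiers_b = tiers_b.loc[tiers_a.index]
    counts = pd.crosstab(tiers_a, tiers_b)
    counts = counts.reindex(index=categories, columns=categories, fill_value=0)
    counts.index.name = "species_a"
    counts.columns.name = "species_b"
    total = counts.to_numpy().sum()
    diag = np.trace(counts.to_numpy())
    return ConsistencyTable(counts, float(diag / total))
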