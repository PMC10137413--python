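"""Moderated-t differential expression with empirical-Bayes variance shrinkage.

The statistic is the classical two-group moderated t: per-gene pooled
residual variances s²_g (df = nA + nB − 2) are shrunk toward a prior
estimated across genes by borrowing strength, and the t-statistic uses the
posterior variance

    s̃²_g = (d0·s0² + df·s²_g) / (d0 + df),      t_g = Δ_g / sqrt(s̃²_g (1/nA + 1/nB)),

referred to a Student-t distribution with df + d0 degrees of freedom.  The
prior (d0, s0²) is estimated by the method of moments on z = log s²: under
the scaled-inverse-chi-square hierarchy, Var(z) = ψ′(df/2) + ψ′(d0/2), so

    ψ′(d0/2) = Var(z) − ψ′(df/2)

is inverted with Newton's method (d0 = ∞ when the right side is ≤ 0, i.e.
the observed variances are no more dispersed than sampling alone implies),
and s0² follows from E(z).  Two-sided p-values are Benjamini–Hochberg
adjusted within each contrast.

Log2 fold change is the difference of group means of log2(TPM + 0.25);
both tissue-specific gene calling (one tissue versus the rest, within a
species) and cross-species per-tissue DEG calling (species A vs species B
on quantile-normalized log values) are thin drivers over the same engine.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import (
    ExpressionMatrix,
    Thresholds,
    log_transform,
    normalize_cross_species,
    split_by_species,
)

__all__ = [
    "EBPrior",
    "DEResult",
    "eb_shrink",
    "moderated_ttest",
    "bh_fdr",
    "call_tsg",
    "call_species_deg",
    "species_deg",
    "rank_divergence",
    "tsg_sets",
]


@dataclasses.dataclass(frozen=True)
class EBPrior:
    """Empirical-Bayes variance prior: d0 prior degrees of freedom (may be
    0 for "no shrinkage" or ``inf`` for complete pooling) and s0² prior
    variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior degrees of freedom must be >= 0")
        if self.d0 > 0 and not self.s0_sq > 0:
            raise ValueError("prior variance must be positive when d0 > 0")


@dataclasses.dataclass
class DEResult:
    """One contrast's per-gene table plus the variance prior used.

    ``table`` columns: ``log2fc``, ``t``, ``df_total``, ``p``, ``fdr`` and,
    for the calling drivers, a boolean call column (``tsg`` or ``deg`` with
    ``up``/``down``).
    """

    table: pd.DataFrame
    prior: EBPrior

    def called(self, column: str) -> set[str]:
        return set(self.table.index[self.table[column]])


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration, tol 1e-8)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires a positive target")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = float(special.polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += step
        if abs(step) < 1e-8 * x:
            break
    return x


def eb_shrink(s_sq, df) -> tuple[EBPrior, np.ndarray]:
    """Estimate the variance prior and return posterior variances.

    Parameters
    ----------
    s_sq
        Per-gene residual variances (length ≥ 2, non-negative).
    df
        Residual degrees of freedom of each variance (scalar, ≥ 1).

    Zero variances are excluded from moment estimation (their log is
    undefined) but still receive a posterior; all variances zero is
    degenerate and raises.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    if s_sq.ndim != 1 or s_sq.size < 2:
        raise ValueError("eb_shrink needs a 1-d array of at least two variances")
    if (s_sq < 0).any():
        raise ValueError("variances must be non-negative")
    if df < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    pos = s_sq > 0
    if not pos.any():
        raise ValueError("all residual variances are zero; nothing to moderate")

    z = np.log(s_sq[pos])
    mean_z = float(z.mean())
    var_z = float(z.var(ddof=1)) if z.size > 1 else 0.0
    half_df = df / 2.0
    target = var_z - float(special.polygamma(1, half_df))
    bias_df = float(special.digamma(half_df)) - math.log(half_df)
    if target <= 0:
        d0 = math.inf
        s0_sq = math.exp(mean_z - bias_df)
    else:
        x = _trigamma_inverse(target)
        d0 = 2.0 * x
        bias_d0 = float(special.digamma(x)) - math.log(x)
        s0_sq = math.exp(mean_z - bias_df + bias_d0)
    prior = EBPrior(d0, s0_sq)
    return prior, posterior_variance(prior, s_sq, df)


def posterior_variance(prior: EBPrior, s_sq, df) -> np.ndarray:
    """Shrink per-gene variances toward the prior; d0 = 0 returns them
    unchanged and d0 = ∞ returns s0² for every gene."""
    s_sq = np.asarray(s_sq, dtype=float)
    if prior.d0 == 0:
        return s_sq.copy()
    if math.isinf(prior.d0):
        return np.full_like(s_sq, prior.s0_sq)
    return (prior.d0 * prior.s0_sq + df * s_sq) / (prior.d0 + df)


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j ≥ i} p_(j) · m / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = q_sorted
    return out


def moderated_ttest(
    group_a,
    group_b,
    prior: EBPrior | None = None,
    gene_ids=None,
) -> DEResult:
    """Two-group moderated t-test across genes (rows).

    ``group_a`` / ``group_b`` are genes × samples arrays (or DataFrames
    with identical row index) of log2-scale expression, each with at least
    two samples.  ``log2fc`` is mean(A) − mean(B).  When ``prior`` is None
    the prior is estimated with :func:`eb_shrink`; pass
    ``EBPrior(0, 1)`` to force the ordinary pooled t-test.

    A single gene, or all-zero residual variances, cannot support prior
    estimation; the ordinary t is used with the documented zero-variance
    convention (p = 0 when log2fc ≠ 0, p = 1 when log2fc = 0).
    """
    if isinstance(group_a, pd.DataFrame) and isinstance(group_b, pd.DataFrame):
        if not group_a.index.equals(group_b.index):
            raise ValueError("group DataFrames must share their gene index")
        if gene_ids is None:
            gene_ids = group_a.index
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise ValueError("groups must cover the same genes")
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least two samples")

    lfc = a.mean(axis=1) - b.mean(axis=1)
    df = n_a + n_b - 2
    s_sq = ((n_a - 1) * a.var(axis=1, ddof=1) + (n_b - 1) * b.var(axis=1, ddof=1)) / df

    if prior is None:
        if a.shape[0] < 2 or not (s_sq > 0).any():
            prior = EBPrior(0.0, 1.0)
            post = s_sq.copy()
        else:
            prior, post = eb_shrink(s_sq, df)
    else:
        post = posterior_variance(prior, s_sq, df)

    df_total = df + prior.d0
    se = np.sqrt(post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), np.sign(lfc) * np.inf)
    t = np.where((se == 0) & (lfc == 0), 0.0, t)
    p = np.empty_like(lfc)
    finite = np.isfinite(t)
    p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), df_total)
    p[~finite] = 0.0  # zero variance, non-zero fold change
    p = np.minimum(p, 1.0)

    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "t": t,
            "df_total": df_total,
            "p": p,
            "fdr": bh_fdr(p),
        },
        index=pd.Index(gene_ids, name="gene_id") if gene_ids is not None else None,
    )
    return DEResult(table, prior)


# -- calling drivers ----------------------------------------------------------

def call_tsg(
    em: ExpressionMatrix, thr: Thresholds | None = None
) -> dict[str, DEResult]:
    """One-vs-rest tissue-specific gene calling within one species.

    For every tissue with at least two samples (and at least two samples
    in the rest), a moderated t-test of that tissue's samples against all
    remaining samples on log2(TPM + pseudocount) values.  A gene is a TSG
    for the tissue iff log2fc > ``tsg_log2fc`` (over-expression in the
    focal tissue) and fdr < ``fdr``; the boolean lands in column ``tsg``.
    Tissues that cannot be tested are skipped with a warning.
    """
    thr = thr or Thresholds()
    tissues = em.tissue_labels
    if len(tissues) < 2:
        raise ValueError("tissue-specific calling needs at least two tissues")
    logv = log_transform(em.values, thr)
    results: dict[str, DEResult] = {}
    for tissue in tissues:
        focal = em.samples_of(tissue)
        rest = [s for s in em.sample_ids if s not in set(focal)]
        if len(focal) < 2 or len(rest) < 2:
            warnings.warn(f"tissue {tissue!r} has fewer than two samples; skipped")
            continue
        res = moderated_ttest(logv[focal], logv[rest], gene_ids=em.gene_ids)
        res.table["tsg"] = (res.table["log2fc"] > thr.tsg_log2fc) & (
            res.table["fdr"] < thr.fdr
        )
        results[tissue] = res
    return results


def tsg_sets(results: Mapping[str, DEResult]) -> dict[str, set[str]]:
    """tissue → set of called tissue-specific genes."""
    return {t: r.called("tsg") for t, r in results.items()}


def species_deg(
    em_a: ExpressionMatrix,
    em_b: ExpressionMatrix,
    thr: Thresholds | None = None,
    tissues=None,
) -> dict[str, DEResult]:
    """Per-tissue species-A-vs-species-B moderated t-tests.

    Matrices must be one-to-one ortholog aligned; they are log-transformed
    and quantile-normalized jointly across all samples of both species
    before testing.  ``log2fc`` > 0 means higher in species A.  Gene ids in
    the result tables are species-A ids.  Columns ``deg`` (significant:
    |log2fc| > ``deg_log2fc`` and fdr < ``fdr``), ``up`` (species A) and
    ``down`` (species B) are added.
    """
    thr = thr or Thresholds()
    qa, qb = normalize_cross_species(em_a, em_b, thr)
    # aligned rows are positionally paired orthologs; report species-A ids
    qb = pd.DataFrame(qb.to_numpy(), index=qa.index, columns=qb.columns)
    tissues_a = set(em_a.tissue_labels)
    tissues_b = set(em_b.tissue_labels)
    if tissues is None:
        tissues = sorted(tissues_a & tissues_b)
    results: dict[str, DEResult] = {}
    for tissue in tissues:
        if tissue not in tissues_a or tissue not in tissues_b:
            raise ValueError(f"tissue {tissue!r} absent in one species")
        sa = em_a.samples_of(tissue)
        sb = em_b.samples_of(tissue)
        if len(sa) < 2 or len(sb) < 2:
            raise ValueError(f"tissue {tissue!r} has fewer than two samples in a species")
        res = moderated_ttest(qa[sa], qb[sb], gene_ids=em_a.gene_ids)
        sig = (res.table["log2fc"].abs() > thr.deg_log2fc) & (res.table["fdr"] < thr.fdr)
        res.table["deg"] = sig
        res.table["up"] = sig & (res.table["log2fc"] > 0)
        res.table["down"] = sig & (res.table["log2fc"] < 0)
        results[tissue] = res
    return results


def call_species_deg(
    em_a: ExpressionMatrix,
    em_b: ExpressionMatrix,
    tissue: str,
    thr: Thresholds | None = None,
) -> DEResult:
    """Single-tissue convenience wrapper over :func:`species_deg`."""
    return species_deg(em_a, em_b, thr, tissues=[tissue])[tissue]


def rank_divergence(
    results: Mapping[str, DEResult], thr: Thresholds | None = None
) -> dict[str, tuple[set[str], set[str]]]:
    """Most divergent / most conserved genes per tissue.

    Genes are ranked by −log10(p) descending; the top ⌈fraction·m⌉ are the
    divergent set and the bottom ⌈fraction·m⌉ the conserved set.  Ties are
    broken by |log2fc| (larger first) and then lexicographic gene id, so
    the ranking is deterministic.
    """
    thr = thr or Thresholds()
    out: dict[str, tuple[set[str], set[str]]] = {}
    for tissue, res in results.items():
        tab = res.table
        with np.errstate(divide="ignore"):
            neglogp = -np.log10(tab["p"].to_numpy())
        ranking = pd.DataFrame(
            {
                "gene_id": tab.index.to_numpy(),
                "neglogp": neglogp,
                "abs_lfc": tab["log2fc"].abs().to_numpy(),
            }
        ).sort_values(
            by=["neglogp", "abs_lfc", "gene_id"],
            ascending=[False, False, True],
            kind="mergesort",
        )
        order = ranking["gene_id"].to_numpy()
        k = math.ceil(thr.divergence_fraction * len(order))
        out[tissue] = (set(order[:k]), set(order[-k:]) if k else set())
    return out
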