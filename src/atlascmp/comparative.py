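"""Cross-species conservation statistics.

Summaries that compare the two species' results: Spearman correlation of
per-tissue counts, hypergeometric overlap of tissue-specific gene sets,
decile shared-expression windows (conservation across the expression
range), overlap of tissue-specific genes with divergent/conserved gene
sets, and a generic over-representation test against user-supplied
annotation sets.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import Thresholds, TissueProfile
from .de import bh_fdr

__all__ = [
    "OverlapTest",
    "spearman_counts",
    "hypergeom_overlap",
    "batch_overlap_bh",
    "tsg_overlap_tests",
    "decile_shared",
    "tsg_divergence_overlap",
    "overrepresentation",
]


@dataclasses.dataclass
class OverlapTest:
    """Upper-tail hypergeometric overlap test.

    Drawing ``draw_size`` genes from a universe of ``universe_size`` of
    which ``set_a_size`` are marked, ``p`` is P(X ≥ overlap).  ``fdr`` is
    filled by batch adjustment across a family of tests.
    """

    universe_size: int
    set_a_size: int
    draw_size: int
    overlap: int
    p: float
    fdr: float = math.nan


def spearman_counts(counts_a, counts_b, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman rank correlation of two per-tissue count vectors.

    Inputs are mappings/Series keyed by tissue (keys must match) or plain
    sequences of equal length.  Ties receive average ranks.  For n ≤
    ``exact_max_n`` the two-sided p-value is computed from the exact
    permutation distribution of the rank correlation; for larger n the
    usual t-approximation (via :func:`scipy.stats.spearmanr`) is used.
    """
    if isinstance(counts_a, Mapping):
        counts_a = pd.Series(counts_a)
    if isinstance(counts_b, Mapping):
        counts_b = pd.Series(counts_b)
    if isinstance(counts_a, pd.Series) and isinstance(counts_b, pd.Series):
        if set(counts_a.index) != set(counts_b.index):
            raise ValueError("count vectors must share tissue keys")
        counts_b = counts_b.loc[counts_a.index]
    x = np.asarray(counts_a, dtype=float)
    y = np.asarray(counts_b, dtype=float)
    if x.size != y.size:
        raise ValueError("count vectors must have equal length")
    if x.size < 3:
        raise ValueError("Spearman correlation needs at least three tissues")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant count vector; correlation undefined")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= exact_max_n:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value P(|rho| ≥ |rho_obs|).

    Enumerates all n! pairings of the two rank vectors in chunks; average
    ranks (ties) are handled because the statistic is the Pearson
    correlation of the rank vectors.
    """
    n = rx.size
    rxc = rx - rx.mean()
    sx = math.sqrt(float(rxc @ rxc))
    ryc = ry - ry.mean()
    sy = math.sqrt(float(ryc @ ryc))
    if sx == 0 or sy == 0:
        raise ValueError("constant rank vector; correlation undefined")
    threshold = abs(rho_obs) - 1e-12
    total = math.factorial(n)
    count = 0
    chunk_size = 40000
    perms = itertools.permutations(ryc)
    while True:
        chunk = np.array(list(itertools.islice(perms, chunk_size)))
        if chunk.size == 0:
            break
        rhos = (chunk @ rxc) / (sx * sy)
        count += int((np.abs(rhos) >= threshold).sum())
    return count / total


def hypergeom_overlap(set_a: Iterable, set_b: Iterable, universe: Iterable) -> OverlapTest:
    """Exact upper-tail overlap probability of two gene sets.

    With N = |universe|, K = |A|, n = |B| and k = |A ∩ B|, returns
    P(X ≥ k) for X hypergeometric(N, K, n).  Both sets must be contained
    in the universe.
    """
    universe = set(universe)
    set_a = set(set_a)
    set_b = set(set_b)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be contained in the universe")
    n_univ, k_a, n_b = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    p = float(stats.hypergeom.sf(k - 1, n_univ, k_a, n_b))
    return OverlapTest(n_univ, k_a, n_b, k, min(p, 1.0))


def batch_overlap_bh(tests: Iterable[OverlapTest]) -> list[OverlapTest]:
    """Fill the ``fdr`` fields of a family of overlap tests by BH adjustment."""
    tests = list(tests)
    if tests:
        fdrs = bh_fdr([t.p for t in tests])
        for t, q in zip(tests, fdrs):
            t.fdr = float(q)
    return tests


def tsg_overlap_tests(
    tsg_a: Mapping[str, set],
    tsg_b: Mapping[str, set],
    universe: Iterable,
) -> pd.DataFrame:
    """Same-tissue TSG overlap between species, BH-adjusted across tissues.

    Both TSG set mappings must already live in a common gene namespace
    (one species' ids mapped through the one-to-one orthology) and be
    restricted to the given universe.
    """
    tissues = sorted(set(tsg_a) & set(tsg_b))
    tests = [hypergeom_overlap(tsg_a[t], tsg_b[t], universe) for t in tissues]
    batch_overlap_bh(tests)
    return pd.DataFrame(
        {
            "tissue": tissues,
            "universe_size": [t.universe_size for t in tests],
            "set_a_size": [t.set_a_size for t in tests],
            "set_b_size": [t.draw_size for t in tests],
            "overlap": [t.overlap for t in tests],
            "p": [t.p for t in tests],
            "fdr": [t.fdr for t in tests],
        }
    ).set_index("tissue")


def _expression_windows(col: pd.Series, n_windows: int) -> list[set]:
    """Rank genes by expression (descending, ties by gene id) and split
    into ``n_windows`` contiguous windows; remainder genes go to the
    highest-expression windows."""
    ranking = pd.DataFrame(
        {"gene_id": col.index.to_numpy(), "value": col.to_numpy()}
    ).sort_values(by=["value", "gene_id"], ascending=[False, True], kind="mergesort")
    genes = ranking["gene_id"].to_numpy()
    base, extra = divmod(len(genes), n_windows)
    sizes = [base + 1 if i < extra else base for i in range(n_windows)]
    bounds = np.cumsum([0] + sizes)
    return [set(genes[bounds[i] : bounds[i + 1]]) for i in range(n_windows)]


def decile_shared(
    profile_a: TissueProfile,
    profile_b: TissueProfile,
    tissue: str,
    n_windows: int = 10,
) -> pd.Series:
    """Cross-species shared fraction of expression-ranked windows.

    Genes are ranked by median expression in the given tissue within each
    species (profiles must be ortholog-aligned: equal length, row i of A
    paired with row i of B) and split into ``n_windows`` equal windows;
    window i's shared fraction is |window_i(A) ∩ window_i(B)| / size_i,
    computed on species-A identifiers.
    """
    if profile_a.shape[0] != profile_b.shape[0]:
        raise ValueError("profiles must be ortholog-aligned (equal gene counts)")
    if profile_a.shape[0] < n_windows:
        raise ValueError("fewer genes than windows")
    col_a = profile_a[tissue]
    col_b = profile_b[tissue]
    col_b = pd.Series(col_b.to_numpy(), index=profile_a.index)  # pair rows positionally
    wins_a = _expression_windows(col_a, n_windows)
    wins_b = _expression_windows(col_b, n_windows)
    fractions = [
        len(a & b) / len(a) if a else math.nan for a, b in zip(wins_a, wins_b)
    ]
    return pd.Series(
        fractions, index=pd.RangeIndex(1, n_windows + 1, name="window"), name=tissue
    )


def tsg_divergence_overlap(
    tsg: Mapping[str, set],
    divergent: Mapping[str, set],
    conserved: Mapping[str, set],
) -> pd.DataFrame:
    """Per-tissue fraction of TSGs falling in the divergent / conserved sets.

    Tissues with an empty TSG set get NaN fractions.  All sets must live
    in the one-to-one ortholog namespace of one species.
    """
    rows = {}
    for tissue in sorted(tsg):
        genes = tsg[tissue]
        if not genes:
            rows[tissue] = (math.nan, math.nan)
            continue
        div = divergent.get(tissue, set())
        con = conserved.get(tissue, set())
        rows[tissue] = (
            len(genes & div) / len(genes),
            len(genes & con) / len(genes),
        )
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["frac_divergent", "frac_conserved"]
    )
    out.index.name = "tissue"
    return out


def overrepresentation(
    genes: Iterable,
    annotation: Mapping[str, Iterable],
    universe: Iterable,
) -> pd.DataFrame:
    """Generic over-representation analysis of a query gene set.

    One upper-tail hypergeometric test per annotation term (term sets and
    the query must be subsets of the universe), BH adjustment across
    terms, sorted by p then term name.  The annotation source (GO, KEGG,
    custom modules, ...) is entirely up to the caller.
    """
    annotation = {term: set(members) for term, members in annotation.items()}
    if not annotation:
        raise ValueError("empty annotation")
    genes = set(genes)
    terms = sorted(annotation)
    tests = [hypergeom_overlap(annotation[t], genes, universe) for t in terms]
    batch_overlap_bh(tests)
    out = pd.DataFrame(
        {
            "term": terms,
            "term_size": [t.set_a_size for t in tests],
            "query_size": [t.draw_size for t in tests],
            "overlap": [t.overlap for t in tests],
            "p": [t.p for t in tests],
            "fdr": [t.fdr for t in tests],
        }
    ).set_index("term")
    return out.sort_values(by=["p", "term"], kind="mergesort")
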