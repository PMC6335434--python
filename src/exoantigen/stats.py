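"""Statistical primitives: set-overlap tests, rank tests, FDR, clustering.

The overlap of two gene lists drawn from a common genome is scored with the
inclusive upper-tail hypergeometric probability P(X >= k) together with the
representation factor k*N/(K*n) (observed/expected overlap). The genome
universe defaults to 17,611 genes and is overridable everywhere. Tail sums
are accumulated in log space so p-values around 1e-11 keep full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as ss
from scipy.spatial.distance import squareform
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import DataError

DEFAULT_UNIVERSE = 17611


@dataclass(frozen=True)
class OverlapResult:
    """Upper-tail hypergeometric overlap between two sets in a universe of N."""

    k: int                     # observed overlap
    set1_size: int             # K
    set2_size: int             # n
    universe: int              # N
    p_upper: float             # P(X >= k), inclusive
    representation_factor: float  # k*N/(K*n)


@dataclass(frozen=True)
class RankTestResult:
    """Mann-Whitney U with its AUC equivalent ``U / (n1 * n2)``."""

    u_statistic: float
    auc: float
    p_value: float
    method: str                # "exact" | "asymptotic"
    n1: int
    n2: int


@dataclass(frozen=True)
class Dendrogram:
    """Complete-linkage merge history on 1 - Pearson correlation distances."""

    linkage: np.ndarray        # scipy linkage matrix (n-1, 4)
    labels: tuple
    leaf_order: tuple          # labels in dendrogram leaf order

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def hypergeometric_overlap(
    k: int, set1_size: int, set2_size: int, universe: int = DEFAULT_UNIVERSE
) -> OverlapResult:
    """Inclusive upper-tail overlap probability P(X >= k) and representation factor.

    X counts members of a size-``set1_size`` list in a random draw of
    ``set2_size`` genes from a universe of ``universe``; the tail is summed
    from the log-pmf so values far below machine epsilon remain exact.
    """
    k, K, n, N = int(k), int(set1_size), int(set2_size), int(universe)
    if min(k, K, n) < 0 or N < 1:
        raise DataError("overlap inputs must be non-negative with a positive universe")
    if K > N or n > N:
        raise DataError(f"set sizes ({K}, {n}) cannot exceed the universe ({N})")
    if k > min(K, n):
        raise DataError(f"overlap {k} exceeds the smaller set size {min(K, n)}")
    k_max = min(K, n)
    if k == 0:
        p_upper = 1.0
    else:
        support = np.arange(k, k_max + 1)
        p_upper = float(np.exp(logsumexp(ss.hypergeom.logpmf(support, N, K, n))))
        p_upper = min(p_upper, 1.0)
    rf = k * N / (K * n) if K and n else float("nan")
    return OverlapResult(k=k, set1_size=K, set2_size=n, universe=N,
                         p_upper=p_upper, representation_factor=rf)


def fisher_exact(table, alternative: str = "two-sided"):
    """Fisher's exact test on a 2x2 table of non-negative integers.

    The two-sided p-value sums, conditional on the margins, every table whose
    point probability does not exceed the observed one. Returns
    ``(odds_ratio, p_value)``.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise DataError("fisher_exact requires a 2x2 table")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer) and not np.allclose(arr, np.round(arr)):
        raise DataError("table entries must be non-negative integers")
    arr = arr.astype(int)
    if arr.sum() == 0:
        raise DataError("all-zero contingency table")
    res = ss.fisher_exact(arr, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(group1, group2, alternative: str = "two-sided") -> RankTestResult:
    """Mann-Whitney U via midranks; exact p for small tie-free samples.

    The exact null distribution is enumerated when both groups have at most
    eight observations and no ties span the groups; otherwise the normal
    approximation with tie correction (no continuity correction) is used.
    The AUC equals U/(n1*n2): the probability that a random group-1 value
    exceeds a random group-2 value, counting ties as one half.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = ss.rankdata(combined)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    auc = u1 / (n1 * n2)
    has_ties = np.unique(combined).size < combined.size
    if n1 <= 8 and n2 <= 8 and not has_ties:
        method = "exact"
        res = ss.mannwhitneyu(x, y, alternative=alternative, method="exact")
        p = float(res.pvalue)
    else:
        method = "asymptotic"
        res = ss.mannwhitneyu(
            x, y, alternative=alternative, method="asymptotic", use_continuity=False
        )
        p = float(res.pvalue)
        if np.isnan(p):  # all observations identical: no evidence either way
            p = 1.0
    return RankTestResult(u_statistic=float(u1), auc=float(auc), p_value=min(p, 1.0),
                          method=method, n1=n1, n2=n2)


def t_test_unpaired(group1, group2, alternative: str = "two-sided",
                    equal_var: bool = False) -> float:
    """Unpaired t-test p-value, Welch form by default.

    When both groups are constant the test is degenerate: equal means give
    p = 1 by convention, unequal means p = 0 (for "two-sided"; a one-sided
    alternative resolves by the direction of the difference).
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DataError("each group needs at least two values")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        diff = x.mean() - y.mean()
        if diff == 0:
            return 1.0
        if alternative == "two-sided":
            return 0.0
        favored = diff > 0 if alternative == "greater" else diff < 0
        return 0.0 if favored else 1.0
    res = ss.ttest_ind(x, y, equal_var=equal_var, alternative=alternative)
    return float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlation_cluster(matrix: pd.DataFrame) -> Dendrogram:
    """Complete-linkage hierarchical clustering of rows on 1 - Pearson r.

    Rows with zero variance have no defined correlation and are rejected by
    name. Ties in merge order are broken deterministically by input order
    (scipy's behavior on a fixed condensed distance matrix).
    """
    if matrix.shape[0] < 2:
        raise DataError("clustering needs at least two rows")
    values = matrix.to_numpy(dtype=float)
    variances = values.var(axis=1)
    constant = [str(matrix.index[i]) for i in np.flatnonzero(variances == 0)]
    if constant:
        raise DataError(f"constant row(s) have undefined correlation: {constant}")
    corr = np.corrcoef(values)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)  # symmetrize roundoff
    linkage = sch.linkage(squareform(dist, checks=False), method="complete")
    leaves = sch.leaves_list(linkage)
    labels = tuple(matrix.index)
    return Dendrogram(linkage=linkage, labels=labels,
                      leaf_order=tuple(labels[i] for i in leaves))


def annotation_set_enrichment(
    query: Sequence[str],
    annotation_sets: Mapping[str, Sequence[str]],
    universe: int = DEFAULT_UNIVERSE,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``query`` against each annotation term.

    One upper-tail overlap test per term, BH-adjusted across terms. Returns a
    frame sorted by p with columns ``term, overlap, term_size, query_size,
    universe, p, fdr, representation_factor``.
    """
    query_set = set(query)
    if not query_set:
        raise DataError("query set is empty")
    if not annotation_sets:
        raise DataError("no annotation sets provided")
    rows = []
    for term, members in annotation_sets.items():
        members = set(members)
        res = hypergeometric_overlap(
            len(query_set & members), len(members), len(query_set), universe
        )
        rows.append({
            "term": term,
            "overlap": res.k,
            "term_size": res.set1_size,
            "query_size": res.set2_size,
            "universe": res.universe,
            "p": res.p_upper,
            "representation_factor": res.representation_factor,
        })
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
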