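"""Statistical core shared by every analysis stage.

Two-sided Wilcoxon rank-sum comparisons, Benjamini-Hochberg FDR over an
explicitly declared family size, Pearson correlation, and single-sample
gene-set enrichment (ssGSEA) for signature scoring (e.g. Wnt transcriptional
targets across tumor samples).

Family sizes for FDR are always passed explicitly: several comparisons are
members of families larger than the set of tests actually computed (e.g. a
contrast tested within a declared family of marker combinations), and
inferring ``m`` from the number of supplied p-values would silently change
the correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "ComparisonResult",
    "EnrichmentResult",
    "wilcoxon_rank_sum",
    "bh_fdr",
    "pearson",
    "ssgsea",
    "group_contrast",
]

# total-sample-size cutoff below which the exact Wilcoxon null distribution
# is enumerated (ties force the normal approximation regardless)
EXACT_WILCOXON_MAX_N = 12


@dataclass
class ComparisonResult:
    """A two-group comparison: statistic, two-sided p, BH q, sizes, effect."""

    statistic: float
    p: float
    n_a: int
    n_b: int
    median_difference: float
    q: float | None = None
    family: str | None = None
    family_size: int | None = None
    reason_missing: str | None = None

    @property
    def missing(self) -> bool:
        return self.reason_missing is not None


@dataclass
class EnrichmentResult:
    """Per-sample enrichment of one gene set."""

    gene_set: str
    n_genes_used: int
    es: "pd.Series" = field(repr=False)
    nes: "pd.Series" = field(repr=False)


def wilcoxon_rank_sum(
    a,
    b,
    exact_max_n: int = EXACT_WILCOXON_MAX_N,
) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when ``len(a)+len(b) <= exact_max_n``
    and the data have no ties; otherwise the normal approximation with
    mid-rank tie correction and continuity correction.

    Parameters
    ----------
    a, b : array-like
        The two samples. Both must be nonempty.

    Returns
    -------
    ComparisonResult
        With the Mann-Whitney U statistic for `a`, the two-sided p-value,
        and median(a) - median(b) as the effect direction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("wilcoxon_rank_sum requires both samples nonempty")

    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = scipy.stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return ComparisonResult(
        statistic=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
        n_a=int(a.size),
        n_b=int(b.size),
        median_difference=float(np.median(a) - np.median(b)),
    )


def bh_fdr(pvals, family_size: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values over a declared family.

    ``q_(i) = min_{j >= i} ( m * p_(j) / j )`` capped at 1, mapped back to
    the input order. ``family_size`` may exceed ``len(pvals)`` when the
    declared testing family is larger than the set of tests computed here;
    the untested members are treated as unobserved (they contribute only
    through ``m``).

    Parameters
    ----------
    pvals : array-like
        p-values in [0, 1].
    family_size : int, optional
        Declared family size ``m``; defaults to ``len(pvals)``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = int(family_size) if family_size is not None else p.size
    if m < p.size:
        raise ValueError(
            f"declared family size {m} smaller than the {p.size} p-values supplied"
        )
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value.

    p is from the t transform with n-2 degrees of freedom. Requires n >= 3
    and nonzero variance in both inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def ssgsea(
    expression: pd.DataFrame,
    gene_set,
    alpha: float = 0.25,
    gene_set_name: str = "gene_set",
) -> EnrichmentResult:
    """Single-sample gene-set enrichment (running-sum) scores.

    Per sample, genes are ranked by expression in descending order (rank
    ties broken lexicographically by gene name for determinism). The
    enrichment score is the sum over all rank positions of the difference
    between the weighted in-set empirical CDF (weights ``rank^alpha``, rank
    counted from the bottom so the top gene carries weight ``N^alpha``) and
    the unweighted out-of-set ECDF. NES rescales ES by the range
    (max - min) of ES across samples; with a single sample NES is NaN.

    Because only ranks enter, scores are invariant under any strictly
    monotone transform of a sample's expression values.

    Parameters
    ----------
    expression : DataFrame
        Genes as rows (index), samples as columns.
    gene_set : iterable of str
        Gene names; intersected with the matrix index.
    alpha : float
        Rank-weight exponent (0.25 by default).
    """
    if expression.shape[0] < 2:
        raise ValueError("expression matrix must contain at least 2 genes")
    if expression.index.duplicated().any():
        raise ValueError("expression matrix has duplicated gene names")
    genes = expression.index
    members = sorted(set(gene_set) & set(genes))
    if not members:
        missing = sorted(set(gene_set))[:10]
        raise ValueError(
            f"no gene-set member found in the expression matrix (looked for {missing} ...)"
        )
    in_set = np.asarray(genes.isin(members))
    n_genes = len(genes)
    n_in = in_set.sum()
    if n_in == n_genes:
        raise ValueError("gene set covers every gene in the matrix; ES undefined")
    es = {}
    # deterministic tie-break: secondary sort key is the gene name
    name_order = np.argsort(genes.to_numpy().astype(str), kind="stable")
    for sample in expression.columns:
        vals = expression[sample].to_numpy(dtype=float)[name_order]
        order = name_order[np.argsort(-vals, kind="stable")]
        ranked_in = in_set[order]
        # weight of the gene at position i (0 = most expressed) is (N - i)^alpha
        weights = (n_genes - np.arange(n_genes)) ** alpha
        w_in = np.where(ranked_in, weights, 0.0)
        cdf_in = np.cumsum(w_in) / w_in.sum()
        cdf_out = np.cumsum(~ranked_in) / (n_genes - n_in)
        es[sample] = float(np.sum(cdf_in - cdf_out))
    es = pd.Series(es, name="ES")
    spread = es.max() - es.min()
    if len(es) > 1 and spread > 0:
        nes = es / spread
    else:
        nes = pd.Series(np.nan, index=es.index)
    nes.name = "NES"
    return EnrichmentResult(
        gene_set=gene_set_name, n_genes_used=int(n_in), es=es, nes=nes
    )


def group_contrast(
    values,
    groups,
    positive_group,
    family: str | None = None,
    family_size: int | None = None,
) -> ComparisonResult:
    """Two-group contrast of per-patient values with BH correction.

    Missing values (NaN) are dropped. ``positive_group`` defines the 'a'
    side, so the reported ``median_difference`` is
    median(positive) - median(other).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    a = values[groups == positive_group]
    b = values[groups != positive_group]
    if a.size == 0 or b.size == 0:
        return ComparisonResult(
            statistic=np.nan, p=np.nan, n_a=int(a.size), n_b=int(b.size),
            median_difference=np.nan, family=family, family_size=family_size,
            reason_missing="one group empty after dropping missing values",
        )
    res = wilcoxon_rank_sum(a, b)
    res.family = family
    res.family_size = family_size
    if family_size is not None:
        res.q = float(bh_fdr([res.p], family_size=family_size)[0])
    return res


def attach_bh(results: list[ComparisonResult], family: str, family_size: int | None = None):
    """Assign BH q-values jointly across a list of comparisons (in place)."""
    present = [r for r in results if not r.missing]
    if not present:
        return results
    m = family_size if family_size is not None else len(present)
    qs = bh_fdr([r.p for r in present], family_size=m)
    for r, q in zip(present, qs):
        r.q = float(q)
        r.family = family
        r.family_size = m
    return results
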