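"""Cross-dataset and cross-condition concordance of fold differences.

Compares two differential-expression tables over their shared genes: the
product-moment correlation of log2 fold differences, the overlap of genes
exceeding a fold-difference threshold in both datasets in the same direction,
and hypergeometric fold enrichment of annotation sets within such overlap
lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, pearsonr

from sexde.exceptions import ParameterError


@dataclass
class FDComparison:
    n: int
    r: float
    p: float
    n_excluded: int  # genes missing from either table


@dataclass
class FoldEnrichmentResult:
    overlap: int
    fold: float
    p: float  # hypergeometric upper tail


def correlate_fd(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    subset: Callable[[pd.DataFrame], pd.Index] | Iterable[str] | None = None,
) -> FDComparison:
    """Product-moment correlation of log2FD between two DE tables.

    ``subset`` restricts the comparison (a callable applied to table A, or an
    explicit gene list); genes absent from either table are excluded and
    counted.  The p-value uses the t transform with n-2 degrees of freedom.
    """
    if callable(subset):
        genes = pd.Index(subset(table_a))
    elif subset is not None:
        genes = pd.Index(list(subset))
    else:
        genes = table_a.index
    shared = genes.intersection(table_a.index).intersection(table_b.index)
    n_excluded = len(genes) - len(shared)
    if len(shared) < 3:
        raise ParameterError(f"only {len(shared)} shared genes; need >=3")
    x = table_a.loc[shared, "log2FD"].to_numpy()
    y = table_b.loc[shared, "log2FD"].to_numpy()
    res = pearsonr(x, y)
    return FDComparison(n=len(shared), r=float(res.statistic), p=float(res.pvalue),
                        n_excluded=n_excluded)


def correlate_expression_level(table_a: pd.DataFrame, table_b: pd.DataFrame) -> FDComparison:
    """Correlation of per-gene mean log2 expression between two datasets."""
    shared = table_a.index.intersection(table_b.index)
    if len(shared) < 3:
        raise ParameterError(f"only {len(shared)} shared genes; need >=3")
    res = pearsonr(table_a.loc[shared, "mean_expr"], table_b.loc[shared, "mean_expr"])
    return FDComparison(n=len(shared), r=float(res.statistic), p=float(res.pvalue), n_excluded=0)


def replication_overlap(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    fd_threshold: float = 1.2,
    direction: str = "male-higher",
) -> list[str]:
    """Genes beyond the fold-difference threshold in BOTH tables.

    For the male direction: FD >= threshold in both; female: FD <= 1/threshold
    in both.  Returns gene IDs sorted lexicographically.
    """
    if fd_threshold <= 1:
        raise ParameterError("fd_threshold must exceed 1")
    if direction not in ("male-higher", "female-higher"):
        raise ParameterError("direction must be 'male-higher' or 'female-higher'")
    shared = table_a.index.intersection(table_b.index)
    fa = np.exp2(table_a.loc[shared, "log2FD"].to_numpy())
    fb = np.exp2(table_b.loc[shared, "log2FD"].to_numpy())
    if direction == "male-higher":
        keep = (fa >= fd_threshold) & (fb >= fd_threshold)
    else:
        keep = (fa <= 1 / fd_threshold) & (fb <= 1 / fd_threshold)
    return sorted(shared[keep])


def fold_enrichment_in_list(
    gene_list: Sequence[str],
    set_genes: Iterable[str],
    background: Sequence[str],
) -> FoldEnrichmentResult:
    """Fold enrichment of an annotation set within a gene list.

    ``fold = (overlap/|list|) / (|set & background| / |background|)``; the
    p-value is the hypergeometric upper tail of drawing at least ``overlap``
    set members in ``|list|`` draws from the background.
    """
    if not gene_list:
        raise ParameterError("gene list is empty")
    bg = set(background)
    lst = [g for g in dict.fromkeys(gene_list)]
    if not set(lst) <= bg:
        raise ParameterError("gene list must be a subset of the background")
    S = set(set_genes) & bg
    if not S:
        raise ParameterError("set is disjoint from the background")
    overlap = len(S & set(lst))
    fold = (overlap / len(lst)) / (len(S) / len(bg))
    p = float(hypergeom.sf(overlap - 1, len(bg), len(S), len(lst)))
    return FoldEnrichmentResult(overlap=overlap, fold=float(fold), p=p)


def concordance_report(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    collection=None,
    fd_threshold: float = 1.2,
    de_tier: float = 0.05,
) -> pd.DataFrame:
    """Tidy summary of all concordance statistics for two DE tables.

    Correlates log2FD over genes called sex-DE in dataset A at ``de_tier``,
    correlates expression levels over all shared genes, computes the
    two-dataset male-higher/female-higher overlaps, and, if a gene-set
    collection is given, fold enrichment of each set within the male overlap
    (background: genes tested in both datasets).
    """
    rows = []
    tier_col = f"de_{de_tier:g}"
    if tier_col in table_a.columns:
        de_in_a = table_a.index[table_a[tier_col] != ""]
    else:
        fa = np.exp2(table_a["log2FD"])
        de_in_a = table_a.index[
            ((fa >= fd_threshold) | (fa <= 1 / fd_threshold)) & (table_a["p"] <= de_tier)
        ]
    try:
        fd_cmp = correlate_fd(table_a, table_b, subset=de_in_a)
        rows.append({"statistic": "log2fd_correlation_sexde", "n": fd_cmp.n,
                     "value": fd_cmp.r, "p": fd_cmp.p})
    except ParameterError:
        pass
    expr_cmp = correlate_expression_level(table_a, table_b)
    rows.append({"statistic": "expression_level_correlation", "n": expr_cmp.n,
                 "value": expr_cmp.r, "p": expr_cmp.p})
    shared = table_a.index.intersection(table_b.index)
    for direction in ("male-higher", "female-higher"):
        olap = replication_overlap(table_a, table_b, fd_threshold, direction)
        rows.append({"statistic": f"overlap_{direction}", "n": len(shared),
                     "value": float(len(olap)), "p": np.nan})
        if collection is not None and direction == "male-higher" and olap:
            for name in collection.set_names:
                try:
                    fe = fold_enrichment_in_list(olap, collection.genes_of(name), list(shared))
                except ParameterError:
                    continue
                rows.append({"statistic": f"fold_enrichment_{name}", "n": fe.overlap,
                             "value": fe.fold, "p": fe.p})
    return pd.DataFrame(rows, columns=["statistic", "n", "value", "p"])
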