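"""Dual gene-set over-representation framework against matched backgrounds.

Two complementary tests per gene set:

* **Thresholded Fisher**: a two-sided Fisher's exact test of the overlap
  between the set and the sex-DE genes (male-DE and female-DE separately, at
  each p tier), within the set's background universe; Bonferroni adjustment
  over ``2 * n_sets`` tests per tier.
* **Threshold-free binomial shift**: every background gene with a nonzero
  log2 fold difference is classed male-higher or female-higher; a two-sided
  exact binomial test asks whether the set's male-higher proportion departs
  from the background proportion; Bonferroni adjustment over ``n_sets``.

Backgrounds are category-specific: expression-dependent categories
(protein-coding, source-publication universes) are intersected with the
expressed genes, while the genome-wide one-to-one orthologue universe is used
as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist, binom, hypergeom

from sexde.exceptions import ParameterError
from sexde.io import GeneSetCollection, SOURCE_PUBLICATION_PREFIX

#: relative tolerance when comparing point probabilities in two-sided exact
#: tests (guards against ties lost to floating-point rounding)
POINT_PROB_RTOL = 1e-7

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class FisherResult:
    set_name: str
    direction: str  # "male-DE" | "female-DE"
    tier: float
    a: int  # set & DE
    b: int  # set & not DE
    c: int  # not set & DE
    d: int  # not set & not DE
    odds_ratio: float
    fold_of_expected: float
    p: float
    p_adj: float = np.nan

    @property
    def background_size(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def significant(self) -> bool:
        return self.p_adj < SIGNIFICANCE_LEVEL


@dataclass
class ShiftResult:
    set_name: str
    n_set: int  # set genes in background with nonzero log2FD
    k_male: int  # of those, male-higher
    prop: float
    p_bg: float
    shift: float  # prop - p_bg (proportion units)
    ci_lo: float
    ci_hi: float
    p: float
    p_adj: float = np.nan

    @property
    def significant(self) -> bool:
        return self.p_adj < SIGNIFICANCE_LEVEL


def build_background(
    category: str, collection: GeneSetCollection, expressed_genes: Iterable[str]
) -> list[str]:
    """Resolve a background category to a concrete gene universe.

    Expression-dependent categories (protein_coding, source_publication:*)
    are intersected with the expressed genes; the genome-wide orthologue
    category is returned unintersected.
    """
    if category not in collection.backgrounds:
        raise ParameterError(f"unknown background category {category!r}")
    base = collection.backgrounds[category]
    if category == "orthologue_1to1":
        return list(base)
    expressed = set(expressed_genes)
    out = [g for g in base if g in expressed]
    if not out:
        raise ParameterError(f"background {category!r} is empty after intersection")
    return out


def fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p: total probability of all tables (with the
    observed margins) whose point probability does not exceed the observed
    table's, up to a relative tolerance."""
    N = a + b + c + d
    K = a + b  # set size in background
    n = a + c  # DE size in background
    support = np.arange(max(0, K + n - N), min(K, n) + 1)
    pmf = hypergeom.pmf(support, N, K, n)
    p_obs = hypergeom.pmf(a, N, K, n)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + POINT_PROB_RTOL)].sum()))


def binomial_two_sided_p(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p by the minimum-likelihood rule."""
    if not (0 <= p0 <= 1):
        raise ParameterError("p0 must lie in [0, 1]")
    support = np.arange(0, n + 1)
    pmf = binom.pmf(support, n, p0)
    p_obs = binom.pmf(k, n, p0)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + POINT_PROB_RTOL)].sum()))


def clopper_pearson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) confidence interval for a binomial proportion."""
    alpha = 1 - level
    lo = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def fisher_enrichment(
    set_genes: Iterable[str],
    de_genes: Iterable[str],
    background: Sequence[str],
    set_name: str = "",
    direction: str = "",
    tier: float = np.nan,
) -> FisherResult:
    """Two-sided Fisher's exact test of set/DE overlap within a background.

    Both the set and the DE list are first restricted to the background.
    Reports the sample odds ratio ``ad/bc`` and the observed/expected ratio
    ``(a/(a+b)) / ((a+c)/N)`` side by side.
    """
    if not background:
        raise ParameterError("background is empty")
    bg = set(background)
    S = set(set_genes) & bg
    if not S:
        raise ParameterError(f"set {set_name!r} is disjoint from its background")
    D = set(de_genes) & bg
    a = len(S & D)
    b = len(S) - a
    c = len(D) - a
    d = len(bg) - a - b - c
    if b * c > 0:
        odds_ratio = (a * d) / (b * c)
    else:
        odds_ratio = np.inf if a * d > 0 else 0.0
    N = len(bg)
    expected_rate = (a + c) / N
    fold = (a / (a + b)) / expected_rate if expected_rate > 0 else np.nan
    p = fisher_two_sided_p(a, b, c, d)
    return FisherResult(
        set_name=set_name, direction=direction, tier=tier,
        a=a, b=b, c=c, d=d, odds_ratio=float(odds_ratio),
        fold_of_expected=float(fold), p=p,
    )


def bonferroni(p: float, n_tests: int) -> float:
    return min(1.0, p * n_tests)


def adjust_fisher(results: list[FisherResult], n_tests: int) -> list[FisherResult]:
    """Bonferroni adjustment applied within each p-value tier."""
    for tier in {r.tier for r in results}:
        n_at_tier = sum(1 for r in results if r.tier == tier)
        if n_tests < n_at_tier:
            raise ParameterError(
                f"n_tests={n_tests} smaller than the {n_at_tier} results at tier {tier}"
            )
    return [replace(r, p_adj=bonferroni(r.p, n_tests)) for r in results]


def adjust_binomial(results: list[ShiftResult], n_sets: int) -> list[ShiftResult]:
    if n_sets < len(results):
        raise ParameterError(f"n_sets={n_sets} smaller than {len(results)} results")
    return [replace(r, p_adj=bonferroni(r.p, n_sets)) for r in results]


def binomial_shift(
    set_genes: Iterable[str],
    de_table: pd.DataFrame,
    background: Sequence[str],
    set_name: str = "",
    exclude_set_from_background: bool = False,
) -> ShiftResult:
    """Directional binomial shift test of a set against its background.

    Genes are classed male-higher (log2FD > 0) or female-higher (log2FD < 0)
    at any p; log2FD exactly 0 is excluded from both categories.  The
    background male-higher proportion is the null success probability; by
    default the set's genes remain part of the background distribution.
    """
    bg = [g for g in background if g in de_table.index]
    if exclude_set_from_background:
        s = set(set_genes)
        bg_for_p = [g for g in bg if g not in s]
    else:
        bg_for_p = bg
    fd_bg = de_table.loc[bg_for_p, "log2FD"].to_numpy()
    nz = fd_bg != 0
    if not nz.any():
        raise ParameterError("background has no genes with nonzero log2FD")
    p_bg = float((fd_bg[nz] > 0).mean())
    in_bg = set(bg)
    set_in = [g for g in dict.fromkeys(set_genes) if g in in_bg]
    fd_set = de_table.loc[set_in, "log2FD"].to_numpy() if set_in else np.array([])
    fd_set = fd_set[fd_set != 0]
    n_set = int(fd_set.size)
    if n_set == 0:
        raise ParameterError(f"set {set_name!r} has no scorable genes in its background")
    k_male = int((fd_set > 0).sum())
    prop = k_male / n_set
    ci_lo, ci_hi = clopper_pearson_ci(k_male, n_set)
    p = binomial_two_sided_p(k_male, n_set, p_bg)
    return ShiftResult(
        set_name=set_name, n_set=n_set, k_male=k_male, prop=prop, p_bg=p_bg,
        shift=prop - p_bg, ci_lo=ci_lo, ci_hi=ci_hi, p=p,
    )


def run_enrichment_suite(
    de_table: pd.DataFrame,
    collection: GeneSetCollection,
    expressed_genes: Iterable[str] | None = None,
    p_tiers: Sequence[float] = (0.005, 0.01, 0.05),
    exclude_set_from_background: bool = False,
    n_fisher_tests: int | None = None,
    n_binomial_sets: int | None = None,
) -> pd.DataFrame:
    """Run both over-representation tests for every set in the collection.

    Produces ``2 * n_sets * n_tiers`` Fisher rows (adjusted for ``2 * n_sets``
    tests within each tier) and ``n_sets`` binomial shift rows (adjusted for
    ``n_sets``), as one tidy report table.  ``n_fisher_tests`` /
    ``n_binomial_sets`` override the Bonferroni denominators (e.g. to keep
    the reference parameterization of 62 and 31 when testing a subset of a
    larger collection).
    """
    expressed = list(expressed_genes) if expressed_genes is not None else list(de_table.index)
    names = collection.set_names
    n_sets = len(names)
    if n_sets == 0:
        raise ParameterError("collection has no gene sets")
    backgrounds = {
        name: build_background(collection.sets[name].background_category, collection, expressed)
        for name in names
    }

    fisher_results: list[FisherResult] = []
    for alpha in sorted(p_tiers):
        col = f"de_{alpha:g}"
        if col not in de_table.columns:
            raise ParameterError(f"DE table lacks tier column {col!r}")
        for direction in ("male-DE", "female-DE"):
            de_genes = de_table.index[de_table[col] == direction]
            for name in names:
                fisher_results.append(
                    fisher_enrichment(
                        collection.genes_of(name), de_genes, backgrounds[name],
                        set_name=name, direction=direction, tier=alpha,
                    )
                )
    fisher_results = adjust_fisher(fisher_results, n_tests=n_fisher_tests or 2 * n_sets)

    shift_results = [
        binomial_shift(
            collection.genes_of(name), de_table, backgrounds[name], set_name=name,
            exclude_set_from_background=exclude_set_from_background,
        )
        for name in names
    ]
    shift_results = adjust_binomial(shift_results, n_sets=n_binomial_sets or n_sets)

    rows = []
    for r in fisher_results:
        rows.append(
            {
                "set": r.set_name, "test": "fisher", "direction": r.direction,
                "tier": r.tier, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                "odds_ratio": r.odds_ratio, "fold_of_expected": r.fold_of_expected,
                "p": r.p, "p_adj": r.p_adj, "significant": r.significant,
            }
        )
    for r in shift_results:
        rows.append(
            {
                "set": r.set_name, "test": "binomial_shift", "direction": "",
                "tier": np.nan, "n_set": r.n_set, "k_male": r.k_male,
                "prop": r.prop, "p_bg": r.p_bg, "shift": r.shift,
                "ci_lo": r.ci_lo, "ci_hi": r.ci_hi,
                "p": r.p, "p_adj": r.p_adj, "significant": r.significant,
            }
        )
    report = pd.DataFrame(rows)
    col_order = [
        "set", "test", "direction", "tier", "a", "b", "c", "d",
        "odds_ratio", "fold_of_expected", "n_set", "k_male", "prop", "p_bg",
        "shift", "ci_lo", "ci_hi", "p", "p_adj", "significant",
    ]
    return report[[c for c in col_order if c in report.columns]]


def write_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.10g",
                  na_rep="NA", lineterminator="\n")
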