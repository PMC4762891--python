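"""Expression filtering, outlier removal, quantile normalization, sample matching.

The fixed pipeline order is: filter non-expressed genes -> outlier passes
(within each sex, then all samples) -> quantile normalize -> sex-balanced
sample matching -> re-filter expressed genes on the matched subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sexde.exceptions import ParameterError
from sexde.io import ExpressionMatrix, SampleTable

logger = logging.getLogger(__name__)

#: default expression cutoffs: log2(RPKM+1) < 1 in > 50% of either sex's
#: samples for RNA-seq; log2 median probe-set intensity < 6 in > 80% for arrays
FILTER_DEFAULTS = {"rnaseq": (1.0, 0.5), "array": (6.0, 0.8)}


@dataclass
class FilterSpec:
    """Non-expressed gene filter: remove genes below ``level_threshold`` in a
    strict majority (> ``fraction``) of samples, evaluated within each sex."""

    level_threshold: float = 1.0
    fraction: float = 0.5
    per_sex: bool = True
    mode: str = "rnaseq"

    def __post_init__(self) -> None:
        if not (0 < self.fraction <= 1):
            raise ParameterError("fraction must lie in (0, 1]")
        if not np.isfinite(self.level_threshold):
            raise ParameterError("level_threshold must be finite")
        if self.mode not in ("rnaseq", "array"):
            raise ParameterError("mode must be 'rnaseq' or 'array'")

    @classmethod
    def for_mode(cls, mode: str) -> "FilterSpec":
        thr, frac = FILTER_DEFAULTS[mode]
        return cls(level_threshold=thr, fraction=frac, per_sex=True, mode=mode)


@dataclass
class OutlierSpec:
    """Correlation-based outlier rule: drop samples whose mean inter-sample
    correlation falls more than ``z_threshold`` SDs below the group mean.

    ``passes`` lists grouping schemes applied in order ('within_sex' splits by
    sex; 'all' pools every sample), recomputing correlations after each pass.
    """

    z_threshold: float = 2.5
    passes: list[str] = field(default_factory=lambda: ["within_sex", "all"])

    def __post_init__(self) -> None:
        if not self.z_threshold > 0:
            raise ParameterError("z_threshold must be positive")
        bad = set(self.passes) - {"within_sex", "all"}
        if bad:
            raise ParameterError(f"unknown outlier passes: {sorted(bad)}")

    @classmethod
    def replication_style(cls) -> "OutlierSpec":
        """Single all-sample pass at z=2 (summed-correlation z-score rule)."""
        return cls(z_threshold=2.0, passes=["all"])


def filter_nonexpressed(
    matrix: ExpressionMatrix, samples: SampleTable, spec: FilterSpec
) -> ExpressionMatrix:
    """Remove genes not expressed in a strict majority of either sex's samples.

    A gene is removed iff the fraction of samples with value strictly below
    ``level_threshold`` exceeds ``fraction`` (strictly) in males OR in
    females; with ``per_sex=False`` the rule is applied over all samples.
    Gene order is preserved.
    """
    samples.check_covers(matrix)
    meta = samples.data.loc[matrix.sample_ids]
    if spec.per_sex:
        groups = [meta.index[meta["sex"] == s] for s in ("male", "female")]
        for sex, g in zip(("male", "female"), groups):
            if len(g) == 0:
                raise ParameterError(f"no {sex} samples in filter stratum")
    else:
        groups = [meta.index]
    low = matrix.data < spec.level_threshold
    remove = np.zeros(matrix.shape[0], dtype=bool)
    for g in groups:
        frac_low = low[list(g)].mean(axis=1).to_numpy()
        remove |= frac_low > spec.fraction
    kept = matrix.data.loc[~remove]
    logger.info("filter_nonexpressed: removed %d of %d genes", int(remove.sum()), len(remove))
    return ExpressionMatrix(kept)


def _mean_correlations(values: np.ndarray) -> np.ndarray:
    """Per-sample mean product-moment correlation with the other samples."""
    corr = np.corrcoef(values, rowvar=False)
    n = corr.shape[0]
    np.fill_diagonal(corr, np.nan)
    return np.nanmean(corr, axis=0) if n > 1 else np.zeros(1)


def remove_outliers(
    matrix: ExpressionMatrix, samples: SampleTable, spec: OutlierSpec
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Iteratively drop low-correlation outlier samples.

    Per pass and per group, a sample is an outlier when its mean correlation
    with the other group members lies more than ``z_threshold`` standard
    deviations below the group mean of those means.  Only the low side is
    flagged: an unusually high mean correlation cannot indicate a degraded
    sample.  Returns the reduced matrix and a report of removed sample IDs
    with the pass that removed each.
    """
    samples.check_covers(matrix)
    data = matrix.data
    removed: list[dict] = []
    for pass_name in spec.passes:
        meta = samples.data.loc[data.columns]
        if pass_name == "within_sex":
            groups = [meta.index[meta["sex"] == s] for s in ("male", "female")]
        else:
            groups = [meta.index]
        drop: list[str] = []
        for g in groups:
            g = [s for s in g if s in data.columns]
            if len(g) < 3:
                raise ParameterError(
                    f"outlier pass {pass_name!r}: group of {len(g)} samples is too small (need >=3)"
                )
            means = _mean_correlations(data[g].to_numpy())
            sd = means.std(ddof=0)
            if sd == 0:
                continue
            z = (means - means.mean()) / sd
            for sid, zi in zip(g, z):
                if zi < -spec.z_threshold:
                    drop.append(sid)
                    removed.append({"sample": sid, "pass": pass_name, "z": float(zi)})
        if drop:
            data = data.drop(columns=drop)
            logger.info("remove_outliers pass %s: removed %s", pass_name, drop)
    report = pd.DataFrame(removed, columns=["sample", "pass", "z"])
    return ExpressionMatrix(data), report


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common per-rank mean distribution.

    The reference vector is the across-sample mean of the sorted columns;
    each sample's values are replaced by the reference value at their rank,
    with ties receiving the mean of the reference values at their tied ranks.
    Within-sample rank order is preserved and the map is idempotent.
    """
    values = matrix.values
    n_genes, n_samples = values.shape
    if n_samples < 2:
        raise ParameterError("quantile normalization needs >=2 samples")
    reference = np.sort(values, axis=0).mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(values, dtype=float)
    for j in range(n_samples):
        order = np.argsort(values[:, j], kind="mergesort")
        out[order, j] = reference
        # tied blocks get the mean of the reference over their rank span
        sorted_vals = values[order, j]
        block_start = np.flatnonzero(np.r_[True, sorted_vals[1:] != sorted_vals[:-1]])
        block_end = np.r_[block_start[1:], n_genes]
        for s, e in zip(block_start, block_end):
            if e - s > 1:
                out[order[s:e], j] = (csum[e] - csum[s]) / (e - s)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    )


def match_samples(samples: SampleTable) -> tuple[list[str], list[str]]:
    """Balance the sexes by age/region matching.

    Keeps every minority-sex sample and pairs each with a distinct
    majority-sex sample from the same region with minimal absolute age
    difference, assigned greedily in ascending age-difference order (ties
    broken lexicographically by minority then majority sample ID).  Minority
    samples with no remaining region-compatible partner are dropped and
    reported.  Returns (selected sample IDs, dropped minority sample IDs).
    """
    meta = samples.data
    counts = meta["sex"].value_counts()
    if set(counts.index) != set(("male", "female")) or (counts == 0).any():
        raise ParameterError("both sexes must be present for matching")
    minority_sex = "male" if counts.get("male", 0) <= counts.get("female", 0) else "female"
    minority = meta[meta["sex"] == minority_sex]
    majority = meta[meta["sex"] != minority_sex]

    candidates = []
    for mid, mrow in minority.iterrows():
        for jid, jrow in majority.iterrows():
            if mrow["region"] == jrow["region"]:
                candidates.append((abs(float(mrow["age"]) - float(jrow["age"])), mid, jid))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))

    matched: dict[str, str] = {}
    used_majority: set[str] = set()
    for _, mid, jid in candidates:
        if mid in matched or jid in used_majority:
            continue
        matched[mid] = jid
        used_majority.add(jid)
    dropped = sorted(set(minority.index) - set(matched))
    if dropped:
        logger.warning("match_samples: no region-compatible partner for %s", dropped)
    selected = sorted(matched) + sorted(matched.values())
    return selected, dropped


def preprocess_pipeline(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    filter_spec: FilterSpec | None = None,
    outlier_spec: OutlierSpec | None = None,
    match: bool = True,
) -> dict:
    """Run the full fixed-order preprocessing pipeline.

    Returns a dict with the final matrix/samples plus the outlier report and
    the matched/dropped sample lists.
    """
    filter_spec = filter_spec or FilterSpec()
    outlier_spec = outlier_spec or OutlierSpec()
    m1 = filter_nonexpressed(matrix, samples, filter_spec)
    m2, outlier_report = remove_outliers(m1, samples, outlier_spec)
    m3 = quantile_normalize(m2)
    dropped: list[str] = []
    if match:
        selected, dropped = match_samples(samples.subset(m3.sample_ids))
        m3 = m3.subset_samples(selected)
    final_samples = samples.subset(m3.sample_ids)
    m4 = filter_nonexpressed(m3, final_samples, filter_spec)  # re-filter post-match
    return {
        "matrix": m4,
        "samples": final_samples,
        "outlier_report": outlier_report,
        "dropped_unmatched": dropped,
    }
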