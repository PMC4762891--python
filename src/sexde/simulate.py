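"""Synthetic expression-cohort generator with ground truth.

Emulates the structure of a repeated-measures post-mortem cortex study: each
subject contributes one sample per cortical region, sexes are balanced, and
per-gene expression is

    baseline + sex effect + covariate effects + subject intercept + noise

on the log2 scale.  Sex-chromosome signatures are modeled as marker genes
expressed essentially only in one sex (a female-only XIST-like gene, male-only
Y-like genes).  Autosomal effects are planted only in designated gene sets,
as subtle fold differences; all other autosomal genes are true nulls.
Per-gene residual variances are drawn from a scaled inverse-chi-square
hyperprior so that the moderated-test model downstream is exactly satisfied,
and the subject intercept variance is chosen so the intra-subject correlation
equals ``rho_subject``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from sexde import io as sio
from sexde.exceptions import ParameterError

LOBES = ("frontal", "temporal", "parietal")

#: log2 baselines for sex-chromosome marker genes: high in the expressing sex,
#: near-zero in the other — reproduces the extreme-fold-difference wings of a
#: whole-transcriptome volcano without modeling copy number.
MARKER_BASELINE_ON = 6.0
MARKER_BASELINE_OFF = 0.05

COVARIATE_RANGES = {
    "age": (13.0, 40.0),  # years
    "PMI": (5.0, 30.0),  # hours
    "pH": (6.0, 7.0),
    "RIN": (7.0, 10.0),
}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    ``planted_sets`` lists ``(set_name, n_genes, log2fd)`` triples; a positive
    planted log2 fold difference means male-higher.  ``d0``/``s0_sq`` are the
    degrees of freedom and scale of the scaled inverse-chi-square variance
    hyperprior; ``rho_subject`` is the intra-subject correlation induced by
    the subject random intercept.
    """

    n_subjects_per_sex: int = 5
    n_regions_per_subject: int = 6
    n_genes: int = 2000
    d0: float = 4.0
    s0_sq: float = 0.05
    rho_subject: float = 0.3
    planted_sets: list[tuple[str, int, float]] = field(default_factory=list)
    n_sexchrom_female_marker: int = 1
    n_sexchrom_male_marker: int = 6
    covariate_effect_scale: float = 0.1
    baseline_mean_range: tuple[float, float] = (3.0, 8.0)
    seed: int = 0
    #: optional separate seed for subjects/noise; lets two cohorts share the
    #: gene-level truth (set membership, planted FDs, baselines, variances)
    #: while drawing independent subjects and measurement noise
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_subjects_per_sex", "n_regions_per_subject", "n_genes"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.n_sexchrom_female_marker < 0 or self.n_sexchrom_male_marker < 0:
            raise ParameterError("marker counts must be nonnegative")
        if self.d0 <= 2:
            raise ParameterError("d0 must exceed 2 (finite prior variance mean)")
        if self.s0_sq <= 0:
            raise ParameterError("s0_sq must be positive")
        if not (0 <= self.rho_subject < 1):
            raise ParameterError("rho_subject must lie in [0, 1)")
        lo, hi = self.baseline_mean_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ParameterError("baseline_mean_range must be a finite (lo, hi) interval")
        self.planted_sets = [
            (str(n), int(k), float(fd)) for n, k, fd in self.planted_sets
        ]
        names = [n for n, _, _ in self.planted_sets]
        if len(names) != len(set(names)):
            raise ParameterError("planted set names must be unique")
        if any(k <= 0 for _, k, _ in self.planted_sets):
            raise ParameterError("planted set sizes must be positive")
        if sum(k for _, k, _ in self.planted_sets) > self.n_autosomal:
            raise ParameterError("planted set sizes exceed the autosomal gene count")

    @property
    def n_markers(self) -> int:
        return self.n_sexchrom_female_marker + self.n_sexchrom_male_marker

    @property
    def n_autosomal(self) -> int:
        n = self.n_genes - self.n_markers
        if n < 0:
            raise ParameterError("marker counts exceed n_genes")
        return n

    @property
    def n_samples(self) -> int:
        return 2 * self.n_subjects_per_sex * self.n_regions_per_subject

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_sets"] = [list(t) for t in self.planted_sets]
        d["baseline_mean_range"] = list(self.baseline_mean_range)
        return d

    @classmethod
    def from_dict(cls, mapping: dict) -> "SimConfig":
        kwargs = dict(mapping)
        if "planted_sets" in kwargs:
            kwargs["planted_sets"] = [tuple(t) for t in kwargs["planted_sets"]]
        if "baseline_mean_range" in kwargs:
            kwargs["baseline_mean_range"] = tuple(kwargs["baseline_mean_range"])
        return cls(**kwargs)


@dataclass
class Cohort:
    """Bundle of the four consistent simulation outputs."""

    expression: sio.ExpressionMatrix
    samples: sio.SampleTable
    gene_sets: sio.GeneSetCollection
    truth: pd.DataFrame
    config: SimConfig


def sample_gene_variances(
    n_genes: int, d0: float, s0_sq: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw per-gene residual variances from a scaled inverse-chi-square prior.

    Each variance is ``d0 * s0_sq / X`` with ``X ~ chi-square(d0)``; the prior
    mean is ``d0*s0_sq/(d0-2)`` for ``d0 > 2``.
    """
    if n_genes <= 0:
        raise ParameterError("n_genes must be positive")
    if d0 <= 0 or s0_sq <= 0:
        raise ParameterError("d0 and s0_sq must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not np.isfinite(d0):
        return np.full(n_genes, s0_sq)
    chi2 = rng.chisquare(d0, size=n_genes)
    return d0 * s0_sq / chi2


def _gene_ids(config: SimConfig) -> tuple[list[str], np.ndarray]:
    """Gene IDs in fixed order with their sex-chromosome class labels."""
    ids: list[str] = []
    classes: list[str] = []
    for i in range(config.n_sexchrom_female_marker):
        ids.append(f"XMRK{i + 1:02d}")
        classes.append("X_marker")
    for i in range(config.n_sexchrom_male_marker):
        ids.append(f"YMRK{i + 1:02d}")
        classes.append("Y_marker")
    width = max(5, len(str(config.n_autosomal)))
    for i in range(config.n_autosomal):
        ids.append(f"G{i + 1:0{width}d}")
        classes.append("autosomal")
    return ids, np.array(classes)


def _sample_frame(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for sex in ("male", "female"):
        prefix = "M" if sex == "male" else "F"
        for s in range(config.n_subjects_per_sex):
            subject = f"SUBJ_{prefix}{s + 1:02d}"
            age = rng.uniform(*COVARIATE_RANGES["age"])
            pmi = rng.uniform(*COVARIATE_RANGES["PMI"])
            ph = rng.uniform(*COVARIATE_RANGES["pH"])
            for r in range(config.n_regions_per_subject):
                region = f"R{r + 1:02d}"
                rows.append(
                    {
                        "sample": f"{subject}_{region}",
                        "sex": sex,
                        "subject": subject,
                        "region": region,
                        "lobe": LOBES[r % len(LOBES)],
                        "age": round(age, 2),
                        "RIN": round(rng.uniform(*COVARIATE_RANGES["RIN"]), 2),
                        "PMI": round(pmi, 2),
                        "pH": round(ph, 3),
                    }
                )
    return pd.DataFrame(rows).set_index("sample")


def _assign_sets(
    config: SimConfig, autosomal_ids: Sequence[str], rng: np.random.Generator
) -> tuple[dict[str, list[str]], dict[str, list[str]], pd.Series, pd.Series]:
    """Draw disjoint planted sets plus same-size unplanted control sets.

    Returns (planted, controls, per-gene true log2FD, per-gene set labels)
    over autosomal genes.
    """
    true_fd = pd.Series(0.0, index=list(autosomal_ids))
    labels = pd.Series("", index=list(autosomal_ids), dtype=object)
    pool = list(autosomal_ids)
    planted: dict[str, list[str]] = {}
    controls: dict[str, list[str]] = {}
    for name, k, fd in config.planted_sets:
        chosen = [str(g) for g in rng.choice(pool, size=k, replace=False)]
        pool = [g for g in pool if g not in set(chosen)]
        planted[name] = sorted(chosen)
        true_fd[chosen] = fd
        for g in chosen:
            labels[g] = name
    # one control (unplanted, null) set per planted set, same size; at least one
    control_sizes = [k for _, k, _ in config.planted_sets] or [min(50, len(pool))]
    control_names = [f"{name}_control" for name, _, _ in config.planted_sets] or ["control_1"]
    for cname, k in zip(control_names, control_sizes):
        k = min(k, len(pool))
        if k == 0:
            continue
        chosen = [str(g) for g in rng.choice(pool, size=k, replace=False)]
        pool = [g for g in pool if g not in set(chosen)]
        controls[cname] = sorted(chosen)
        for g in chosen:
            labels[g] = cname
    return planted, controls, true_fd, labels


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate a full synthetic cohort with consistent identifiers.

    The output expression matrix has ``n_genes`` rows and
    ``2 * n_subjects_per_sex * n_regions_per_subject`` columns.  The sex
    effect is split symmetrically (+/- log2FD/2 around baseline) so the truth
    table's log2FD equals male mean minus female mean.  Identical configs
    (including seed) produce bit-identical outputs.
    """
    rng = np.random.default_rng([1, config.seed])  # gene-level truth
    noise_rng = np.random.default_rng(
        [2, config.seed if config.noise_seed is None else config.noise_seed]
    )
    gene_ids, classes = _gene_ids(config)
    samples = _sample_frame(config, noise_rng)
    n_genes, n_samples = config.n_genes, config.n_samples
    is_male = (samples["sex"] == "male").to_numpy()

    autosomal_ids = [g for g, c in zip(gene_ids, classes) if c == "autosomal"]
    planted, controls, auto_fd, auto_labels = _assign_sets(config, autosomal_ids, rng)

    # per-gene true log2FD (male minus female); markers get the full on/off gap
    marker_gap = MARKER_BASELINE_ON - MARKER_BASELINE_OFF
    true_fd = pd.Series(0.0, index=gene_ids)
    true_fd[classes == "X_marker"] = -marker_gap
    true_fd[classes == "Y_marker"] = marker_gap
    true_fd.loc[autosomal_ids] = auto_fd

    # baselines: uniform for autosomal genes; sex-specific for markers
    lo, hi = config.baseline_mean_range
    baseline = rng.uniform(lo, hi, size=n_genes)
    mean = np.tile(baseline[:, None], (1, n_samples))
    half = (true_fd.to_numpy() / 2.0)[:, None]
    mean = mean + np.where(is_male[None, :], half, -half)
    # overwrite marker rows with explicit on/off baselines (plus noise below)
    mid = (MARKER_BASELINE_ON + MARKER_BASELINE_OFF) / 2.0
    marker_rows = classes != "autosomal"
    if marker_rows.any():
        mean[marker_rows] = mid + np.where(
            is_male[None, :], half[marker_rows], -half[marker_rows]
        )

    # fixed covariate effects on standardized covariates
    if config.covariate_effect_scale > 0:
        for cov in ("age", "RIN", "PMI", "pH"):
            x = samples[cov].to_numpy(float)
            sd = x.std()
            z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
            beta = rng.normal(0.0, config.covariate_effect_scale, size=n_genes)
            mean = mean + beta[:, None] * z[None, :]
        lobe_codes = pd.Categorical(samples["lobe"]).codes
        n_lobes = lobe_codes.max() + 1
        lobe_eff = rng.normal(0.0, config.covariate_effect_scale, size=(n_genes, n_lobes))
        lobe_eff -= lobe_eff.mean(axis=1, keepdims=True)
        mean = mean + lobe_eff[:, lobe_codes]

    sigma2 = sample_gene_variances(n_genes, config.d0, config.s0_sq, rng)

    # subject random intercepts: tau2 = rho/(1-rho) * sigma2 gives
    # corr(within subject) = tau2/(tau2+sigma2) = rho
    subjects = samples["subject"].to_numpy()
    subj_codes, subj_uniques = pd.factorize(subjects)
    if config.rho_subject > 0:
        tau = np.sqrt(config.rho_subject / (1 - config.rho_subject) * sigma2)
        intercepts = noise_rng.normal(0.0, 1.0, size=(n_genes, len(subj_uniques))) * tau[:, None]
        mean = mean + intercepts[:, subj_codes]

    noise = noise_rng.normal(0.0, 1.0, size=(n_genes, n_samples)) * np.sqrt(sigma2)[:, None]
    values = mean + noise

    expr = sio.ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(gene_ids, name="gene"), columns=samples.index)
    )

    truth = pd.DataFrame(
        {
            "true_log2fd": true_fd,
            "sex_class": classes,
            "sets": pd.concat(
                [pd.Series("", index=[g for g in gene_ids if g not in autosomal_ids], dtype=object), auto_labels]
            ).reindex(gene_ids),
        },
        index=pd.Index(gene_ids, name="gene"),
    )

    sets = {
        name: sio.GeneSet(genes=genes, background_category="protein_coding")
        for name, genes in {**planted, **controls}.items()
    }
    collection = sio.GeneSetCollection(
        sets=sets, backgrounds={"protein_coding": list(autosomal_ids)}
    )
    return Cohort(
        expression=expr, samples=sio.SampleTable(samples), gene_sets=collection,
        truth=truth, config=config,
    )


def write_fixture_bundle(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort as a TSV/GMT fixture bundle that round-trips losslessly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "samples": directory / "samples.tsv",
        "gene_sets": directory / "gene_sets.gmt",
        "truth": directory / "truth.tsv",
        "backgrounds": directory / "backgrounds",
    }
    sio.write_expression(cohort.expression, paths["expression"])
    sio.write_samples(cohort.samples, paths["samples"])
    sio.write_gmt(cohort.gene_sets, paths["gene_sets"])
    sio.write_truth(cohort.truth, paths["truth"])
    sio.write_backgrounds(cohort.gene_sets.backgrounds, paths["backgrounds"])
    return paths


def read_fixture_bundle(directory: str | Path) -> Cohort:
    """Read a fixture bundle written by :func:`write_fixture_bundle`."""
    directory = Path(directory)
    expr = sio.read_expression(directory / "expression.tsv")
    samples = sio.read_samples(directory / "samples.tsv")
    collection = sio.read_gmt(directory / "gene_sets.gmt")
    collection.backgrounds = sio.read_backgrounds(directory / "backgrounds")
    collection.validate_backgrounds()
    truth = sio.read_truth(directory / "truth.tsv")
    return Cohort(expression=expr, samples=samples, gene_sets=collection,
                  truth=truth, config=None)
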