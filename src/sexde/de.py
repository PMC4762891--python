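"""Per-gene sex-contrast estimation with a subject random effect and
empirical-Bayes moderated t-statistics.

The repeated-measures structure (several cortical regions per subject) is
modeled by a compound-symmetry covariance: samples from the same subject share
a common intra-subject correlation ``rho``.  A single consensus ``rho`` is
estimated across genes by REML and then used in per-gene generalized least
squares, the approach that is standard for small repeated-measures expression
cohorts.  Per-gene variances are shrunk toward a scaled inverse-chi-square
prior whose hyperparameters ``(d0, s0_sq)`` are estimated by a closed-form
method of moments on log residual variances; the moderated t-statistic then
has ``d0 + d_g`` degrees of freedom.

Sign convention: the sex contrast is male minus female on the log2 scale, so
positive log2FD means male-higher expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import helmert, qr
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist, trim_mean
from statsmodels.stats.multitest import multipletests

from sexde.exceptions import ParameterError
from sexde.io import ExpressionMatrix, SampleTable

logger = logging.getLogger(__name__)

ALLOWED_COVARIATES = ("RIN", "age", "PMI", "lobe", "pH")
DEFAULT_P_TIERS = (0.005, 0.01, 0.05)
DEFAULT_FD_THRESHOLD = 1.2
RHO_CLAMP = 0.99


@dataclass
class DesignSpec:
    """Fixed-effect design: sex contrast plus optional quality covariates.

    ``lobe`` is categorical and expanded to indicator terms; the other
    covariates enter as unstandardized numeric terms.  Subject is always the
    random effect.
    """

    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.covariates) - set(ALLOWED_COVARIATES)
        if bad:
            raise ParameterError(
                f"unknown covariates {sorted(bad)}; allowed: {ALLOWED_COVARIATES}"
            )


@dataclass
class EBayesParams:
    """Hyperparameters of the moderated test: variance prior (d0, s0_sq) and
    consensus intra-subject correlation rho."""

    d0: float
    s0_sq: float
    rho: float


def impute_missing_covariates(samples: SampleTable) -> tuple[SampleTable, list[dict]]:
    """Replace missing PMI/pH by the subject's mean over non-missing samples.

    A subject with no non-missing value for a covariate falls back to the
    cohort mean; each fallback is reported.  A covariate missing for the
    entire cohort is an error.
    """
    df = samples.data.copy()
    report: list[dict] = []
    for cov in ("PMI", "pH"):
        if cov not in df.columns:
            continue
        col = pd.to_numeric(df[cov])
        if col.isna().all():
            raise ParameterError(f"covariate {cov!r} is missing for the entire cohort")
        cohort_mean = col.mean()
        subj_means = col.groupby(df["subject"]).transform("mean")
        fallback_subjects = sorted(df.loc[subj_means.isna() & col.isna(), "subject"].unique())
        for subj in fallback_subjects:
            report.append({"covariate": cov, "subject": subj, "value": float(cohort_mean)})
        filled = col.fillna(subj_means).fillna(cohort_mean)
        df[cov] = filled
    return SampleTable(df), report


def build_design(
    samples: SampleTable, design: DesignSpec
) -> tuple[np.ndarray, list[str]]:
    """Build the fixed-effect design matrix: intercept, male indicator, covariates.

    The male indicator is coded 1/0 so its coefficient is the male-minus-
    female contrast.  Raises on rank deficiency, naming collinear columns.
    """
    meta = samples.data
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(meta))}
    cols["sex_male"] = (meta["sex"] == "male").to_numpy(float)
    for cov in design.covariates:
        if cov == "lobe":
            dummies = pd.get_dummies(meta["lobe"], prefix="lobe", drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy(float)
        else:
            if cov not in meta.columns:
                raise ParameterError(f"covariate {cov!r} not in sample table")
            vals = pd.to_numeric(meta[cov])
            if vals.isna().any():
                raise ParameterError(
                    f"covariate {cov!r} has missing values; run impute_missing_covariates first"
                )
            cols[cov] = vals.to_numpy(float)
    X = np.column_stack(list(cols.values()))
    names = list(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via QR pivoting
        _, r, piv = qr(X, pivoting=True)
        diag = np.abs(np.diag(r))
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < 1e-8 * diag[0]]
        bad += [names[p] for p in piv[len(diag):]]
        raise ParameterError(f"design matrix is rank deficient; collinear columns: {bad}")
    return X, names


def _block_transform(subjects: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal within-subject Helmert transform diagonalizing compound symmetry.

    Returns (T, msize) where T is n x n orthonormal and, for a covariance with
    intra-subject correlation rho, T V T' is diagonal with entries
    ``1 + (m-1)*rho`` where msize == m on a block-mean coordinate and
    ``1 - rho`` on the contrast coordinates (msize encodes m for the former,
    and is tagged 0 for contrasts).
    """
    n = len(subjects)
    codes, uniques = pd.factorize(subjects)
    T = np.zeros((n, n))
    msize = np.zeros(n)
    row = 0
    for u in range(len(uniques)):
        idx = np.flatnonzero(codes == u)
        m = len(idx)
        if m == 1:
            T[row, idx[0]] = 1.0
            msize[row] = 1
            row += 1
        else:
            H = helmert(m, full=True)  # first row = 1/sqrt(m)
            for k in range(m):
                T[row, idx] = H[k]
                msize[row] = m if k == 0 else 0
                row += 1
    return T, msize


def _eigenvalues(msize: np.ndarray, rho: float) -> np.ndarray:
    lam = np.where(msize > 0, 1 + (msize - 1) * rho, 1 - rho)
    return lam


def _reml_loglik_grid(
    Yt: np.ndarray, Xt: np.ndarray, msize: np.ndarray, rhos: np.ndarray
) -> np.ndarray:
    """Restricted log-likelihood (up to a constant) for each gene at each rho.

    Operates in the Helmert-transformed basis where the compound-symmetry
    covariance is diagonal; sigma^2 is profiled out.  Returns (n_genes,
    n_rhos).
    """
    n, p = Xt.shape
    out = np.empty((Yt.shape[0], len(rhos)))
    for j, rho in enumerate(rhos):
        lam = _eigenvalues(msize, rho)
        w = 1.0 / lam
        sw = np.sqrt(w)
        Xw = Xt * sw[:, None]
        Yw = Yt * sw[None, :]
        A = Xw.T @ Xw
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            out[:, j] = -np.inf
            continue
        coef = np.linalg.solve(A, Xw.T @ Yw.T)  # p x G
        resid = Yw - (Xw @ coef).T
        rss = np.einsum("gi,gi->g", resid, resid)
        out[:, j] = -0.5 * (
            np.sum(np.log(lam)) + logdetA + (n - p) * np.log(np.maximum(rss, 1e-300))
        )
    return out


def estimate_consensus_correlation(
    matrix: ExpressionMatrix,
    design: DesignSpec,
    samples: SampleTable,
    grid_step: float = 0.005,
) -> float:
    """Estimate the consensus intra-subject correlation across genes.

    Each gene's correlation is estimated by REML under compound symmetry on a
    grid; the consensus is ``tanh`` of the 15%-trimmed mean of ``atanh`` of
    the per-gene estimates, clamped to (-0.99, 0.99).  Returns 0 with a
    warning when no subject contributes repeated samples.
    """
    samples.check_covers(matrix)
    meta = samples.subset(matrix.sample_ids)
    subjects = meta.subject.to_numpy()
    block_sizes = pd.Series(subjects).value_counts()
    if (block_sizes < 2).all():
        logger.warning("no subject with repeated samples; consensus rho set to 0")
        return 0.0
    if (block_sizes >= 2).sum() < 2:
        raise ParameterError("need >=2 subjects with >=2 samples to estimate rho")
    X, _ = build_design(meta, design)
    T, msize = _block_transform(subjects)
    Xt = T @ X
    Yt = matrix.values @ T.T
    m_max = int(block_sizes.max())
    lo = max(-0.9, -1.0 / (m_max - 1) + 1e-3)
    rhos = np.arange(lo, RHO_CLAMP, grid_step)
    ll = _reml_loglik_grid(Yt, Xt, msize, rhos)
    best = np.argmax(ll, axis=1)
    rho_g = rhos[best]
    # parabolic refinement for interior grid optima
    interior = (best > 0) & (best < len(rhos) - 1)
    b = best[interior]
    y0, y1, y2 = (ll[interior, b - 1], ll[interior, b], ll[interior, b + 1])
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    rho_g[interior] = rhos[b] + np.clip(shift, -1, 1) * grid_step
    rho_g = np.clip(rho_g, -RHO_CLAMP + 1e-6, RHO_CLAMP - 1e-6)
    consensus = float(np.tanh(trim_mean(np.arctanh(rho_g), 0.15)))
    return float(np.clip(consensus, -RHO_CLAMP, RHO_CLAMP))


def fit_gene_models(
    matrix: ExpressionMatrix,
    design: DesignSpec,
    samples: SampleTable,
    rho: float,
) -> pd.DataFrame:
    """Per-gene GLS under block compound-symmetry covariance.

    Returns a DEFit table indexed by gene with the sex contrast (log2FD,
    positive = male-higher), its unit standard error, the residual variance
    ``s2`` and residual degrees of freedom, plus the mean expression.
    With ``rho = 0`` the estimates collapse to ordinary least squares.
    """
    if not (-1 < rho < 1):
        raise ParameterError("rho must lie in (-1, 1)")
    samples.check_covers(matrix)
    meta = samples.subset(matrix.sample_ids)
    X, names = build_design(meta, design)
    n, p = X.shape
    if n <= p:
        raise ParameterError(f"{n} samples cannot identify {p} fixed effects")
    T, msize = _block_transform(meta.subject.to_numpy())
    lam = _eigenvalues(msize, rho)
    if (lam <= 0).any():
        raise ParameterError(f"rho={rho} incompatible with subject block sizes")
    sw = 1.0 / np.sqrt(lam)
    Xw = (T @ X) * sw[:, None]
    Yw = (matrix.values @ T.T) * sw[None, :]
    A = Xw.T @ Xw
    Ainv = np.linalg.inv(A)
    coef = Ainv @ (Xw.T @ Yw.T)  # p x G
    resid = Yw - (Xw @ coef).T
    rss = np.einsum("gi,gi->g", resid, resid)
    d_resid = n - p
    s2 = rss / d_resid
    sex_ix = names.index("sex_male")
    unit_se = np.sqrt(Ainv[sex_ix, sex_ix])
    fits = pd.DataFrame(
        {
            "log2FD": coef[sex_ix],
            "unit_se": unit_se,
            "stderr": np.sqrt(s2) * unit_se,
            "s2": s2,
            "df_resid": float(d_resid),
            "mean_expr": matrix.values.mean(axis=1),
        },
        index=pd.Index(matrix.gene_ids, name="gene"),
    )
    return fits


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex target)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Matches the first two moments of ``log(s2)`` using digamma/trigamma
    identities for the log of a scaled chi-square variable.  Returns
    ``(d0, s0_sq)``; ``d0`` is infinite when the observed spread of log
    variances is no larger than expected under equal true variances.
    """
    ok = s2 > 0
    if ok.sum() < 10:
        raise ParameterError("need >=10 genes with positive residual variance")
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = np.var(e, ddof=1) - np.mean(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return float(d0), float(s0_sq)


def ebayes_moderate(
    fits: pd.DataFrame, rho: float = 0.0
) -> tuple[pd.DataFrame, EBayesParams]:
    """Empirical-Bayes moderation of the per-gene sex contrast.

    Posterior variances shrink each gene's ``s2`` toward the prior scale:
    ``s2_post = (d0*s0_sq + d_g*s2_g) / (d0 + d_g)``.  The moderated t uses
    the posterior standard deviation and gains prior degrees of freedom:
    two-sided p on ``d0 + d_g`` dof, BH-adjusted across genes.
    """
    d0, s0_sq = estimate_variance_prior(
        fits["s2"].to_numpy(), fits["df_resid"].to_numpy()
    )
    s2 = fits["s2"].to_numpy()
    df = fits["df_resid"].to_numpy()
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    t_mod = fits["log2FD"].to_numpy() / (fits["unit_se"].to_numpy() * np.sqrt(s2_post))
    finite_df = np.minimum(df_total, 1e9)  # t(1e9) == normal to double precision
    p = 2.0 * t_dist.sf(np.abs(t_mod), finite_df)
    p = np.clip(p, 0.0, 1.0)
    _, p_bh, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame(
        {
            "log2FD": fits["log2FD"],
            "FD": np.exp2(fits["log2FD"]),
            "t": t_mod,
            "p": p,
            "p_bh": p_bh,
            "mean_expr": fits["mean_expr"],
            "s2_post": s2_post,
        },
        index=fits.index,
    )
    return table, EBayesParams(d0=d0, s0_sq=s0_sq, rho=rho)


def call_sex_de(
    table: pd.DataFrame,
    fd_threshold: float = DEFAULT_FD_THRESHOLD,
    p_tiers: tuple[float, ...] = DEFAULT_P_TIERS,
) -> pd.DataFrame:
    """Label sex-DE genes at each p tier and the threshold-free direction.

    male-DE at tier alpha: FD >= fd_threshold and p <= alpha; female-DE:
    FD <= 1/fd_threshold and p <= alpha.  Every gene with nonzero log2FD is
    additionally labeled male-higher or female-higher regardless of p; genes
    with log2FD exactly 0 belong to neither directional category.
    """
    if fd_threshold <= 1:
        raise ParameterError("fd_threshold must exceed 1")
    out = table.copy()
    fd = out["FD"].to_numpy()
    p = out["p"].to_numpy()
    direction = np.where(out["log2FD"] > 0, "male-higher",
                         np.where(out["log2FD"] < 0, "female-higher", ""))
    out["direction"] = direction
    for alpha in sorted(p_tiers):
        label = np.full(len(out), "", dtype=object)
        label[(fd >= fd_threshold) & (p <= alpha)] = "male-DE"
        label[(fd <= 1.0 / fd_threshold) & (p <= alpha)] = "female-DE"
        out[f"de_{alpha:g}"] = label
    return out


def run_de(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    covariates: list[str] | None = None,
    fd_threshold: float = DEFAULT_FD_THRESHOLD,
    p_tiers: tuple[float, ...] = DEFAULT_P_TIERS,
) -> tuple[pd.DataFrame, EBayesParams]:
    """Full differential-expression stage: impute covariates, estimate the
    consensus correlation, fit per-gene GLS, moderate, and call sex-DE."""
    design = DesignSpec(covariates=list(covariates or []))
    samples_imp, _ = impute_missing_covariates(samples)
    rho = estimate_consensus_correlation(matrix, design, samples_imp)
    fits = fit_gene_models(matrix, design, samples_imp, rho)
    table, params = ebayes_moderate(fits, rho=rho)
    table = call_sex_de(table, fd_threshold=fd_threshold, p_tiers=p_tiers)
    return table, params


def write_de_table(table: pd.DataFrame, path) -> None:
    df = table.copy()
    df.index.name = df.index.name or "gene"
    df.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False, na_values=[""])
    for col in ("log2FD", "FD", "t", "p", "p_bh", "mean_expr"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    if "direction" in df.columns:
        df["direction"] = df["direction"].fillna("")
    return df
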