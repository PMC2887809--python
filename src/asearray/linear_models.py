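"""SNP-wise linear models for allelic log-ratios.

For SNP *i* with log-ratios ``y_i`` across the N non-flagged arrays of one
material, fit ``y_i = X beta_i + e_i`` by ordinary least squares, where X is
a full-column-rank design matrix shared across SNPs (one coefficient per
mixture, or intercept + dye-orientation for dye-swap designs). Contrasts
``alpha_i = C' beta_i`` express comparisons of interest, e.g. each mixture
versus the balanced 50:50 baseline — which cancels systematic dye or
genotype effects that shift the baseline away from 0.

Per-SNP residual variances are then shrunk toward a shared prior estimated
across SNPs by empirical Bayes (moment matching of the log variances to a
scaled F distribution), giving moderated t-statistics with augmented degrees
of freedom and a log-odds (B) score used to rank SNPs by evidence of
allelic imbalance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

#: Safeguard: the prior degrees of freedom are capped here when the moment
#: estimate diverges (no excess variability among the sample variances).
MAX_PRIOR_DF = 1e7


@dataclass
class DesignMatrix:
    """Design matrix with labelled columns, aligned to a list of arrays."""

    X: np.ndarray
    columns: list[str]
    array_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.array_ids):
            raise ValueError("X rows must align with array_ids")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("X columns must align with column labels")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError(f"design matrix is rank deficient; columns: {self.columns}")


@dataclass
class SnpModelFit:
    """Per-SNP OLS results: coefficients, residual scale and covariance.

    ``unscaled_cov[g]`` is ``(X'X)^-1`` for SNP g (after any row drops), so
    the standard error of coefficient k is ``sqrt(unscaled_cov[g,k,k]) *
    sigma[g]``.
    """

    snp_ids: np.ndarray
    coefficients: np.ndarray      # (G, K)
    unscaled_cov: np.ndarray      # (G, K, K)
    sigma: np.ndarray             # (G,) residual SD; NaN when df == 0
    df_residual: np.ndarray       # (G,)
    column_labels: list[str]

    @property
    def unscaled_se(self) -> np.ndarray:
        return np.sqrt(np.diagonal(self.unscaled_cov, axis1=1, axis2=2))


@dataclass
class ModeratedStats:
    """Empirical-Bayes moderated statistics per SNP x contrast."""

    snp_ids: np.ndarray
    column_labels: list[str]
    coefficients: np.ndarray      # (G, L)
    t: np.ndarray                 # (G, L) moderated t
    p_value: np.ndarray           # (G, L)
    log_odds: np.ndarray          # (G, L) B statistic
    df_total: np.ndarray          # (G,)
    s2_post: np.ndarray           # (G,)
    df_prior: float
    s2_prior: float

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-form table: one row per SNP and contrast."""
        rows = []
        for li, lab in enumerate(self.column_labels):
            rows.append(pd.DataFrame({
                "snp_id": self.snp_ids,
                "contrast": lab,
                "estimate": self.coefficients[:, li],
                "t_moderated": self.t[:, li],
                "df_total": self.df_total,
                "p_value": self.p_value[:, li],
                "log_odds": self.log_odds[:, li],
            }))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design_matrix(sample_sheet: pd.DataFrame, design: str = "per_mixture") -> DesignMatrix:
    """Construct a design matrix from the sample sheet of one material.

    ``per_mixture``: one indicator column per mixture proportion (sorted
    labels), so each coefficient is that mixture's mean log-ratio.
    ``dye_swap``: an intercept column (the dye effect) plus a true-effect
    column coded +1 for standard and -1 for dye-swapped arrays.
    """
    materials = set(sample_sheet["material"])
    if len(materials) > 1:
        raise ValueError(f"sample sheet mixes materials {sorted(materials)}; fit them separately")
    array_ids = list(sample_sheet["array_id"])
    if design == "per_mixture":
        mixes = sorted(set(np.round(sample_sheet["mix_p"].astype(float), 6)))
        if any(math.isnan(m) for m in mixes):
            raise ValueError("per_mixture design requires mix_p for every array")
        labels = [f"mix_{int(round(m * 100)):03d}" for m in mixes]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicated mixture labels after rounding: {labels}")
        X = np.zeros((len(array_ids), len(mixes)))
        mix_vals = np.round(sample_sheet["mix_p"].astype(float), 6).to_numpy()
        for k, m in enumerate(mixes):
            X[mix_vals == m, k] = 1.0
        return DesignMatrix(X, labels, array_ids)
    if design == "dye_swap":
        dye = sample_sheet["dye"].to_numpy()
        bad = set(dye) - {"standard", "swapped"}
        if bad:
            raise ValueError(f"unknown dye orientation labels: {sorted(bad)}")
        X = np.column_stack([np.ones(len(dye)), np.where(dye == "standard", 1.0, -1.0)])
        return DesignMatrix(X, ["dye_effect", "true_effect"], array_ids)
    raise ValueError(f"unknown design {design!r}")


def pivot_m_matrix(summary: pd.DataFrame, value: str = "mean_M") -> pd.DataFrame:
    """Pivot a summary table into a SNP x array matrix of one quantity."""
    return summary.pivot(index="snp_id", columns="array_id", values=value)


# ---------------------------------------------------------------------------
# OLS fitting
# ---------------------------------------------------------------------------

def fit_snp_models(m_matrix: pd.DataFrame, design: DesignMatrix) -> SnpModelFit:
    """Ordinary least squares per SNP with row-wise deletion of missing arrays.

    ``m_matrix`` is SNP x array (columns must cover ``design.array_ids``);
    SNPs whose missingness leaves the design rank deficient are skipped with
    a warning. SNPs with zero residual degrees of freedom keep their
    coefficients but get an undefined residual scale (NaN).
    """
    Y = m_matrix.reindex(columns=design.array_ids).to_numpy(dtype=float)
    X = design.X
    G, N = Y.shape
    K = X.shape[1]
    present = np.isfinite(Y)

    coefs = np.full((G, K), np.nan)
    cov = np.full((G, K, K), np.nan)
    sigma = np.full(G, np.nan)
    dfres = np.zeros(G)
    keep = np.ones(G, dtype=bool)

    patterns, inverse = np.unique(present, axis=0, return_inverse=True)
    for pi, pat in enumerate(patterns):
        rows = np.flatnonzero(inverse == pi)
        Xs = X[pat]
        if Xs.shape[0] < K or np.linalg.matrix_rank(Xs) < K:
            logger.warning("skipping %d SNPs: design rank deficient after dropping missing arrays", rows.size)
            keep[rows] = False
            continue
        xtx_inv = np.linalg.inv(Xs.T @ Xs)
        beta = Y[np.ix_(rows, pat)] @ Xs @ xtx_inv.T
        resid = Y[np.ix_(rows, pat)] - beta @ Xs.T
        rss = np.einsum("ij,ij->i", resid, resid)
        d = Xs.shape[0] - K
        coefs[rows] = beta
        cov[rows] = xtx_inv
        dfres[rows] = d
        if d > 0:
            sigma[rows] = np.sqrt(rss / d)
        else:
            logger.warning("%d SNPs have zero residual df; residual scale undefined", rows.size)

    return SnpModelFit(
        snp_ids=m_matrix.index.to_numpy()[keep],
        coefficients=coefs[keep],
        unscaled_cov=cov[keep],
        sigma=sigma[keep],
        df_residual=dfres[keep],
        column_labels=list(design.columns),
    )


def make_baseline_contrasts(columns: list[str], baseline: str) -> tuple[np.ndarray, list[str]]:
    """All pairwise contrasts of each coefficient against a baseline column."""
    if baseline not in columns:
        raise ValueError(f"baseline {baseline!r} not among design columns {columns}")
    bi = columns.index(baseline)
    others = [c for c in columns if c != baseline]
    C = np.zeros((len(columns), len(others)))
    for li, c in enumerate(others):
        C[columns.index(c), li] = 1.0
        C[bi, li] = -1.0
    return C, [f"{c}_vs_{baseline}" for c in others]


def apply_contrasts(fit: SnpModelFit, C: np.ndarray, labels: list[str]) -> SnpModelFit:
    """Transform a fit to contrast space: alpha = C' beta.

    Unscaled covariances propagate as ``C' (X'X)^-1 C``. A zero column in C
    would yield a zero-variance contrast and is rejected.
    """
    C = np.asarray(C, dtype=float)
    if C.shape[0] != len(fit.column_labels):
        raise ValueError("contrast matrix rows must match design columns")
    if C.shape[1] != len(labels):
        raise ValueError("contrast labels must match contrast matrix columns")
    if (np.abs(C).sum(axis=0) == 0).any():
        raise ValueError("contrast matrix contains an all-zero column")
    alpha = fit.coefficients @ C
    cov = np.einsum("jk,gjl,lm->gkm", C, fit.unscaled_cov, C)
    return SnpModelFit(fit.snp_ids, alpha, cov, fit.sigma, fit.df_residual, list(labels))


# ---------------------------------------------------------------------------
# empirical Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if -dif / y < 1e-8:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match sample variances to a scaled F distribution.

    Matches the mean and variance of ``log(s2)`` given residual df to the
    density implied by a chi-square sampling distribution around an inverse
    chi-square prior; returns ``(df_prior, s2_prior)``. The prior df are
    capped at :data:`MAX_PRIOR_DF` when the moment estimate diverges.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        raise ValueError("need at least 2 positive sample variances to fit the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    evar = np.sum((e - emean) ** 2) / (n - 1) - np.mean(special.polygamma(1, df / 2.0))
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(evar)
        if not np.isfinite(df_prior) or df_prior > MAX_PRIOR_DF:
            df_prior = MAX_PRIOR_DF
        s2_prior = float(np.exp(emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0)))
    else:
        df_prior = MAX_PRIOR_DF
        s2_prior = float(np.exp(emean))
    return float(df_prior), s2_prior


def squeeze_variances(s2: np.ndarray, df: np.ndarray, df_prior: float, s2_prior: float) -> np.ndarray:
    """Posterior variances: weighted average of prior and sample variances."""
    if np.isinf(df_prior):
        return np.full_like(s2, s2_prior)
    return (df_prior * s2_prior + df * s2) / (df_prior + df)


def _tmixture_vector(t: np.ndarray, u: np.ndarray, df: np.ndarray,
                     proportion: float, v0_lim: tuple[float, float]) -> float:
    """Estimate the prior variance ratio v0 from the top fraction of |t|."""
    ok = np.isfinite(t)
    t, u, df = np.abs(t[ok]), u[ok], df[ok]
    ngenes = t.size
    ntarget = int(np.ceil(proportion / 2.0 * ngenes))
    if ntarget < 1 or ngenes == 0:
        return float(np.mean(v0_lim))
    p = max(ntarget / ngenes, proportion)
    max_df = df.max()
    smaller = df < max_df
    if smaller.any():
        log_tail = stats.t.logsf(t[smaller], df[smaller])
        t = t.copy()
        t[smaller] = stats.t.isf(np.exp(log_tail), max_df)
    order = np.argsort(t)[::-1][:ntarget]
    tsel = t[order]
    v1 = u[order] ** 2
    r = np.arange(1, ntarget + 1)
    p0 = 2.0 * stats.t.sf(tsel, max_df)
    ptarget = ((r - 0.5) / ngenes - (1.0 - p) * p0) / p
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if pos.any():
        qtarget = stats.t.isf(ptarget[pos] / 2.0, max_df)
        v0[pos] = v1[pos] * ((tsel[pos] / qtarget) ** 2 - 1.0)
    v0 = np.clip(v0, v0_lim[0], v0_lim[1])
    return float(v0.mean())


def empirical_bayes_moderate(
    fit: SnpModelFit,
    proportion: float = 0.01,
    prior_df: float | None = None,
    prior_var: float | None = None,
    stdev_coef_lim: tuple[float, float] = (0.1, 4.0),
) -> ModeratedStats:
    """Moderated t-statistics and log-odds via empirical-Bayes shrinkage.

    The shared hyperparameters ``(d0, s0^2)`` are estimated from all SNPs'
    residual variances by moment matching (overridable via ``prior_df`` /
    ``prior_var``, e.g. to force the no-shrinkage d0=0 or fully-pooled
    d0=inf limits). Each SNP's posterior variance is
    ``(d0 s0^2 + d_i s_i^2) / (d0 + d_i)``; moderated t has ``d0 + d_i``
    degrees of freedom. The B statistic is the log posterior odds of a real
    effect, computed with an assumed ``proportion`` of truly imbalanced SNPs
    and a prior effect variance estimated from the top |t| quantiles.
    """
    s2 = fit.sigma ** 2
    df = fit.df_residual
    usable = np.isfinite(s2) & (df > 0)
    if not usable.any() or np.nanmax(s2[usable] if usable.any() else s2) == 0:
        raise ValueError(
            "all residual variances are zero or undefined; the empirical-Bayes prior "
            "is degenerate — add noise or replicate arrays")
    if usable.sum() < 10:
        logger.warning("only %d SNPs inform the variance prior; estimates may be unstable",
                       int(usable.sum()))
    excluded = ~usable
    if excluded.any():
        logger.warning("%d SNPs excluded from moderation (zero residual df)", int(excluded.sum()))

    if prior_df is None or prior_var is None:
        est_d0, est_s20 = fit_f_dist(s2[usable], df[usable])
    else:
        est_d0, est_s20 = np.nan, np.nan
    d0 = float(prior_df) if prior_df is not None else est_d0
    s20 = float(prior_var) if prior_var is not None else est_s20

    # an infinite prior df is honoured exactly in the squeeze; only the
    # t-distribution df is capped at a large finite value
    s2_post = squeeze_variances(s2, df, d0, s20)
    df_total = np.minimum(df + d0, MAX_PRIOR_DF)
    u = fit.unscaled_se

    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.coefficients / (u * np.sqrt(s2_post)[:, None])
    t[excluded] = np.nan
    p = 2.0 * stats.t.sf(np.abs(t), df_total[:, None])

    L = t.shape[1]
    lods = np.full_like(t, np.nan)
    # v0 is a variance ratio (relative to sigma^2); the coefficient-sd
    # limits are converted to that scale via the median residual variance
    med_s2 = float(np.median(s2[usable]))
    v0_lim = (stdev_coef_lim[0] ** 2 / med_s2, stdev_coef_lim[1] ** 2 / med_s2)
    log_prior_odds = np.log(proportion / (1.0 - proportion))
    for li in range(L):
        v0 = _tmixture_vector(t[:, li], u[:, li], df_total, proportion, v0_lim)
        r = (u[:, li] ** 2 + v0) / (u[:, li] ** 2)
        t2 = t[:, li] ** 2
        if d0 >= MAX_PRIOR_DF:
            kernel = t2 * (1.0 - 1.0 / r) / 2.0
        else:
            kernel = (1.0 + df_total) / 2.0 * np.log((t2 + df_total) / (t2 / r + df_total))
        lods[:, li] = log_prior_odds - np.log(r) / 2.0 + kernel

    return ModeratedStats(
        snp_ids=fit.snp_ids,
        column_labels=list(fit.column_labels),
        coefficients=fit.coefficients,
        t=t,
        p_value=p,
        log_odds=lods,
        df_total=df_total,
        s2_post=s2_post,
        df_prior=d0,
        s2_prior=s20,
    )


# ---------------------------------------------------------------------------
# dye effects
# ---------------------------------------------------------------------------

def estimate_dye_effects(summary: pd.DataFrame, sample_sheet: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-SNP dye-effect (intercept) estimates from a dye-swap experiment.

    Fits the dye-swap linear model to each SNP's log-ratios and extracts the
    intercept, which measures the asymmetry of the log-ratios under dye
    swapping: a pure dye bias survives the swap while the allelic signal
    changes sign. Also summarizes the intensity trend by regressing the
    intercepts on the SNPs' mean A values.

    Returns ``(per-SNP DataFrame, trend summary dict)``.
    """
    design = build_design_matrix(sample_sheet, "dye_swap")
    m = pivot_m_matrix(summary, "mean_M")
    a = pivot_m_matrix(summary, "mean_A").reindex(columns=design.array_ids).mean(axis=1)
    fit = fit_snp_models(m, design)
    idx = fit.column_labels.index("dye_effect")
    se = fit.unscaled_se[:, idx] * fit.sigma
    per_snp = pd.DataFrame({
        "snp_id": fit.snp_ids,
        "dye_effect": fit.coefficients[:, idx],
        "se": se,
        "mean_A": a.reindex(fit.snp_ids).to_numpy(),
    })
    ok = np.isfinite(per_snp["dye_effect"]) & np.isfinite(per_snp["mean_A"])
    slope, intercept = np.polyfit(per_snp.loc[ok, "mean_A"], per_snp.loc[ok, "dye_effect"], 1)
    if per_snp.loc[ok, "dye_effect"].std() > 0 and per_snp.loc[ok, "mean_A"].std() > 0:
        r = np.corrcoef(per_snp.loc[ok, "mean_A"], per_snp.loc[ok, "dye_effect"])[0, 1]
    else:
        r = 0.0  # constant intercepts (e.g. bias-free noise-free data)
    trend = {
        "trend_slope": float(slope),
        "trend_intercept": float(intercept),
        "trend_r": float(r),
        "mean_abs_effect": float(np.abs(per_snp.loc[ok, "dye_effect"]).mean()),
    }
    return per_snp, trend
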