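"""Per-feature linear modelling for longitudinal two-group multi-omics.

Each feature (CpG M-value or gene log-CPM) is fitted to

    y = b0 + b_{d,t} * s + b_a * age + b_m * memory + b_c * viability

where ``s`` indexes the combined (group, timepoint) cell, so that the
coefficients ``b_{d,t}`` measure the effect of time within each group.
Repeated sampling of the same donor is absorbed by a single consensus
intra-donor correlation ``rho`` used in a generalized-least-squares fit
with block-equicorrelated errors. Count data additionally receive
mean-variance precision weights estimated from a lowess trend of
residual scale against average log-count. Residual variances are shrunk
toward a common prior by empirical-Bayes moderation and contrasts are
tested with moderated t-statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import digamma, polygamma

from .containers import NormFactors, OmicsMatrix, SampleTable, ValidationError
from .preprocess import log_cpm


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Sample x coefficient design with donor block labels.

    ``matrix`` holds an intercept, one indicator per observed
    (group, timepoint) cell except each group's reference timepoint, and
    one column per covariate. ``donor`` maps each sample to its block.
    """

    matrix: pd.DataFrame
    donor: pd.Series
    reference_time: str

    def __post_init__(self) -> None:
        x = self.matrix.to_numpy(dtype=float)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            bad = _collinear_columns(self.matrix)
            raise ValidationError(f"design is rank deficient; collinear columns: {bad}")
        if not self.matrix.index.equals(self.donor.index):
            raise ValidationError("design rows and donor labels misaligned")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_coef(self) -> int:
        return self.matrix.shape[1]

    @property
    def column_names(self) -> list[str]:
        return list(self.matrix.columns)

    def group_time_column(self, group: str, timepoint: str) -> str | None:
        """Column name for a (group, time) cell; None for the reference."""
        name = f"{group}:{timepoint}"
        if name in self.matrix.columns:
            return name
        if timepoint == self.reference_time:
            return None
        raise ValidationError(f"no design column for ({group}, {timepoint})")

    def contrast(self, group: str, time_b: str, time_a: str) -> np.ndarray:
        """Contrast vector for (time_b - time_a) within ``group``."""
        c = np.zeros(self.n_coef)
        for t, sign in ((time_b, 1.0), (time_a, -1.0)):
            col = self.group_time_column(group, t)
            if col is not None:
                c[self.matrix.columns.get_loc(col)] += sign
        if not np.any(c):
            raise ValidationError(
                f"contrast {time_b}-{time_a} in {group} is identically zero"
            )
        return c


def _collinear_columns(matrix: pd.DataFrame) -> list[str]:
    """Names of columns implicated in rank deficiency (via QR pivoting)."""
    x = matrix.to_numpy(dtype=float)
    _, r, piv = linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    dropped = piv[len(diag[diag > tol]):]
    return [matrix.columns[j] for j in sorted(dropped)]


def build_design(
    samples: SampleTable,
    covariates: list[str] | None = None,
    reference_time: str = "T1",
) -> DesignMatrix:
    """Build the group x time design with appended covariate columns.

    One indicator column is created per (group, timepoint) combination
    observed in the data, dropping each group's ``reference_time`` cell
    (groups missing a timepoint simply contribute no column for it).
    """
    covariates = list(covariates or [])
    df = samples.data
    if reference_time not in set(df["timepoint"]):
        raise ValidationError(f"reference time {reference_time!r} not observed")
    for cov in covariates:
        if cov not in df.columns:
            raise ValidationError(f"covariate {cov!r} missing from sample table")
        if not np.issubdtype(df[cov].dtype, np.number):
            raise ValidationError(f"covariate {cov!r} is not numeric")

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    for group in sorted(df["group"].unique()):
        in_group = df["group"] == group
        times = [t for t in samples.timepoints if ((df["timepoint"] == t) & in_group).any()]
        for t in times:
            if t == reference_time:
                continue
            cols[f"{group}:{t}"] = (in_group & (df["timepoint"] == t)).to_numpy(float)
    for cov in covariates:
        cols[cov] = df[cov].to_numpy(float)

    matrix = pd.DataFrame(cols, index=df.index)
    return DesignMatrix(matrix, df["donor"], reference_time)


# ---------------------------------------------------------------------------
# consensus intra-donor correlation
# ---------------------------------------------------------------------------

def _block_matrix(donor: pd.Series) -> np.ndarray:
    """Indicator B with B[i, j] = 1 iff samples i, j share a donor."""
    d = donor.to_numpy()
    return (d[:, None] == d[None, :]).astype(float)


def estimate_block_correlation(
    data: OmicsMatrix, design: DesignMatrix, trim: float = 0.05
) -> float:
    """Consensus intra-donor correlation from per-feature OLS residuals.

    For every feature the within-donor cross-products of OLS residuals are
    compared with the residual sum of squares; the implied per-feature
    correlation (corrected for the bias the hat-matrix projection
    introduces in both quantities) is Fisher-z transformed, trimmed-mean
    averaged over features, and transformed back.
    """
    x = design.matrix.to_numpy(dtype=float)
    y = data.to_numpy()
    if not data.sample_ids.equals(design.matrix.index):
        raise ValidationError("data samples and design rows misaligned")
    n, p = x.shape
    b = _block_matrix(design.donor)
    pair = b - np.eye(n)  # off-diagonal within-donor indicator
    n_pairs = pair.sum() / 2.0
    if n_pairs == 0:
        warnings.warn("no donor with >= 2 samples; consensus rho set to 0", stacklevel=2)
        return 0.0

    h = x @ np.linalg.solve(x.T @ x, x.T)
    m = np.eye(n) - h
    # moments of the residual quadratic forms, linear in the true rho
    c1 = np.trace(pair @ m) / 2.0
    c2 = np.trace(pair @ m @ b @ m) / 2.0
    c3 = float(n - p)
    c4 = np.trace(m @ b)

    resid = y @ m.T  # features x samples (m symmetric)
    q = 0.5 * np.einsum("gi,ij,gj->g", resid, pair, resid)
    v = np.einsum("gi,gi->g", resid, resid)
    ok = v > 0
    t = q[ok] / v[ok]
    denom = (c2 - c1) - t * (c4 - c3)
    rho_g = np.where(np.abs(denom) > 1e-12, (t * c3 - c1) / denom, 0.0)

    max_block = int(design.donor.value_counts().max())
    lo = -1.0 / (max_block - 1) + 1e-6
    rho_g = np.clip(rho_g, max(lo, -0.99), 0.99)
    z = np.arctanh(rho_g)
    zbar = stats.trim_mean(z, trim)
    return float(np.tanh(zbar))


# ---------------------------------------------------------------------------
# precision weights (voom analogue)
# ---------------------------------------------------------------------------

def voom_weights(
    counts: OmicsMatrix,
    design: DesignMatrix,
    factors: NormFactors,
    span: float = 0.5,
) -> np.ndarray:
    """Mean-variance precision weights for count data.

    Ordinary least squares is fitted per gene on log-CPM; the square root
    of the residual standard deviation is smoothed against average
    log2 count with lowess, and each observation's weight is the
    trend value at its fitted log-count raised to the power -4.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if counts.kind != "count":
        raise ValidationError(f"expected counts, got kind={counts.kind!r}")
    x = design.matrix.to_numpy(dtype=float)
    n, p = x.shape
    if n - p < 1:
        raise ValidationError("no residual degrees of freedom for the variance trend")

    nf = factors.reindex(counts.sample_ids)
    eff_lib = nf.lib_size * nf.factors
    y = np.log2((counts.to_numpy() + 0.5) / (eff_lib + 1.0) * 1e6)

    coef, _, _, _ = np.linalg.lstsq(x, y.T, rcond=None)
    fitted = (x @ coef).T
    rss = ((y - fitted) ** 2).sum(axis=1)
    sigma = np.sqrt(rss / (n - p))

    n_genes = y.shape[0]
    if n_genes < 50:
        warnings.warn("too few genes to fit a variance trend; uniform weights", stacklevel=2)
        return np.ones_like(y)

    sx = y.mean(axis=1) + np.mean(np.log2(eff_lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    lo = lowess(sy, sx, frac=span, it=3, return_sorted=True)
    lx, ly = lo[:, 0], lo[:, 1]

    fitted_logcount = fitted + np.log2(eff_lib + 1.0)[None, :] - np.log2(1e6)
    pred = np.interp(fitted_logcount, lx, ly)  # clamps outside the range
    pred = np.clip(pred, 1e-6, None)
    return pred ** -4.0


# ---------------------------------------------------------------------------
# GLS fits
# ---------------------------------------------------------------------------

@dataclass
class FeatureFits:
    """Per-feature GLS fit results.

    coef: features x p coefficient estimates; xtx_inv: features x p x p
    unscaled coefficient covariances; sigma2: residual variances;
    df_resid: residual degrees of freedom; rho: the equicorrelation used.
    """

    feature_ids: pd.Index
    coef_names: list[str]
    coef: np.ndarray
    xtx_inv: np.ndarray
    sigma2: np.ndarray
    df_resid: float
    rho: float
    moderation: "Moderation | None" = None


def fit_feature_models(
    data: OmicsMatrix,
    design: DesignMatrix,
    rho: float = 0.0,
    weights: np.ndarray | None = None,
) -> FeatureFits:
    """Generalized least squares per feature with equicorrelated donors.

    The error covariance is block-diagonal with unit diagonal and ``rho``
    off-diagonal within donor blocks, scaled elementwise by 1/weights.
    With ``rho = 0`` and unit weights this reduces exactly to OLS.
    """
    if not data.sample_ids.equals(design.matrix.index):
        raise ValidationError("data samples and design rows misaligned")
    x = design.matrix.to_numpy(dtype=float)
    y = data.to_numpy()
    n, p = x.shape
    if n - p < 1:
        raise ValidationError("no residual degrees of freedom")

    b = _block_matrix(design.donor)
    corr = (1.0 - rho) * np.eye(n) + rho * b
    try:
        chol = linalg.cholesky(corr, lower=True)
    except linalg.LinAlgError as err:
        raise ValidationError(
            f"equicorrelation rho={rho} is not positive definite for the donor blocks"
        ) from err

    n_feat = y.shape[0]
    if weights is None:
        xw = linalg.solve_triangular(chol, x, lower=True)
        yw = linalg.solve_triangular(chol, y.T, lower=True).T
        xtx_inv_one = np.linalg.inv(xw.T @ xw)
        coef = yw @ xw @ xtx_inv_one  # (G, p)
        resid = yw - coef @ xw.T
        rss = np.einsum("gi,gi->g", resid, resid)
        xtx_inv = np.broadcast_to(xtx_inv_one, (n_feat, p, p))
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != y.shape:
            raise ValidationError(
                f"weights shape {weights.shape} does not match data {y.shape}"
            )
        if np.any(weights <= 0):
            raise ValidationError("weights must be positive")
        sw = np.sqrt(weights)
        coef = np.empty((n_feat, p))
        xtx_inv = np.empty((n_feat, p, p))
        rss = np.empty(n_feat)
        for g in range(n_feat):
            xg = linalg.solve_triangular(chol, sw[g][:, None] * x, lower=True)
            yg = linalg.solve_triangular(chol, sw[g] * y[g], lower=True)
            xtx_inv_g = np.linalg.inv(xg.T @ xg)
            cg = xtx_inv_g @ (xg.T @ yg)
            rg = yg - xg @ cg
            coef[g] = cg
            xtx_inv[g] = xtx_inv_g
            rss[g] = rg @ rg

    df_resid = float(n - p)
    sigma2 = rss / df_resid
    return FeatureFits(
        feature_ids=data.feature_ids,
        coef_names=design.column_names,
        coef=coef,
        xtx_inv=xtx_inv,
        sigma2=sigma2,
        df_resid=df_resid,
        rho=rho,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

@dataclass
class Moderation:
    """Empirical-Bayes variance moderation parameters and shrunk variances."""

    df_prior: float
    s2_prior: float
    s2_post: np.ndarray


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_scaled_f(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log residual variances to a scaled F distribution.

    Returns (df_prior, s2_prior); df_prior may be +inf when the observed
    spread of log variances is no larger than the chi-square sampling
    spread alone.
    """
    s2 = np.clip(np.asarray(sigma2, dtype=float), 1e-300, None)
    if s2.size < 2:
        raise ValidationError("need at least 2 features to moderate variances")
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if e_var > 0:
        df_prior = 2.0 * _trigamma_inverse(e_var)
        s2_prior = float(np.exp(e_mean + digamma(df_prior / 2.0) - np.log(df_prior / 2.0)))
    else:
        df_prior = np.inf
        s2_prior = float(np.exp(e_mean))
    return df_prior, s2_prior


def ebayes_moderate(
    fits: FeatureFits,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> Moderation:
    """Shrink per-feature variances toward an empirical-Bayes prior.

    The prior degrees of freedom and variance are estimated by matching
    the first two moments of log s_g^2 to a scaled F distribution
    (trigamma inversion), unless supplied. The posterior variance is the
    df-weighted average s2_post = (d0 s0^2 + d_g s_g^2) / (d0 + d_g);
    prior_df=0 disables shrinkage and prior_df=inf replaces every
    variance by the prior.
    """
    dg = fits.df_resid
    if prior_df is None or prior_var is None:
        est_df, est_var = fit_scaled_f(fits.sigma2, dg)
        d0 = est_df if prior_df is None else prior_df
        s02 = est_var if prior_var is None else prior_var
    else:
        d0, s02 = prior_df, prior_var

    if np.isinf(d0):
        s2_post = np.full_like(fits.sigma2, s02)
    elif d0 == 0:
        s2_post = fits.sigma2.copy()
    else:
        s2_post = (d0 * s02 + dg * fits.sigma2) / (d0 + dg)
    mod = Moderation(df_prior=d0, s2_prior=s02, s2_post=s2_post)
    fits.moderation = mod
    return mod


# ---------------------------------------------------------------------------
# contrast testing
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    """Per-feature contrast estimates with moderated statistics.

    ``table`` is indexed by feature with columns estimate, se, t, p,
    adj_p and optionally delta_beta (methylation contrasts only).
    """

    table: pd.DataFrame
    contrast_name: str
    rho: float
    df_prior: float
    s2_prior: float
    df_total: float

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature")


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_contrast(
    fits: FeatureFits,
    contrast: np.ndarray,
    name: str = "contrast",
    moderation: Moderation | None = None,
) -> DifferentialResult:
    """Test c'beta = 0 per feature with a moderated t-statistic."""
    c = np.asarray(contrast, dtype=float)
    if c.shape != (len(fits.coef_names),):
        raise ValidationError(
            f"contrast length {c.size} != {len(fits.coef_names)} coefficients"
        )
    mod = moderation or fits.moderation
    if mod is None:
        mod = ebayes_moderate(fits)

    est = fits.coef @ c
    var_unit = np.einsum("i,gij,j->g", c, fits.xtx_inv, c)
    se = np.sqrt(var_unit * mod.s2_post)
    df_total = fits.df_resid + mod.df_prior
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(se > 0, p, 1.0)

    table = pd.DataFrame(
        {"estimate": est, "se": se, "t": t, "p": p, "adj_p": bh_adjust(p)},
        index=fits.feature_ids,
    )
    return DifferentialResult(
        table=table,
        contrast_name=name,
        rho=fits.rho,
        df_prior=mod.df_prior,
        s2_prior=mod.s2_prior,
        df_total=float(df_total) if np.isfinite(df_total) else np.inf,
    )


def mean_beta_difference(
    beta: OmicsMatrix,
    samples: SampleTable,
    group: str,
    time_a: str,
    time_b: str,
) -> pd.Series:
    """Per-CpG difference of group-mean beta values, time_b minus time_a."""
    if beta.kind != "beta":
        raise ValidationError(f"expected beta values, got kind={beta.kind!r}")
    df = samples.aligned_to(beta).data
    sel_a = (df["group"] == group) & (df["timepoint"] == time_a)
    sel_b = (df["group"] == group) & (df["timepoint"] == time_b)
    if not sel_a.any() or not sel_b.any():
        raise ValidationError(
            f"group {group!r} has no samples at {time_a!r} or {time_b!r}"
        )
    x = beta.to_numpy()
    d = x[:, sel_b.to_numpy()].mean(axis=1) - x[:, sel_a.to_numpy()].mean(axis=1)
    return pd.Series(d, index=beta.feature_ids, name="delta_beta")


def activation_contrast(
    counts: OmicsMatrix,
    samples: SampleTable,
    activation_level: str = "activation_level",
    covariates: list[str] | None = None,
    fdr_max: float = 0.05,
) -> DifferentialResult:
    """Genes affected by in vitro activation, adjusting for activation level.

    Fits the standard machinery with a resting/activated indicator plus
    the per-sample activation level as covariate; features with
    BH-adjusted p <= ``fdr_max`` carry ``significant=True``.
    """
    from .preprocess import tmm_factors

    df = samples.aligned_to(counts).data
    if "state" not in df.columns:
        raise ValidationError("sample table has no 'state' column")
    states = sorted(df["state"].unique())
    if len(states) < 2:
        raise ValidationError(f"need both resting and activated samples, found {states}")
    if activation_level not in df.columns:
        raise ValidationError(f"missing activation level column {activation_level!r}")

    covariates = list(covariates or [])
    cols = {"intercept": np.ones(len(df)), "activated": (df["state"] == "activated").to_numpy(float)}
    cols[activation_level] = df[activation_level].to_numpy(float)
    for cov in covariates:
        cols[cov] = df[cov].to_numpy(float)
    design = DesignMatrix(
        pd.DataFrame(cols, index=df.index), df["donor"], reference_time="n/a"
    )

    factors = tmm_factors(counts)
    weights = voom_weights(counts, design, factors)
    logcpm = log_cpm(counts, factors)
    rho = estimate_block_correlation(logcpm, design)
    fits = fit_feature_models(logcpm, design, rho=rho, weights=weights)
    ebayes_moderate(fits)
    c = np.zeros(design.n_coef)
    c[design.matrix.columns.get_loc("activated")] = 1.0
    result = test_contrast(fits, c, name="activated-resting")
    result.table["significant"] = result.table["adj_p"] <= fdr_max
    return result
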