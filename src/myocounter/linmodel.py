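"""Precision-weighted linear modelling of log2-CPM expression.

The model chain: a no-intercept design with one indicator column per disease
subtype plus treatment-coded cartridge and conservation covariates; a
mean-variance trend fitted on log2-CPM residual standard deviations giving
per-observation precision weights; a consensus within-patient correlation
estimated by restricted maximum likelihood under a random-intercept model and
pooled across genes by a trimmed mean on the atanh scale; per-gene generalized
least squares with the block-structured correlation; the six pairwise subtype
contrasts; and empirical-Bayes moderation of the residual variances with
moderated t and F statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ValidationError
from .normalize import NormalizationFactors
from .rcc import CountMatrix, SUBTYPES
from .simulate import COMPARISON_PAIRS, COMPARISONS


@dataclass
class DesignMatrix:
    """Samples x p design with group-means subtype coding and treatment-coded
    nuisance covariates."""

    matrix: pd.DataFrame  # index: sample_id
    subtype_columns: list[str]
    nuisance_columns: list[str]

    @property
    def column_names(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass
class VoomObject:
    """log2-CPM expression with matching precision weights and the fitted
    sqrt-sd vs log2-count trend."""

    E: pd.DataFrame  # genes x samples
    weights: np.ndarray  # same shape, > 0
    design: DesignMatrix
    trend_x: np.ndarray
    trend_y: np.ndarray
    log2_effective_libsize: pd.Series


@dataclass
class ConsensusCorrelation:
    rho_c: float
    per_gene_atanh: pd.Series


@dataclass
class LinearFit:
    beta: pd.DataFrame  # genes x p
    cov_unscaled: np.ndarray  # genes x p x p
    stdev_unscaled: pd.DataFrame  # genes x p
    sigma: pd.Series  # gene-wise residual sd
    df_residual: float
    design: DesignMatrix
    rho_c: float


@dataclass
class ContrastFit:
    contrast_matrix: pd.DataFrame  # p x 6
    log2fc: pd.DataFrame  # genes x 6
    u_contrast: pd.DataFrame  # genes x 6 unscaled stdevs
    cov_contrast: np.ndarray  # genes x 6 x 6 unscaled covariances
    fit: LinearFit


@dataclass
class EBayesStats:
    d0: float
    s0_sq: float
    s_post_sq: pd.Series
    t_mod: pd.DataFrame
    p_t: pd.DataFrame
    F: pd.Series
    p_F: pd.Series
    df_residual: float
    df_total: float
    f_rank: int


# -- design ----------------------------------------------------------------------


def build_design(sheet: pd.DataFrame) -> DesignMatrix:
    """Group-means subtype coding (no intercept) with treatment-coded cartridge
    and conservation columns; first observed level is the reference.  Raises on
    rank deficiency, naming the aliased columns."""
    subtype_levels = [s for s in SUBTYPES if s in set(sheet["subtype"])]
    cols: dict[str, np.ndarray] = {}
    for level in subtype_levels:
        cols[level] = (sheet["subtype"] == level).to_numpy(dtype=float)
    nuisance: list[str] = []
    for covariate in ("cartridge", "conservation"):
        levels = list(dict.fromkeys(sheet[covariate]))
        for level in levels[1:]:  # first observed level is reference
            name = f"{covariate}[{level}]"
            cols[name] = (sheet[covariate] == level).to_numpy(dtype=float)
            nuisance.append(name)
    x = pd.DataFrame(cols, index=pd.Index(sheet["sample_id"], name="sample_id"))
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        aliased = []
        xv = x.to_numpy()
        for j, name in enumerate(x.columns):
            reduced = np.delete(xv, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                aliased.append(name)
        raise ValidationError(f"design matrix is rank deficient; aliased columns: {aliased}")
    return DesignMatrix(matrix=x, subtype_columns=subtype_levels, nuisance_columns=nuisance)


# -- voom ------------------------------------------------------------------------


def voom_transform(
    m: CountMatrix,
    factors: NormalizationFactors,
    design: DesignMatrix,
    span: float = 0.5,
) -> VoomObject:
    """Mean-variance modelling of log2-CPM counts.

    Per-gene least squares on the design yields residual standard deviations;
    their square roots are smoothed against average log2 count by locally
    weighted regression (``span``), and each fitted observation is mapped
    through the trend to a predicted sqrt-sd whose inverse fourth power is the
    precision weight.  Only endogenous probes enter the returned object.
    """
    if m.scale != "raw":
        raise ValidationError("voom_transform expects raw counts")
    endo = m.values.loc[m.class_mask("Endogenous").to_numpy()]
    x = design.matrix.to_numpy(dtype=float)
    n, p = x.shape
    if list(design.matrix.index) != list(m.values.columns):
        raise ValidationError("design rows do not match count matrix columns")
    if n < p + 1:
        raise ValidationError(f"need >= {p + 1} samples for {p} design columns")

    eff = factors.effective_library_size().reindex(m.values.columns).to_numpy(dtype=float)
    counts = endo.to_numpy(dtype=float)
    e = np.log2((counts + 0.5) / (eff + 1.0)[None, :] * 1e6)

    pinv_x = np.linalg.pinv(x)
    beta = e @ pinv_x.T  # genes x p
    fitted = beta @ x.T
    resid = e - fitted
    s2 = (resid ** 2).sum(axis=1) / (n - p)
    sqrt_sd = s2 ** 0.25

    log2_lib = np.log2(eff + 1.0)
    amean = e.mean(axis=1)
    sx = amean + log2_lib.mean() - math.log2(1e6)  # average log2 count
    smoothed = lowess(sqrt_sd, sx, frac=span, return_sorted=True)
    trend_x, inverse = np.unique(smoothed[:, 0], return_inverse=True)
    trend_y = np.bincount(inverse, weights=smoothed[:, 1]) / np.bincount(inverse)

    fitted_logcount = fitted + (log2_lib - math.log2(1e6))[None, :]
    predicted = np.interp(fitted_logcount, trend_x, trend_y)
    predicted = np.maximum(np.abs(predicted), 1e-6)
    weights = predicted ** -4.0

    return VoomObject(
        E=pd.DataFrame(e, index=endo.index, columns=endo.columns),
        weights=weights,
        design=design,
        trend_x=trend_x,
        trend_y=trend_y,
        log2_effective_libsize=pd.Series(log2_lib, index=m.values.columns),
    )


# -- batched GLS machinery -------------------------------------------------------


def _block_indicator(blocks: list) -> np.ndarray:
    b = np.asarray(blocks)
    same = b[:, None] == b[None, :]
    np.fill_diagonal(same, False)
    return same


def _batched_gls(
    y: np.ndarray, w: np.ndarray, x: np.ndarray, r_corr: np.ndarray,
    want_cov: bool = True,
):
    """Generalized least squares for every gene at once.

    Observation covariance per gene: sigma_g^2 * D_g^{-1/2} R D_g^{-1/2} with
    D_g = diag(w_g) and R the block correlation (shared across genes).
    Returns beta, unscaled covariance (X' V^-1 X)^-1, the whitened residual
    quadratic form q, log|R| and log|X' V^-1 X| for REML use.
    """
    n, p = x.shape
    try:
        np.linalg.cholesky(r_corr)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("implied block correlation matrix is not positive definite") from exc
    r_inv = np.linalg.inv(r_corr)
    sign, logdet_r = np.linalg.slogdet(r_corr)
    sw = np.sqrt(w)
    xw = sw[:, :, None] * x[None, :, :]  # G x n x p
    yw = sw * y
    byw = yw @ r_inv.T  # G x n
    bxw = np.einsum("nm,gmp->gnp", r_inv, xw, optimize=True)
    a = np.einsum("gnp,gnq->gpq", xw, bxw, optimize=True)  # X' V^-1 X
    b = np.einsum("gnp,gn->gp", xw, byw, optimize=True)
    beta = np.linalg.solve(a, b[..., None])[..., 0]
    ytby = np.einsum("gn,gn->g", yw, byw, optimize=True)
    q = ytby - np.einsum("gp,gp->g", beta, b, optimize=True)
    q = np.maximum(q, 0.0)
    sign_a, logdet_a = np.linalg.slogdet(a)
    cov = np.linalg.inv(a) if want_cov else None
    return beta, cov, q, logdet_r, logdet_a


def estimate_consensus_correlation(
    v: VoomObject,
    design: DesignMatrix,
    blocks: list,
    trim: float = 0.15,
    grid_size: int = 25,
) -> ConsensusCorrelation:
    """Consensus within-block (within-patient) correlation.

    Per gene, the within-block correlation of a random-intercept model on
    weighted residuals is estimated by restricted maximum likelihood over a
    grid on the atanh scale with parabolic refinement; the consensus is the
    trimmed-mean back-transform across genes.
    """
    same = _block_indicator(blocks)
    if not same.any():
        warnings.warn("no block with >= 2 samples; consensus correlation set to 0")
        zeros = pd.Series(0.0, index=v.E.index)
        return ConsensusCorrelation(rho_c=0.0, per_gene_atanh=zeros)
    x = design.matrix.to_numpy(dtype=float)
    n, p = x.shape
    y = v.E.to_numpy(dtype=float)
    w = v.weights
    # symmetric search range keeps flat likelihoods unbiased; the lower bound
    # shrinks when large blocks would make I + rho*S indefinite
    max_block = int(pd.Series(blocks).value_counts().max())
    lo = max(-0.95, -1.0 / (max_block - 1) + 0.05)
    z_grid = np.linspace(math.atanh(lo), math.atanh(0.95), grid_size)
    rho_grid = np.tanh(z_grid)
    ll = np.full((grid_size, y.shape[0]), -np.inf)
    for i, rho in enumerate(rho_grid):
        r_corr = np.eye(n) + rho * same
        try:
            _, _, q, logdet_r, logdet_a = _batched_gls(y, w, x, r_corr, want_cov=False)
        except ValidationError:
            continue
        with np.errstate(divide="ignore"):
            ll[i] = -0.5 * ((n - p) * np.log(q / (n - p)) + logdet_r + logdet_a)

    best = np.argmax(ll, axis=0)
    z_hat = z_grid[best]
    # parabolic refinement on the atanh scale for interior optima
    interior = (best > 0) & (best < grid_size - 1)
    idx = np.where(interior)[0]
    if idx.size:
        g = best[idx]
        y0, y1, y2 = ll[g - 1, idx], ll[g, idx], ll[g + 1, idx]
        denom = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        step = z_grid[1] - z_grid[0]
        z_hat[idx] = z_grid[g] + np.clip(shift, -1.0, 1.0) * step
    per_gene = pd.Series(z_hat, index=v.E.index, name="atanh_rho")
    rho_c = float(np.tanh(stats.trim_mean(z_hat, proportiontocut=trim)))
    return ConsensusCorrelation(rho_c=rho_c, per_gene_atanh=per_gene)


def fit_linear_models(
    v: VoomObject, design: DesignMatrix, rho_c: float = 0.0, blocks: list | None = None
) -> LinearFit:
    """Per-gene GLS with covariance = block correlation ``rho_c`` between
    same-patient samples and per-observation variances 1/W.  With rho_c = 0
    this reduces to weighted least squares."""
    x = design.matrix.to_numpy(dtype=float)
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise ValidationError("design matrix must be full rank")
    y = v.E.to_numpy(dtype=float)
    if blocks is not None and rho_c != 0.0:
        same = _block_indicator(blocks)
        r_corr = np.eye(n) + rho_c * same
    else:
        r_corr = np.eye(n)
    beta, cov, q, _, _ = _batched_gls(y, v.weights, x, r_corr)
    sigma = np.sqrt(q / (n - p))
    u = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    genes = v.E.index
    cols = design.column_names
    return LinearFit(
        beta=pd.DataFrame(beta, index=genes, columns=cols),
        cov_unscaled=cov,
        stdev_unscaled=pd.DataFrame(u, index=genes, columns=cols),
        sigma=pd.Series(sigma, index=genes, name="sigma"),
        df_residual=float(n - p),
        design=design,
        rho_c=float(rho_c),
    )


# -- contrasts and moderation ----------------------------------------------------


def make_contrast_matrix(design: DesignMatrix) -> pd.DataFrame:
    """The six pairwise subtype-difference contrasts as a p x 6 matrix."""
    missing = [s for s in SUBTYPES if s not in design.subtype_columns]
    if missing:
        raise ValidationError(f"missing subtype levels in design: {missing}")
    c = pd.DataFrame(0.0, index=design.column_names, columns=list(COMPARISONS))
    for (a, b), name in zip(COMPARISON_PAIRS, COMPARISONS):
        c.loc[a, name] = 1.0
        c.loc[b, name] = -1.0
    return c


def apply_contrasts(fit: LinearFit) -> ContrastFit:
    c = make_contrast_matrix(fit.design)
    cv = c.to_numpy()
    log2fc = fit.beta.to_numpy() @ cv
    cov_contrast = np.einsum("pk,gpq,ql->gkl", cv, fit.cov_unscaled, cv, optimize=True)
    u = np.sqrt(np.maximum(np.diagonal(cov_contrast, axis1=1, axis2=2), 0.0))
    genes = fit.beta.index
    return ContrastFit(
        contrast_matrix=c,
        log2fc=pd.DataFrame(log2fc, index=genes, columns=c.columns),
        u_contrast=pd.DataFrame(u, index=genes, columns=c.columns),
        cov_contrast=cov_contrast,
        fit=fit,
    )


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y <= 0:
        raise ValidationError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif / x) < 1e-10:
            break
    return x


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log s^2 to a scaled-F prior; returns (prior df d0, s0^2)."""
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return d0, s0_sq


def ebayes_moderate(cf: ContrastFit, fit: LinearFit, prior_df: float | None = None) -> EBayesStats:
    """Empirical-Bayes variance moderation with moderated t and F statistics.

    ``prior_df`` overrides the estimated prior degrees of freedom (0 recovers
    ordinary per-gene t statistics; inf fully pools the variances).  The F
    statistic is the quadratic form of the six (correlated) contrast estimates
    in their unscaled covariance, which orthogonalizes the contrast space; its
    numerator degrees of freedom equal the contrast-space rank.
    """
    d = fit.df_residual
    if d <= 0:
        raise ValidationError("residual degrees of freedom must be positive")
    s2 = fit.sigma.to_numpy(dtype=float) ** 2
    zero = s2 <= 0
    if zero.any():
        positive = s2[~zero]
        if positive.size == 0:
            raise ValidationError("all residual variances are zero")
        repl = float(np.quantile(positive, 0.05))
        warnings.warn(f"{int(zero.sum())} genes with zero residual sd; replaced by 5th percentile")
        s2 = np.where(zero, repl, s2)

    if prior_df is None:
        d0, s0_sq = _fit_f_dist(s2, d)
    else:
        d0 = float(prior_df)
        s0_sq = float(np.exp(np.mean(np.log(s2))))  # geometric-mean prior scale

    if math.isinf(d0):
        s_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d

    fc = cf.log2fc.to_numpy()
    u = cf.u_contrast.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fc / (u * np.sqrt(s_post)[:, None])
    t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
    if math.isinf(df_total):
        p_t = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p_t = 2.0 * stats.t.sf(np.abs(t), df=df_total)

    # moderated F over the contrast space
    cov = cf.cov_contrast
    eigvals, eigvecs = np.linalg.eigh(cov)
    tol = np.max(eigvals, axis=1, keepdims=True) * 1e-10
    keep = eigvals > tol
    ranks = keep.sum(axis=1)
    rank = int(np.min(ranks))
    inv_eig = np.where(keep, 1.0 / np.where(keep, eigvals, 1.0), 0.0)
    proj = np.einsum("gkl,gl->gk", np.transpose(eigvecs, (0, 2, 1)), fc, optimize=True)
    quad = (proj ** 2 * inv_eig).sum(axis=1)
    f_stat = quad / (ranks * s_post)
    if math.isinf(df_total):
        p_f = stats.chi2.sf(f_stat * ranks, df=ranks)
    else:
        p_f = stats.f.sf(f_stat, ranks, df_total)

    genes = cf.log2fc.index
    cols = cf.log2fc.columns
    return EBayesStats(
        d0=float(d0),
        s0_sq=float(s0_sq),
        s_post_sq=pd.Series(s_post, index=genes, name="s_post_sq"),
        t_mod=pd.DataFrame(t, index=genes, columns=cols),
        p_t=pd.DataFrame(p_t, index=genes, columns=cols),
        F=pd.Series(f_stat, index=genes, name="F"),
        p_F=pd.Series(p_f, index=genes, name="p_F"),
        df_residual=d,
        df_total=float(df_total) if not math.isinf(df_total) else math.inf,
        f_rank=rank,
    )


def batch_corrected_log2cpm(v: VoomObject, fit: LinearFit) -> pd.DataFrame:
    """Expression with fitted cartridge and conservation effects subtracted;
    subtype effects and residuals are retained.  Idempotent by construction."""
    nuisance = fit.design.nuisance_columns
    if not nuisance:
        return v.E.copy()
    xn = fit.design.matrix[nuisance].to_numpy(dtype=float)
    bn = fit.beta[nuisance].to_numpy(dtype=float)
    corrected = v.E.to_numpy() - bn @ xn.T
    return pd.DataFrame(corrected, index=v.E.index, columns=v.E.columns)
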