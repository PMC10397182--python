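"""Expression filtering, covariate-adjusted association, and inflation control.

The differential-expression engine is a per-gene ordinary least squares model
on log2-CPM (offset: log2((count + 0.5) / (libsize + 1) * 1e6)) with the trait
of interest, covariates, and optionally genetic PCs as fixed effects.  The
per-gene chi-square statistic is the squared normal quantile of the two-sided
p-value, so the systematic-inflation metric

    m = median(chi^2 with PCs) / median(chi^2 without PCs)

is well defined regardless of the underlying engine; m < 1 after PC
adjustment indicates population structure was inflating test statistics.

A GRM-based linear mixed model (y = Xb + g + e, g ~ N(0, sg^2 GRM)) is fitted
by eigendecomposition-accelerated REML (one decomposition, 1-D profile over
the variance ratio), with a per-variant GLS association scan on top.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotype_io import MISSING, GenotypeDataset
from .popstruct import GRM

_CHI2_CAP_P = 1e-300  # p-values below this are flagged and capped


@dataclass
class ExpressionMatrix:
    """Genes x samples integer counts with derived library sizes and log-CPM.

    ``lib_sizes`` defaults to the per-sample count totals; passing them
    explicitly (e.g. totals before gene filtering) keeps CPM values stable
    across gene subsets.
    """

    counts: pd.DataFrame  # genes x samples
    lib_sizes: Optional[np.ndarray] = None

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.lib_sizes is not None:
            self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
            if len(self.lib_sizes) != self.counts.shape[1]:
                raise ValueError("lib_sizes not aligned with samples")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.counts.columns]

    @property
    def library_sizes(self) -> np.ndarray:
        if self.lib_sizes is not None:
            return self.lib_sizes
        return self.counts.sum(axis=0).to_numpy(dtype=float)

    def cpm(self) -> np.ndarray:
        lib = self.library_sizes
        if (lib == 0).any():
            bad = self.counts.columns[lib == 0][0]
            raise ValueError(f"zero library size for sample {bad}")
        return self.counts.to_numpy(dtype=float) / lib * 1e6

    def log2_cpm(self) -> np.ndarray:
        """log2((count + 0.5) / (libsize + 1) * 1e6), the fixed offset convention."""
        lib = self.library_sizes
        if (lib == 0).any():
            bad = self.counts.columns[lib == 0][0]
            raise ValueError(f"zero library size for sample {bad}")
        return np.log2((self.counts.to_numpy(dtype=float) + 0.5) / (lib + 1.0) * 1e6)


@dataclass
class DGEResult:
    """Per-gene association results for the trait coefficient."""

    table: pd.DataFrame  # index: gene; columns: logFC, se, t, p, chisq, q, flagged

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def n_significant(self, p_max: float = 0.05, use_fdr: bool = False) -> int:
        col = "q" if use_fdr else "p"
        return int((self.table[col] < p_max).sum())


@dataclass
class InflationReport:
    """Median chi-square of two nested analyses and their ratio m."""

    median_chisq_with_pcs: float
    median_chisq_without_pcs: float

    @property
    def m(self) -> float:
        return self.median_chisq_with_pcs / self.median_chisq_without_pcs


@dataclass
class LMMFit:
    """REML fit of y = Xb + g + e with g ~ N(0, sg^2 GRM), e ~ N(0, se^2 I)."""

    sigma_g2: float
    sigma_e2: float
    reml_loglik: float
    beta: np.ndarray
    beta_se: np.ndarray
    wald_chisq: np.ndarray
    converged: bool

    @property
    def ratio(self) -> float:
        """Heritability-like ratio sg^2 / (sg^2 + se^2)."""
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


def cpm_filter(
    expr: ExpressionMatrix,
    cpm_min: float = 0.05,
    sample_frac: float = 0.2,
    gene_chrom: Optional[pd.Series] = None,
    autosomal_only: bool = False,
) -> ExpressionMatrix:
    """Keep genes with CPM strictly above ``cpm_min`` in at least
    ceil(sample_frac * n_samples) samples; optionally restrict to autosomal
    genes via a gene -> chromosome annotation."""
    cpm = expr.cpm()
    n = cpm.shape[1]
    need = int(np.ceil(sample_frac * n))
    keep = (cpm > cpm_min).sum(axis=1) >= need
    if autosomal_only:
        if gene_chrom is None:
            raise ValueError("autosomal_only requires a gene_chrom annotation")
        auto = gene_chrom.reindex(expr.counts.index).astype(str).str.lstrip("chr")
        keep &= auto.isin([str(c) for c in range(1, 23)]).to_numpy()
    # library sizes stay those of the unfiltered matrix
    return ExpressionMatrix(expr.counts.loc[keep], expr.library_sizes)


def _build_design(
    n: int,
    trait: np.ndarray,
    covariates: Optional[pd.DataFrame],
    pcs: Optional[np.ndarray],
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(n), np.asarray(trait, dtype=float)]
    names = ["intercept", "trait"]
    if covariates is not None:
        enc = pd.get_dummies(covariates, drop_first=True, dtype=float)
        for c in enc.columns:
            cols.append(enc[c].to_numpy(dtype=float))
            names.append(str(c))
    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        if pcs.ndim == 1:
            pcs = pcs[:, None]
        for i in range(pcs.shape[1]):
            cols.append(pcs[:, i])
            names.append(f"PC{i + 1}")
    x = np.column_stack(cols)
    if np.isnan(x).any():
        raise ValueError("missing values in trait/covariates/PCs are not allowed")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # identify collinear columns by sequential rank growth
        bad = []
        r = 0
        for j in range(x.shape[1]):
            rj = np.linalg.matrix_rank(x[:, : j + 1])
            if rj == r:
                bad.append(names[j])
            r = rj
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return x, names


def chisq_from_p(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1-df chi-square equivalent of two-sided p-values (z^2 convention).

    Underflowing p-values are capped and flagged.
    """
    p = np.asarray(p, dtype=float)
    flagged = p < _CHI2_CAP_P
    chisq = stats.chi2.isf(np.clip(p, _CHI2_CAP_P, 1.0), df=1)
    return chisq, flagged


def dge_lm(
    expr: ExpressionMatrix,
    trait: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    pcs: Optional[np.ndarray] = None,
) -> DGEResult:
    """Per-gene OLS of log2-CPM on [intercept, trait, covariates, PCs].

    Reports the trait coefficient (logFC in log2-CPM units), its standard
    error, t and two-sided p on residual df, the z^2 chi-square, and
    Benjamini-Hochberg q-values.
    """
    y = expr.log2_cpm()  # genes x samples
    n = y.shape[1]
    x, names = _build_design(n, trait, covariates, pcs)
    k = x.shape[1]
    if n - k < 2:
        raise ValueError(f"too many covariates: residual df = {n - k}")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ x @ xtx_inv.T  # genes x k
    resid = y - beta @ x.T
    dof = n - k
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.maximum(sigma2, 0) * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[:, 1] / se
    p = 2 * stats.t.sf(np.abs(t), df=dof)
    chisq, flagged = chisq_from_p(p)
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "logFC": beta[:, 1],
            "se": se,
            "t": t,
            "p": p,
            "chisq": chisq,
            "q": q,
            "flagged": flagged,
        },
        index=pd.Index(expr.gene_ids, name="gene"),
    )
    return DGEResult(table)


def inflation_m(with_pcs: DGEResult, without_pcs: DGEResult) -> InflationReport:
    """Systematic inflation m: ratio of median chi-square statistics.

    Both analyses must cover the identical gene set in identical order.
    """
    if with_pcs.gene_ids != without_pcs.gene_ids:
        raise ValueError("gene sets of the two analyses differ")
    return median_chisq_ratio(
        with_pcs.table["chisq"].to_numpy(), without_pcs.table["chisq"].to_numpy()
    )


def median_chisq_ratio(chisq_with: np.ndarray, chisq_without: np.ndarray) -> InflationReport:
    if len(chisq_with) != len(chisq_without):
        raise ValueError("statistic vectors differ in length")
    return InflationReport(
        float(np.median(chisq_with)), float(np.median(chisq_without))
    )


# ---------------------------------------------------------------------------
# REML linear mixed model


def _reml_profile(
    lam: float, d: np.ndarray, yt: np.ndarray, xt: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Profiled REML log-likelihood at variance ratio lam = sg^2/se^2.

    Operates in the GRM eigenbasis: weights w = lam * d + 1.  Returns
    (loglik, beta, cov_beta_unit, sigma_e2); cov_beta_unit * sigma_e2 is the
    GLS covariance of beta.
    """
    n, k = xt.shape
    w = lam * d + 1.0
    xw = xt / w[:, None]
    a = xt.T @ xw  # X' W^-1 X
    b = xw.T @ yt
    cov_unit = np.linalg.inv(a)
    beta = cov_unit @ b
    r = yt - xt @ beta
    rss = float((r**2 / w).sum())
    dof = n - k
    sigma_e2 = rss / dof
    sign, logdet_a = np.linalg.slogdet(a)
    ll = -0.5 * (
        dof * np.log(sigma_e2) + np.log(w).sum() + logdet_a + dof
    )
    return ll, beta, cov_unit, sigma_e2


def reml_lmm(y: np.ndarray, x: np.ndarray, grm: GRM) -> LMMFit:
    """REML fit of the GRM mixed model by 1-D profile over sg^2/se^2.

    The GRM is eigendecomposed once; the profiled REML log-likelihood is
    maximized over the variance ratio on a log-spaced grid (including the
    ratio-0 boundary) refined by golden-section search to 1e-6 on the
    log-likelihood.  Fixed effects and Wald statistics come from GLS at the
    optimum.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != len(y):
        x = x.T
    n = len(y)
    if grm.matrix.shape != (n, n):
        raise ValueError("GRM not aligned with samples")
    d, q = np.linalg.eigh(grm.matrix)
    if d.min() < -1e-8 * max(np.trace(grm.matrix) / n, 1.0):
        raise ValueError("GRM is not positive semidefinite within tolerance")
    d = np.clip(d, 0.0, None)
    yt = q.T @ y
    xt = q.T @ x

    grid = np.concatenate([[0.0], np.exp(np.linspace(np.log(1e-4), np.log(1e4), 41))])
    lls = np.array([_reml_profile(g, d, yt, xt)[0] for g in grid])
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    converged = True
    if hi > lo:
        # golden-section on [lo, hi]
        invphi = (np.sqrt(5) - 1) / 2
        a, b = lo, hi
        c = b - invphi * (b - a)
        e = a + invphi * (b - a)
        fc = _reml_profile(c, d, yt, xt)[0]
        fe = _reml_profile(e, d, yt, xt)[0]
        for _ in range(200):
            if abs(fc - fe) < 1e-6 and abs(b - a) < 1e-6 * (1 + abs(a)):
                break
            if fc > fe:
                b, e, fe = e, c, fc
                c = b - invphi * (b - a)
                fc = _reml_profile(c, d, yt, xt)[0]
            else:
                a, c, fc = c, e, fe
                e = a + invphi * (b - a)
                fe = _reml_profile(e, d, yt, xt)[0]
        else:
            converged = False
        lam = c if fc >= fe else e
    else:
        lam = grid[i]
    ll, beta, cov_unit, sigma_e2 = _reml_profile(lam, d, yt, xt)
    if lls[0] >= ll:  # boundary (ratio 0) wins
        lam = 0.0
        ll, beta, cov_unit, sigma_e2 = _reml_profile(lam, d, yt, xt)
    se = np.sqrt(np.diag(cov_unit) * sigma_e2)
    wald = (beta / se) ** 2
    return LMMFit(
        sigma_g2=lam * sigma_e2,
        sigma_e2=sigma_e2,
        reml_loglik=ll,
        beta=beta,
        beta_se=se,
        wald_chisq=wald,
        converged=converged,
    )


def lmm_scan(
    y: np.ndarray,
    variants: GenotypeDataset,
    grm: GRM,
    covariates: Optional[np.ndarray] = None,
    pcs: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-variant GLS association scan under a null-model REML fit.

    Variance components are estimated once under the null (no variant);
    each variant (mean-imputed) is then tested by GLS with the components
    fixed, yielding a 1-df Wald chi-square.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    cols = [np.ones(n)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.append(cov)
    if pcs is not None:
        pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
        if pcs.shape[0] != n:
            pcs = pcs.T
        cols.append(pcs)
    x0 = np.column_stack(cols)
    fit = reml_lmm(y, x0, grm)
    lam = fit.sigma_g2 / fit.sigma_e2 if fit.sigma_e2 > 0 else 0.0

    d, q = np.linalg.eigh(grm.matrix)
    d = np.clip(d, 0.0, None)
    w = lam * d + 1.0
    sw = np.sqrt(w)
    yt = (q.T @ y) / sw
    x0t = (q.T @ x0) / sw[:, None]

    # mean-impute missing dosages, rotate, whiten
    g = variants.dosage.astype(float)
    miss = variants.dosage == MISSING
    colmean = np.where(
        (~miss).sum(axis=0) > 0,
        np.where(miss, 0, g).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1),
        0.0,
    )
    g[miss] = np.take(colmean, np.nonzero(miss)[1])
    gt = (q.T @ g) / sw[:, None]

    # residualize y and each genotype on the whitened null design
    q0, _ = np.linalg.qr(x0t)
    yr = yt - q0 @ (q0.T @ yt)
    gr = gt - q0 @ (q0.T @ gt)
    gg = (gr**2).sum(axis=0)
    gy = gr.T @ yr
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(gg > 0, gy / gg, 0.0)
        chisq = np.where(gg > 0, beta**2 * gg / fit.sigma_e2, 0.0)
    p = stats.chi2.sf(chisq, df=1)
    return pd.DataFrame(
        {
            "chrom": [v.chrom for v in variants.variants],
            "pos": [v.pos for v in variants.variants],
            "beta": beta,
            "chisq": chisq,
            "p": p,
        }
    )


def lmm_scan_with_report(
    y: np.ndarray,
    variants: GenotypeDataset,
    grm: GRM,
    pcs: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, InflationReport]:
    """Run the scan with and without PCs and report the inflation ratio m."""
    with_pcs = lmm_scan(y, variants, grm, covariates=covariates, pcs=pcs)
    without = lmm_scan(y, variants, grm, covariates=covariates, pcs=None)
    report = median_chisq_ratio(
        with_pcs["chisq"].to_numpy(), without["chisq"].to_numpy()
    )
    return with_pcs, without, report
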