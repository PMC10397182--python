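"""Statistical agreement between two PC sets over the same samples.

Three complementary views: (i) a Spearman correlation matrix between the two
score sets; (ii) canonical correlation analysis — paired linear combinations
of the two blocks maximizing correlation — with Wilks' Lambda sequential
significance tests (Bartlett chi-square approximation); (iii) a
shared-variance summary via the redundancy index: how much of one block's
variance the other block's canonical variates explain.

CCA is computed through orthonormal (QR/SVD) bases of the centered blocks, so
results are invariant to invertible re-mixing of either block's columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg
from scipy import stats


@dataclass
class PCCorrelationMatrix:
    """Spearman rho and p-values between two score sets (kA x kB)."""

    rho: np.ndarray
    p: np.ndarray


@dataclass
class CCAResult:
    """Canonical correlations and variates of two multivariate blocks.

    ``correlations`` R_c1..R_cs are non-increasing in [0, 1];
    ``x_variates``/``y_variates`` hold the per-sample canonical variate
    scores (unit variance); ``wilks_lambda[k-1]`` = prod_{i>=k} (1 - R_ci^2);
    ``p_values`` are the Bartlett sequential chi-square p-values, filled by
    :func:`wilks_sequential_test`.
    """

    correlations: np.ndarray
    x_variates: np.ndarray
    y_variates: np.ndarray
    n: int
    p: int
    q: int
    rank_x: int
    rank_y: int
    wilks_lambda: Optional[np.ndarray] = None
    chi2: Optional[np.ndarray] = None
    df: Optional[np.ndarray] = None
    p_values: Optional[np.ndarray] = None
    underflow: Optional[np.ndarray] = None

    @property
    def s(self) -> int:
        return len(self.correlations)


def spearman_matrix(x: np.ndarray, y: np.ndarray) -> PCCorrelationMatrix:
    """Spearman correlations between every column pair of two score sets.

    Ranks use mid-ranks for ties; p-values use the t approximation.  Constant
    columns yield NaN in the corresponding cells.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("X and Y must have the same samples in the same order")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    rx = np.apply_along_axis(stats.rankdata, 0, x)
    ry = np.apply_along_axis(stats.rankdata, 0, y)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean(axis=0)
    sx = np.sqrt((rx**2).sum(axis=0))
    sy = np.sqrt((ry**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rx.T @ ry) / np.outer(sx, sy)
    const = np.outer(sx == 0, np.ones(len(sy), bool)) | np.outer(
        np.ones(len(sx), bool), sy == 0
    )
    rho = np.where(const, np.nan, np.clip(rho, -1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(rho), np.nan, np.where(np.abs(rho) >= 1, 0.0, p))
    return PCCorrelationMatrix(rho, p)


def _orthobasis(x: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space of the centered matrix."""
    xc = x - x.mean(axis=0)
    u, s, _ = scipy.linalg.svd(xc, full_matrices=False)
    rank = int((s > tol * (s[0] if s.size else 1.0)).sum())
    return u[:, :rank]


def canonical_correlation(x: np.ndarray, y: np.ndarray) -> CCAResult:
    """Canonical correlation analysis of two blocks over the same samples.

    Columns are centered internally; each block is reduced to an orthonormal
    basis and the canonical correlations are the singular values of the
    cross-product of the bases.  Rank-deficient blocks reduce s to the
    effective rank (with a warning).  Variates are scaled to unit sample
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("X and Y must have the same samples")
    n, p = x.shape
    q = y.shape[1]
    if n <= p + q:
        import warnings

        warnings.warn(f"n={n} <= p+q={p + q}: canonical correlations may saturate", stacklevel=2)
    qx = _orthobasis(x)
    qy = _orthobasis(y)
    rank_x, rank_y = qx.shape[1], qy.shape[1]
    if rank_x < p or rank_y < q:
        import warnings

        warnings.warn(
            f"rank-deficient block (rank X={rank_x}/{p}, rank Y={rank_y}/{q}); "
            "reducing the number of canonical dimensions",
            stacklevel=2,
        )
    u, s, vt = scipy.linalg.svd(qx.T @ qy, full_matrices=False)
    s = np.clip(s, 0.0, 1.0)
    xv = qx @ u * np.sqrt(n - 1)
    yv = qy @ vt.T * np.sqrt(n - 1)
    res = CCAResult(s, xv, yv, n, p, q, rank_x, rank_y)
    wilks_sequential_test(res)
    return res


def wilks_sequential_test(result: CCAResult, n: int | None = None,
                          p: int | None = None, q: int | None = None) -> np.ndarray:
    """Bartlett chi-square sequential tests of the remaining canonical dims.

    For k = 1..s, Lambda_k = prod_{i=k..s} (1 - R_ci^2); the statistic
    -(n - 1 - (p + q + 1)/2) ln Lambda_k is referred to chi-square with
    (p - k + 1)(q - k + 1) degrees of freedom.  Lambda_k = 0 (a perfect
    correlation) is reported as an underflow-flagged minimal p-value.
    Fills the result in place and returns the p-values.
    """
    n = result.n if n is None else n
    p = result.p if p is None else p
    q = result.q if q is None else q
    r2 = result.correlations**2
    s = len(r2)
    lam = np.ones(s)
    acc = 1.0
    for i in range(s - 1, -1, -1):
        acc *= 1.0 - r2[i]
        lam[i] = acc
    ks = np.arange(1, s + 1)
    df = (p - ks + 1) * (q - ks + 1)
    factor = n - 1 - (p + q + 1) / 2.0
    underflow = lam <= 0
    with np.errstate(divide="ignore"):
        chi2 = np.where(underflow, np.inf, -factor * np.log(np.where(underflow, 1.0, lam)))
    pv = stats.chi2.sf(chi2, df)
    pv = np.where(underflow, np.finfo(float).tiny, pv)
    result.wilks_lambda = lam
    result.chi2 = chi2
    result.df = df.astype(int)
    result.p_values = pv
    result.underflow = underflow
    return pv


def shared_variance(result: CCAResult, y: np.ndarray) -> dict[str, np.ndarray]:
    """Redundancy-index shared variance of block Y given X's canonical variates.

    For variate i, Rd_i = R_ci^2 * mean_j corr(Y_j, y-variate_i)^2 — the
    average variance of Y's (standardized) columns reproduced through the
    i-th canonical pair.  Returns per-variate and cumulative proportions
    alongside the raw squared canonical correlations.
    """
    y = np.asarray(y, dtype=float)
    yc = y - y.mean(axis=0)
    sd = yc.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant column in Y")
    ys = yc / sd
    yv = result.y_variates
    n = ys.shape[0]
    # corr(Y_j, yv_i); variates have unit variance
    load = (ys.T @ (yv - yv.mean(axis=0))) / ((n - 1) * yv.std(axis=0, ddof=1))
    mean_sq_load = (load**2).mean(axis=0)
    rd = result.correlations**2 * mean_sq_load
    return {
        "r2": result.correlations**2,
        "redundancy": rd,
        "cumulative": np.cumsum(rd),
        "y_variance_extracted": mean_sq_load,
    }
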