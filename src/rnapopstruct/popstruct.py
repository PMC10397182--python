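"""Genotype standardization, genetic PCA, joint PCA, and the GRM.

Standardization follows the binomial convention used by genotype-PCA tools:
z = (g - 2p) / sqrt(2 p (1 - p)) with p the cohort alternate-allele frequency
of the variant, and missing calls mean-imputed to z = 0.  Principal
components are computed from the exact SVD of the standardized matrix;
eigenvalues are those of (1/m) Z Z', and per-sample scores are the
eigenvectors scaled by sqrt(n * eigenvalue).  The genomic relationship
matrix is Z Z' / m on the same standardization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .genotype_io import MISSING, GenotypeDataset
from . import harmonize


@dataclass
class StandardizedMatrix:
    """Standardized genotypes with the frequencies used for standardization.

    ``Z`` is samples x variants; ``freqs`` holds the per-variant alternate
    allele frequency p; ``zero_variance`` flags columns constant across
    non-missing calls (kept, uninformative).
    """

    Z: np.ndarray
    freqs: np.ndarray
    samples: list[str]
    zero_variance: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.Z.shape[0]

    @property
    def n_variants(self) -> int:
        return self.Z.shape[1]


@dataclass
class PCResult:
    """Principal components of a standardized genotype matrix.

    ``eigenvalues`` are those of (1/m) Z Z', non-increasing; ``scores``
    (samples x k) are eigenvectors scaled by sqrt(n * eigenvalue);
    ``loadings`` (variants x k) are the right singular directions; ``freqs``
    are the standardization frequencies, retained for reuse.
    """

    k: int
    eigenvalues: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    freqs: np.ndarray
    samples: list[str]


@dataclass
class GRM:
    """Genomic relationship matrix Z Z' / m (samples x samples)."""

    matrix: np.ndarray
    n_variants_used: int
    samples: list[str]

    def __post_init__(self):
        a = self.matrix
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")


def standardize(data: GenotypeDataset) -> StandardizedMatrix:
    """Binomially standardize dosages; missing entries become exactly 0.

    Frequencies come from the non-missing calls of this dataset.  A
    monomorphic variant (p = 0 or 1) is an error: the MAF filter must run
    first.
    """
    d = data.dosage
    miss = d == MISSING
    ncall = (~miss).sum(axis=0)
    if (ncall == 0).any():
        j = int(np.nonzero(ncall == 0)[0][0])
        raise ValueError(f"variant {data.variants[j].chrom}:{data.variants[j].pos} has no calls")
    g = np.where(miss, 0, d).astype(float)
    p = g.sum(axis=0) / (2 * ncall)
    if ((p <= 0) | (p >= 1)).any():
        j = int(np.nonzero((p <= 0) | (p >= 1))[0][0])
        v = data.variants[j]
        raise ValueError(f"monomorphic variant {v.chrom}:{v.pos}; apply the MAF filter first")
    z = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    z[miss] = 0.0
    # a column is zero-variance when all non-missing calls are equal
    dm = np.where(miss, np.nan, d.astype(float))
    with np.errstate(invalid="ignore"):
        zero_var = np.nanmax(dm, axis=0) == np.nanmin(dm, axis=0)
    return StandardizedMatrix(z, p, list(data.samples), zero_var)


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> None:
    """Deterministic sign: the loading of largest |value| is made positive."""
    for c in range(loadings.shape[1]):
        col = loadings[:, c]
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            loadings[:, c] = -col
            scores[:, c] = -scores[:, c]


def compute_pcs(zmat: StandardizedMatrix, k: int) -> PCResult:
    """Exact-SVD principal components of the standardized genotype matrix.

    Eigenvalues lambda_i of (1/m) Z Z'; scores u_i * sqrt(n * lambda_i);
    loadings are the right singular vectors.  ``k`` must satisfy
    k <= min(n_samples - 1, n_variants).
    """
    n, m = zmat.Z.shape
    if not (1 <= k <= min(n - 1, m)):
        raise ValueError(f"k={k} must be in [1, min(n_samples-1, n_variants)={min(n - 1, m)}]")
    u, s, vt = scipy.linalg.svd(zmat.Z, full_matrices=False)
    eigvals = (s**2) / m
    scores = u[:, :k] * np.sqrt(n * eigvals[:k])
    loadings = vt[:k].T.copy()
    _fix_signs(scores, loadings)
    return PCResult(k, eigvals[:k].copy(), scores, loadings, zmat.freqs.copy(), list(zmat.samples))


def pca(data: GenotypeDataset, k: int) -> PCResult:
    """Standardize then compute PCs (convenience wrapper)."""
    return compute_pcs(standardize(data), k)


def joint_pca(
    a: GenotypeDataset, b: GenotypeDataset, k: int
) -> tuple[PCResult, list[str]]:
    """PCA of two cohorts merged on their harmonized variant intersection.

    Variants are matched with strand-flip awareness, B is aligned to A's
    orientation, the sample sets are stacked, and frequencies are
    re-estimated on the merged cohort before standardization.  Returns the
    PCs and a per-sample cohort label ("A"/"B") in score row order.
    """
    records = harmonize.match_variants(a.variants, b.variants)
    usable = [m for m in records if m.action in ("direct", "swap", "flip", "flip_swap")]
    if not usable:
        raise ValueError("no overlapping variants between cohorts after harmonization")
    if len(usable) < 100:
        import warnings

        warnings.warn(f"only {len(usable)} overlapping variants", stacklevel=2)
    b_al = harmonize.align_genotypes(b, records)
    a_sub = a.take_variants([m.index_a for m in usable])
    samples = [f"A:{s}" for s in a_sub.samples] + [f"B:{s}" for s in b_al.samples]
    merged = GenotypeDataset(
        list(a_sub.variants), samples, np.vstack([a_sub.dosage, b_al.dosage])
    )
    labels = ["A"] * a_sub.n_samples + ["B"] * b_al.n_samples
    return compute_pcs(standardize(merged), k), labels


def compute_grm(zmat: StandardizedMatrix) -> GRM:
    """GRM = Z Z' / m."""
    if zmat.n_variants < 1:
        raise ValueError("at least one variant required")
    m = zmat.n_variants
    g = (zmat.Z @ zmat.Z.T) / m
    g = (g + g.T) / 2
    return GRM(g, m, list(zmat.samples))
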