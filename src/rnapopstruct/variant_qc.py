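"""Variant- and sample-level QC and LD pruning.

Replicates PLINK-style genotype filtering: autosomal-SNP restriction,
duplicate and palindromic removal, region exclusion (HLA by default),
call-rate (``geno``), minor-allele-frequency (``maf``), Hardy-Weinberg exact
test (``hwe``), per-sample missingness (``mind``), and ``--indep-pairwise``
style LD pruning with the window and step expressed in variant counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeDataset

# GRCh38 extended MHC/HLA region, half-open
HLA_REGION = ("6", 25_000_000, 34_000_000)


@dataclass
class VariantStats:
    """Per-variant summaries computed over non-missing calls.

    ``alt_freq`` is the alternate-allele frequency p; ``maf = min(p, 1-p)``.
    Variants with zero non-missing calls have ``call_rate`` 0 and NaN
    frequencies, flagged in ``undefined``.
    """

    n_ref_hom: np.ndarray  # dosage 0
    n_het: np.ndarray  # dosage 1
    n_alt_hom: np.ndarray  # dosage 2
    call_rate: np.ndarray
    alt_freq: np.ndarray
    maf: np.ndarray
    hwe_p: np.ndarray
    is_palindromic: np.ndarray
    monomorphic: np.ndarray
    undefined: np.ndarray

    def __len__(self) -> int:
        return len(self.call_rate)


@dataclass
class QCThresholds:
    """PLINK-style filter thresholds.

    Defaults follow the PC-stage settings: MAF strictly > 0.05, per-variant
    missingness <= 0.1 (geno), per-sample missingness <= 0.2 (mind), HWE
    disabled (hwe_min_p = 0), LD r^2 threshold 0.05 with a sliding window of
    1000 variants advanced by 50.  ``excluded_regions`` holds half-open
    (chrom, start, end) intervals and defaults to the HLA region.
    """

    maf_min: float = 0.05
    geno_max: float = 0.1
    mind_max: float = 0.2
    hwe_min_p: float = 0.0
    r2_max: float = 0.05
    window: int = 1000
    step: int = 50
    excluded_regions: list[tuple[str, int, int]] = field(
        default_factory=lambda: [HLA_REGION]
    )

    def __post_init__(self):
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if not (0 < self.r2_max <= 1):
            raise ValueError("r2_max must be in (0, 1]")
        if self.step > self.window:
            raise ValueError("step must be <= window")


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Conditional on the genotype total n and the minor-allele count, sums the
    probabilities of all heterozygote counts whose conditional probability is
    no larger than that of the observed count.  Monomorphic input returns 1.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("at least one genotype required")
    rare = 2 * min(n_hom1, n_hom2) + n_het
    if rare == 0:
        return 1.0
    # enumerate all het counts with the parity of the rare-allele count
    hets = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    # log P(het | n, rare) up to a constant:
    #   n! / (hom_r! het! hom_c!) * 2^het, hom_r = (rare-het)/2
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        hets * math.log(2.0)
        - _lgamma_arr(hom_r + 1)
        - _lgamma_arr(hets + 1)
        - _lgamma_arr(hom_c + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs_het = n_het
    obs_p = probs[np.nonzero(hets == obs_het)[0][0]]
    # tolerance absorbs float ties between symmetric configurations
    p = probs[probs <= obs_p * (1 + 1e-10)].sum()
    return float(min(1.0, p))


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(x)


def compute_variant_stats(data: GenotypeDataset, with_hwe: bool = True) -> VariantStats:
    """Compute per-variant counts, call rate, allele frequencies, and HWE p.

    All statistics use non-missing calls only.  ``with_hwe=False`` skips the
    exact test (hwe_p all 1) when the HWE filter is disabled.
    """
    if data.n_variants == 0 or data.n_samples == 0:
        raise ValueError("empty dataset")
    d = data.dosage
    n0 = (d == 0).sum(axis=0)
    n1 = (d == 1).sum(axis=0)
    n2 = (d == 2).sum(axis=0)
    ncall = n0 + n1 + n2
    call_rate = ncall / data.n_samples
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_freq = np.where(ncall > 0, (2 * n2 + n1) / (2 * np.maximum(ncall, 1)), np.nan)
    maf = np.minimum(alt_freq, 1 - alt_freq)
    undefined = ncall == 0
    monomorphic = (maf == 0) | undefined
    pal = np.array([v.is_palindromic for v in data.variants], dtype=bool)
    hwe_p = np.ones(data.n_variants)
    if with_hwe:
        for j in range(data.n_variants):
            if ncall[j] > 0:
                hwe_p[j] = hwe_exact_test(int(n0[j]), int(n1[j]), int(n2[j]))
    return VariantStats(
        n_ref_hom=n0,
        n_het=n1,
        n_alt_hom=n2,
        call_rate=call_rate,
        alt_freq=alt_freq,
        maf=maf,
        hwe_p=hwe_p,
        is_palindromic=pal,
        monomorphic=monomorphic,
        undefined=undefined,
    )


_FILTER_RULES = (
    "non_autosomal_or_non_snp",
    "duplicate",
    "palindromic",
    "excluded_region",
    "call_rate",
    "maf",
    "hwe",
)


def filter_variants(
    data: GenotypeDataset, stats: VariantStats, th: QCThresholds
) -> tuple[GenotypeDataset, dict[str, int]]:
    """Apply variant filters in fixed order and report removals per rule.

    Order: autosomal-SNP keep; duplicate (chrom,pos,ref,alt) removal keeping
    the first; palindromic removal; excluded-region removal; call-rate >=
    1-geno_max; MAF strictly > maf_min; HWE p >= hwe_min_p (skipped when
    hwe_min_p == 0).  A variant is counted once, at the first rule removing it.
    """
    if len(stats) != data.n_variants:
        raise ValueError("stats not aligned with dataset")
    counts = {r: 0 for r in _FILTER_RULES}
    keep = []
    seen: set[tuple] = set()
    for j, v in enumerate(data.variants):
        if not v.is_autosomal:
            counts["non_autosomal_or_non_snp"] += 1
            continue
        full_key = (v.chrom, v.pos, v.ref, v.alt)
        if full_key in seen:
            counts["duplicate"] += 1
            continue
        seen.add(full_key)
        if v.is_palindromic:
            counts["palindromic"] += 1
            continue
        if any(
            v.chrom == c and s <= v.pos < e for (c, s, e) in th.excluded_regions
        ):
            counts["excluded_region"] += 1
            continue
        if stats.call_rate[j] < 1 - th.geno_max:
            counts["call_rate"] += 1
            continue
        if stats.undefined[j] or not (stats.maf[j] > th.maf_min):
            counts["maf"] += 1
            continue
        if th.hwe_min_p > 0 and stats.hwe_p[j] < th.hwe_min_p:
            counts["hwe"] += 1
            continue
        keep.append(j)
    counts["kept"] = len(keep)
    return data.take_variants(keep), counts


def filter_samples(
    data: GenotypeDataset, mind_max: float = 0.2
) -> tuple[GenotypeDataset, list[str]]:
    """Remove samples with missing-genotype fraction strictly above ``mind_max``.

    Variant statistics must be recomputed by the caller after sample removal.
    """
    if data.n_variants == 0:
        raise ValueError("empty dataset")
    miss_frac = data.missing_mask().mean(axis=1)
    keep = np.nonzero(miss_frac <= mind_max)[0]
    removed = [data.samples[i] for i in np.nonzero(miss_frac > mind_max)[0]]
    if len(keep) == 0:
        raise ValueError("empty cohort: all samples exceed the missingness limit")
    return data.take_samples(keep), removed


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over samples non-missing in both; NaN when fewer than two shared
    calls remain or either vector is constant on the shared support.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = (g1 != MISSING) & (g2 != MISSING)
    x, y = g1[ok].astype(float), g2[ok].astype(float)
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _window_r2_matrix(dosage: np.ndarray) -> np.ndarray:
    """Pairwise r^2 on the pairwise-complete (both non-missing) support.

    ``dosage``: samples x w window slice.  Constant-on-support or <2-call
    pairs get 0 (they cannot trigger pruning).
    """
    m = (dosage != MISSING).astype(float)
    d = np.where(dosage == MISSING, 0, dosage).astype(float)
    d2 = d * d
    n = m.T @ m  # shared call counts
    sx = d.T @ m  # sum of x over pair support (rows: x variant)
    sxx = d2.T @ m
    sxy = d.T @ d
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sx.T / n
        vx = sxx - sx * sx / n
        denom = vx * vx.T
        r2 = np.where(denom > 0, cov * cov / denom, 0.0)
    r2 = np.nan_to_num(r2, nan=0.0)
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(
    data: GenotypeDataset, th: QCThresholds, maf: np.ndarray | None = None
) -> list[int]:
    """Greedy indep-pairwise LD pruning; returns kept variant indices.

    Variants must be sorted by (chrom, pos).  Per chromosome, a window of
    ``th.window`` variants slides by ``th.step``; within each window the pair
    of still-kept variants with the highest r^2 above ``th.r2_max`` is found
    repeatedly and the lower-MAF member removed (tie: the later-positioned
    one).  Afterwards no kept pair co-occurring in any window exceeds the
    threshold.
    """
    keys = data.variant_keys()
    # sorted = contiguous chromosome blocks with non-decreasing positions
    blocks = []
    for c, _ in keys:
        if not blocks or blocks[-1] != c:
            blocks.append(c)
    if len(set(blocks)) != len(blocks) or any(
        keys[i][0] == keys[i + 1][0] and keys[i][1] > keys[i + 1][1]
        for i in range(len(keys) - 1)
    ):
        raise ValueError("variants must be sorted by (chrom, pos); sort the input")
    if maf is None:
        maf = compute_variant_stats(data, with_hwe=False).maf
    maf = np.asarray(maf, dtype=float)

    kept = np.ones(data.n_variants, dtype=bool)
    chrom_arr = np.array([v.chrom for v in data.variants])
    for chrom in dict.fromkeys(chrom_arr):  # preserves order
        idx = np.nonzero(chrom_arr == chrom)[0]
        nv = len(idx)
        starts = range(0, max(nv - th.window, 0) + 1, th.step) if nv > th.window else [0]
        for s in starts:
            widx = idx[s : s + th.window]
            widx = widx[kept[widx]]
            if len(widx) < 2:
                continue
            r2 = _window_r2_matrix(data.dosage[:, widx])
            alive = np.ones(len(widx), dtype=bool)
            while True:
                sub = np.where(np.outer(alive, alive), r2, 0.0)
                i, j = np.unravel_index(np.argmax(sub), sub.shape)
                if sub[i, j] <= th.r2_max:
                    break
                a, b = widx[i], widx[j]
                if maf[a] < maf[b]:
                    victim = i
                elif maf[b] < maf[a]:
                    victim = j
                else:  # MAF tie: remove the later-positioned variant
                    victim = i if data.variants[a].pos > data.variants[b].pos else j
                alive[victim] = False
                kept[widx[victim]] = False
    return list(np.nonzero(kept)[0])


def max_window_r2(data: GenotypeDataset, kept: list[int], th: QCThresholds) -> float:
    """Post-condition scan: max pairwise r^2 among kept variants co-occurring
    in any pruning window (0 if no pair co-occurs)."""
    keys = data.variant_keys()
    chrom_arr = np.array([k[0] for k in keys])
    best = 0.0
    for chrom in dict.fromkeys(chrom_arr):
        idx = np.nonzero(chrom_arr == chrom)[0]
        nv = len(idx)
        starts = range(0, max(nv - th.window, 0) + 1, th.step) if nv > th.window else [0]
        kept_set = set(kept)
        for s in starts:
            widx = [i for i in idx[s : s + th.window] if i in kept_set]
            if len(widx) < 2:
                continue
            r2 = _window_r2_matrix(data.dosage[:, widx])
            best = max(best, float(r2.max()))
    return best
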