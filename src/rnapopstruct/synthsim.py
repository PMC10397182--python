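"""Synthetic structured genotypes, paired array/RNAseq views, and counts.

The genotype simulator uses the Balding-Nichols model: an ancestral allele
frequency p per variant, per-subpopulation frequencies
p_k ~ Beta(p (1-F)/F, (1-p)(1-F)/F) with differentiation F (Fst), and
genotypes Binomial(2, p_k).  Paired "array" and "RNAseq" views emulate an
array manifest subset versus a transcribed-region ascertainment with
depth-dependent missingness, dosage-level genotype errors, and a fraction of
strand-complemented records to exercise harmonization.  Expression counts are
negative-binomial with log-normal library sizes and optional
ancestry-confounded and sex-associated genes with recorded truth labels.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset, Variant, complement_allele

# ordered non-palindromic allele pairs
_NONPAL_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class PopulationModel:
    """Balding-Nichols population model parameters."""

    k: int = 3
    fst: float = 0.1
    n_per_pop: int = 100
    n_variants: int = 5000
    freq_range: tuple[float, float] = (0.05, 0.95)
    palindromic_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.fst < 1):
            raise ValueError("fst must be in [0, 1)")
        if self.k < 1 or self.n_per_pop < 1 or self.n_variants < 1:
            raise ValueError("k, n_per_pop and n_variants must be positive")


@dataclass
class AscertainmentModel:
    """Paired-view ascertainment: array manifest vs transcribed regions."""

    transcribed_fraction: float = 0.2
    array_fraction: float = 0.6
    array_missing_rate: float = 0.01
    missing_rate_base: float = 0.05
    genotype_error_rate: float = 0.02
    strand_flip_fraction: float = 0.1
    depth_effect: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in (
            "transcribed_fraction", "array_fraction", "array_missing_rate",
            "missing_rate_base", "genotype_error_rate", "strand_flip_fraction",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class ExpressionModel:
    """Negative-binomial expression with confounded and sex-associated genes."""

    n_genes: int = 2000
    frac_confounded: float = 0.1
    frac_sex_de: float = 0.05
    confound_log2fc: float = 1.0
    sex_log2fc: float = 1.0
    base_log2_mean_range: tuple[float, float] = (1.0, 9.0)
    dispersion: float = 0.2
    lib_size_log_mean: float = np.log(2e6)
    lib_size_log_sd: float = 0.3
    seed: int = 0


def simulate_genotypes(model: PopulationModel) -> tuple[GenotypeDataset, np.ndarray]:
    """Draw a structured genotype dataset; returns (dataset, population labels).

    Variants are assigned uniformly to chromosomes 1..22 with unique
    positions, sorted by (chrom, pos).  F = 0 degenerates to shared
    frequencies (no Beta draw).  Deterministic under the seed.
    """
    rng = np.random.default_rng(model.seed)
    m = model.n_variants
    n = model.k * model.n_per_pop

    p_anc = rng.uniform(*model.freq_range, size=m)
    if model.fst > 0:
        a = p_anc * (1 - model.fst) / model.fst
        b = (1 - p_anc) * (1 - model.fst) / model.fst
        p_pop = rng.beta(a, b, size=(model.k, m))
        p_pop = np.clip(p_pop, 1e-6, 1 - 1e-6)
    else:
        p_pop = np.tile(p_anc, (model.k, 1))

    labels = np.repeat(np.arange(model.k), model.n_per_pop)
    dosage = np.empty((n, m), dtype=np.int8)
    for k in range(model.k):
        rows = labels == k
        dosage[rows] = rng.binomial(2, p_pop[k], size=(model.n_per_pop, m)).astype(np.int8)

    chroms = rng.integers(1, 23, size=m)
    positions = rng.integers(1, 200_000_000, size=m)
    order = np.lexsort((positions, chroms))
    chroms, positions = chroms[order], positions[order]
    dosage = dosage[:, order]
    # enforce unique, strictly increasing positions within a chromosome
    for i in range(1, m):
        if chroms[i] == chroms[i - 1] and positions[i] <= positions[i - 1]:
            positions[i] = positions[i - 1] + 1

    n_pal = int(round(model.palindromic_fraction * m))
    pal_idx = set(rng.choice(m, size=n_pal, replace=False).tolist()) if n_pal else set()
    pair_choice = rng.integers(0, len(_NONPAL_PAIRS), size=m)
    pal_choice = rng.integers(0, len(_PAL_PAIRS), size=m)
    variants = []
    for j in range(m):
        ref, alt = (
            _PAL_PAIRS[pal_choice[j]] if j in pal_idx else _NONPAL_PAIRS[pair_choice[j]]
        )
        variants.append(Variant(str(chroms[j]), int(positions[j]), ref, alt, f"sv{j}"))
    samples = [f"S{i:04d}" for i in range(n)]
    return GenotypeDataset(variants, samples, dosage), labels


def derive_paired_views(
    full: GenotypeDataset, model: AscertainmentModel
) -> tuple[GenotypeDataset, GenotypeDataset]:
    """Derive (array_view, rnaseq_view) from a full genotype dataset.

    The array view is a random variant subset (``array_fraction``) with a
    small uniform missing rate.  The RNAseq view is the transcribed subset
    with per-call missingness (``missing_rate_base``, scaled per sample by a
    depth factor when ``depth_effect``), dosage-level genotype errors
    (an erroneous call becomes one of the other two dosages uniformly), and a
    fraction of variants reported on the complementary strand — half of those
    additionally with ref/alt swapped (dosage recoded), exercising both flip
    and flip_swap harmonization.
    """
    if full.n_variants == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(model.seed)
    m, n = full.n_variants, full.n_samples

    arr_idx = np.sort(
        rng.choice(m, size=max(1, int(round(model.array_fraction * m))), replace=False)
    )
    array_view = full.take_variants(arr_idx)
    arr_d = array_view.dosage.copy()
    arr_d[rng.random(arr_d.shape) < model.array_missing_rate] = MISSING
    array_view = GenotypeDataset(list(array_view.variants), list(array_view.samples), arr_d)

    rna_idx = np.sort(
        rng.choice(m, size=max(1, int(round(model.transcribed_fraction * m))), replace=False)
    )
    rna = full.take_variants(rna_idx)
    d = rna.dosage.copy()
    mr = rna.n_variants

    if model.depth_effect:
        depth = np.exp(rng.normal(0.0, 0.5, size=n))  # per-sample depth factor
        miss_p = np.clip(model.missing_rate_base * (1 / depth), 0, 1)[:, None]
    else:
        miss_p = np.full((n, 1), model.missing_rate_base)
    miss = rng.random(d.shape) < miss_p

    err = (rng.random(d.shape) < model.genotype_error_rate) & ~miss
    # replace an erroneous call with one of the other two dosages uniformly
    shift = rng.integers(1, 3, size=d.shape)
    d = np.where(err, (d + shift) % 3, d).astype(np.int8)
    d[miss] = MISSING

    variants = list(rna.variants)
    n_flip = int(round(model.strand_flip_fraction * mr))
    flip_idx = rng.choice(mr, size=n_flip, replace=False) if n_flip else np.array([], int)
    for t, j in enumerate(flip_idx):
        v = variants[j]
        ref, alt = complement_allele(v.ref), complement_allele(v.alt)
        if t % 2 == 1:  # also swap ref/alt: flip_swap; recode dosage
            ref, alt = alt, ref
            nz = d[:, j] != MISSING
            d[nz, j] = 2 - d[nz, j]
        variants[j] = dc_replace(v, ref=ref, alt=alt)
    rnaseq_view = GenotypeDataset(variants, list(rna.samples), d)
    return array_view, rnaseq_view


def simulate_counts(
    labels: np.ndarray,
    sex: np.ndarray,
    model: ExpressionModel,
) -> tuple["pd.DataFrame", pd.DataFrame]:
    """Simulate a genes x samples NB count matrix with known truth labels.

    counts_gi ~ NB(mean = s_i * 2^(b0_g + bpop_g * u_k(i) + bsex_g * sex_i),
    dispersion phi) via the gamma-Poisson mixture, with u_k a per-population
    offset (scaled to unit spread) for confounded genes.  Returns
    (counts DataFrame, truth DataFrame with is_confounded / is_sex_de /
    log2fc columns).
    """
    labels = np.asarray(labels)
    sex = np.asarray(sex, dtype=float)
    if len(labels) != len(sex):
        raise ValueError("labels and sex must be aligned")
    rng = np.random.default_rng(model.seed)
    n = len(labels)
    g = model.n_genes

    lib = np.exp(rng.normal(model.lib_size_log_mean, model.lib_size_log_sd, size=n))
    b0 = rng.uniform(*model.base_log2_mean_range, size=g)
    n_conf = int(round(model.frac_confounded * g))
    n_sex = int(round(model.frac_sex_de * g))
    conf_genes = rng.choice(g, size=n_conf, replace=False)
    sex_genes = rng.choice(g, size=n_sex, replace=False)
    is_conf = np.zeros(g, bool)
    is_conf[conf_genes] = True
    is_sex = np.zeros(g, bool)
    is_sex[sex_genes] = True

    pops = np.unique(labels)
    u = {k: (i - (len(pops) - 1) / 2) / max(len(pops) - 1, 1) * 2 for i, k in enumerate(pops)}
    u_sample = np.array([u[k] for k in labels])

    bpop = np.where(is_conf, model.confound_log2fc, 0.0) * rng.choice([-1, 1], size=g)
    bsex = np.where(is_sex, model.sex_log2fc, 0.0) * rng.choice([-1, 1], size=g)

    log2_mu = b0[:, None] + bpop[:, None] * u_sample[None, :] + bsex[:, None] * sex[None, :]
    rel = 2.0**log2_mu
    mu = rel / rel.sum(axis=0, keepdims=True) * lib[None, :]
    phi = model.dispersion
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    counts = rng.poisson(lam)

    genes = [f"G{j:05d}" for j in range(g)]
    samples = [f"S{i:04d}" for i in range(n)]
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    truth = pd.DataFrame(
        {
            "is_confounded": is_conf,
            "is_sex_de": is_sex,
            "log2fc_pop": bpop,
            "log2fc_sex": bsex,
        },
        index=pd.Index(genes, name="gene"),
    )
    return counts_df, truth


def simulate_sex(
    labels: np.ndarray,
    imbalance: float = 0.0,
    seed: int = 0,
    exact_balance: bool = False,
) -> np.ndarray:
    """Draw per-sample binary sex, optionally imbalanced across populations.

    ``imbalance`` in [0, 0.5): population k's male probability is
    0.5 + imbalance * direction_k with alternating directions, confounding
    sex with ancestry (the mechanism the inflation experiments exercise).
    ``exact_balance`` assigns exactly half of each population to each sex
    (seeded permutation), eliminating chance sex-ancestry correlation — the
    strict reading of "sex balanced across populations".
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    if exact_balance:
        if imbalance != 0:
            raise ValueError("exact_balance requires imbalance = 0")
        sex = np.zeros(len(labels), dtype=int)
        for k in np.unique(labels):
            idx = np.nonzero(labels == k)[0]
            chosen = rng.permutation(idx)[: len(idx) // 2]
            sex[chosen] = 1
        return sex
    pops = {k: i for i, k in enumerate(np.unique(labels))}
    probs = np.array(
        [0.5 + imbalance * (1 if pops[k] % 2 == 0 else -1) for k in labels]
    )
    return (rng.random(len(labels)) < probs).astype(int)
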