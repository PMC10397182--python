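"""Reference experiments on synthetic cohorts.

Each function builds a study with the synthetic generator, runs the relevant
pipeline stages, and returns the headline quantities.  These experiments
mirror, on data with known truth, the validation surfaces of the method:
paired-view genotype concordance, population-structure recovery by PCA,
canonical-correlation agreement between two PC sets, inflation control in
expression association, and mixed-model variance-component recovery.

All randomness flows from the explicit seed arguments.
"""

from __future__ import annotations

import numpy as np

from . import harmonize, popstruct, strat_dge, structcompare, synthsim, variant_qc
from .popstruct import GRM
from .variant_qc import QCThresholds


def _qc(data, maf_min=0.05, window=1000, step=50, r2_max=0.05, prune=True):
    """MAF/palindromic/region QC followed by optional LD pruning."""
    stats = variant_qc.compute_variant_stats(data, with_hwe=False)
    data, _ = variant_qc.filter_variants(data, stats, QCThresholds(maf_min=maf_min))
    if prune:
        th = QCThresholds(maf_min=maf_min, window=window, step=step, r2_max=r2_max)
        stats = variant_qc.compute_variant_stats(data, with_hwe=False)
        data = data.take_variants(variant_qc.ld_prune(data, th, maf=stats.maf))
    return data


def concordance_experiment(
    seed: int,
    genotype_error_rate: float = 0.02,
    n_per_pop: int = 50,
    n_variants: int = 2000,
) -> dict:
    """Paired array/RNAseq views -> harmonize -> per-sample concordance.

    With dosage-level error rate e in the RNAseq view only, the per-call
    mismatch probability is e, so expected concordance is 1 - e.
    """
    full, _ = synthsim.simulate_genotypes(
        synthsim.PopulationModel(
            k=3, fst=0.1, n_per_pop=n_per_pop, n_variants=n_variants, seed=seed
        )
    )
    arr, rna = synthsim.derive_paired_views(
        full,
        synthsim.AscertainmentModel(
            genotype_error_rate=genotype_error_rate,
            strand_flip_fraction=0.1,
            seed=seed + 1,
        ),
    )
    records = harmonize.match_variants(arr.variants, rna.variants)
    usable = [m for m in records if m.action != "ambiguous_palindromic"]
    rna_al = harmonize.align_genotypes(rna, records)
    arr_sub = arr.take_variants([m.index_a for m in usable])
    rep = harmonize.sample_concordance(arr_sub, rna_al, [(s, s) for s in arr.samples])
    total_calls = int(rep.n_compared.sum())
    return {
        "mean_concordance": rep.mean_concordance,
        "expected": 1 - genotype_error_rate,
        "n_pairs": len(rep.pairs),
        "total_calls": total_calls,
        "binomial_se": float(
            np.sqrt(genotype_error_rate * (1 - genotype_error_rate) / max(total_calls, 1))
        )
        if genotype_error_rate > 0
        else 0.0,
        "match_summary": harmonize.match_summary(records),
    }


def structure_recovery_experiment(
    seed: int, k: int = 3, fst: float = 0.1, n_per_pop: int = 100, n_variants: int = 5000
) -> dict:
    """QC -> LD prune -> PCA -> k-means on PC1-PC2 vs true population labels."""
    from sklearn.cluster import KMeans
    from sklearn.metrics import adjusted_rand_score

    full, labels = synthsim.simulate_genotypes(
        synthsim.PopulationModel(
            k=k, fst=fst, n_per_pop=n_per_pop, n_variants=n_variants, seed=seed
        )
    )
    data = _qc(full)
    res = popstruct.pca(data, 2)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed % (2**31)).fit(
        res.scores[:, :2]
    )
    ari = adjusted_rand_score(labels, km.labels_)
    return {
        "adjusted_rand_index": float(ari),
        "n_samples": full.n_samples,
        "n_variants_used": data.n_variants,
    }


def pc_agreement_experiment(
    seed: int,
    k_pcs: int = 10,
    n_per_pop: int = 100,
    n_variants: int = 5000,
) -> dict:
    """Array-view PCs vs RNAseq-view PCs: CCA with Wilks sequential tests.

    The RNAseq view sees 20% of the variants with 5% base missingness and 2%
    genotype error; both views are QC'd and PCA'd to ``k_pcs`` components.
    """
    full, _ = synthsim.simulate_genotypes(
        synthsim.PopulationModel(
            k=3, fst=0.1, n_per_pop=n_per_pop, n_variants=n_variants, seed=seed
        )
    )
    arr, rna = synthsim.derive_paired_views(
        full, synthsim.AscertainmentModel(seed=seed + 1)
    )
    arr_q = _qc(arr, prune=False)
    rna_q = _qc(rna, prune=False)
    pcs_arr = popstruct.pca(arr_q, k_pcs)
    pcs_rna = popstruct.pca(rna_q, k_pcs)
    cca = structcompare.canonical_correlation(pcs_rna.scores, pcs_arr.scores)
    lam_direct = np.array(
        [np.prod(1 - cca.correlations[i:] ** 2) for i in range(cca.s)]
    )
    sv = structcompare.shared_variance(cca, pcs_arr.scores)
    return {
        "canonical_correlations": cca.correlations,
        "R_c1": float(cca.correlations[0]),
        "n_significant_dims": int((cca.p_values < 0.05).sum()),
        "wilks_lambda_identity_max_err": float(
            np.abs(cca.wilks_lambda - lam_direct).max()
        ),
        "cumulative_shared_variance_3": float(sv["cumulative"][min(2, cca.s - 1)]),
        "n_samples": full.n_samples,
    }


def inflation_experiment(
    seed: int,
    imbalance: float = 0.25,
    frac_confounded: float = 0.1,
    n_per_pop: int = 100,
    n_genes: int = 2000,
    n_variants: int = 2000,
) -> dict:
    """Sex-association inflation with/without genotype PCs as covariates.

    ``imbalance`` > 0 confounds sex with ancestry so ancestry-associated
    genes leak into the sex contrast; adjusting for the top-2 genotype PCs
    then deflates the statistics (m < 1).  The balanced null —
    ``imbalance = 0`` (exact within-population balance) with
    ``frac_confounded = 0`` — leaves the PCs nothing to correct, so m sits
    near 1.  (With confounded genes present but sex balanced, PCs still
    absorb ancestry variance in those genes and sharpen their sex statistics,
    pushing the aggregate median above 1: precision gain, not stratification.)
    """
    full, labels = synthsim.simulate_genotypes(
        synthsim.PopulationModel(
            k=2, fst=0.1, n_per_pop=n_per_pop, n_variants=n_variants, seed=seed
        )
    )
    sex = synthsim.simulate_sex(
        labels, imbalance=imbalance, seed=seed + 1, exact_balance=imbalance == 0
    )
    counts, _ = synthsim.simulate_counts(
        labels,
        sex,
        synthsim.ExpressionModel(
            n_genes=n_genes, frac_confounded=frac_confounded, seed=seed + 2
        ),
    )
    pcs = popstruct.pca(_qc(full, prune=False), 2).scores
    expr = strat_dge.ExpressionMatrix(counts)
    expr = strat_dge.cpm_filter(expr)
    with_pcs = strat_dge.dge_lm(expr, sex.astype(float), None, pcs)
    without = strat_dge.dge_lm(expr, sex.astype(float), None, None)
    rep = strat_dge.inflation_m(with_pcs, without)
    return {
        "m": rep.m,
        "median_chisq_with_pcs": rep.median_chisq_with_pcs,
        "median_chisq_without_pcs": rep.median_chisq_without_pcs,
        "n_genes": len(expr.counts),
        "n_samples": len(sex),
    }


def lmm_recovery_experiment(
    seed: int,
    h2: float = 0.5,
    n_replicates: int = 50,
    n_samples: int = 200,
    n_variants: int = 2000,
) -> dict:
    """Variance-ratio recovery of the REML mixed model on a structured GRM."""
    full, _ = synthsim.simulate_genotypes(
        synthsim.PopulationModel(
            k=2, fst=0.1, n_per_pop=n_samples // 2, n_variants=n_variants, seed=seed
        )
    )
    data = _qc(full, maf_min=0.01, prune=False)
    grm = popstruct.compute_grm(popstruct.standardize(data))
    d, q = np.linalg.eigh(grm.matrix)
    d = np.clip(d, 0, None)
    n = n_samples
    x = np.ones((n, 1))
    ratios = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + 100 + rep)
        g = q @ (np.sqrt(d) * rng.normal(size=n))
        g = g / g.std()
        e = rng.normal(size=n)
        y = np.sqrt(h2) * g + np.sqrt(1 - h2) * e
        ratios.append(strat_dge.reml_lmm(y, x, grm).ratio)
    return {
        "mean_ratio": float(np.mean(ratios)),
        "true_ratio": h2,
        "n_replicates": n_replicates,
        "n_samples": n,
    }


def grm_identity_limit_check(seed: int, n: int = 120) -> dict:
    """Max |Wald difference| between the GRM=I mixed model and OLS."""
    rng = np.random.default_rng(seed)
    x = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    y = x @ np.array([1.0, 0.4, -0.3]) + rng.normal(size=n)
    grm = GRM(np.eye(n), 1, [f"s{i}" for i in range(n)])
    fit = strat_dge.reml_lmm(y, x, grm)
    beta = np.linalg.lstsq(x, y, rcond=None)[0]
    resid = y - x @ beta
    s2 = (resid**2).sum() / (n - x.shape[1])
    wald = (beta / np.sqrt(np.diag(np.linalg.inv(x.T @ x)) * s2)) ** 2
    return {
        "max_wald_abs_diff": float(np.abs(fit.wald_chisq - wald).max()),
        "total_variance_abs_diff": float(abs(fit.sigma_g2 + fit.sigma_e2 - s2)),
        "n_samples": n,
    }


def hwe_oracle_check(max_total: int = 50) -> dict:
    """Max |p difference| between the HWE exact test and an exact-rational
    full enumeration over every genotype configuration with total <= max_total."""
    import math
    from fractions import Fraction

    worst = 0.0
    n_checked = 0
    for n in range(1, max_total + 1):
        for n1 in range(n + 1):
            for het in range(n - n1 + 1):
                n2 = n - n1 - het
                rare = 2 * min(n1, n2) + het
                if rare == 0:
                    expected = 1.0
                else:
                    weights = {}
                    for h in range(rare % 2, min(rare, 2 * n - rare) + 1, 2):
                        hr = (rare - h) // 2
                        hc = n - h - hr
                        weights[h] = Fraction(
                            math.factorial(n) * 2**h,
                            math.factorial(hr) * math.factorial(h) * math.factorial(hc),
                        )
                    w_obs = weights[het]
                    expected = float(
                        sum(w for w in weights.values() if w <= w_obs)
                        / sum(weights.values())
                    )
                got = variant_qc.hwe_exact_test(n1, het, n2)
                worst = max(worst, abs(got - expected))
                n_checked += 1
    return {"max_abs_diff": worst, "n_configurations": n_checked}
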