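"""Strand-flip-aware variant matching, genotype alignment, and concordance.

Two genotype sources for the same loci (e.g. RNAseq-called and array) may
report a variant with the alleles in opposite order (swap), on opposite DNA
strands (flip, Watson-Crick complement), or both.  Matching is by
(chrom, pos); the allele pair then decides the orientation.  Palindromic
(A/T, C/G) variants are categorically excluded: flip and swap are
indistinguishable for them without frequency heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genotype_io import (
    MISSING,
    GenotypeDataset,
    Variant,
    VariantPanel,
    complement_allele,
    is_palindromic_pair,
)

ACTIONS = ("direct", "swap", "flip", "flip_swap", "unmatched", "ambiguous_palindromic")


@dataclass(frozen=True)
class MatchRecord:
    """How a (chrom, pos) shared by two variant sets relates allele-wise.

    ``swap`` and ``flip_swap`` imply the dosage recode d -> 2-d when aligning
    B to A.  ``ambiguous_palindromic`` records never enter concordance or
    intersection outputs.
    """

    key: tuple[str, int]
    action: str
    index_a: int
    index_b: int


@dataclass
class ConcordanceReport:
    """Per-sample-pair genotype concordance over harmonized shared variants.

    ``concordance = n_identical / n_compared`` with the denominator counting
    variants non-missing in both sources.  Pairs with no comparable variant
    are flagged and excluded from the cohort mean.
    """

    pairs: list[tuple[str, str]]
    n_compared: np.ndarray
    n_identical: np.ndarray

    @property
    def concordance(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.n_compared > 0, self.n_identical / self.n_compared, np.nan
            )

    @property
    def mean_concordance(self) -> float:
        c = self.concordance
        ok = ~np.isnan(c)
        return float(c[ok].mean()) if ok.any() else float("nan")


def classify_pair(ref_a: str, alt_a: str, ref_b: str, alt_b: str) -> str:
    """Orientation of B's allele pair relative to A's."""
    if is_palindromic_pair(ref_a, alt_a) or is_palindromic_pair(ref_b, alt_b):
        return "ambiguous_palindromic"
    if (ref_a, alt_a) == (ref_b, alt_b):
        return "direct"
    if (ref_a, alt_a) == (alt_b, ref_b):
        return "swap"
    cr, ca = complement_allele(ref_b), complement_allele(alt_b)
    if (ref_a, alt_a) == (cr, ca):
        return "flip"
    if (ref_a, alt_a) == (ca, cr):
        return "flip_swap"
    return "unmatched"


def match_variants(a: list[Variant], b: list[Variant]) -> list[MatchRecord]:
    """Match two deduplicated variant lists on (chrom, pos) with strand logic.

    Returns one record per shared position, in A's order.
    """
    b_by_key = {v.key: i for i, v in enumerate(b)}
    if len(b_by_key) != len(b):
        raise ValueError("dataset B has duplicated (chrom, pos) entries")
    records = []
    seen_a: set[tuple[str, int]] = set()
    for ia, va in enumerate(a):
        if va.key in seen_a:
            raise ValueError("dataset A has duplicated (chrom, pos) entries")
        seen_a.add(va.key)
        ib = b_by_key.get(va.key)
        if ib is None:
            continue
        vb = b[ib]
        action = classify_pair(va.ref, va.alt, vb.ref, vb.alt)
        records.append(MatchRecord(va.key, action, ia, ib))
    return records


def match_summary(records: list[MatchRecord]) -> dict[str, int]:
    out = {a: 0 for a in ACTIONS}
    for r in records:
        out[r.action] += 1
    return out


def align_genotypes(b: GenotypeDataset, matches: list[MatchRecord]) -> GenotypeDataset:
    """Restrict B to matched variants and rewrite it in A's orientation.

    Dosages are recoded d -> 2-d for swap/flip_swap; missing stays missing;
    variant metadata is rewritten to A's ref/alt strand and order.  Only
    direct/swap/flip/flip_swap records are used.
    """
    usable = [m for m in matches if m.action in ("direct", "swap", "flip", "flip_swap")]
    for m in usable:
        if not (0 <= m.index_b < b.n_variants):
            raise IndexError(f"match record references invalid B index {m.index_b}")
    idx = [m.index_b for m in usable]
    dosage = b.dosage[:, idx].copy()
    variants = []
    for col, m in enumerate(usable):
        v = b.variants[m.index_b]
        ref, alt = v.ref, v.alt
        if m.action in ("flip", "flip_swap"):
            ref, alt = complement_allele(ref), complement_allele(alt)
        if m.action in ("swap", "flip_swap"):
            ref, alt = alt, ref
            nz = dosage[:, col] != MISSING
            dosage[nz, col] = 2 - dosage[nz, col]
        variants.append(replace(v, ref=ref, alt=alt))
    return GenotypeDataset(variants, list(b.samples), dosage)


def sample_concordance(
    a: GenotypeDataset,
    b_aligned: GenotypeDataset,
    sample_pairs: list[tuple[str, str]],
) -> ConcordanceReport:
    """Genotype concordance per sample pair over the shared variant set.

    ``a`` and ``b_aligned`` must carry the matched variants in identical
    order (as produced by :func:`align_genotypes` plus ``take_variants`` on A).
    """
    if a.variant_keys() != b_aligned.variant_keys():
        raise ValueError("A and aligned B must share the matched variant set in order")
    ia = {s: i for i, s in enumerate(a.samples)}
    ib = {s: i for i, s in enumerate(b_aligned.samples)}
    unknown = [p for p in sample_pairs if p[0] not in ia or p[1] not in ib]
    if unknown:
        raise KeyError(f"unknown sample ids in pairs: {unknown}")
    n_comp = np.zeros(len(sample_pairs), dtype=int)
    n_id = np.zeros(len(sample_pairs), dtype=int)
    for k, (sa, sb) in enumerate(sample_pairs):
        ga = a.dosage[ia[sa]]
        gb = b_aligned.dosage[ib[sb]]
        ok = (ga != MISSING) & (gb != MISSING)
        n_comp[k] = int(ok.sum())
        n_id[k] = int((ga[ok] == gb[ok]).sum())
    return ConcordanceReport(list(sample_pairs), n_comp, n_id)


def intersect_with_panel(data: GenotypeDataset, panel: VariantPanel) -> GenotypeDataset:
    """Keep variants present in the panel with compatible alleles.

    A variant is kept when its (chrom, pos) is in the panel and its allele
    pair matches the panel entry under direct/swap/flip/flip_swap.  Alleles
    are not reoriented (orientation is irrelevant for downstream PCA);
    variant order is preserved.  Palindromic variants never match.
    """
    lut = panel.lookup()
    keep = []
    for j, v in enumerate(data.variants):
        entry = lut.get(v.key)
        if entry is None:
            continue
        action = classify_pair(v.ref, v.alt, entry[0], entry[1])
        if action in ("direct", "swap", "flip", "flip_swap"):
            keep.append(j)
    return data.take_variants(keep)
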