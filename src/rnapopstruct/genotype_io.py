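"""Genotype data model and file I/O.

The in-memory representation is a :class:`GenotypeDataset`: an ordered list of
biallelic SNP :class:`Variant` records, an ordered list of sample identifiers,
and a samples x variants dosage matrix counting copies of the alternate allele
(0, 1, 2) with ``MISSING`` (-1) as the single missingness sentinel.

Readers accept multi-sample VCF v4.2 (via cyvcf2) and a plain-TSV reference SNP
panel (chrom, pos, allele1, allele2[, id]).  The principal-component writer
emits the whitespace-delimited ``FID IID PC1..PCk`` layout that downstream
genetics tools expect.

Coordinates are 1-based throughout; chromosome labels are normalized by
stripping a leading ``chr``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AUTOSOMES = frozenset(str(c) for c in range(1, 23))


class VcfFormatError(ValueError):
    """Raised for structurally invalid VCF content (e.g. a record without GT)."""


def normalize_chrom(chrom: str) -> str:
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


def complement_allele(base: str) -> str:
    return _COMPLEMENT[base]


def is_palindromic_pair(a1: str, a2: str) -> bool:
    """True for A/T or C/G variants, whose strand cannot be resolved from alleles."""
    return _COMPLEMENT.get(a1) == a2


def _chrom_sort_key(chrom: str):
    return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP.

    ``pos`` is 1-based; ``ref``/``alt`` are single bases in {A,C,G,T} and must
    differ; ``id`` may be ".".
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = "."

    def __post_init__(self):
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"non-ACGT allele in {self.chrom}:{self.pos} {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def is_palindromic(self) -> bool:
        return is_palindromic_pair(self.ref, self.alt)

    @property
    def is_autosomal(self) -> bool:
        return self.chrom in _AUTOSOMES

    @property
    def key(self):
        return (self.chrom, self.pos)


@dataclass
class GenotypeDataset:
    """Samples x variants dosage calls with variant and sample metadata.

    ``dosage`` has shape (n_samples, n_variants), dtype int8, entries in
    {0, 1, 2, MISSING}.  Variant order is the file order after sorting by
    (chrom, pos); sample identifiers are unique.
    """

    variants: list[Variant]
    samples: list[str]
    dosage: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {len(self.variants)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be in {0,1,2} or MISSING")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def take_variants(self, idx) -> "GenotypeDataset":
        idx = np.asarray(idx, dtype=int)
        return GenotypeDataset(
            [self.variants[i] for i in idx], list(self.samples), self.dosage[:, idx]
        )

    def take_samples(self, idx) -> "GenotypeDataset":
        idx = np.asarray(idx, dtype=int)
        return GenotypeDataset(
            list(self.variants), [self.samples[i] for i in idx], self.dosage[idx, :]
        )

    def variant_keys(self) -> list[tuple[str, int]]:
        return [v.key for v in self.variants]


@dataclass
class VariantPanel:
    """Reference SNP panel: (chrom, pos, allele1, allele2, id) entries.

    (chrom, pos) is unique; the allele pair is unordered for matching purposes.
    """

    entries: pd.DataFrame  # columns: chrom, pos, a1, a2, id
    n_duplicates_dropped: int = 0

    def __post_init__(self):
        self.entries = self.entries.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self) -> dict[tuple[str, int], tuple[str, str]]:
        return {
            (row.chrom, int(row.pos)): (row.a1, row.a2)
            for row in self.entries.itertuples(index=False)
        }


@dataclass
class SkipSummary:
    """Counts of VCF records excluded on read, by reason."""

    multiallelic: int = 0
    non_snp: int = 0
    filtered: int = 0
    no_gt: int = 0

    def total(self) -> int:
        return self.multiallelic + self.non_snp + self.filtered + self.no_gt


def read_vcf(path, keep_samples=None) -> tuple[GenotypeDataset, SkipSummary]:
    """Read biallelic SNP genotypes from a VCF v4.2 file.

    Only biallelic SNP records with FILTER in {PASS, "."} are retained;
    multi-allelic records, indels/MNPs and soft-filtered records are skipped
    and counted in the returned :class:`SkipSummary`.  ``./.`` and half-calls
    map to MISSING; phase is ignored (0|1 == 0/1 -> dosage 1).  Records are
    sorted by (chrom, pos).

    Parameters
    ----------
    path : str
        VCF file path (plain or bgzipped).
    keep_samples : sequence of str, optional
        Restrict to these samples (order as given).

    Returns
    -------
    (GenotypeDataset, SkipSummary)
    """
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise FileNotFoundError(path)

    header = VCF(str(path))
    all_samples = list(header.samples)
    header.close()
    if keep_samples is not None:
        unknown = [s for s in keep_samples if s not in all_samples]
        if unknown:
            raise KeyError(f"samples not present in VCF: {unknown}")
        vcf = VCF(str(path), samples=list(keep_samples))
    else:
        vcf = VCF(str(path))
    samples = list(vcf.samples)

    skip = SkipSummary()
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            skip.multiallelic += 1
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            skip.non_snp += 1
            continue
        if rec.FILTER is not None:  # cyvcf2: None means PASS or "."
            skip.filtered += 1
            continue
        if "GT" not in rec.FORMAT:
            raise VcfFormatError(
                f"record {normalize_chrom(rec.CHROM)}:{rec.POS} has no GT field"
            )
        col = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            a, b = gt[0], gt[1]
            if a in (0, 1) and b in (0, 1):
                col[i] = a + b
        variants.append(
            Variant(normalize_chrom(rec.CHROM), rec.POS, ref, alt, rec.ID or ".")
        )
        columns.append(col)
    vcf.close()

    order = sorted(
        range(len(variants)),
        key=lambda i: (_chrom_sort_key(variants[i].chrom), variants[i].pos),
    )
    variants = [variants[i] for i in order]
    dosage = (
        np.stack([columns[i] for i in order], axis=1)
        if columns
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeDataset(variants, samples, dosage), skip


def write_vcf(data: GenotypeDataset, path) -> None:
    """Write a GenotypeDataset as a minimal VCF v4.2 (GT only, FILTER=PASS)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted({v.chrom for v in data.variants}, key=_chrom_sort_key):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(data.samples)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", int(MISSING): "./."}
        for j, v in enumerate(data.variants):
            gts = "\t".join(gt_map[int(d)] for d in data.dosage[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_panel(path) -> VariantPanel:
    """Read a reference SNP panel TSV (chrom, pos, a1, a2[, id]).

    A header line is auto-detected by a non-numeric ``pos`` in row 1.
    Duplicated (chrom, pos) rows beyond the first are dropped and counted in
    ``n_duplicates_dropped``.  Non-ACGT alleles raise with the line number.
    """
    rows = []
    n_dup = 0
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return VariantPanel(
            pd.DataFrame(columns=["chrom", "pos", "a1", "a2", "id"]), 0
        )
    start = 0
    first = lines[0].split("\t")
    if len(first) >= 2 and not first[1].strip().isdigit():
        start = 1  # header
    for lineno, ln in enumerate(lines[start:], start=start + 1):
        parts = ln.split("\t")
        if len(parts) < 4:
            raise ValueError(f"panel line {lineno}: expected >= 4 columns")
        chrom = normalize_chrom(parts[0].strip())
        pos = int(parts[1])
        a1, a2 = parts[2].strip().upper(), parts[3].strip().upper()
        if a1 not in _BASES or a2 not in _BASES:
            raise ValueError(f"panel line {lineno}: non-ACGT allele {a1}/{a2}")
        vid = parts[4].strip() if len(parts) > 4 and parts[4].strip() else "."
        key = (chrom, pos)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        rows.append((chrom, pos, a1, a2, vid))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "a1", "a2", "id"])
    return VariantPanel(df, n_dup)


def write_pcs(result, path) -> None:
    """Write PC scores as whitespace-delimited ``FID IID PC1..PCk``.

    FID is duplicated from IID; floats are printed at 6 significant digits;
    row order equals the sample order of the PCA result.
    """
    scores = np.asarray(result.scores)
    k = scores.shape[1]
    if k < 1:
        raise ValueError("PCResult must have k >= 1 components")
    with open(path, "w") as fh:
        fh.write("FID IID " + " ".join(f"PC{i + 1}" for i in range(k)) + "\n")
        for sid, row in zip(result.samples, scores):
            fh.write(f"{sid} {sid} " + " ".join(f"{x:.6g}" for x in row) + "\n")


def read_pcs(path) -> tuple[list[str], np.ndarray]:
    """Read an ``FID IID PC1..PCk`` table; returns (sample ids, scores)."""
    df = pd.read_csv(path, sep=r"\s+")
    pc_cols = [c for c in df.columns if c.upper().startswith("PC")]
    return [str(s) for s in df["IID"]], df[pc_cols].to_numpy(dtype=float)
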