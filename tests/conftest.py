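import numpy as np
import pytest

from rnapopstruct.genotype_io import GenotypeDataset, Variant


def make_dataset(variant_specs, dosage, samples=None):
    """Build a GenotypeDataset from (chrom, pos, ref, alt) tuples and a
    samples x variants dosage array."""
    variants = [Variant(str(c), int(p), r, a) for (c, p, r, a) in variant_specs]
    dosage = np.asarray(dosage, dtype=np.int8)
    if samples is None:
        samples = [f"s{i}" for i in range(dosage.shape[0])]
    return GenotypeDataset(variants, samples, dosage)


@pytest.fixture
def tiny_dataset():
    """3 samples x 4 autosomal non-palindromic variants, one missing call."""
    return make_dataset(
        [("1", 100, "A", "G"), ("1", 200, "C", "T"), ("2", 50, "G", "A"), ("2", 60, "T", "C")],
        [[0, 1, 2, 0], [1, 1, 0, 1], [2, -1, 1, 2]],
    )


def write_vcf_text(path, records, samples):
    """Write a hand-rolled VCF for reader tests.

    records: list of (chrom, pos, id, ref, alt, filter, format, gt_strings).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FILTER=<ID=lowqual,Description="Low quality">\n')
        for c in sorted({str(r[0]) for r in records}):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for chrom, pos, vid, ref, alt, filt, fmt, gts in records:
            fh.write(
                f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t{filt}\t.\t{fmt}\t"
                + "\t".join(gts) + "\n"
            )
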