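"""Build an SBS-96 count matrix from VCF files and a reference genome.

Writes a toy reference FASTA and two small somatic-SNV VCFs into a
temporary directory, then classifies each variant by its substitution type
and trinucleotide context (collapsing purine references onto the pyrimidine
strand). Records that are not simple SNVs, or whose REF disagrees with the
genome, are skipped and tallied.
"""

import tempfile
from pathlib import Path

import numpy as np

from sigsolve import IndexedGenome, build_count_matrix

workdir = Path(tempfile.mkdtemp())
genome_seq = "ACGTACGTGGATCCATGCATTTACGCGTATAT"
(workdir / "ref.fa").write_text(f">chr1\n{genome_seq}\n")

header = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=32>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)
# sample 1: two SNVs (one purine-reference), one indel to be skipped
(workdir / "s1.vcf").write_text(
    header
    + "chr1\t2\t.\tC\tT\t.\tPASS\t.\n"     # A[C>T]G
    + "chr1\t9\t.\tG\tT\t.\tPASS\t.\n"     # purine ref: collapses by revcomp
    + "chr1\t15\t.\tA\tAT\t.\tPASS\t.\n"   # insertion: skipped
)
# sample 2: one SNV whose REF contradicts the genome (skipped), one good SNV
(workdir / "s2.vcf").write_text(
    header
    + "chr1\t6\t.\tT\tA\t.\tPASS\t.\n"     # genome has C at pos 6: mismatch
    + "chr1\t22\t.\tT\tG\t.\tPASS\t.\n"
)

genome = IndexedGenome(workdir / "ref.fa")
result = build_count_matrix(
    [("patient1", workdir / "s1.vcf"), ("patient2", workdir / "s2.vcf")], genome
)

m = result.matrix
print(f"classified {result.n_classified} SNVs; skipped "
      f"{result.n_non_snv} non-SNV and {result.n_ref_mismatch} REF-mismatch "
      f"record(s)\n")
print("non-zero channels per sample:")
for i, sample in enumerate(m.samples):
    hit = np.flatnonzero(m.counts[i])
    channels = {m.catalog.labels[j]: int(m.counts[i, j]) for j in hit}
    print(f"  {sample}: {channels}")
print("\neach count sits in exactly one of the 96 substitution-context channels.")
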