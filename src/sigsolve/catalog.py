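"""Mutation count matrices: construction from VCF + reference genome, and TSV IO.

The central container is :class:`CountMatrix` — the samples × channels matrix
``A`` of classified somatic mutation counts. For SNVs it is built directly
from VCF files and an indexed FASTA genome; matrices over other channel sets
(DBS-78, ID-83) are read from TSV as produced by external matrix generators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .channels import (
    ChannelCatalog,
    UnclassifiableContextError,
    classify_snv,
)

__all__ = [
    "CountMatrix",
    "IndexedGenome",
    "CatalogBuildResult",
    "build_count_matrix",
    "read_count_matrix",
    "write_count_matrix",
]

logger = logging.getLogger(__name__)

_SAMPLE_COL = "Sample"


@dataclass
class CountMatrix:
    """Samples × mutation-type channels matrix of non-negative integer counts.

    Rows are samples (:math:`n_g`), columns the channels of ``catalog``
    (:math:`n_t`). The row sum is each sample's total classified mutation
    count.
    """

    samples: list[str]
    catalog: ChannelCatalog
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.samples), len(self.catalog)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.samples)}, {len(self.catalog)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.samples, name=_SAMPLE_COL),
            columns=list(self.catalog.labels),
        )


class IndexedGenome:
    """Random access to an indexed FASTA reference genome.

    Serves single bases and trinucleotide contexts at 1-based coordinates.
    Soft-masked (lower-case) bases are uppercased. Chromosome names are
    resolved with and without a ``chr`` prefix.
    """

    def __init__(self, fasta_path: str | Path):
        self.path = Path(fasta_path)
        self._fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
        self._names = set(self._fasta.keys())

    def resolve_chrom(self, chrom: str) -> str:
        if chrom in self._names:
            return chrom
        alt = chrom[3:] if chrom.startswith("chr") else f"chr{chrom}"
        if alt in self._names:
            return alt
        raise KeyError(f"chromosome {chrom!r} not found in {self.path.name}")

    def base(self, chrom: str, pos: int) -> str:
        """Uppercase base at 1-based ``pos``; out-of-range is an error."""
        chrom = self.resolve_chrom(chrom)
        n = len(self._fasta[chrom])
        if not 1 <= pos <= n:
            raise IndexError(f"position {pos} outside {chrom} (length {n})")
        return str(self._fasta[chrom][pos - 1 : pos])

    def context(self, chrom: str, pos: int) -> tuple[str, str, str]:
        """(5' neighbour, reference base, 3' neighbour) around 1-based ``pos``."""
        chrom = self.resolve_chrom(chrom)
        n = len(self._fasta[chrom])
        if not 2 <= pos <= n - 1:
            raise IndexError(f"position {pos} lacks flanking context on {chrom}")
        seq = str(self._fasta[chrom][pos - 2 : pos + 1])
        return seq[0], seq[1], seq[2]


@dataclass
class CatalogBuildResult:
    """A built count matrix plus bookkeeping of what was skipped and why."""

    matrix: CountMatrix
    n_classified: int = 0
    n_non_snv: int = 0
    n_ref_mismatch: int = 0
    n_unclassifiable: int = 0

    @property
    def n_skipped(self) -> int:
        return self.n_non_snv + self.n_ref_mismatch + self.n_unclassifiable


def _iter_candidate_snvs(path: str | Path):
    """Yield (chrom, pos, ref, alt, is_snv) per ALT allele of a VCF file.

    Multi-allelic records are split into one candidate per ALT. Records whose
    REF or ALT is not a single A/C/G/T base (indels, MNVs, symbolic alleles,
    breakends) are flagged non-SNV.
    """
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            ref = (rec.ref or "").upper()
            for alt in rec.alts or ():
                alt = (alt or "").upper()
                is_snv = (
                    len(ref) == 1
                    and len(alt) == 1
                    and ref in "ACGT"
                    and alt in "ACGT"
                    and ref != alt
                )
                yield rec.chrom, rec.pos, ref, alt, is_snv


def build_count_matrix(
    vcf_sources: Mapping[str, str | Path] | Sequence[tuple[str, str | Path]],
    genome: IndexedGenome,
) -> CatalogBuildResult:
    """Build an SBS-96 count matrix from per-sample VCF files.

    ``vcf_sources`` maps sample label → VCF path (or is a sequence of
    ``(label, path)`` pairs; order defines row order). Each passing SNV
    increments exactly one channel. Non-SNV records, records whose VCF REF
    disagrees with the genome base, and SNVs with ambiguous context are
    skipped and tallied in the returned :class:`CatalogBuildResult`.
    """
    if isinstance(vcf_sources, Mapping):
        items = list(vcf_sources.items())
    else:
        items = list(vcf_sources)
    samples = [s for s, _ in items]
    catalog = ChannelCatalog.sbs96()
    counts = np.zeros((len(samples), len(catalog)), dtype=np.int64)
    result = CatalogBuildResult(CountMatrix(samples, catalog, counts))

    for row, (sample, path) in enumerate(items):
        n_records = 0
        for chrom, pos, ref, alt, is_snv in _iter_candidate_snvs(path):
            n_records += 1
            if not is_snv:
                result.n_non_snv += 1
                continue
            left, genome_ref, right = genome.context(chrom, pos)
            if genome_ref != ref:
                result.n_ref_mismatch += 1
                continue
            try:
                channel = classify_snv(ref, alt, left, right)
            except UnclassifiableContextError:
                result.n_unclassifiable += 1
                continue
            counts[row, channel] += 1
            result.n_classified += 1
        if n_records == 0:
            logger.warning("VCF %s for sample %s contains no records", path, sample)

    result.matrix = CountMatrix(samples, catalog, counts)
    logger.info(
        "catalog build: %d classified, %d non-SNV, %d REF-mismatch, "
        "%d unclassifiable",
        result.n_classified, result.n_non_snv, result.n_ref_mismatch,
        result.n_unclassifiable,
    )
    return result


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a count matrix TSV (header = channel labels, first column = sample).

    The channel set is recognised from the labels (SBS-96) or the column
    count (78 → DBS78, 83 → ID83); anything else is a custom catalog.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id(s) in {path}: {dupes}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = np.argwhere(~df.map(lambda x: isinstance(x, (int, np.integer))).to_numpy())
        r, c = bad[0]
        raise ValueError(
            f"non-numeric cell at sample {df.index[r]!r}, channel {df.columns[c]!r}"
        )
    if np.any(values != np.floor(values)):
        r, c = np.argwhere(values != np.floor(values))[0]
        raise ValueError(
            f"non-integer count at sample {df.index[r]!r}, channel {df.columns[c]!r}"
        )
    if np.any(values < 0):
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at sample {df.index[r]!r}, channel {df.columns[c]!r}"
        )
    catalog = ChannelCatalog.from_labels(df.columns)
    return CountMatrix(list(map(str, df.index)), catalog, values.astype(np.int64))


def write_count_matrix(m: CountMatrix, path: str | Path) -> None:
    """Write a count matrix TSV; ``read_count_matrix`` is its inverse."""
    m.to_frame().to_csv(path, sep="\t")
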