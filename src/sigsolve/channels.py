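"""Mutation-type channel sets and SNV classification.

Single-base substitutions are classified into the SBS-96 channel set: six
pyrimidine-referenced substitution classes (C>A, C>G, C>T, T>A, T>C, T>G)
times the sixteen combinations of 5' and 3' flanking bases. Strand symmetry
is assumed, so a substitution observed on a purine reference base is mapped
to the reverse complement of its trinucleotide context before classification.

Channel ordering follows the COSMIC convention: substitution class major,
then flanking context alphabetical (5' base, then 3' base). Doublet-base
(DBS-78) and indel (ID-83) channel sets are supported as opaque label lists
for matrices computed by external tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ChannelCatalog",
    "MutationRecord",
    "UnclassifiableContextError",
    "SBS96_LABELS",
    "SUBSTITUTION_CLASSES",
    "classify_snv",
    "revcomp",
]

SUBSTITUTION_CLASSES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-DNA base in {seq!r}") from exc


def _sbs96_labels() -> tuple[str, ...]:
    return tuple(
        f"{left}[{sub}]{right}"
        for sub in SUBSTITUTION_CLASSES
        for left in _BASES
        for right in _BASES
    )


SBS96_LABELS: tuple[str, ...] = _sbs96_labels()
_SBS96_INDEX = {label: i for i, label in enumerate(SBS96_LABELS)}


class UnclassifiableContextError(ValueError):
    """Raised when an SNV cannot be assigned a channel (e.g. an N base)."""


@dataclass(frozen=True)
class MutationRecord:
    """A single somatic SNV call.

    Positions are 1-based; ``ref`` and ``alt`` are single canonical bases and
    must differ.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for b in (self.ref, self.alt):
            if b not in _BASES:
                raise ValueError(f"non-canonical base {b!r} at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class ChannelCatalog:
    """An ordered, named set of mutation-type channels.

    ``name`` is one of ``SBS96``, ``DBS78``, ``ID83`` or ``custom``; ``labels``
    holds the ordered channel labels (the :math:`n_t` columns of a count
    matrix).
    """

    name: str
    labels: tuple[str, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def sbs96(cls) -> "ChannelCatalog":
        return cls("SBS96", SBS96_LABELS)

    @classmethod
    def from_labels(cls, labels) -> "ChannelCatalog":
        """Build a catalog from labels, recognising standard channel sets.

        A label set equal to SBS-96 (any order is rejected — order is part of
        the convention only for SBS-96 written by this package; matching is by
        exact label set) is named ``SBS96``; 78 and 83 channels dispatch to
        ``DBS78`` / ``ID83``; anything else is ``custom``.
        """
        labels = tuple(str(x) for x in labels)
        if set(labels) == set(SBS96_LABELS):
            return cls("SBS96", labels)
        if len(labels) == 78:
            return cls("DBS78", labels)
        if len(labels) == 83:
            return cls("ID83", labels)
        return cls("custom", labels)


def classify_snv(ref: str, alt: str, left: str, right: str) -> int:
    """Classify one SNV into its SBS-96 channel.

    Parameters are the reference base, alternate base and the 5' / 3'
    neighbouring reference bases. Purine reference bases are collapsed onto
    the pyrimidine strand by reverse-complementing the trinucleotide, so the
    reported reference base is always C or T.

    Returns the channel index into :data:`SBS96_LABELS`.

    Raises
    ------
    ValueError
        If ``ref == alt``.
    UnclassifiableContextError
        If any base is not one of A/C/G/T (e.g. an N in the context).
    """
    ref, alt, left, right = (b.upper() for b in (ref, alt, left, right))
    if ref == alt:
        raise ValueError(f"ref == alt ({ref}): not a substitution")
    for b in (ref, alt, left, right):
        if b not in _BASES:
            raise UnclassifiableContextError(f"unclassifiable base {b!r}")
    if ref in "AG":  # purine reference: flip to the pyrimidine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        left, right = _COMPLEMENT[right], _COMPLEMENT[left]
    return _SBS96_INDEX[f"{left}[{ref}>{alt}]{right}"]
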