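import numpy as np
import pytest

from sigsolve import (
    ChannelCatalog,
    CountMatrix,
    SignaturePanel,
    extended_panel,
    six_signature_panel,
)


@pytest.fixture(scope="session")
def panel6() -> SignaturePanel:
    return six_signature_panel()


@pytest.fixture(scope="session")
def panelx() -> SignaturePanel:
    return extended_panel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_panel(n_sigs: int, n_channels: int, rng: np.random.Generator) -> SignaturePanel:
    """Random probability rows over a custom channel set."""
    probs = rng.uniform(0.05, 1.0, size=(n_sigs, n_channels))
    probs /= probs.sum(axis=1, keepdims=True)
    labels = tuple(f"ch{j}" for j in range(n_channels))
    return SignaturePanel(
        [f"sig{i}" for i in range(n_sigs)], ChannelCatalog("custom", labels), probs
    )


def random_counts(
    n_samples: int, catalog: ChannelCatalog, rng: np.random.Generator, lam: float = 30.0
) -> CountMatrix:
    counts = rng.poisson(lam, size=(n_samples, len(catalog)))
    return CountMatrix([f"s{i}" for i in range(n_samples)], catalog, counts)


def write_fasta(path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


def write_vcf(path, records) -> None:
    """records: iterable of (chrom, pos, ref, alt) with alt possibly 'A,T'."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = {r[0] for r in records}
        for c in sorted(chroms):
            fh.write(f"##contig=<ID={c},length=1000000>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
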