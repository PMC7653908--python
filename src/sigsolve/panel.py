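"""Signature panels: probability distributions over mutation-type channels.

A :class:`SignaturePanel` is the matrix ``H`` — one row per signature, one
column per channel, each row a probability distribution (sums to one). TSV IO
accepts both the COSMIC layout (rows = channels, columns = signatures) and
the transposed layout, auto-detected from the first column.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .channels import ChannelCatalog

__all__ = ["SignaturePanel", "read_signature_panel", "write_signature_panel"]

_ROW_SUM_TOL = 1e-6
_CHANNEL_RE = re.compile(r"^[ACGT]\[[ACGT]>[ACGT]\][ACGT]$")


@dataclass
class SignaturePanel:
    """Signatures × channels matrix of per-channel mutation probabilities.

    Each of the :math:`n_k` rows sums to one within 1e-6 (renormalised
    exactly on construction; a larger deviation is an input error, never
    silently normalised away).
    """

    names: list[str]
    catalog: ChannelCatalog
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.names), len(self.catalog)):
            raise ValueError(
                f"probs shape {self.probs.shape} != "
                f"({len(self.names)}, {len(self.catalog)})"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate signature names")
        if np.any(self.probs < 0):
            raise ValueError("negative signature probabilities")
        sums = self.probs.sum(axis=1)
        bad = np.abs(sums - 1.0) > _ROW_SUM_TOL
        if np.any(bad):
            offenders = [self.names[i] for i in np.flatnonzero(bad)]
            raise ValueError(
                f"signature rows must sum to 1 within {_ROW_SUM_TOL}: {offenders}"
            )
        self.probs = self.probs / sums[:, None]

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    def row(self, name: str) -> np.ndarray:
        return self.probs[self.names.index(name)]

    def subset(self, names: Sequence[str]) -> "SignaturePanel":
        """Panel restricted to ``names``, in the given order."""
        idx = [self.names.index(n) for n in names]
        return SignaturePanel(list(names), self.catalog, self.probs[idx].copy())

    def reorder_channels(self, labels: Sequence[str]) -> "SignaturePanel":
        """Panel with channel columns permuted to match ``labels`` exactly.

        Raises ``ValueError`` listing unmatched labels if the label sets
        differ — label sets are never silently intersected.
        """
        labels = list(labels)
        have = {lab: j for j, lab in enumerate(self.catalog.labels)}
        missing = [lab for lab in labels if lab not in have]
        extra = [lab for lab in self.catalog.labels if lab not in set(labels)]
        if missing or extra:
            raise ValueError(
                f"channel label mismatch: missing from panel {missing[:5]}, "
                f"absent from target {extra[:5]}"
            )
        perm = [have[lab] for lab in labels]
        return SignaturePanel(
            list(self.names), ChannelCatalog.from_labels(labels), self.probs[:, perm]
        )

    def to_frame(self) -> pd.DataFrame:
        """COSMIC layout: rows = channels, columns = signatures."""
        return pd.DataFrame(
            self.probs.T, index=pd.Index(self.catalog.labels, name="Channel"),
            columns=self.names,
        )

    @classmethod
    def concat(cls, first: "SignaturePanel", second: "SignaturePanel") -> "SignaturePanel":
        if tuple(first.catalog.labels) != tuple(second.catalog.labels):
            raise ValueError("catalogs differ; reorder_channels first")
        return cls(
            first.names + second.names, first.catalog,
            np.vstack([first.probs, second.probs]),
        )


def _looks_like_channels(values: Iterable[str]) -> bool:
    values = [str(v) for v in values]
    hits = sum(bool(_CHANNEL_RE.match(v)) for v in values)
    return len(values) > 0 and hits >= len(values) / 2


def read_signature_panel(path: str | Path) -> SignaturePanel:
    """Read a signature panel TSV, auto-detecting its orientation.

    If the first column holds channel labels (COSMIC layout) the table is
    transposed; otherwise rows are taken as signatures. Stored internally as
    signatures × channels.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if _looks_like_channels(df.index) and not _looks_like_channels(df.columns):
        df = df.T
    catalog = ChannelCatalog.from_labels(df.columns)
    return SignaturePanel(list(map(str, df.index)), catalog, df.to_numpy(dtype=float))


def write_signature_panel(panel: SignaturePanel, path: str | Path) -> None:
    """Write a panel in COSMIC layout (channels as rows), 6 significant digits."""
    panel.to_frame().to_csv(path, sep="\t", float_format="%.6g")
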