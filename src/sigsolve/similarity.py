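"""Signature similarity via the Hellinger distance.

Mutational signatures are probability distributions over mutation channels,
so similarity is measured with a metric built for distributions: the
Hellinger distance

    H(p, q) = (1/sqrt(2)) * sqrt( sum_i (sqrt(p_i) - sqrt(q_i))^2 )

which is 0 iff p == q and attains 1 exactly on disjoint supports. The
1/sqrt(2) normaliser is the convention that makes the range [0, 1].
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .panel import SignaturePanel

__all__ = ["hellinger", "distance_matrix", "best_match", "Match"]

_SUM_TOL = 1e-6


def _as_probability(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{name} must be a 1-D vector")
    if np.any(v < 0):
        raise ValueError(f"{name} has negative entries")
    s = v.sum()
    if abs(s - 1.0) > _SUM_TOL:
        raise ValueError(f"{name} sums to {s:.8g}, not 1 within {_SUM_TOL}")
    return v / s


def hellinger(p, q) -> float:
    """Hellinger distance between two probability vectors, in [0, 1].

    Vectors must have equal length, non-negative entries and sum to one
    within 1e-6 (renormalised within that tolerance; beyond it is an input
    error).
    """
    p = _as_probability(p, "p")
    q = _as_probability(q, "q")
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape[0]} vs {q.shape[0]}")
    d = np.sqrt(np.sum((np.sqrt(p) - np.sqrt(q)) ** 2) / 2.0)
    return float(min(d, 1.0))


def distance_matrix(Q: SignaturePanel, R: SignaturePanel) -> pd.DataFrame:
    """All-pairs Hellinger distances; rows = query, columns = reference."""
    if tuple(Q.catalog.labels) != tuple(R.catalog.labels):
        R = R.reorder_channels(Q.catalog.labels)
    from scipy.spatial.distance import cdist

    sq, sr = np.sqrt(Q.probs), np.sqrt(R.probs)
    d = np.minimum(cdist(sq, sr) / np.sqrt(2.0), 1.0)
    return pd.DataFrame(d, index=Q.names, columns=R.names)


class Match(NamedTuple):
    query: str
    reference: str
    distance: float


def best_match(Q: SignaturePanel, R: SignaturePanel) -> list[Match]:
    """Closest reference signature per query row, ties to earlier reference."""
    if R.n_signatures == 0:
        raise ValueError("reference panel is empty")
    D = distance_matrix(Q, R)
    out = []
    for name, row in zip(D.index, D.to_numpy()):
        j = int(np.argmin(row))  # argmin returns the first minimum: panel order
        out.append(Match(name, D.columns[j], float(row[j])))
    return out
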