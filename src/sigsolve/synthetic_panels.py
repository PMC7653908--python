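"""Synthetic reference signature panels (stand-ins, not published tables).

This module builds a deterministic, fully synthetic SBS-96 reference panel
whose signatures emulate the qualitative character of well-known COSMIC v2
processes — e.g. a clock-like CpG deamination profile (Signature.1-like), a
flat homologous-recombination-deficiency profile (Signature.3-like), a
broad T>C-leaning profile (Signature.5-like) — without reproducing any
published probability values. It exists so that simulation studies, tests
and examples are self-contained; analyses of real data should load a real
COSMIC/PCAWG panel TSV with :func:`sigsolve.panel.read_signature_panel`.

Every profile is a fixed mixture of hand-chosen class/context concentrations
plus a small tilted broad background (real signatures are never supported on
a single substitution class, and their "flat" components are not uniform);
nothing is random.
"""

from __future__ import annotations

import numpy as np

from .channels import SBS96_LABELS, ChannelCatalog
from .panel import SignaturePanel

__all__ = ["six_signature_panel", "extended_panel", "SIX_SIGNATURE_NAMES"]

#: The six signature names used by the simulation scenarios.
SIX_SIGNATURE_NAMES = (
    "Signature.1",
    "Signature.3",
    "Signature.5",
    "Signature.11",
    "Signature.18",
    "Signature.22",
)

_DECOY_NAMES = (
    "Signature.2",
    "Signature.4",
    "Signature.6",
    "Signature.8",
    "Signature.9",
    "Signature.12",
    "Signature.13",
    "Signature.16",
    "Signature.17",
    "Signature.30",
)


def _channel_parts(label: str) -> tuple[str, str, str]:
    # "A[C>T]G" -> ("A", "C>T", "G")
    return label[0], label[2:5], label[6]


def _profile(concentrations) -> np.ndarray:
    """96-vector from weighted channel concentrations.

    ``concentrations`` is a list of (mass, predicate) pairs; each mass is
    spread over the channels matching its predicate proportionally to the
    per-channel weight the predicate returns (truthy value).
    """
    v = np.zeros(96)
    for mass, pred in concentrations:
        weights = np.array(
            [float(pred(*_channel_parts(lab)) or 0.0) for lab in SBS96_LABELS]
        )
        if weights.sum() > 0:
            v += mass * weights / weights.sum()
    return v / v.sum()


# smooth context tilts used for the broad components: flanking-base
# preferences vary, they are never uniform
_LEFT_TILT = {"A": 1.6, "C": 1.2, "G": 0.8, "T": 0.6}
_RIGHT_TILT = {"A": 0.7, "C": 1.3, "G": 1.0, "T": 1.0}


def _broad(l: str, s: str, r: str) -> float:
    return _LEFT_TILT[l] * _RIGHT_TILT[r]


def _profiles() -> dict[str, np.ndarray]:
    return {
        # clock-like: C>T at CpG (3' G), sharply peaked
        "Signature.1": _profile(
            [
                (0.62, lambda l, s, r: s == "C>T" and r == "G"),
                (0.23, lambda l, s, r: s == "C>T" and r != "G"),
                (0.10, lambda l, s, r: s in ("C>A", "T>C") and _LEFT_TILT[l]),
                (0.05, _broad),
            ]
        ),
        # HRD-like: broad and near-featureless across all classes, tilted
        "Signature.3": _profile([(1.0, _broad)]),
        # broad T>C-leaning profile with a diffuse base
        "Signature.5": _profile(
            [
                (0.50, lambda l, s, r: s == "T>C" and (1.5 if l == "A" else 1.0)),
                (0.25, lambda l, s, r: s == "C>T" and _RIGHT_TILT[r]),
                (0.25, lambda l, s, r: s in ("C>A", "T>A", "T>G") and _LEFT_TILT[l]),
            ]
        ),
        # alkylating-like: C>T away from CpG
        "Signature.11": _profile(
            [
                (0.77, lambda l, s, r: s == "C>T" and r != "G"),
                (0.18, lambda l, s, r: s in ("C>A", "C>G") and _RIGHT_TILT[r]),
                (0.05, _broad),
            ]
        ),
        # oxidative-damage-like: C>A, 3' A/T preferred
        "Signature.18": _profile(
            [
                (0.62, lambda l, s, r: s == "C>A" and r in "AT"),
                (0.21, lambda l, s, r: s == "C>A" and r in "CG"),
                (0.12, lambda l, s, r: s == "T>A" and _LEFT_TILT[l]),
                (0.05, _broad),
            ]
        ),
        # aristolochic-acid-like: T>A with 5' C preference
        "Signature.22": _profile(
            [
                (0.58, lambda l, s, r: s == "T>A" and l == "C"),
                (0.25, lambda l, s, r: s == "T>A" and l != "C"),
                (0.12, lambda l, s, r: s == "T>C" and _RIGHT_TILT[r]),
                (0.05, _broad),
            ]
        ),
        # decoys used only to make panel selection non-trivial
        "Signature.2": _profile(
            [
                (0.85, lambda l, s, r: s in ("C>T", "C>G") and l == "T"),
                (0.15, _broad),
            ]
        ),
        "Signature.4": _profile(
            [
                (0.65, lambda l, s, r: s == "C>A" and l in "CT"),
                (0.20, lambda l, s, r: s == "T>A" and _RIGHT_TILT[r]),
                (0.15, _broad),
            ]
        ),
        # MMR-deficiency-like: CpG C>T overlapping Signature.1, on a broad base
        # (the panel's deliberately collinear pair, as in real reference sets)
        "Signature.6": _profile(
            [
                (0.58, lambda l, s, r: s == "C>T" and r == "G"),
                (0.16, lambda l, s, r: s == "C>T" and r != "G"),
                (0.26, _broad),
            ]
        ),
        "Signature.8": _profile(
            [
                (0.55, lambda l, s, r: s in ("C>A", "C>G") and _LEFT_TILT[l]),
                (0.45, _broad),
            ]
        ),
        # broad T>C profiles overlapping Signature.5, mirroring the redundancy
        # of T>C-heavy signatures in published reference panels
        "Signature.9": _profile(
            [
                (0.45, lambda l, s, r: s == "T>C" and _LEFT_TILT[l]),
                (0.55, _broad),
            ]
        ),
        "Signature.12": _profile(
            [
                (0.55, lambda l, s, r: s == "T>C" and _RIGHT_TILT[r]),
                (0.20, lambda l, s, r: s == "C>T"),
                (0.25, _broad),
            ]
        ),
        "Signature.13": _profile(
            [
                (0.80, lambda l, s, r: s == "C>G" and l == "T"),
                (0.12, lambda l, s, r: s == "C>T" and l == "T"),
                (0.08, _broad),
            ]
        ),
        "Signature.16": _profile(
            [
                (0.70, lambda l, s, r: s == "T>C" and (2.0 if l == "A" else 0.7)),
                (0.30, _broad),
            ]
        ),
        "Signature.17": _profile(
            [
                (0.75, lambda l, s, r: s == "T>G" and l in "CT" and r == "T"),
                (0.15, lambda l, s, r: s == "T>C" and r == "T"),
                (0.10, _broad),
            ]
        ),
        # broad C>T on a diffuse base
        "Signature.30": _profile(
            [
                (0.55, lambda l, s, r: s == "C>T" and _RIGHT_TILT[r]),
                (0.45, _broad),
            ]
        ),
    }


def six_signature_panel() -> SignaturePanel:
    """The six-signature synthetic panel used by the simulation scenarios."""
    profiles = _profiles()
    names = list(SIX_SIGNATURE_NAMES)
    return SignaturePanel(
        names, ChannelCatalog.sbs96(), np.array([profiles[n] for n in names])
    )


def extended_panel() -> SignaturePanel:
    """The six scenario signatures plus ten decoys, for selection studies.

    The decoys include deliberately collinear partners of the scenario
    signatures (a CpG C>T profile overlapping Signature.1, several broad
    T>C profiles overlapping Signature.5), mirroring the redundancy of
    published reference panels that makes signature selection non-trivial.
    """
    profiles = _profiles()
    names = sorted(profiles, key=lambda n: int(n.split(".")[1]))
    return SignaturePanel(
        names, ChannelCatalog.sbs96(), np.array([profiles[n] for n in names])
    )
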