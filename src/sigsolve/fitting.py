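"""Refitting a reference signature panel by non-negative least squares.

Given a count matrix ``A`` and a signature panel ``H``, the exposures ``W``
are estimated per sample by NNLS (rows are independent problems), minimising
the sample-size-normalised Frobenius cost

    C = ||A - W·H||_F / n_g .

To guard against overfitting, forward or backward stepwise selection over
the panel produces a cost curve; the user chooses how many signatures to
keep (an automatic elbow suggestion — the point of maximum perpendicular
distance from the chord joining the curve's endpoints — is advisory only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.optimize

from .catalog import CountMatrix
from .panel import SignaturePanel

__all__ = [
    "ExposureMatrix",
    "CostCurve",
    "CostStep",
    "align_panel",
    "nnls_exposures",
    "model_cost",
    "forward_select",
    "backward_select",
    "truncate_model",
    "elbow_index",
]

_TIE_RTOL = 1e-12


@dataclass
class ExposureMatrix:
    """Samples × signatures matrix ``W`` of mutation counts attributed."""

    samples: list[str]
    signatures: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.signatures)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.samples)}, {len(self.signatures)})"
            )
        if np.any(self.values < 0):
            raise ValueError("negative exposures")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=pd.Index(self.samples, name="Sample"),
            columns=self.signatures,
        )


@dataclass(frozen=True)
class CostStep:
    """One step of a stepwise selection: which signature moved, cost after."""

    index: int
    signature: str
    cost: float
    members: tuple[str, ...]


@dataclass
class CostCurve:
    """Ordered record of a forward or backward stepwise selection.

    ``direction`` is ``"forward"`` (signatures added to an empty model) or
    ``"backward"`` (removed from the full model). ``ranking`` lists the panel
    signatures from most to least important: addition order for forward,
    reverse removal order for backward.
    """

    direction: str
    steps: list[CostStep]

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"unknown direction {self.direction!r}")
        for i, step in enumerate(self.steps, start=1):
            if step.index != i:
                raise ValueError("step indices must be consecutive from 1")

    @property
    def costs(self) -> np.ndarray:
        return np.array([s.cost for s in self.steps])

    @property
    def ranking(self) -> list[str]:
        order = [s.signature for s in self.steps]
        return order if self.direction == "forward" else order[::-1]

    def elbow_suggestion(self) -> int:
        """Advisory model size: the elbow of the importance-ordered curve."""
        costs = self.costs if self.direction == "forward" else self.costs[::-1]
        return elbow_index(costs) + 1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "step": [s.index for s in self.steps],
                "signature": [s.signature for s in self.steps],
                "cost": [s.cost for s in self.steps],
            }
        )


def align_panel(A: CountMatrix, panel: SignaturePanel) -> SignaturePanel:
    """Panel with channels reordered to match the catalog of ``A``."""
    if tuple(panel.catalog.labels) == tuple(A.catalog.labels):
        return panel
    return panel.reorder_channels(A.catalog.labels)


def _nnls_rows(counts: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Row-wise Lawson–Hanson NNLS: minimise ||row - w·H|| over w >= 0."""
    W = np.empty((counts.shape[0], H.shape[0]))
    HT = H.T
    for i, row in enumerate(counts):
        W[i], _ = scipy.optimize.nnls(HT, row.astype(float))
    return W


def nnls_exposures(A: CountMatrix, H: SignaturePanel) -> ExposureMatrix:
    """Fit exposures ``W`` by per-sample non-negative least squares.

    Each row of ``W`` minimises ``||A_row - w·H||_2`` subject to ``w >= 0``;
    sample rows are independent problems. Channel labels of ``A`` and ``H``
    must agree as sets; the panel is reordered by label.
    """
    if H.n_signatures < 1:
        raise ValueError("panel must contain at least one signature")
    H = align_panel(A, H)
    W = _nnls_rows(A.counts, H.probs)
    return ExposureMatrix(list(A.samples), list(H.names), W)


def model_cost(A: CountMatrix, W: ExposureMatrix, H: SignaturePanel) -> float:
    """Sample-size-normalised Frobenius cost ``||A - W·H||_F / n_g``."""
    if A.n_samples == 0:
        raise ValueError("empty count matrix")
    H = align_panel(A, H)
    resid = A.counts - W.values @ H.probs
    return float(np.linalg.norm(resid, "fro") / A.n_samples)


def _cost_of(counts: np.ndarray, H: np.ndarray) -> float:
    W = _nnls_rows(counts, H)
    return float(np.linalg.norm(counts - W @ H, "fro") / counts.shape[0])


def _argbest(costs: Sequence[float]) -> int:
    """Index of the lowest cost; ties within 1e-12 relative go to the earliest."""
    best = min(costs)
    tol = abs(best) * _TIE_RTOL
    for i, c in enumerate(costs):
        if c <= best + tol:
            return i
    raise AssertionError("unreachable")


def forward_select(A: CountMatrix, panel: SignaturePanel) -> CostCurve:
    """Greedy forward selection over the panel, refitting NNLS at each trial.

    Starts from the empty model; at each step every not-yet-included
    signature is trialled and the one yielding the lowest cost is added.
    Runs until all signatures are included — truncation is the user's choice.
    """
    panel = align_panel(A, panel)
    counts = A.counts.astype(float)
    remaining = list(range(panel.n_signatures))
    included: list[int] = []
    steps: list[CostStep] = []
    while remaining:
        trial_costs = [
            _cost_of(counts, panel.probs[included + [j]]) for j in remaining
        ]
        pick = remaining[_argbest(trial_costs)]
        cost = trial_costs[remaining.index(pick)]
        included.append(pick)
        remaining.remove(pick)
        steps.append(
            CostStep(
                len(included), panel.names[pick], cost,
                tuple(panel.names[i] for i in included),
            )
        )
    return CostCurve("forward", steps)


def backward_select(A: CountMatrix, panel: SignaturePanel) -> CostCurve:
    """Greedy backward elimination: drop the signature whose removal costs least.

    Starts from the full model and removes one signature per step down to the
    empty model; each step's cost is that of the model *after* the removal.
    The implied importance ranking is the reverse removal order.
    """
    panel = align_panel(A, panel)
    counts = A.counts.astype(float)
    current = list(range(panel.n_signatures))
    steps: list[CostStep] = []
    step_no = 0
    while current:
        if len(current) == 1:
            # removing the last signature leaves the empty model: W·H = 0
            pick_pos, cost = 0, float(np.linalg.norm(counts, "fro") / counts.shape[0])
        else:
            trial_costs = [
                _cost_of(counts, panel.probs[[i for i in current if i != j]])
                for j in current
            ]
            pick_pos = _argbest(trial_costs)
            cost = trial_costs[pick_pos]
        removed = current.pop(pick_pos)
        step_no += 1
        steps.append(
            CostStep(
                step_no, panel.names[removed], cost,
                tuple(panel.names[i] for i in current),
            )
        )
    return CostCurve("backward", steps)


def truncate_model(
    A: CountMatrix,
    panel: SignaturePanel,
    curve: CostCurve,
    n_keep: int,
) -> tuple[SignaturePanel, ExposureMatrix, float]:
    """Keep the ``n_keep`` most important signatures of ``curve`` and refit.

    Returns the restricted panel, the NNLS exposures on exactly that subset
    and the resulting cost. Importance follows the curve's ranking; the elbow
    is the user's decision (``curve.elbow_suggestion()`` is advisory only).
    """
    n_k = len(curve.steps)
    if not 1 <= n_keep <= n_k:
        raise ValueError(f"n_keep must be in [1, {n_k}], got {n_keep}")
    keep = curve.ranking[:n_keep]
    sub = align_panel(A, panel).subset(keep)
    W = nnls_exposures(A, sub)
    return sub, W, model_cost(A, W, sub)


def elbow_index(costs: np.ndarray) -> int:
    """Elbow of a decreasing cost curve: max perpendicular distance to the chord.

    ``costs[i]`` is the cost of a model of size ``i + 1``; the return value
    is the 0-based index of the suggested elbow point.
    """
    costs = np.asarray(costs, dtype=float)
    n = len(costs)
    if n <= 2:
        return 0
    x = np.arange(n, dtype=float)
    p0 = np.array([0.0, costs[0]])
    p1 = np.array([n - 1.0, costs[-1]])
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    if norm == 0:
        return 0
    rel = np.stack([x, costs], axis=1) - p0
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / norm
    return int(np.argmax(dist))
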