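"""De novo signature extraction from counts unexplained by the reference fit.

After refitting a reference panel, the residual matrix ``A' = A - W·H``
holds the mutation counts the panel cannot explain. New signatures are
extracted from ``A'`` by a partially-fixed non-negative matrix factorisation:
``A' ≈ W'·H'`` where ``H'`` stacks the n_k_ref reference signatures (frozen)
on top of n_k_new free rows; multiplicative Frobenius updates (Lee–Seung)
touch only the free rows of ``H'`` and all of ``W'``, so the frozen rows are
bit-identical before and after fitting. The number of de novo signatures is
chosen by leave-k-out cross-validation: models are trained with k samples
held out, held-out exposures are obtained by NNLS projection onto the
learned ``H'``, and the held-out reconstruction cost is averaged over folds.
With no reference signatures (n_k_ref = 0) the same machinery performs pure
de novo extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .catalog import CountMatrix
from .channels import ChannelCatalog
from .fitting import ExposureMatrix, _nnls_rows, align_panel
from .panel import SignaturePanel

__all__ = [
    "ResidualMatrix",
    "NMFResult",
    "CVResult",
    "residual_matrix",
    "nmf_partial_fixed",
    "project_exposures",
    "cross_validate",
    "combine_exposures",
    "rename_denovo",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12
DENOVO_PREFIX = "Denovo"


@dataclass
class ResidualMatrix:
    """Samples × channels matrix ``A'`` of unexplained (residual) counts.

    Entries are clamped at zero — the raw residual ``A - W·H`` can be
    negative where the fit overshoots, which a non-negative factorisation
    cannot accept; the total clamped mass is recorded.
    """

    samples: list[str]
    catalog: ChannelCatalog
    values: np.ndarray = field(repr=False)
    clamped_mass: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.catalog)):
            raise ValueError("residual shape mismatch")
        if np.any(self.values < 0):
            raise ValueError("residual entries must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_rows(self, idx: Sequence[int]) -> "ResidualMatrix":
        idx = list(idx)
        return ResidualMatrix(
            [self.samples[i] for i in idx], self.catalog, self.values[idx].copy(),
            self.clamped_mass,
        )


def residual_matrix(
    A: CountMatrix, W: ExposureMatrix, H: SignaturePanel
) -> ResidualMatrix:
    """``A' = A - W·H`` with negative entries clamped to zero.

    The clamped mass (total of what was below zero) is recorded on the
    result and logged.
    """
    H = align_panel(A, H)
    raw = A.counts - W.values @ H.probs
    clamped = float(-raw[raw < 0].sum())
    if clamped > 0:
        logger.info("residual matrix: clamped %.4g of negative mass to zero", clamped)
    return ResidualMatrix(
        list(A.samples), A.catalog, np.maximum(raw, 0.0), clamped
    )


@dataclass
class NMFResult:
    """Outcome of one partially-fixed NMF fit (best of the restarts).

    ``panel`` holds the fixed reference rows followed by the fitted free
    rows (``fixed`` flags which is which); ``objective_trace`` is the
    Frobenius objective per iteration of the winning restart and is
    non-increasing.
    """

    panel: SignaturePanel
    fixed: list[bool]
    exposures: ExposureMatrix
    objective_trace: np.ndarray
    converged: bool
    seed: int
    best_restart: int

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])

    @property
    def denovo_names(self) -> list[str]:
        return [n for n, f in zip(self.panel.names, self.fixed) if not f]


def _mu_fit(
    A: np.ndarray,
    H_fixed: np.ndarray,
    n_new: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    tol_window: int,
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    """One multiplicative-update run; returns (W, H_free, trace, converged).

    W is (n_g, n_ref + n_new); the first n_ref rows of H are held at
    ``H_fixed`` and only the trailing n_new rows are updated. The Frobenius
    objective ||A - W·H||_F is recorded each iteration.
    """
    n_g, n_t = A.shape
    n_ref = H_fixed.shape[0]
    H_free = rng.uniform(size=(n_new, n_t))
    H_free /= H_free.sum(axis=1, keepdims=True)
    scale = A.max() if A.size and A.max() > 0 else 1.0
    W = rng.uniform(0.0, scale, size=(n_g, n_ref + n_new))

    trace: list[float] = []
    converged = False
    for it in range(max_iter):
        H = np.vstack([H_fixed, H_free]) if n_new else H_fixed
        WH = W @ H
        W *= (A @ H.T) / (WH @ H.T + _EPS)
        if n_new:
            H = np.vstack([H_fixed, H_free])
            WtW = W.T @ W
            numer = W.T @ A
            denom = WtW @ H + _EPS
            H_free *= numer[n_ref:] / denom[n_ref:]
            H = np.vstack([H_fixed, H_free])
        obj = float(np.linalg.norm(A - W @ H, "fro"))
        trace.append(obj)
        if len(trace) > tol_window:
            prev = trace[-1 - tol_window]
            if prev - obj <= tol * max(prev, _EPS):
                converged = True
                break
    return W, H_free, trace, converged


def nmf_partial_fixed(
    Ares: ResidualMatrix,
    H_ref: SignaturePanel | None,
    n_new: int,
    *,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 10_000,
    tol: float = 1e-8,
    tol_window: int = 10,
) -> NMFResult:
    """Factorise the residual with the reference signatures held fixed.

    Minimises ``||A' - W'·H'||_F`` by multiplicative updates in which only
    the ``n_new`` free rows of ``H'`` and all of ``W'`` move; the best of
    ``n_restarts`` random initialisations is returned. Free rows are
    renormalised to sum to one at the end, with the compensating scale folded
    into the matching columns of ``W'``. With ``n_new = 0`` this reduces to a
    plain NNLS fit of the fixed panel.
    """
    if n_new < 0:
        raise ValueError("n_new must be >= 0")
    n_ref = 0 if H_ref is None else H_ref.n_signatures
    if n_new + n_ref < 1:
        raise ValueError("nothing to fit: n_new = 0 and no reference signatures")
    if H_ref is not None and tuple(H_ref.catalog.labels) != tuple(Ares.catalog.labels):
        H_ref = H_ref.reorder_channels(Ares.catalog.labels)
    H_fixed = H_ref.probs.copy() if H_ref is not None else np.empty((0, len(Ares.catalog)))
    ref_names = list(H_ref.names) if H_ref is not None else []
    A = Ares.values

    if n_new == 0:
        W = _nnls_rows(A, H_fixed)
        obj = float(np.linalg.norm(A - W @ H_fixed, "fro"))
        return NMFResult(
            panel=SignaturePanel(ref_names, Ares.catalog, H_fixed.copy()),
            fixed=[True] * n_ref,
            exposures=ExposureMatrix(list(Ares.samples), ref_names, W),
            objective_trace=np.array([obj]),
            converged=True,
            seed=seed,
            best_restart=0,
        )

    seed_seq = np.random.SeedSequence(seed)
    best = None
    for restart, child in enumerate(seed_seq.spawn(n_restarts)):
        rng = np.random.default_rng(child)
        W, H_free, trace, converged = _mu_fit(
            A, H_fixed, n_new, rng, max_iter, tol, tol_window
        )
        if best is None or trace[-1] < best[3][-1]:
            best = (restart, W, H_free, trace, converged)
    restart, W, H_free, trace, converged = best

    # fold row scales into W so each free signature sums to one
    row_sums = H_free.sum(axis=1)
    row_sums[row_sums == 0] = 1.0
    H_free = H_free / row_sums[:, None]
    W = W.copy()
    W[:, n_ref:] *= row_sums

    names = ref_names + [f"{DENOVO_PREFIX}_{i + 1}" for i in range(n_new)]
    panel = SignaturePanel(names, Ares.catalog, np.vstack([H_fixed, H_free]))
    return NMFResult(
        panel=panel,
        fixed=[True] * n_ref + [False] * n_new,
        exposures=ExposureMatrix(list(Ares.samples), names, W),
        objective_trace=np.asarray(trace),
        converged=converged,
        seed=seed,
        best_restart=restart,
    )


def rename_denovo(result: NMFResult) -> NMFResult:
    """Relabel free signatures ``Denovo_1..n`` by decreasing total attribution."""
    free_idx = [i for i, f in enumerate(result.fixed) if not f]
    totals = result.exposures.values[:, free_idx].sum(axis=0)
    order = [free_idx[j] for j in np.argsort(-totals, kind="stable")]
    new_order = [i for i, f in enumerate(result.fixed) if f] + order
    names = []
    k = 0
    for i in new_order:
        if result.fixed[i]:
            names.append(result.panel.names[i])
        else:
            k += 1
            names.append(f"{DENOVO_PREFIX}_{k}")
    panel = SignaturePanel(names, result.panel.catalog, result.panel.probs[new_order])
    exposures = ExposureMatrix(
        list(result.exposures.samples), names, result.exposures.values[:, new_order]
    )
    return NMFResult(
        panel, [result.fixed[i] for i in new_order], exposures,
        result.objective_trace, result.converged, result.seed, result.best_restart,
    )


def project_exposures(Ares: ResidualMatrix, H_model: SignaturePanel) -> ExposureMatrix:
    """NNLS projection of residual rows onto a fixed signature model.

    Used to attribute left-out samples to a model learned without them; the
    contract is that of per-row non-negative least squares.
    """
    if H_model.n_signatures < 1:
        raise ValueError("model panel must contain at least one signature")
    if tuple(H_model.catalog.labels) != tuple(Ares.catalog.labels):
        H_model = H_model.reorder_channels(Ares.catalog.labels)
    W = _nnls_rows(Ares.values, H_model.probs)
    return ExposureMatrix(list(Ares.samples), list(H_model.names), W)


@dataclass
class CVResult:
    """Leave-k-out cross-validation over the number of de novo signatures.

    ``candidates`` holds the n_new values evaluated (0 is the reference-only
    baseline when reference signatures exist); per candidate, mean held-out
    ("test") and retained ("train") costs plus the per-fold values. ``folds``
    records the left-out sample indices of each fold.
    """

    candidates: list[int]
    mean_test_cost: np.ndarray
    mean_train_cost: np.ndarray
    test_costs: np.ndarray  # (n_candidates, n_folds)
    train_costs: np.ndarray
    k: int
    folds: list[list[int]]
    seed: int
    n_restarts: int

    def suggest_n_new(self, min_rel_drop: float = 0.05) -> int:
        """Elbow of the test-cost curve by the relative-drop rule.

        Returns the largest candidate whose mean test cost improves on the
        previous candidate by at least ``min_rel_drop`` (relative); returns
        the smallest candidate if no drop ever qualifies.
        """
        best = self.candidates[0]
        for cur, c_prev, c_cur in zip(
            self.candidates[1:], self.mean_test_cost, self.mean_test_cost[1:]
        ):
            if c_prev > 0 and (c_prev - c_cur) / c_prev >= min_rel_drop:
                best = cur
            else:
                break
        return best

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "n_new": self.candidates,
                "train_cost": self.mean_train_cost,
                "test_cost": self.mean_test_cost,
            }
        )


def _norm_cost(values: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    return float(np.linalg.norm(values - W @ H, "fro") / values.shape[0])


def cross_validate(
    Ares: ResidualMatrix,
    H_ref: SignaturePanel | None,
    max_new: int,
    *,
    k: int = 1,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> CVResult:
    """Choose the number of de novo signatures by leave-k-out cross-validation.

    For each candidate n_new and each fold, a partially-fixed NMF is trained
    on the retained samples; the left-out samples are then projected onto the
    learned ``H'`` by NNLS and scored by the sample-size-normalised Frobenius
    cost of their reconstruction. Folds are consecutive blocks of ``k``
    samples in input order (the last fold holds any remainder), so every
    sample is left out exactly once. Fully deterministic for a given seed.
    """
    n_g = Ares.n_samples
    if n_g < 2:
        raise ValueError("cross-validation needs at least 2 samples")
    if not 1 <= k < n_g:
        raise ValueError(f"k must satisfy 1 <= k < n_samples ({n_g}), got {k}")
    if max_new < 1:
        raise ValueError("max_new must be >= 1")

    folds = [list(range(i, min(i + k, n_g))) for i in range(0, n_g, k)]
    n_ref = 0 if H_ref is None else H_ref.n_signatures
    candidates = ([0] if n_ref > 0 else []) + list(range(1, max_new + 1))

    test = np.zeros((len(candidates), len(folds)))
    train = np.zeros_like(test)
    seed_seq = np.random.SeedSequence(seed)
    fit_seeds = seed_seq.generate_state(len(candidates) * len(folds)) % (2**31)

    for ci, n_new in enumerate(candidates):
        for fi, left_out in enumerate(folds):
            retained = [i for i in range(n_g) if i not in set(left_out)]
            fit = nmf_partial_fixed(
                Ares.subset_rows(retained), H_ref, n_new,
                seed=int(fit_seeds[ci * len(folds) + fi]),
                n_restarts=n_restarts, max_iter=max_iter, tol=tol,
            )
            H_model = fit.panel
            held = Ares.subset_rows(left_out)
            W_k = project_exposures(held, H_model)
            test[ci, fi] = _norm_cost(held.values, W_k.values, H_model.probs)
            train[ci, fi] = _norm_cost(
                Ares.values[retained], fit.exposures.values, H_model.probs
            )

    return CVResult(
        candidates=candidates,
        mean_test_cost=test.mean(axis=1),
        mean_train_cost=train.mean(axis=1),
        test_costs=test,
        train_costs=train,
        k=k,
        folds=folds,
        seed=seed,
        n_restarts=n_restarts,
    )


def combine_exposures(W_fit: ExposureMatrix, W_prime: ExposureMatrix) -> ExposureMatrix:
    """Final emissions: stage-1 reference exposures plus stage-2 additions.

    Reference signatures present in both stages are summed elementwise; de
    novo columns come from stage 2 alone. With an empty stage-1 fit (pure de
    novo extraction) the result equals ``W_prime``.
    """
    if W_fit.samples != W_prime.samples:
        raise ValueError("sample sets of the two stages differ")
    names = list(W_fit.signatures) + [
        s for s in W_prime.signatures if s not in set(W_fit.signatures)
    ]
    out = np.zeros((len(W_fit.samples), len(names)))
    for j, name in enumerate(names):
        if name in W_fit.signatures:
            out[:, j] += W_fit.values[:, W_fit.signatures.index(name)]
        if name in W_prime.signatures:
            out[:, j] += W_prime.values[:, W_prime.signatures.index(name)]
    return ExposureMatrix(list(W_fit.samples), names, out)
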