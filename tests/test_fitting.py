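"""NNLS refitting, the normalised Frobenius cost, and stepwise selection."""

import itertools

import numpy as np
import pytest

from sigsolve import (
    CountMatrix,
    ExposureMatrix,
    SimulationSpec,
    backward_select,
    elbow_index,
    forward_select,
    model_cost,
    nnls_exposures,
    simulate_catalog,
    truncate_model,
)
from sigsolve.panel import SignaturePanel

from conftest import random_counts, random_panel


def nnls_oracle(row: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Exhaustive active-set solver: try every support set, keep the feasible
    minimum. Independent of the production NNLS path."""
    n_k = H.shape[0]
    best_w, best_cost = np.zeros(n_k), float(np.dot(row, row))
    for r in range(1, n_k + 1):
        for support in itertools.combinations(range(n_k), r):
            Hs = H[list(support)]
            w_s, *_ = np.linalg.lstsq(Hs.T, row, rcond=None)
            if np.any(w_s < -1e-10):
                continue
            w = np.zeros(n_k)
            w[list(support)] = np.clip(w_s, 0, None)
            cost = float(np.sum((row - w @ H) ** 2))
            if cost < best_cost - 1e-12:
                best_w, best_cost = w, cost
    return best_w


def test_exact_nonnegative_factorisation_is_recovered(rng):
    """A = W0·H with W0 >= 0 and full-row-rank H is its own NNLS optimum."""
    H = random_panel(2, 8, rng)
    W0 = rng.uniform(1, 100, size=(4, 2))
    A = CountMatrix(["a", "b", "c", "d"], H.catalog, W0 @ H.probs)
    W = nnls_exposures(A, H)
    np.testing.assert_allclose(W.values, W0, rtol=1e-8)


def test_zero_counts_give_zero_exposures(rng):
    H = random_panel(3, 6, rng)
    A = CountMatrix(["a"], H.catalog, np.zeros((1, 6), dtype=int))
    assert nnls_exposures(A, H).values.sum() == 0


@pytest.mark.parametrize("n_sigs", [2, 3])
def test_nnls_matches_active_set_enumeration_oracle(rng, n_sigs):
    H = random_panel(n_sigs, 6, rng)
    A = random_counts(4, H.catalog, rng)
    W = nnls_exposures(A, H)
    for i in range(4):
        expect = nnls_oracle(A.counts[i].astype(float), H.probs)
        got_cost = np.sum((A.counts[i] - W.values[i] @ H.probs) ** 2)
        exp_cost = np.sum((A.counts[i] - expect @ H.probs) ** 2)
        assert got_cost <= exp_cost + 1e-8


def test_model_cost_formula(rng):
    H = random_panel(1, 96, rng)
    # one sample, residual (3, 4, 0...) -> cost 5
    resid = np.zeros(96)
    resid[:2] = [3, 4]
    A1 = CountMatrix(["a"], H.catalog, resid[None, :].astype(int))
    W0 = ExposureMatrix(["a"], ["sig0"], np.zeros((1, 1)))
    assert model_cost(A1, W0, H) == pytest.approx(5.0)
    # two samples with the same residual -> sqrt(50) / 2
    A2 = CountMatrix(["a", "b"], H.catalog, np.vstack([resid, resid]).astype(int))
    W2 = ExposureMatrix(["a", "b"], ["sig0"], np.zeros((2, 1)))
    assert model_cost(A2, W2, H) == pytest.approx(np.sqrt(50) / 2)
    assert model_cost(A2, W2, H) == pytest.approx(3.53553, abs=1e-5)


def test_perfect_reconstruction_has_zero_cost(rng):
    H = random_panel(2, 8, rng)
    W0 = np.array([[10.0, 5.0], [2.0, 8.0]])
    prod = W0 @ H.probs
    # scale so the product is integral
    A = CountMatrix(["a", "b"], H.catalog, np.zeros((2, 8), dtype=int))
    A.counts = prod  # non-integer counts acceptable for the cost computation
    W = ExposureMatrix(["a", "b"], list(H.names), W0)
    assert model_cost(A, W, H) == pytest.approx(0.0, abs=1e-9)


def test_forward_finds_single_ground_truth_signature(panel6):
    spec = SimulationSpec(
        panel6, np.array([0, 0, 0, 0, 1.0, 0]), n_samples=25,
        n_mutations=5000, seed=7,
    )
    A, _ = simulate_catalog(spec)
    curve = forward_select(A, panel6)
    assert curve.steps[0].signature == "Signature.18"
    final_cost = curve.steps[-1].cost
    assert curve.steps[0].cost <= 1.05 * final_cost or final_cost == 0


def test_backward_keeps_single_ground_truth_signature_last(panel6):
    spec = SimulationSpec(
        panel6, np.array([0, 0, 0, 0, 1.0, 0]), n_samples=15,
        n_mutations=5000, seed=8,
    )
    A, _ = simulate_catalog(spec)
    curve = backward_select(A, panel6)
    assert curve.steps[-1].signature == "Signature.18"
    assert curve.ranking[0] == "Signature.18"


def test_duplicate_signature_tie_broken_by_panel_order(panel6, rng):
    dup = SignaturePanel(
        ["first_copy", "second_copy"], panel6.catalog,
        np.vstack([panel6.probs[4], panel6.probs[4]]),
    )
    spec = SimulationSpec(panel6, np.array([0, 0, 0, 0, 1.0, 0]), 5, 2000, seed=9)
    A, _ = simulate_catalog(spec)
    curve = forward_select(A, dup)
    assert curve.steps[0].signature == "first_copy"


def test_single_signature_backward_curve_has_one_step(panel6, rng):
    one = panel6.subset(["Signature.1"])
    A = random_counts(3, panel6.catalog, rng)
    curve = backward_select(A, one)
    assert len(curve.steps) == 1


def test_curve_monotonicity_on_random_instances(rng):
    """Forward cost never increases with model size; backward never decreases
    along removals (a superset model can zero the extra column)."""
    for _ in range(5):
        H = random_panel(4, 10, rng)
        A = random_counts(6, H.catalog, rng)
        f = forward_select(A, H).costs
        b = backward_select(A, H).costs
        assert np.all(np.diff(f) <= 1e-9)
        assert np.all(np.diff(b) >= -1e-9)


def test_truncate_full_model_reproduces_final_cost(panel6, rng):
    A = random_counts(5, panel6.catalog, rng)
    curve = forward_select(A, panel6)
    _, _, cost = truncate_model(A, panel6, curve, panel6.n_signatures)
    assert cost == pytest.approx(curve.steps[-1].cost, abs=1e-10)
    with pytest.raises(ValueError):
        truncate_model(A, panel6, curve, 0)
    with pytest.raises(ValueError):
        truncate_model(A, panel6, curve, 7)


def test_truncation_refits_on_subset_only(panel6, rng):
    A = random_counts(5, panel6.catalog, rng)
    curve = backward_select(A, panel6)
    sub, W, _ = truncate_model(A, panel6, curve, 2)
    assert sub.names == curve.ranking[:2]
    assert W.values.shape == (5, 2)


def test_elbow_on_synthetic_kinked_curve():
    """Monotone curve with a single sharp kink at the third point."""
    costs = np.array([100.0, 60.0, 5.0, 4.0, 3.0, 2.0])
    assert elbow_index(costs) == 2  # 0-based; model size 3


def test_forward_backward_agree_on_dominant_signature(panel6, panelx):
    """When one signature explains >= 95% of the data, both directions rank
    it first (20 seeded simulations)."""
    agree = 0
    for seed in range(20):
        w = np.full(6, 0.05 / 5)
        w[0] = 0.95
        spec = SimulationSpec(panel6, w, n_samples=8, n_mutations=2000, seed=seed)
        A, _ = simulate_catalog(spec)
        f = forward_select(A, panel6).ranking[0]
        b = backward_select(A, panel6).ranking[0]
        agree += f == b == "Signature.1"
    assert agree == 20
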