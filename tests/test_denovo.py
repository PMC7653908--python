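"""Residual construction, partially-fixed NMF, and cross-validated rank choice."""

import numpy as np
import pytest

from sigsolve import (
    CountMatrix,
    ExposureMatrix,
    ResidualMatrix,
    SimulationSpec,
    combine_exposures,
    cross_validate,
    dirichlet_fractions,
    hellinger,
    nmf_partial_fixed,
    nnls_exposures,
    project_exposures,
    rename_denovo,
    residual_matrix,
    scenario_preset,
    simulate_catalog,
)

from conftest import random_panel


@pytest.fixture(scope="module")
def ref4(panel6):
    return panel6.subset(
        ["Signature.1", "Signature.11", "Signature.18", "Signature.22"]
    )


def test_residual_is_clamped_difference(rng):
    H = random_panel(2, 6, rng)
    W = ExposureMatrix(["a", "b"], list(H.names), rng.uniform(0, 50, (2, 2)))
    counts = rng.integers(0, 60, size=(2, 6))
    A = CountMatrix(["a", "b"], H.catalog, counts)
    res = residual_matrix(A, W, H)
    raw = counts - W.values @ H.probs
    np.testing.assert_allclose(res.values, np.maximum(raw, 0), atol=1e-12)
    assert res.clamped_mass == pytest.approx(float(-raw[raw < 0].sum()))


def test_perfect_fit_gives_zero_residual(rng):
    H = random_panel(2, 6, rng)
    W0 = rng.uniform(1, 30, (3, 2))
    A = CountMatrix(["a", "b", "c"], H.catalog, W0 @ H.probs)
    res = residual_matrix(A, ExposureMatrix(A.samples, list(H.names), W0), H)
    assert res.values.max() == pytest.approx(0.0, abs=1e-9)
    assert res.clamped_mass < 1e-9


def test_nmf_with_no_free_rows_reduces_to_nnls_fit(ref4, rng):
    Ares = ResidualMatrix(
        ["a", "b"], ref4.catalog, rng.uniform(0, 20, (2, 96))
    )
    out = nmf_partial_fixed(Ares, ref4, 0)
    expect = nnls_exposures(
        CountMatrix(["a", "b"], ref4.catalog, Ares.values), ref4
    )
    np.testing.assert_allclose(out.exposures.values, expect.values, atol=1e-9)
    assert out.panel.names == ref4.names


def test_nmf_rejects_empty_model():
    cat_res = ResidualMatrix(["a"], random_panel(1, 4, np.random.default_rng(0)).catalog,
                             np.ones((1, 4)))
    with pytest.raises(ValueError, match="nothing to fit"):
        nmf_partial_fixed(cat_res, None, 0)


def test_nmf_objective_monotone_fixed_rows_untouched_free_rows_normalised(
    panel6, ref4
):
    spec = scenario_preset("A", 10, 5000, seed=4, panel=panel6)
    A, _ = simulate_catalog(spec)
    W = nnls_exposures(A, ref4)
    Ares = residual_matrix(A, W, ref4)
    before = ref4.probs.copy()
    out = nmf_partial_fixed(Ares, ref4, 2, seed=1, n_restarts=2, max_iter=800,
                            tol=1e-7)
    trace = out.objective_trace
    assert np.all(np.diff(trace) <= 1e-9 * max(trace[0], 1.0))
    # frozen reference rows are bit-identical
    assert np.array_equal(out.panel.probs[:4], before)
    assert out.fixed == [True] * 4 + [False] * 2
    np.testing.assert_allclose(out.panel.probs[4:].sum(axis=1), 1.0, atol=1e-6)


def test_single_hidden_signature_recovered(panel6):
    """Simulate from two references plus one distinctive hidden process; the
    free NMF row lands within Hellinger distance 0.1 of the hidden truth."""
    sub = panel6.subset(["Signature.1", "Signature.18", "Signature.22"])
    ref = panel6.subset(["Signature.1", "Signature.18"])
    A, _ = simulate_catalog(
        SimulationSpec(sub, np.array([0.375, 0.375, 0.25]), 25, 35000, seed=5)
    )
    W = nnls_exposures(A, ref)
    Ares = residual_matrix(A, W, ref)
    out = nmf_partial_fixed(Ares, ref, 1, seed=3, n_restarts=5, max_iter=4000,
                            tol=1e-7)
    d = hellinger(out.panel.probs[-1], panel6.row("Signature.22"))
    assert d < 0.1


def test_pure_denovo_mode(rng):
    H = random_panel(2, 8, rng)
    W0 = rng.uniform(5, 50, (12, 2))
    Ares = ResidualMatrix(
        [f"s{i}" for i in range(12)], H.catalog, W0 @ H.probs
    )
    out = nmf_partial_fixed(Ares, None, 2, seed=0, n_restarts=6, max_iter=3000,
                            tol=1e-9)
    # both true signatures recovered up to order
    dists = [
        min(hellinger(row, H.probs[0]), hellinger(row, H.probs[1]))
        for row in out.panel.probs
    ]
    assert max(dists) < 0.1


def test_project_exposures_exact_and_oracle_cases(ref4, rng):
    zero = ResidualMatrix(["a"], ref4.catalog, np.zeros((1, 96)))
    assert project_exposures(zero, ref4).values.sum() == 0
    one = ResidualMatrix(["a"], ref4.catalog, 100 * ref4.probs[[2]])
    W = project_exposures(one, ref4)
    expect = np.zeros(4)
    expect[2] = 100
    np.testing.assert_allclose(W.values[0], expect, atol=1e-6)


def test_cross_validate_argument_errors(ref4, rng):
    Ares = ResidualMatrix(
        ["a", "b", "c"], ref4.catalog, rng.uniform(0, 5, (3, 96))
    )
    with pytest.raises(ValueError):
        cross_validate(Ares, ref4, 2, k=3)  # k == n_g
    with pytest.raises(ValueError):
        cross_validate(Ares.subset_rows([0]), ref4, 2, k=1)  # n_g < 2


def test_cv_flags_no_gain_on_null_data(panel6, ref4):
    """Residuals of data generated exactly from the reference panel show no
    notable test-cost drop for any added signature (< 2% per step)."""
    A, _ = simulate_catalog(
        SimulationSpec(ref4, np.array([0.4, 0.3, 0.2, 0.1]), 25, 20000, seed=9)
    )
    W = nnls_exposures(A, ref4)
    Ares = residual_matrix(A, W, ref4)
    cv = cross_validate(Ares, ref4, 3, k=5, seed=1, n_restarts=3,
                        max_iter=2000, tol=1e-6)
    drops = -np.diff(cv.mean_test_cost) / cv.mean_test_cost[:-1]
    assert np.all(drops < 0.02)
    assert cv.suggest_n_new() == 0


def test_cv_is_bit_reproducible(panel6, ref4):
    spec = scenario_preset("A", 8, 3000, seed=2, panel=panel6)
    A, _ = simulate_catalog(spec)
    W = nnls_exposures(A, ref4)
    Ares = residual_matrix(A, W, ref4)
    kw = dict(k=4, seed=11, n_restarts=2, max_iter=500, tol=1e-6)
    a = cross_validate(Ares, ref4, 2, **kw)
    b = cross_validate(Ares, ref4, 2, **kw)
    assert np.array_equal(a.test_costs, b.test_costs)
    assert np.array_equal(a.train_costs, b.train_costs)
    assert a.folds == b.folds


def test_cv_folds_partition_samples(panel6, ref4, rng):
    Ares = ResidualMatrix(
        [f"s{i}" for i in range(7)], ref4.catalog, rng.uniform(0, 5, (7, 96))
    )
    cv = cross_validate(Ares, ref4, 1, k=3, n_restarts=1, max_iter=100, tol=1e-4)
    flat = [i for fold in cv.folds for i in fold]
    assert sorted(flat) == list(range(7))
    assert [len(f) for f in cv.folds] == [3, 3, 1]  # remainder in last fold


def test_two_hidden_signatures_recovered_with_elbow(panel6, ref4):
    """Cohorts with heterogeneous exposures to two unmodelled processes: the
    CV elbow lands on two de novo signatures in most runs and the recovered
    profiles match their truths within the expected Hellinger band."""
    truth = panel6.subset(["Signature.3", "Signature.5"])
    elbows, hds_ok = 0, 0
    n_runs = 10
    for seed in range(n_runs):
        spec = scenario_preset("A", 25, 35000, seed=400 + seed, panel=panel6,
                               heterogeneity=50.0)
        A, _ = simulate_catalog(spec)
        W = nnls_exposures(A, ref4)
        Ares = residual_matrix(A, W, ref4)
        cv = cross_validate(Ares, ref4, 3, k=5, seed=seed, n_restarts=3,
                            max_iter=2000, tol=1e-6)
        elbows += cv.suggest_n_new() == 2
        out = rename_denovo(
            nmf_partial_fixed(Ares, ref4, 2, seed=seed, n_restarts=4,
                              max_iter=3000, tol=1e-7)
        )
        free = out.panel.probs[[i for i, f in enumerate(out.fixed) if not f]]
        # each free row must match a distinct truth within the band
        pair1 = max(hellinger(free[0], truth.probs[0]),
                    hellinger(free[1], truth.probs[1]))
        pair2 = max(hellinger(free[0], truth.probs[1]),
                    hellinger(free[1], truth.probs[0]))
        hds_ok += min(pair1, pair2) <= 0.35
    assert elbows >= 8
    assert hds_ok >= 8


def test_train_cost_below_test_cost_past_true_rank(panel6, ref4):
    spec = scenario_preset("A", 16, 20000, seed=6, panel=panel6,
                           heterogeneity=50.0)
    A, _ = simulate_catalog(spec)
    W = nnls_exposures(A, ref4)
    Ares = residual_matrix(A, W, ref4)
    cv = cross_validate(Ares, ref4, 3, k=4, seed=3, n_restarts=2,
                        max_iter=1500, tol=1e-6)
    past = [i for i, n in enumerate(cv.candidates) if n > 2]
    assert np.all(cv.mean_test_cost[past] >= cv.mean_train_cost[past])


def test_combine_exposures_rules(rng):
    W_fit = ExposureMatrix(["a", "b"], ["r1", "r2"], rng.uniform(0, 5, (2, 2)))
    zeros = ExposureMatrix(["a", "b"], ["r1", "r2"], np.zeros((2, 2)))
    np.testing.assert_array_equal(
        combine_exposures(W_fit, zeros).values, W_fit.values
    )
    # pure de novo: empty stage-1
    empty = ExposureMatrix(["a", "b"], [], np.zeros((2, 0)))
    W_p = ExposureMatrix(["a", "b"], ["Denovo_1"], rng.uniform(0, 5, (2, 1)))
    np.testing.assert_array_equal(combine_exposures(empty, W_p).values, W_p.values)
    # shared column sums elementwise
    W_p2 = ExposureMatrix(["a", "b"], ["r2", "Denovo_1"], rng.uniform(0, 5, (2, 2)))
    out = combine_exposures(W_fit, W_p2)
    assert out.signatures == ["r1", "r2", "Denovo_1"]
    np.testing.assert_allclose(
        out.values[:, 1], W_fit.values[:, 1] + W_p2.values[:, 0]
    )
    with pytest.raises(ValueError, match="sample"):
        combine_exposures(W_fit, ExposureMatrix(["x", "b"], ["r1"], np.zeros((2, 1))))


def test_denovo_names_ordered_by_attribution(panel6, ref4, rng):
    Ares = ResidualMatrix(
        [f"s{i}" for i in range(6)], ref4.catalog, rng.uniform(0, 40, (6, 96))
    )
    out = rename_denovo(
        nmf_partial_fixed(Ares, ref4, 3, seed=5, n_restarts=2, max_iter=500,
                          tol=1e-6)
    )
    free_idx = [i for i, f in enumerate(out.fixed) if not f]
    totals = out.exposures.values[:, free_idx].sum(axis=0)
    assert out.denovo_names == ["Denovo_1", "Denovo_2", "Denovo_3"]
    assert np.all(np.diff(totals) <= 1e-9)
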