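"""Rate-matrix construction, NMF with AICc order selection, and the
assembly-level statistics, checked on planted ground-truth models."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from slowwave import (
    FixtureSpec,
    NMFResult,
    assembly_statistics,
    build_rate_matrix,
    make_fixture_raster,
    nmf,
    pattern_activation_correlation,
    select_nmf_order,
)


def test_rate_matrix_single_spike_and_silent_row():
    ids = np.array([2], np.int32)
    ts = np.array([250.0])
    rm = build_rate_matrix(ids, ts, n_neurons=4, T=1000.0, window=200.0,
                           step=200.0)
    assert rm.D.shape == (4, 5)          # floor((1000-200)/200)+1
    assert rm.D[2, 1] == pytest.approx(5.0)   # 1 spike / 0.2 s
    assert rm.D[2].sum() == pytest.approx(5.0)
    assert np.all(rm.D[0] == 0.0)        # silent neuron: zero row


def test_rate_matrix_sliding_default_gives_20hz_sampling():
    """Default 200 ms window at 50 ms steps: 20 rate vectors per second."""
    rm = build_rate_matrix(np.empty(0, np.int32), np.empty(0), 2, T=10_200.0)
    assert rm.step == 50.0
    n_expected = int(np.floor((10_200.0 - 200.0) / 50.0)) + 1
    assert rm.D.shape[1] == n_expected
    assert n_expected / 10.0 == pytest.approx(20.0, rel=0.01)


def test_rate_matrix_validation():
    with pytest.raises(ValueError):
        build_rate_matrix(np.empty(0, np.int32), np.empty(0), 2, T=100.0,
                          window=200.0)
    with pytest.raises(ValueError):
        build_rate_matrix(np.empty(0, np.int32), np.empty(0), 2, T=1000.0,
                          window=-1.0)


def test_nmf_objective_monotone_nonincreasing():
    rng = np.random.default_rng(0)
    D = rng.random((30, 40))
    for init in ("nndsvda", "random"):
        _, _, trace = nmf(D, 4, init=init, seed=1)
        assert np.all(np.diff(trace) <= 1e-9 * max(trace[0], 1.0))


def test_nmf_input_validation():
    with pytest.raises(ValueError):
        nmf(-np.ones((4, 4)), 2)
    with pytest.raises(ValueError):
        nmf(np.ones((4, 4)), 0)
    with pytest.raises(ValueError):
        nmf(np.ones((4, 4)), 2, init="kmeans")


def test_planted_rank_one_recovered():
    rng = np.random.default_rng(3)
    D = np.outer(rng.random(25) + 0.2, rng.random(60) + 0.2)
    r = select_nmf_order(D, k_range=range(1, 6), restarts=2, seed=0)
    assert r.k == 1
    assert r.rss / (D**2).sum() < 1e-6


def test_planted_rank_two_recovered_with_noise():
    rng = np.random.default_rng(4)
    B = np.zeros((40, 2))
    B[:20, 0] = 1.0
    B[20:, 1] = 1.0
    C = rng.random((2, 120)) * 10.0 + 2.0
    D = (B @ C + rng.normal(0, 0.05, (40, 120))).clip(min=0.0)
    # multiplicative updates converge slowly; an under-converged k=2 fit
    # would make the extra component look informative
    r = select_nmf_order(D, k_range=range(1, 7), restarts=3, seed=0,
                         max_iter=1500)
    assert r.k == 2


def test_rss_nesting_and_aicc_trace():
    rng = np.random.default_rng(5)
    D = rng.random((25, 50)) + 0.01
    r = select_nmf_order(D, k_range=range(1, 6), restarts=2, seed=2)
    ks = sorted(r.rss_by_k)
    rss = [r.rss_by_k[k] for k in ks]
    assert all(b <= a * (1 + 1e-6) for a, b in zip(rss[:-1], rss[1:]))
    assert {k for k, _ in r.aicc_trace} == set(ks)
    best_k = min(r.aicc_trace, key=lambda t: t[1])[0]
    assert r.k == best_k


def test_order_scan_excludes_overparameterised_k():
    D = np.random.default_rng(0).random((6, 8)) + 0.1
    with pytest.warns(UserWarning, match="residual degrees"):
        r = select_nmf_order(D, k_range=range(1, 6), restarts=1, seed=0)
    assert all(k * (6 + 8) < D.size - 1 for k, _ in r.aicc_trace)


@pytest.mark.parametrize("g", [2, 3, 5])
def test_planted_assembly_recovery(g):
    """Rasters with g ground-truth assemblies: AICc selects order g and
    the basis matches the membership at > 0.8 cosine after assignment."""
    n = 12 * g
    spec = FixtureSpec(
        n_neurons=n,
        assemblies=[list(range(12 * k, 12 * (k + 1))) for k in range(g)],
        up_windows=[(1000.0 * w + 300.0, 1000.0 * w + 800.0)
                    for w in range(6 * g)],
        T=1000.0 * 6 * g,
        rate_up=1.0, rate_down=0.1, rate_assembly=30.0,
        seed=g,
    )
    fx = make_fixture_raster(spec)
    # non-overlapping windows: overlapping ones correlate the noise across
    # columns, which the independent-entry AICc penalty under-counts
    rm = build_rate_matrix(fx.spike_ids, fx.spike_times, n, spec.T,
                           window=200.0, step=200.0)
    r = select_nmf_order(rm, k_range=range(1, g + 4), restarts=3, seed=0)
    assert r.k == g
    truth = fx.membership.astype(float)
    Bn = r.B / (np.linalg.norm(r.B, axis=0, keepdims=True) + 1e-12)
    Tn = (truth.T / (np.linalg.norm(truth, axis=1) + 1e-12))
    cos = Tn.T @ Bn                      # (g, k) cosine similarity
    rows, cols = linear_sum_assignment(-cos)
    assert np.all(cos[rows, cols] > 0.8)


def test_assembly_statistics_constructed_monotone_case():
    """Orders strictly decreasing in duration: correlation exactly -1."""
    orders = np.array([9, 7, 5, 3, 1])
    durations = np.exp(10.0 - orders)    # log-duration affine in order
    rep = assembly_statistics(orders, durations)
    assert rep.r_order == pytest.approx(-1.0, abs=1e-9)
    assert rep.p_order < 0.05
    assert rep.r_normalized < 0
    with pytest.raises(ValueError):
        assembly_statistics([1, 2], [10.0, 20.0])
    degen = assembly_statistics([3, 3, 3, 3, 3], durations)
    assert np.isnan(degen.r_order) and not degen.defined


def test_pattern_activation_correlation_limits():
    mk = lambda C: NMFResult(B=np.ones((4, C.shape[0])), Cmat=C,
                             k=C.shape[0], aicc_trace=[], rss=0.0,
                             rss_by_k={}, objective_trace=np.empty(0))
    row = np.random.default_rng(0).random(50)
    assert pattern_activation_correlation(mk(np.vstack([row, row]))) == pytest.approx(1.0)
    a = np.zeros(50); a[:25] = 1.0
    b = np.zeros(50); b[25:] = 1.0
    assert pattern_activation_correlation(mk(np.vstack([a, b]))) < 0
    assert np.isnan(pattern_activation_correlation(mk(row[None, :])))


def test_nmf_best_rss_comparable_to_sklearn():
    """Independent cross-check: our multiplicative-update RSS is within a
    few percent of scikit-learn's NMF at the same order."""
    from sklearn.decomposition import NMF as SkNMF

    rng = np.random.default_rng(8)
    D = (rng.random((40, 80)) * (rng.random((40, 1)) > 0.4)).clip(min=0) + 0.01
    _, _, tr = nmf(D, 5, init="nndsvda", max_iter=500)
    sk = SkNMF(n_components=5, solver="mu", init="nndsvda", max_iter=500,
               tol=1e-7, random_state=0)
    W = sk.fit_transform(D)
    rss_sk = np.sum((D - W @ sk.components_) ** 2)
    assert tr[-1] <= rss_sk * 1.05
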