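"""Detector correctness: g-test formula, rank invariance, Fourier scoring,
cutoff calibration, call combination, peak times and period fitting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tilecycle.periodic import (
    calibrate_cutoff,
    combine_calls,
    delichtenberg_score,
    delichtenberg_scores,
    exact_g_pvalue,
    fourier_score,
    optimize_period,
    peak_time,
    robust_g_test,
    score_profiles,
)

T = np.arange(0, 205, 5.0)  # 41 points, 5-min sampling


def planted(phase, amp=1.0, noise=0.0, seed=0, period=60.0, times=T):
    rng = np.random.default_rng(seed)
    x = amp * np.cos(2 * np.pi * (times / period - phase))
    return x + rng.normal(0, noise, times.size)


# ---------------------------------------------------------------- exact g


def test_exact_g_boundary_and_hand_values():
    assert exact_g_pvalue(1.0, 5) == pytest.approx(0.0, abs=1e-12)
    # m=2: p = 2*(1-g); hand evaluation at g=0.75
    assert exact_g_pvalue(0.75, 2) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        exact_g_pvalue(0.05, 10)
    with pytest.raises(ValueError):
        exact_g_pvalue(1.2, 10)


# ---------------------------------------------------------------- robust g


def test_robust_g_detects_planted_sinusoid():
    x = planted(0.3, amp=1.0, noise=0.1, seed=1)
    _, p = robust_g_test(x, T, 60.0, n_null=9999, seed=2)
    assert p < 0.01


def test_robust_g_rank_invariance_under_monotone_transform():
    x = planted(0.7, amp=1.0, noise=0.5, seed=3)
    g1, p1 = robust_g_test(x, T, 60.0, seed=4)
    g2, p2 = robust_g_test(np.exp(2 * x) + 7, T, 60.0, seed=4)
    assert g1 == pytest.approx(g2, abs=1e-12)
    assert p1 == p2


def test_robust_g_constant_profile():
    g, p = robust_g_test(np.full(T.size, 2.0), T, 60.0, seed=5)
    assert g == 0.0 and p == 1.0


# ---------------------------------------------------------------- Fourier


def test_fourier_score_constant_is_zero():
    assert fourier_score(np.full(40, 3.3), np.arange(40) * 3.0, 60.0) == 0.0


def test_fourier_score_two_full_periods():
    tt = np.arange(40) * 3.0  # spans exactly 2 periods of T=60
    x = np.cos(2 * np.pi * tt / 60.0)
    assert fourier_score(x, tt, 60.0) == pytest.approx(20.0, abs=1e-9)
    assert fourier_score(x + 5.0, tt, 60.0) == pytest.approx(20.0, abs=1e-9)


# ---------------------------------------------------------------- permutation score


def test_permutation_score_constant_profile():
    pop = np.random.default_rng(6).uniform(0.1, 2.0, 200)
    p_per, p_reg, comb = delichtenberg_score(np.full(T.size, 1.0), T, 60.0, pop)
    assert p_per == 1.0
    assert comb == p_per * p_reg


def test_regulation_pvalue_order_free():
    rng = np.random.default_rng(7)
    x = planted(0.2, amp=0.8, noise=0.3, seed=8)
    pop = rng.uniform(0.05, 1.5, 300)
    _, p_reg1, _ = delichtenberg_score(x, T, 60.0, pop)
    _, p_reg2, _ = delichtenberg_score(rng.permutation(x), T, 60.0, pop)
    assert p_reg1 == pytest.approx(p_reg2, abs=1e-12)


def test_permutation_score_separates_planted_profiles():
    rng = np.random.default_rng(9)
    X = rng.normal(0, 0.25, (500, T.size))
    periodic_rows = np.arange(50)
    for i in periodic_rows:
        X[i] += planted(rng.uniform(), amp=1.0)
    _, _, _, comb = delichtenberg_scores(X, T, 60.0, n_perm=200, seed=1)
    called = np.argsort(comb)[:50]
    assert len(set(called) & set(periodic_rows)) >= 45


# ---------------------------------------------------------------- calibration


def test_cutoff_perfect_separation_admits_benchmark():
    scores = pd.Series(
        np.r_[np.linspace(0.001, 0.01, 10), np.linspace(0.5, 0.9, 40)],
        index=[f"x{i}" for i in range(50)],
    )
    bench = [f"x{i}" for i in range(10)]
    cut = calibrate_cutoff(scores, bench)
    assert (scores <= cut).sum() == 10
    assert set(scores.index[scores <= cut]) == set(bench)


def test_cutoff_equals_full_scan_optimum():
    rng = np.random.default_rng(10)
    scores = pd.Series(rng.uniform(0, 1, 200), index=[f"t{i}" for i in range(200)])
    bench = list(rng.choice(scores.index, 40, replace=False))
    cut = calibrate_cutoff(scores, bench)
    # brute-force scan over every candidate cutoff
    best = None
    for c in sorted(scores.unique()):
        called = scores <= c
        recall = called[bench].mean()
        other = called[~scores.index.isin(bench)].mean()
        j = recall - other
        if best is None or j > best[0] + 1e-12:
            best = (j, c)
    assert cut == pytest.approx(best[1])


def test_cutoff_requires_benchmark_subset():
    scores = pd.Series([0.1, 0.2], index=["a", "b"])
    with pytest.raises(ValueError):
        calibrate_cutoff(scores, [])
    with pytest.raises(ValueError):
        calibrate_cutoff(scores, ["missing"])


# ---------------------------------------------------------------- combination


def test_combine_calls_two_of_three_and_symmetry():
    assert combine_calls(True, True, False) is True
    assert combine_calls(True, False, False) is False
    assert combine_calls(False, False, None) is False
    assert combine_calls(True, True, None) is True
    assert combine_calls(True, False, None) is False
    for a, b, c in itertools.product([True, False], repeat=3):
        base = combine_calls(a, b, c)
        for perm in itertools.permutations((a, b, c)):
            assert combine_calls(*perm) == base


# ---------------------------------------------------------------- peak time


def test_peak_time_exact_phases():
    tt = np.arange(40) * 3.0  # exactly 2 periods
    assert peak_time(np.cos(2 * np.pi * tt / 60), tt, 60) == pytest.approx(0.0, abs=1e-9)
    shifted = np.cos(2 * np.pi * (tt - 15.0) / 60)  # quarter-cycle delay
    assert peak_time(shifted, tt, 60) == pytest.approx(25.0, abs=1e-9)
    assert np.isnan(peak_time(np.full(40, 1.0), tt, 60))


def test_peak_time_recovery_under_noise():
    hits = 0
    for seed in range(200):
        x = planted(0.6, amp=1.0, noise=0.25, seed=seed)
        p = peak_time(x, T, 60.0)
        d = abs(p - 60.0)
        hits += min(d, 100 - d) <= 5.0
    assert hits >= 190  # 95% of runs within +/-5% of the cycle


def test_peak_time_difference_tracks_planted_offset():
    for seed, delta in enumerate([0.1, 0.33, 0.48]):
        a = planted(0.2, amp=1.0, noise=0.2, seed=100 + seed)
        b = planted(0.2 + delta, amp=1.0, noise=0.2, seed=200 + seed)
        pa, pb = peak_time(a, T, 60.0), peak_time(b, T, 60.0)
        d = abs(pa - pb)
        assert min(d, 100 - d) == pytest.approx(100 * delta, abs=5.0)


# ---------------------------------------------------------------- period fit


def test_optimize_period_recovers_planted_period():
    X = np.array([planted(ph, amp=1.0, noise=0.1, seed=i)
                  for i, ph in enumerate([0.0, 0.25, 0.6, 0.8])])
    T_star = optimize_period(X, T, np.arange(45, 80.5, 1.0))
    assert abs(T_star - 60.0) <= 1.0


def test_optimize_period_scale_equivariance():
    X = np.array([planted(ph, amp=1.0, noise=0.05, seed=i)
                  for i, ph in enumerate([0.1, 0.5, 0.9])])
    T1 = optimize_period(X, T, np.arange(45, 80.5, 1.0))
    T2 = optimize_period(X, 2 * T, np.arange(90, 161, 2.0))
    assert T2 == pytest.approx(2 * T1)


def test_optimize_period_all_flat_is_error():
    X = np.ones((4, T.size))
    with pytest.raises(ValueError):
        optimize_period(X, T, np.arange(45, 80.5, 1.0))


# ---------------------------------------------------------------- batch table


def test_score_profiles_table_contract():
    rows = [{"id": f"p{i}", **{f"t{5*j:03d}": v for j, v in enumerate(planted(0.2, noise=0.3, seed=i))}}
            for i in range(5)]
    prof = pd.DataFrame(rows)
    sc = score_profiles(prof, T, period=60.0, n_null=999, n_perm=100, seed=0)
    assert list(sc["id"]) == [f"p{i}" for i in range(5)]
    assert ((sc["p_g"] > 0) & (sc["p_g"] <= 1)).all()
    assert ((sc["peak_time"] >= 0) & (sc["peak_time"] < 100)).all()
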