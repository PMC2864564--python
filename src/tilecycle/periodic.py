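"""Periodicity detection, cutoff calibration, peak times and period fitting.

Two detectors score each expression profile for cell-cycle periodicity:

* a robust nonparametric g-test: the profile is rank-transformed, its
  periodogram computed, and the ordinate nearest the cell-cycle frequency is
  compared with the total spectral power; significance comes from a simulated
  permutation null, which is exact and distribution-free because ranks of an
  i.i.d. continuous series are a uniform random permutation.
* a permutation Fourier score: the magnitude F of the mean-centered profile's
  projection onto (cos, sin) at the cell-cycle frequency measures periodicity
  (p_per, from within-profile time shuffles) while the profile's standard
  deviation measures regulation strength (p_reg, from the population of
  scored profiles); the combined score is their product, smaller = more
  periodic.

Score cutoffs are calibrated against a benchmark list of known cycling
transcripts, a transcript is called cycling when at least two of the three
methods (the two detectors plus optional curated calls) agree, and the peak
time of expression is the phase of the first harmonic expressed as a
percentage of the cell-cycle duration.

The classical Fisher g-test null distribution (``exact_g_pvalue``) is kept as
an analytic reference for the spectral machinery.
"""

from __future__ import annotations

from math import comb, floor

import numpy as np
import pandas as pd
from scipy.stats import rankdata

DEFAULT_PERIOD = 60.0

_NULL_CACHE: dict = {}


def exact_g_pvalue(g: float, m: int) -> float:
    """Exact null P(G >= g) for Fisher's g with m periodogram ordinates.

    p = sum_{k=1}^{min(m, floor(1/g))} (-1)^(k-1) C(m,k) (1 - k g)^(m-1)
    """
    if m < 2:
        raise ValueError("need at least 2 periodogram ordinates")
    if not (1.0 / m - 1e-12 <= g <= 1.0 + 1e-12):
        raise ValueError(f"g={g} outside [1/m, 1] for m={m}")
    g = min(max(g, 1.0 / m), 1.0)
    kmax = min(m, floor(1.0 / g + 1e-12))
    terms = [(-1.0) ** (k - 1) * comb(m, k) * (1.0 - k * g) ** (m - 1)
             for k in range(1, kmax + 1)]
    return float(min(1.0, max(0.0, sum(terms))))


def cycle_frequency_index(n: int, dt: float, period: float) -> int:
    """Fourier-frequency index nearest the cell-cycle frequency 1/period."""
    if period <= 0:
        raise ValueError("period must be positive")
    m = n // 2
    return int(np.clip(round(n * dt / period), 1, m))


def _check_times(times: np.ndarray) -> float:
    t = np.asarray(times, dtype=float)
    if t.size < 8:
        raise ValueError("need at least 8 time points")
    dt = np.diff(t)
    if not np.all(dt > 0) or not np.allclose(dt, dt[0]):
        raise ValueError("time points must be strictly increasing and evenly spaced")
    return float(dt[0])


def rank_g_statistics(values: np.ndarray, times, period: float = DEFAULT_PERIOD) -> np.ndarray:
    """Rank-periodogram g statistic for each row of ``values``.

    g = I(l*) / sum_l I(l), with I the periodogram of the centered ranks and
    l* the ordinate nearest 1/period.  Constant rows give g = 0.
    """
    x = np.atleast_2d(np.asarray(values, dtype=float))
    dt = _check_times(times)
    n = x.shape[1]
    lstar = cycle_frequency_index(n, dt, period)
    r = rankdata(x, axis=1)
    r = r - r.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(r, axis=1)) ** 2
    m = n // 2
    total = spec[:, 1:m + 1].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(total > 0, spec[:, lstar] / total, 0.0)
    return g


def _null_g_distribution(n: int, dt: float, period: float, n_null: int, seed: int) -> np.ndarray:
    key = (n, round(dt, 6), round(period, 6), n_null, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng([seed, 97])
        perms = rng.permuted(np.tile(np.arange(1, n + 1, dtype=float), (n_null, 1)), axis=1)
        times = np.arange(n) * dt
        _NULL_CACHE[key] = np.sort(rank_g_statistics(perms, times, period))
    return _NULL_CACHE[key]


def robust_g_pvalues(
    values, times, period: float = DEFAULT_PERIOD,
    n_null: int = 9999, seed: int = 0,
):
    """Vectorized robust g-test: (g, p) arrays for each profile row.

    p = (1 + #{null g >= g_obs}) / (n_null + 1); the null is shared across
    profiles of equal length (it depends only on n, dt and the period).
    Constant profiles get p = 1.
    """
    x = np.atleast_2d(np.asarray(values, dtype=float))
    dt = _check_times(times)
    g = rank_g_statistics(x, times, period)
    null = _null_g_distribution(x.shape[1], dt, period, n_null, seed)
    n_ge = null.size - np.searchsorted(null, g, side="left")
    p = (1.0 + n_ge) / (null.size + 1.0)
    constant = np.ptp(x, axis=1) == 0
    p[constant] = 1.0
    return g, p


def robust_g_test(values, times, period: float = DEFAULT_PERIOD,
                  n_null: int = 9999, seed: int = 0):
    """Single-profile robust g-test; returns (g_rob, p)."""
    g, p = robust_g_pvalues(np.asarray(values)[None, :], times, period, n_null, seed)
    return float(g[0]), float(p[0])


def fourier_score(values, times, period: float = DEFAULT_PERIOD) -> float:
    """F = |sum_k x_k exp(-i omega t_k)| with x mean-centered, omega = 2*pi/period."""
    x = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if period <= 0:
        raise ValueError("period must be positive")
    x = x - x.mean()
    w = 2 * np.pi / period
    return float(np.hypot((x * np.cos(w * t)).sum(), (x * np.sin(w * t)).sum()))


def delichtenberg_scores(
    values, times, period: float = DEFAULT_PERIOD,
    population_sds=None, n_perm: int = 200, seed: int = 0,
):
    """Permutation Fourier scoring for each profile row.

    Returns (F, p_per, p_reg, combined).  p_per uses ``n_perm`` shared
    within-profile time shuffles with add-one correction; p_reg is the
    fraction of population profiles at least as strongly regulated (SD);
    combined = p_per * p_reg.
    """
    x = np.atleast_2d(np.asarray(values, dtype=float))
    t = np.asarray(times, dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    w = 2 * np.pi / period
    c, s = np.cos(w * t), np.sin(w * t)
    F = np.hypot(x @ c, x @ s)

    rng = np.random.default_rng([seed, 131])
    n = t.size
    perms = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    Fp = np.hypot(x @ c[perms].T, x @ s[perms].T)  # (N, n_perm)
    p_per = (1.0 + (Fp >= F[:, None]).sum(axis=1)) / (n_perm + 1.0)

    sd = x.std(axis=1)
    pop = sd if population_sds is None else np.asarray(population_sds, dtype=float)
    pop_sorted = np.sort(pop)
    n_ge = pop.size - np.searchsorted(pop_sorted, sd, side="left")
    p_reg = n_ge / pop.size
    p_per[sd == 0] = 1.0
    return F, p_per, p_reg, p_per * p_reg


def delichtenberg_score(values, times, period, population_sds,
                        n_perm: int = 200, seed: int = 0):
    """Single-profile permutation Fourier score; returns (p_per, p_reg, combined)."""
    if population_sds is not None and len(population_sds) < 100:
        raise ValueError("regulation null needs a population of >= 100 profiles")
    F, p_per, p_reg, comb_ = delichtenberg_scores(
        np.asarray(values)[None, :], times, period, population_sds, n_perm, seed
    )
    return float(p_per[0]), float(p_reg[0]), float(comb_[0])


def calibrate_cutoff(scores: pd.Series, benchmark_ids, smaller_is_better: bool = True) -> float:
    """Score cutoff maximizing benchmark recall minus non-benchmark call rate.

    ``scores`` is indexed by transcript id.  The scan considers every
    boundary between distinct score values; ties in the objective go to the
    most stringent cutoff.  A call is score <= cutoff (or >= when larger
    scores are better).
    """
    benchmark = set(benchmark_ids)
    if not benchmark:
        raise ValueError("benchmark set is empty")
    missing = benchmark - set(scores.index)
    if missing:
        raise ValueError(f"benchmark ids absent from scores: {sorted(missing)[:5]}")
    s = scores.sort_values(ascending=smaller_is_better, kind="mergesort")
    is_bench = s.index.isin(benchmark).astype(float)
    n_b = is_bench.sum()
    n_o = len(s) - n_b
    tp = np.cumsum(is_bench)
    fp = np.cumsum(1.0 - is_bench)
    j = tp / n_b - (fp / n_o if n_o else 0.0)
    vals = s.to_numpy()
    boundary = np.r_[vals[:-1] != vals[1:], True]  # last index of each distinct score
    cand = np.flatnonzero(boundary)
    best = cand[int(np.argmax(j[cand]))]
    return float(vals[best])


def combine_calls(call_g: bool, call_dl: bool, call_manual=None) -> bool:
    """Cycling iff at least two of the three methods agree (manual optional)."""
    if call_manual is None:
        return bool(call_g) and bool(call_dl)
    return int(bool(call_g)) + int(bool(call_dl)) + int(bool(call_manual)) >= 2


def peak_time(values, times, period: float = DEFAULT_PERIOD) -> float:
    """Within-cycle time of maximal fitted cosine, in % of the cycle [0, 100).

    Returns NaN for profiles with no power at the cycle frequency.
    """
    x = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    x = x - x.mean()
    w = 2 * np.pi / period
    a = float((x * np.cos(w * t)).sum())
    b = float((x * np.sin(w * t)).sum())
    if np.hypot(a, b) < 1e-12:
        return float("nan")
    return float((100.0 * np.arctan2(b, a) / (2 * np.pi)) % 100.0)


def peak_times(values, times, period: float = DEFAULT_PERIOD) -> np.ndarray:
    x = np.atleast_2d(np.asarray(values, dtype=float))
    return np.array([peak_time(row, times, period) for row in x])


def optimize_period(values, times, grid) -> float:
    """Period maximizing the amplitude-normalized Fourier score of benchmark profiles.

    T* = argmax_T sum_profiles F(profile, T) / SD(profile); ties go to the
    smallest T.  Flat profiles are excluded; all-flat input is an error.
    """
    x = np.atleast_2d(np.asarray(values, dtype=float))
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty period grid")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 benchmark profiles")
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all benchmark profiles are flat")
    x = x[keep] - x[keep].mean(axis=1, keepdims=True)
    sd = sd[keep]
    t = np.asarray(times, dtype=float)
    scores = np.empty(grid.size)
    for i, T in enumerate(grid):
        w = 2 * np.pi / T
        F = np.hypot(x @ np.cos(w * t), x @ np.sin(w * t))
        scores[i] = (F / sd).sum()
    order = np.argsort(grid, kind="mergesort")
    best = order[int(np.argmax(scores[order]))]  # first max along ascending T
    return float(grid[best])


def score_profiles(
    profiles: pd.DataFrame,
    times,
    period: float = DEFAULT_PERIOD,
    n_null: int = 9999,
    n_perm: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Run both detectors and peak-time estimation on a profile table.

    ``profiles`` has an ``id`` column plus one column per time point (any
    order-preserving names); rows with undefined profiles are dropped.
    """
    value_cols = [c for c in profiles.columns if c not in
                  ("id", "chrom", "strand", "start", "end", "defined", "category")]
    ok = profiles[value_cols].notna().all(axis=1)
    if "defined" in profiles.columns:
        ok &= profiles["defined"].astype(bool)
    sub = profiles.loc[ok]
    x = sub[value_cols].to_numpy(dtype=float)
    g, p_g = robust_g_pvalues(x, times, period, n_null=n_null, seed=seed)
    F, p_per, p_reg, dl = delichtenberg_scores(x, times, period, n_perm=n_perm, seed=seed)
    return pd.DataFrame(
        {
            "id": sub["id"].to_numpy(),
            "g_stat": g,
            "p_g": p_g,
            "fourier_score": F,
            "p_per": p_per,
            "p_reg": p_reg,
            "dl_score": dl,
            "amplitude_sd": x.std(axis=1),
            "peak_time": peak_times(x, times, period),
            "period": period,
        }
    )


def merge_dataset_calls(combined: dict, method_support: dict) -> pd.Series:
    """Merge per-dataset combined calls into one final call per transcript.

    With a single dataset the combined call stands.  With several, a
    transcript is cycling when some dataset makes the combined call and at
    least one *other* dataset shows method support (>= 1 detector call).
    """
    names = list(combined)
    ids = sorted(set().union(*[set(c.index) for c in combined.values()]))
    if len(names) == 1:
        base = combined[names[0]]
        return base.reindex(ids).fillna(False).astype(bool)
    final = pd.Series(False, index=ids)
    for ds in names:
        call = combined[ds].reindex(ids).fillna(False).astype(bool)
        others = [
            method_support[o].reindex(ids).fillna(False).astype(bool)
            for o in names if o != ds
        ]
        support = np.logical_or.reduce(others)
        final |= call & support
    return final
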