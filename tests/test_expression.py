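"""Background fit, expression threshold, categorization and feature profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tilecycle.express import (
    call_expressed,
    categorize_segments,
    estimate_background_threshold,
    feature_expression,
    shorth_midpoint,
)

# ---------------------------------------------------------------- shorth


def shorth_oracle(values):
    x = sorted(values)
    n = len(x)
    h = -(-n // 2)
    best = None
    for i in range(n - h + 1):
        width = x[i + h - 1] - x[i]
        if best is None or width < best[0]:
            best = (width, (x[i] + x[i + h - 1]) / 2)
    return best[1]


def test_shorth_example_leftmost_tie():
    assert shorth_midpoint([0, 0.1, 0.2, 5.0]) == pytest.approx(0.05)


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.floats(-50, 50), min_size=1, max_size=60))
def test_shorth_equals_enumeration(values):
    assert shorth_midpoint(values) == pytest.approx(shorth_oracle(values), abs=1e-9)


def test_shorth_recovers_normal_center():
    rng = np.random.default_rng(0)
    x = rng.normal(3, 1, 100_000)
    assert shorth_midpoint(x) == pytest.approx(3.0, abs=0.05)


# ---------------------------------------------------------------- threshold


def null_expressed_mixture(seed=0, n_null=100_000, n_expr=1000, shift=6.0):
    rng = np.random.default_rng(seed)
    null = rng.normal(0, 1, n_null)
    expressed = rng.normal(shift, 1, n_expr)
    return null, np.concatenate([null, expressed])


def test_threshold_controls_fdr_on_mixture():
    null, allv = null_expressed_mixture(seed=1)
    fit = estimate_background_threshold(null, 0.001, all_levels=allv)
    assert fit.mu == pytest.approx(0.0, abs=0.05)
    assert fit.sigma == pytest.approx(1.0, rel=0.05)
    called_null = (null >= fit.theta).sum()
    called = (allv >= fit.theta).sum()
    assert called > 0
    fdr = called_null / called
    se = np.sqrt(0.001 * 0.999 / called)
    assert abs(fdr - 0.001) <= 3 * se + 1e-6


def test_threshold_monotone_in_target():
    null, allv = null_expressed_mixture(seed=2)
    thetas = [
        estimate_background_threshold(null, t, all_levels=allv).theta
        for t in (0.0005, 0.001, 0.01, 0.05)
    ]
    assert all(a >= b for a, b in zip(thetas, thetas[1:]))


def test_all_null_call_rate_bounded():
    rng = np.random.default_rng(3)
    null = rng.normal(0, 1, 100_000)
    fit = estimate_background_threshold(null, 0.001)
    frac = (null >= fit.theta).mean()
    assert frac <= 2 * 0.001


def test_degenerate_background_rejected():
    with pytest.raises(ValueError):
        estimate_background_threshold(np.zeros(100), 0.001)


def test_expressed_boundary_inclusive():
    segs = pd.DataFrame({"mean_level": [1.0, 2.0, 3.0]})
    fit = estimate_background_threshold(
        np.random.default_rng(4).normal(0, 0.3, 1000), 0.5
    )
    fit.theta = 2.0
    flags = call_expressed(segs, fit)
    assert list(flags) == [False, True, True]


# ---------------------------------------------------------------- categories


def seg_table(rows):
    recs = []
    for i, (chrom, strand, start, end, level) in enumerate(rows, 1):
        recs.append(
            {"segment_id": f"s{i}", "chrom": chrom, "strand": strand,
             "start": start, "end": end, "mean_level": level,
             "level_t000": level, "level_t005": level}
        )
    return pd.DataFrame(recs)


GENES = pd.DataFrame(
    {
        "id": ["g1", "g2"],
        "chrom": ["chrI", "chrI"],
        "type": ["gene", "gene"],
        "start": [1000, 5000],
        "end": [2000, 6000],
        "strand": ["+", "-"],
    }
)


def test_categorize_trivial_cases():
    segs = seg_table(
        [
            ("chrI", "+", 1100, 1900, 5.0),   # inside g1, same strand
            ("chrI", "+", 5100, 5900, 5.0),   # wholly opposite g2
            ("chrI", "+", 3000, 3500, 5.0),   # overlaps nothing
            ("chrI", "-", 8000, 8050, 5.0),   # too short -> unassigned
        ]
    )
    out = categorize_segments(segs, GENES)
    assert list(out["category"]) == [
        "annotated", "unannotated_antisense", "unannotated_intergenic", "unassigned"
    ]


def test_categories_partition_segments():
    rng = np.random.default_rng(5)
    rows = []
    for _ in range(200):
        start = int(rng.integers(1, 9000))
        rows.append(
            ("chrI", rng.choice(["+", "-"]), start,
             start + int(rng.integers(50, 2000)), float(rng.normal(3, 2)))
        )
    out = categorize_segments(seg_table(rows), GENES)
    assert len(out) == 200
    assert out["category"].isin(
        ["annotated", "unannotated_antisense", "unannotated_intergenic", "unassigned"]
    ).all()


def test_unstranded_annotation_rejected():
    bad = GENES.assign(strand=".")
    with pytest.raises(ValueError, match="strand"):
        categorize_segments(seg_table([("chrI", "+", 1, 100, 1.0)]), bad)


# ---------------------------------------------------------------- profiles


def test_weighted_feature_expression_example():
    segs = seg_table([("chrI", "+", 1000, 1099, 2.0), ("chrI", "+", 1100, 1399, 4.0)])
    feat = pd.DataFrame(
        {"id": ["f"], "chrom": ["chrI"], "type": ["gene"],
         "start": [1000], "end": [1399], "strand": ["+"]}
    )
    prof = feature_expression(segs, feat)
    assert prof.loc[0, "level_t000"] == pytest.approx(3.5)


def test_feature_expression_matches_per_base_oracle():
    rng = np.random.default_rng(6)
    cuts = np.sort(rng.choice(np.arange(1001, 4000), 5, replace=False))
    bounds = [1000, *cuts, 4500]
    rows = [("chrI", "+", lo, hi - 1, float(rng.normal(2, 1)))
            for lo, hi in zip(bounds, bounds[1:])]
    segs = seg_table(rows)
    feat = pd.DataFrame(
        {"id": ["f"], "chrom": ["chrI"], "type": ["gene"],
         "start": [1200], "end": [4100], "strand": ["+"]}
    )
    prof = feature_expression(segs, feat)
    # per-base oracle
    base_levels = np.zeros(4100 - 1200 + 1)
    for (c, s, lo, hi, lv) in rows:
        for pos in range(max(lo, 1200), min(hi, 4100) + 1):
            base_levels[pos - 1200] = lv
    assert prof.loc[0, "level_t000"] == pytest.approx(base_levels.mean(), abs=1e-9)


def test_feature_expression_invariant_to_segment_split():
    whole = seg_table([("chrI", "+", 1000, 1999, 3.0)])
    split = seg_table([("chrI", "+", 1000, 1499, 3.0), ("chrI", "+", 1500, 1999, 3.0)])
    feat = pd.DataFrame(
        {"id": ["f"], "chrom": ["chrI"], "type": ["gene"],
         "start": [1100], "end": [1900], "strand": ["+"]}
    )
    a = feature_expression(whole, feat).loc[0, "level_t000"]
    b = feature_expression(split, feat).loc[0, "level_t000"]
    assert a == pytest.approx(b, abs=1e-12)


def test_zero_overlap_feature_flagged_not_zero():
    segs = seg_table([("chrI", "+", 1000, 1999, 3.0)])
    feat = pd.DataFrame(
        {"id": ["f"], "chrom": ["chrI"], "type": ["gene"],
         "start": [5000], "end": [5900], "strand": ["+"]}
    )
    prof = feature_expression(segs, feat)
    assert not prof.loc[0, "defined"]
    assert np.isnan(prof.loc[0, "level_t000"])
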