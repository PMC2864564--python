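"""Sense-antisense pairing, overlap typing, circular timing and association."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tilecycle.sap import (
    COUPLING_CLASSES,
    OVERLAP_TYPES,
    build_saps,
    classify_saps,
    coupling_class,
    coupling_overlap_association,
    overlap_type,
    peak_time_difference,
)

GENES = pd.DataFrame(
    {
        "id": ["g1", "g2"],
        "chrom": ["chrI", "chrI"],
        "type": ["gene", "gene"],
        "start": [1000, 3000],
        "end": [2000, 4000],
        "strand": ["+", "+"],
    }
)


def antisense(rows):
    return pd.DataFrame(
        [{"id": f"a{i}", "chrom": "chrI", "strand": "-", "start": s, "end": e}
         for i, (s, e) in enumerate(rows, 1)]
    )


# ---------------------------------------------------------------- pairing


def test_single_contained_antisense_yields_one_sap():
    saps = build_saps(antisense([(1200, 1800)]), GENES)
    assert len(saps) == 1
    assert saps.loc[0, "sense_id"] == "g1"
    assert saps.loc[0, "overlap_type"] == "contained"


def test_bridging_antisense_yields_single_spans_two_record():
    saps = build_saps(antisense([(1500, 3500)]), GENES)
    assert len(saps) == 1
    assert saps.loc[0, "overlap_type"] == "spans_two"
    assert set(saps.loc[0, "all_sense_ids"].split(";")) == {"g1", "g2"}
    # coupling partner is the more-overlapped gene
    assert saps.loc[0, "sense_id"] in {"g1", "g2"}


def test_orphan_antisense_excluded():
    saps = build_saps(antisense([(5000, 5500)]), GENES)
    assert len(saps) == 0


# ---------------------------------------------------------------- coupling


def test_coupling_classes():
    assert coupling_class(True, True) == "AS-periodic/S-periodic"
    assert coupling_class(True, False) == "AS-periodic/S-nonperiodic"
    assert coupling_class(False, True) == "AS-nonperiodic/S-periodic"
    assert coupling_class(False, False) == "AS-nonperiodic/S-nonperiodic"


def test_classify_saps_partitions_and_delta():
    saps = build_saps(antisense([(1200, 1800), (3200, 3800)]), GENES)
    out = classify_saps(
        saps,
        periodic_antisense_ids={"a1"},
        periodic_sense_ids={"g1", "g2"},
        peak_times={"a1": 10.0, "g1": 60.0, "a2": 30.0, "g2": 30.0},
    )
    assert out["coupling_class"].isin(COUPLING_CLASSES).all()
    assert len(out) == 2
    row1 = out[out["antisense_id"] == "a1"].iloc[0]
    assert row1["peak_time_difference"] == pytest.approx(50.0)
    row2 = out[out["antisense_id"] == "a2"].iloc[0]
    assert np.isnan(row2["peak_time_difference"])  # a2 not periodic


# ---------------------------------------------------------------- timing


def test_peak_time_difference_printed_examples():
    assert peak_time_difference(20, 20) == 0.0
    assert peak_time_difference(10, 60) == 50.0
    assert peak_time_difference(95, 5) == 10.0


@settings(max_examples=200, derandomize=True)
@given(st.floats(0, 100, exclude_max=True), st.floats(0, 100, exclude_max=True),
       st.integers(-3, 3), st.integers(-3, 3))
def test_peak_time_difference_symmetric_circular(p1, p2, k1, k2):
    d = peak_time_difference(p1, p2)
    assert 0 <= d <= 50
    assert d == pytest.approx(peak_time_difference(p2, p1), abs=1e-9)
    assert d == pytest.approx(
        peak_time_difference(p1 + 100 * k1, p2 + 100 * k2), abs=1e-6
    )


# ---------------------------------------------------------------- overlap typing


def test_overlap_type_trivial_cases():
    assert overlap_type(50, 600, 100, 500, "+") == "contains"
    assert overlap_type(50, 200, 100, 500, "+") == "overlaps_5prime"
    assert overlap_type(50, 200, 100, 500, "-") == "overlaps_3prime"
    assert overlap_type(150, 450, 100, 500, "+") == "contained"
    assert overlap_type(100, 500, 100, 500, "+") == "contains"  # tie rule


def test_overlap_type_translation_and_strand_flip():
    cases = [(50, 600), (50, 200), (300, 700), (150, 450)]
    swap = {"overlaps_5prime": "overlaps_3prime", "overlaps_3prime": "overlaps_5prime"}
    for a_s, a_e in cases:
        base = overlap_type(a_s, a_e, 100, 500, "+")
        shifted = overlap_type(a_s + 10_000, a_e + 10_000, 10_100, 10_500, "+")
        assert base == shifted
        flipped = overlap_type(a_s, a_e, 100, 500, "-")
        assert flipped == swap.get(base, base)


# ---------------------------------------------------------------- association


def fake_saps(overlaps, classes):
    return pd.DataFrame({"overlap_type": overlaps, "coupling_class": classes})


def test_chi2_identical_rows_is_zero():
    saps = fake_saps(
        ["contains"] * 20 + ["contained"] * 20,
        (["AS-periodic/S-periodic"] * 10 + ["AS-periodic/S-nonperiodic"] * 10) * 2,
    )
    _, chi2, df, p, _ = coupling_overlap_association(saps)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi2_textbook_2x2():
    saps = fake_saps(
        ["contains"] * 30 + ["contained"] * 30,
        ["AS-periodic/S-periodic"] * 10 + ["AS-periodic/S-nonperiodic"] * 20
        + ["AS-periodic/S-periodic"] * 20 + ["AS-periodic/S-nonperiodic"] * 10,
    )
    _, chi2, df, p, _ = coupling_overlap_association(saps)
    assert chi2 == pytest.approx(6.6667, abs=1e-3)
    assert df == 1


def test_chi2_matches_formula_on_random_tables():
    rng = np.random.default_rng(11)
    for _ in range(100):
        n = int(rng.integers(40, 200))
        ov = rng.choice(OVERLAP_TYPES, n)
        cl = rng.choice(COUPLING_CLASSES, n)
        saps = fake_saps(ov, cl)
        try:
            table, chi2, df, p, _ = coupling_overlap_association(saps)
        except ValueError:
            continue
        obs = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0].to_numpy(float)
        exp = obs.sum(1)[:, None] * obs.sum(0)[None, :] / obs.sum()
        manual = ((obs - exp) ** 2 / exp).sum()
        assert chi2 == pytest.approx(manual, abs=1e-9)
        assert df == (obs.shape[0] - 1) * (obs.shape[1] - 1)


def test_planted_association_reaches_reported_significance():
    """Class-dependent overlap preferences at n=500 give p < 0.002."""
    rng = np.random.default_rng(12)
    prefs = {
        "AS-periodic/S-periodic": [0.1, 0.6, 0.1, 0.1, 0.1],
        "AS-periodic/S-nonperiodic": [0.45, 0.1, 0.1, 0.1, 0.25],
        "AS-nonperiodic/S-periodic": [0.1, 0.1, 0.6, 0.1, 0.1],
        "AS-nonperiodic/S-nonperiodic": [0.2, 0.2, 0.2, 0.2, 0.2],
    }
    classes = rng.choice(COUPLING_CLASSES, 500, p=[0.1, 0.15, 0.25, 0.5])
    overlaps = [rng.choice(OVERLAP_TYPES, p=prefs[c]) for c in classes]
    _, chi2, df, p, _ = coupling_overlap_association(fake_saps(overlaps, classes))
    assert p < 0.002


def test_degenerate_single_cell_rejected():
    saps = fake_saps(["contains"] * 10, ["AS-periodic/S-periodic"] * 10)
    with pytest.raises(ValueError):
        coupling_overlap_association(saps)
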