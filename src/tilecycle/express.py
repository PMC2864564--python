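"""Expression thresholding, segment categorization and feature profiles.

The background level of the array is estimated from segments that overlap no
annotated transcribed feature: a normal distribution is fitted with its mean
at the midpoint of the shorth (the shortest interval covering half of the
values) and its variance from the lowest 99.9% of the data, and the
expression threshold is the smallest level at which the estimated false
discovery rate drops to the target (default 0.1%).  Expressed segments are
then categorized by how they overlap the annotation, and per-feature
expression profiles are overlap-length-weighted averages of same-strand
segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import norm as _norm

from .annotation import NON_TRANSCRIBED_TYPES, require_strands


@dataclass
class BackgroundFit:
    """Normal background model and derived expression threshold."""

    mu: float
    sigma: float
    theta: float
    target_fdr: float
    n_background: int


def shorth_midpoint(values) -> float:
    """Midpoint of the shortest interval containing ceil(n/2) of the values.

    Ties between equally short intervals go to the leftmost one.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    h = int(np.ceil(n / 2))
    widths = x[h - 1:] - x[: n - h + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: leftmost tie
    return float((x[i] + x[i + h - 1]) / 2)


def estimate_background_threshold(
    background_levels,
    target_fdr: float = 0.001,
    all_levels=None,
) -> BackgroundFit:
    """Fit the background normal and find the expression threshold.

    ``background_levels`` are mean levels of segments overlapping no annotated
    transcribed feature; ``all_levels`` (default: the background levels) is
    the full segment-level list over which discoveries are counted.  The
    threshold is the smallest observed level x with estimated
    FDR(x) = N_bg * (1 - Phi((x - mu)/sigma)) / #{levels >= x} <= target.
    """
    bg = np.asarray(background_levels, dtype=float)
    if bg.size < 20:
        raise ValueError("need at least 20 background levels")
    allv = bg if all_levels is None else np.asarray(all_levels, dtype=float)
    mu = shorth_midpoint(bg)
    low = bg[bg <= np.quantile(bg, 0.999)]
    var = float(np.var(low, ddof=1))
    if var <= 0:
        raise ValueError("degenerate background: zero variance")
    sigma = float(np.sqrt(var))

    cand = np.sort(np.unique(allv))
    n_ge = allv.size - np.searchsorted(np.sort(allv), cand, side="left")
    expected_null = bg.size * _norm.sf((cand - mu) / sigma)
    fdr = expected_null / n_ge
    ok = np.flatnonzero(fdr <= target_fdr)
    theta = float(cand[ok[0]]) if ok.size else float("inf")
    return BackgroundFit(
        mu=float(mu), sigma=sigma, theta=theta,
        target_fdr=float(target_fdr), n_background=int(bg.size),
    )


def call_expressed(segments: pd.DataFrame, fit: BackgroundFit) -> pd.Series:
    """Expressed flag per segment: mean level (over all arrays) >= threshold."""
    return segments["mean_level"] >= fit.theta


def _strand_trees(features: pd.DataFrame) -> dict:
    trees: dict = {}
    for row in features.itertuples(index=False):
        trees.setdefault((row.chrom, row.strand), IntervalTree()).addi(
            row.start, row.end + 1, (row.id, row.type)
        )
    return trees


def _overlap_nt(tree: IntervalTree | None, start: int, end: int, types=None):
    """Total nt of [start, end] covered by tree intervals (union), plus hits."""
    if tree is None:
        return 0, []
    hits = []
    ivs = []
    for iv in tree.overlap(start, end + 1):
        fid, ftype = iv.data
        if types is not None and ftype not in types:
            continue
        lo, hi = max(iv.begin, start), min(iv.end - 1, end)
        ivs.append((lo, hi))
        hits.append((fid, hi - lo + 1))
    ivs.sort()
    covered, cur_lo, cur_hi = 0, None, None
    for lo, hi in ivs:
        if cur_lo is None:
            cur_lo, cur_hi = lo, hi
        elif lo <= cur_hi + 1:
            cur_hi = max(cur_hi, hi)
        else:
            covered += cur_hi - cur_lo + 1
            cur_lo, cur_hi = lo, hi
    if cur_lo is not None:
        covered += cur_hi - cur_lo + 1
    return covered, hits


def background_segment_levels(segments: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """Mean levels of segments overlapping no annotated transcribed feature.

    Overlap is strand-aware: the platform is strand-specific, so a segment
    opposite an annotated gene measures antisense abundance, which belongs to
    the background population unless annotated in its own right.
    """
    transcribed = features[~features["type"].isin(NON_TRANSCRIBED_TYPES)]
    trees = _strand_trees(transcribed)
    keep = []
    for row in segments.itertuples(index=False):
        tree = trees.get((row.chrom, row.strand))
        keep.append(tree is None or not tree.overlaps(row.start, row.end + 1))
    return segments.loc[keep, "mean_level"].to_numpy(dtype=float)


def categorize_segments(
    segments: pd.DataFrame,
    features: pd.DataFrame,
    expressed: pd.Series | None = None,
    f_same: float = 0.5,
    f_anti: float = 0.5,
    f_min: float = 0.2,
    min_length_nt: int = 80,
    coding_types=("gene",),
) -> pd.DataFrame:
    """Assign each segment a transcript category against the annotation.

    annotated: same-strand overlap with any annotated transcribed feature
    covers >= ``f_same`` of the segment; unannotated_antisense: same-strand
    overlap < ``f_same`` and opposite-strand overlap with a protein-coding
    feature >= ``f_anti``; unannotated_intergenic: both strand overlap
    fractions < ``f_min``; otherwise (or when failing the expressed /
    minimum-length filters) unassigned.
    """
    require_strands(features)
    transcribed = features[~features["type"].isin(NON_TRANSCRIBED_TYPES)]
    trees = _strand_trees(transcribed)
    coding_types = set(coding_types)
    if expressed is None:
        expressed = pd.Series(True, index=segments.index)

    recs = []
    for (_, row), is_expr in zip(segments.iterrows(), expressed):
        length = row["end"] - row["start"] + 1
        anti_strand = "-" if row["strand"] == "+" else "+"
        same_nt, same_hits = _overlap_nt(
            trees.get((row["chrom"], row["strand"])), row["start"], row["end"]
        )
        anti_nt, anti_hits = _overlap_nt(
            trees.get((row["chrom"], anti_strand)), row["start"], row["end"],
            types=coding_types,
        )
        same_frac = same_nt / length
        anti_frac = anti_nt / length
        if not is_expr or length < min_length_nt:
            cat = "unassigned"
        elif same_frac >= f_same:
            cat = "annotated"
        elif anti_frac >= f_anti:
            cat = "unannotated_antisense"
        elif same_frac < f_min and anti_frac < f_min:
            cat = "unannotated_intergenic"
        else:
            cat = "unassigned"
        recs.append(
            {
                "id": row["segment_id"],
                "chrom": row["chrom"],
                "strand": row["strand"],
                "start": row["start"],
                "end": row["end"],
                "category": cat,
                "expressed": bool(is_expr),
                "mean_level": row["mean_level"],
                "same_strand_frac": same_frac,
                "opposite_strand_frac": anti_frac,
                "same_strand_hits": ";".join(f"{f}:{o}" for f, o in sorted(same_hits)),
                "opposite_strand_hits": ";".join(f"{f}:{o}" for f, o in sorted(anti_hits)),
            }
        )
    return pd.DataFrame(recs)


def feature_expression(
    segments: pd.DataFrame,
    features: pd.DataFrame,
    expressed: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-feature expression profiles from same-strand overlapping segments.

    profile(feature, k) = sum_s w_s * level(s, k) / sum_s w_s with w_s the
    overlap length in nt.  Features with zero same-strand overlap get NaN
    profiles and ``defined = False``.
    """
    require_strands(features)
    level_cols = [c for c in segments.columns if c.startswith("level_")]
    if expressed is None:
        expressed = pd.Series(True, index=segments.index)
    segs = segments.loc[list(expressed)]
    seg_trees: dict = {}
    for idx, row in segs.iterrows():
        seg_trees.setdefault((row["chrom"], row["strand"]), IntervalTree()).addi(
            row["start"], row["end"] + 1, idx
        )
    recs = []
    for row in features.itertuples(index=False):
        tree = seg_trees.get((row.chrom, row.strand))
        wsum = 0.0
        acc = np.zeros(len(level_cols))
        if tree is not None:
            for iv in tree.overlap(row.start, row.end + 1):
                w = min(iv.end - 1, row.end) - max(iv.begin, row.start) + 1
                acc += w * segs.loc[iv.data, level_cols].to_numpy(dtype=float)
                wsum += w
        rec = {"id": row.id, "chrom": row.chrom, "strand": row.strand,
               "start": row.start, "end": row.end, "defined": wsum > 0}
        vals = acc / wsum if wsum > 0 else np.full(len(level_cols), np.nan)
        rec.update({c: v for c, v in zip(level_cols, vals)})
        recs.append(rec)
    out = pd.DataFrame(recs)
    out.attrs["arrays"] = [c[len("level_"):] for c in level_cols]
    return out


def category_summary(transcripts: pd.DataFrame) -> pd.DataFrame:
    """Counts of segments per category (the expressed-segment pie)."""
    counts = transcripts["category"].value_counts()
    return counts.rename_axis("category").reset_index(name="n_segments")
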