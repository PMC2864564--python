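"""Sense-antisense pair (SAP) construction, classification and association.

Every unannotated antisense transcript is paired with the protein-coding
feature(s) it overlaps on the opposite strand.  Pairs are classified two
ways: by expression coupling (the 2x2 of antisense-periodic x
sense-periodic) and by overlap geometry (antisense contains the sense
message, is contained in it, overlaps its 5' or 3' end, or spans two sense
transcripts).  When both members cycle, the circular peak-time difference on
the percent-of-cycle scale quantifies their relative timing: 0 is in-phase,
50 is opposite-phase.  A chi-square test measures the association between
coupling class and overlap type.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import chi2_contingency

log = logging.getLogger(__name__)

COUPLING_CLASSES = [
    "AS-periodic/S-periodic",
    "AS-periodic/S-nonperiodic",
    "AS-nonperiodic/S-periodic",
    "AS-nonperiodic/S-nonperiodic",
]
OVERLAP_TYPES = ["contains", "contained", "overlaps_5prime", "overlaps_3prime", "spans_two"]


def peak_time_difference(p1: float, p2: float) -> float:
    """Circular peak-time difference on the 0-100 %-of-cycle scale.

    Delta = min(|p1 - p2|, 100 - |p1 - p2|), in [0, 50]: 0 means in-phase,
    50 means opposite-phase (180 degree shift).
    """
    if not (np.isfinite(p1) and np.isfinite(p2)):
        return float("nan")
    d = abs(float(p1) % 100.0 - float(p2) % 100.0)
    return float(min(d, 100.0 - d))


def overlap_type(
    as_start: int, as_end: int,
    s_start: int, s_end: int, s_strand: str,
    contained_frac: float = 0.9,
) -> str:
    """Geometric relation of an antisense interval to its sense partner.

    ``contains``: antisense covers the whole sense interval (identical
    intervals count as contains).  ``contained``: at least ``contained_frac``
    of the antisense lies inside the sense interval ("mainly contained").
    Otherwise the antisense overlaps the 5' or 3' transcriptional end of the
    sense mRNA, which is strand-aware: the 5' end of a + strand gene is its
    start coordinate, of a - strand gene its end coordinate.
    """
    if as_start <= s_start and as_end >= s_end:
        return "contains"
    ov = min(as_end, s_end) - max(as_start, s_start) + 1
    if ov <= 0:
        raise ValueError("antisense and sense intervals do not overlap")
    if ov / (as_end - as_start + 1) >= contained_frac:
        return "contained"
    covers_start = as_start <= s_start <= as_end
    covers_end = as_start <= s_end <= as_end
    if covers_start and not covers_end:
        return "overlaps_5prime" if s_strand == "+" else "overlaps_3prime"
    if covers_end and not covers_start:
        return "overlaps_3prime" if s_strand == "+" else "overlaps_5prime"
    # interior overlap without reaching a sense end: the antisense pokes out
    # of the sense interval on one side only by construction; treat as mainly
    # contained
    return "contained"


def build_saps(
    antisense: pd.DataFrame,
    features: pd.DataFrame,
    coding_types=("gene",),
    contained_frac: float = 0.9,
) -> pd.DataFrame:
    """One SAP per antisense transcript and overlapped opposite-strand gene.

    An antisense overlapping two (or more) sense features yields a single
    ``spans_two`` record listing all of them; coupling then uses the
    most-overlapped sense feature.  Antisense transcripts overlapping no
    sense feature are excluded (logged).
    """
    coding = features[features["type"].isin(set(coding_types))]
    trees: dict = {}
    for row in coding.itertuples(index=False):
        trees.setdefault((row.chrom, row.strand), IntervalTree()).addi(
            row.start, row.end + 1, (row.id, row.start, row.end)
        )
    recs = []
    for row in antisense.itertuples(index=False):
        s_strand = "-" if row.strand == "+" else "+"
        tree = trees.get((row.chrom, s_strand))
        hits = []
        if tree is not None:
            for iv in tree.overlap(row.start, row.end + 1):
                fid, fs, fe = iv.data
                ov = min(fe, row.end) - max(fs, row.start) + 1
                hits.append((ov, fid, fs, fe))
        if not hits:
            log.info("antisense %s overlaps no sense feature; excluded", row.id)
            continue
        hits.sort(reverse=True)
        ov, fid, fs, fe = hits[0]  # coupling partner = most-overlapped gene
        if len(hits) >= 2:
            otype = "spans_two"
        else:
            otype = overlap_type(row.start, row.end, fs, fe, s_strand, contained_frac)
        recs.append(
            {
                "antisense_id": row.id,
                "sense_id": fid,
                "chrom": row.chrom,
                "antisense_start": row.start,
                "antisense_end": row.end,
                "antisense_strand": row.strand,
                "sense_start": fs,
                "sense_end": fe,
                "sense_strand": s_strand,
                "overlap_nt": ov,
                "overlap_type": otype,
                "all_sense_ids": ";".join(h[1] for h in hits),
            }
        )
    return pd.DataFrame(
        recs,
        columns=[
            "antisense_id", "sense_id", "chrom", "antisense_start", "antisense_end",
            "antisense_strand", "sense_start", "sense_end", "sense_strand",
            "overlap_nt", "overlap_type", "all_sense_ids",
        ],
    )


def coupling_class(antisense_periodic: bool, sense_periodic: bool) -> str:
    a = "AS-periodic" if antisense_periodic else "AS-nonperiodic"
    s = "S-periodic" if sense_periodic else "S-nonperiodic"
    return f"{a}/{s}"


def classify_saps(
    saps: pd.DataFrame,
    periodic_antisense_ids,
    periodic_sense_ids,
    peak_times: dict | None = None,
) -> pd.DataFrame:
    """Attach coupling classes and (where defined) peak-time differences."""
    per_as = set(periodic_antisense_ids)
    per_s = set(periodic_sense_ids)
    out = saps.copy()
    out["coupling_class"] = [
        coupling_class(a in per_as, s in per_s)
        for a, s in zip(out["antisense_id"], out["sense_id"])
    ]
    if peak_times is not None:
        out["peak_time_antisense"] = [peak_times.get(a, np.nan) for a in out["antisense_id"]]
        out["peak_time_sense"] = [peak_times.get(s, np.nan) for s in out["sense_id"]]
        out["peak_time_difference"] = [
            peak_time_difference(pa, ps) if (a in per_as and s in per_s) else np.nan
            for a, s, pa, ps in zip(
                out["antisense_id"], out["sense_id"],
                out["peak_time_antisense"], out["peak_time_sense"],
            )
        ]
    return out


def coupling_overlap_association(saps: pd.DataFrame, monte_carlo: int = 0, seed: int = 0):
    """Chi-square association between overlap type (5) and coupling class (4).

    Returns ``(table, chi2, df, p, warning)``; the table keeps all defined
    categories, the test drops empty rows/columns, and ``warning`` is set
    when any expected count is below 5.  ``monte_carlo > 0`` replaces the
    asymptotic p-value by a permutation estimate for sparse tables.
    """
    if "coupling_class" not in saps.columns:
        raise ValueError("classify_saps must run before the association test")
    table = pd.crosstab(saps["overlap_type"], saps["coupling_class"])
    table = table.reindex(index=OVERLAP_TYPES, columns=COUPLING_CLASSES, fill_value=0)
    trimmed = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if trimmed.shape[0] < 2 or trimmed.shape[1] < 2:
        raise ValueError("association test needs >= 2 non-empty rows and columns")
    res = chi2_contingency(trimmed.to_numpy(), correction=False)
    chi2, p, df, expected = res.statistic, res.pvalue, res.dof, res.expected_freq
    warning = bool((expected < 5).any())
    if monte_carlo > 0:
        rng = np.random.default_rng([seed, 57])
        rows = saps["overlap_type"].to_numpy()
        cols = saps["coupling_class"].to_numpy()
        hits = 0
        for _ in range(monte_carlo):
            perm = pd.crosstab(rows, rng.permutation(cols))
            perm = perm.loc[perm.sum(axis=1) > 0, perm.sum(axis=0) > 0]
            stat = chi2_contingency(perm.to_numpy(), correction=False).statistic
            hits += stat >= chi2
        p = (1 + hits) / (monte_carlo + 1)
    return table, float(chi2), int(df), float(p), warning
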