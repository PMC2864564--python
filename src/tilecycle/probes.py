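"""Probe-level data containers, TSV I/O and DNA-reference normalization.

A tiling array interrogates both genome strands at a regular spacing; each
probe carries one raw intensity per hybridized array (time point) plus a few
DNA-reference intensities measured by hybridizing sheared genomic DNA.  The
reference channel estimates each probe's sequence-specific affinity, so that
dividing it out calibrates probes against each other.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ["probe_id", "chrom", "strand", "start", "unique"]
_ARRAY_RE = re.compile(r"^t(\d+(?:\.\d+)?)$")
_REF_RE = re.compile(r"^ref\d+$")


@dataclass
class ProbeMatrix:
    """Strand-specific probe coordinates with per-array raw intensities.

    Attributes
    ----------
    meta : DataFrame with columns probe_id, chrom, strand, start, unique,
        sorted by (chrom, strand, start); one row per probe.
    intensities : DataFrame (same index as meta), one column per array,
        columns named ``t<minutes>``.
    reference : DataFrame (same index), one column per DNA-reference
        replicate, columns named ``ref<i>``.
    times : ndarray of time points in minutes, parallel to the
        intensity columns.
    chrom_sizes : optional mapping chromosome -> length (nt).
    """

    meta: pd.DataFrame
    intensities: pd.DataFrame
    reference: pd.DataFrame
    times: np.ndarray
    chrom_sizes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.meta) != len(self.intensities) or len(self.meta) != len(self.reference):
            raise ValueError("meta, intensities and reference must have one row per probe")
        if self.intensities.shape[1] != self.times.size:
            raise ValueError("one time point per intensity column required")

    @property
    def n_probes(self) -> int:
        return len(self.meta)

    @property
    def arrays(self) -> list:
        return list(self.intensities.columns)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.meta.reset_index(drop=True),
             self.intensities.reset_index(drop=True),
             self.reference.reset_index(drop=True)],
            axis=1,
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _sort_probes(frame: pd.DataFrame) -> pd.DataFrame:
    return frame.sort_values(["chrom", "strand", "start"], kind="mergesort").reset_index(drop=True)


def probe_matrix_from_frame(frame: pd.DataFrame, chrom_sizes: dict | None = None) -> ProbeMatrix:
    """Assemble a ProbeMatrix from a wide table (see :func:`read_probe_table`)."""
    missing = [c for c in META_COLUMNS if c != "unique" and c not in frame.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    frame = frame.copy()
    if "unique" not in frame.columns:
        frame["unique"] = True
    array_cols = [c for c in frame.columns if _ARRAY_RE.match(str(c))]
    ref_cols = [c for c in frame.columns if _REF_RE.match(str(c))]
    if not array_cols:
        raise ValueError("no intensity columns found (expected names like 't000')")
    if not ref_cols:
        raise ValueError("no DNA-reference columns found (expected names like 'ref1')")
    times = np.array([float(_ARRAY_RE.match(str(c)).group(1)) for c in array_cols])
    order = np.argsort(times, kind="stable")
    array_cols = [array_cols[i] for i in order]
    times = times[order]

    bad_strand = ~frame["strand"].isin(["+", "-"])
    if bad_strand.any():
        row = int(np.flatnonzero(bad_strand.to_numpy())[0])
        raise ValueError(f"invalid strand at data line {row + 1}")
    for col in array_cols + ref_cols:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = ~(vals > 0) | ~np.isfinite(vals)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-positive or non-numeric intensity in column {col!r} "
                f"at data line {row + 1}"
            )
        frame[col] = vals.astype(float)

    frame = _sort_probes(frame)
    dup = frame.duplicated(subset=["chrom", "strand", "start"])
    if dup.any():
        row = frame.loc[dup, ["chrom", "strand", "start"]].iloc[0]
        raise ValueError(
            f"duplicate probe position {row['chrom']}:{row['start']}({row['strand']})"
        )
    meta = frame[META_COLUMNS].copy()
    return ProbeMatrix(
        meta=meta,
        intensities=frame[array_cols].copy(),
        reference=frame[ref_cols].copy(),
        times=times,
        chrom_sizes=dict(chrom_sizes or {}),
    )


def read_probe_table(path, chrom_sizes: dict | None = None) -> ProbeMatrix:
    """Read a probe TSV (probe_id, chrom, strand, start[, unique], t*, ref*)."""
    frame = pd.read_csv(path, sep="\t")
    return probe_matrix_from_frame(frame, chrom_sizes=chrom_sizes)


@dataclass
class NormalizedMatrix:
    """Normalized log2-scale expression values z, one per (probe, array)."""

    meta: pd.DataFrame
    z: pd.DataFrame
    times: np.ndarray
    chrom_sizes: dict = field(default_factory=dict)

    @property
    def n_probes(self) -> int:
        return len(self.meta)

    @property
    def arrays(self) -> list:
        return list(self.z.columns)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.meta.reset_index(drop=True), self.z.reset_index(drop=True)], axis=1
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_bedgraph(self, path, array) -> None:
        """Write one array's z values as bedGraph (0-based half-open)."""
        starts0 = self.meta["start"].to_numpy() - 1
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="z_{array}"\n')
            for chrom, s0, val in zip(self.meta["chrom"], starts0, self.z[array]):
                fh.write(f"{chrom}\t{s0}\t{s0 + 1}\t{val:.5f}\n")


def read_normalized_table(path, chrom_sizes: dict | None = None) -> NormalizedMatrix:
    frame = pd.read_csv(path, sep="\t")
    array_cols = [c for c in frame.columns if _ARRAY_RE.match(str(c))]
    times = np.array([float(_ARRAY_RE.match(str(c)).group(1)) for c in array_cols])
    meta_cols = [c for c in META_COLUMNS if c in frame.columns]
    return NormalizedMatrix(
        meta=frame[meta_cols].copy(),
        z=frame[array_cols].copy(),
        times=times,
        chrom_sizes=dict(chrom_sizes or {}),
    )


def normalize(
    raw: ProbeMatrix,
    background_quantile: float | None = 0.05,
    eps: float = 1.0,
    per_array_calibration: bool = True,
    unique_only: bool = True,
) -> NormalizedMatrix:
    """Background-correct and calibrate raw intensities against the DNA reference.

    For probe j and array k,

        z_jk = log2(max(y_jk - b_k, eps)) - log2(median_m r_jm) + c_k

    where b_k is a low quantile (default 5th percentile) of array k's raw
    intensities modelling additive optical background (``background_quantile
    = None`` disables the correction, b_k = 0), the per-probe median
    DNA-reference intensity divides out probe affinity, and c_k recenters each
    array so that its median z is 0 (global median when
    ``per_array_calibration`` is False).  z is therefore invariant to scaling
    all intensities of one array by a positive constant.
    """
    meta = raw.meta
    y = raw.intensities.to_numpy(dtype=float)
    r = raw.reference.to_numpy(dtype=float)
    keep = meta["unique"].to_numpy(dtype=bool) if unique_only else np.ones(len(meta), bool)
    meta = meta.loc[keep].reset_index(drop=True)
    y = y[keep]
    r = r[keep]
    if y.shape[0] == 0:
        raise ValueError("no (unique) probes to normalize")

    ptp = y.max(axis=0) - y.min(axis=0)
    if np.any(ptp == 0):
        k = int(np.flatnonzero(ptp == 0)[0])
        raise ValueError(
            f"array {raw.arrays[k]!r} has identical intensity at every probe; "
            "background is undefined"
        )
    if background_quantile is None:
        b = np.zeros(y.shape[1])
    else:
        b = np.quantile(y, background_quantile, axis=0)
    rbar = np.median(r, axis=1)
    z = np.log2(np.maximum(y - b[None, :], eps)) - np.log2(rbar)[:, None]
    if per_array_calibration:
        c = -np.median(z, axis=0)
        z = z + c[None, :]
    else:
        z = z - np.median(z)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite normalized values produced")
    zf = pd.DataFrame(z, columns=raw.arrays)
    return NormalizedMatrix(meta=meta, z=zf, times=raw.times.copy(), chrom_sizes=dict(raw.chrom_sizes))
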