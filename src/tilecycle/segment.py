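"""Piecewise-constant segmentation of normalized probe intensities.

Transcript boundaries are found by fitting, separately to each strand of each
chromosome, the model

    z_jk = mu_sk + eps_jk,   t_s <= j < t_{s+1},

where j indexes probes in genomic order, k indexes arrays (time points),
mu_sk is the array-specific level of segment s and t_2..t_S are the S-1
interior change-points shared by all arrays.  The change-points minimizing
the residual sum of squares are found exactly by dynamic programming with
O(1) segment costs from cumulative sums.  S is chosen per chromosome so that
the average segment length hits a target (default 1,250 nt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .probes import NormalizedMatrix


@dataclass
class SegmentationConfig:
    """Controls segment count and DP search window.

    avg_length_nt: target mean segment length used to pick S per chromosome.
    max_segment_nt: cap on single-segment genomic span; bounds the DP search
        window (and runtime) on long chromosomes.  None = unbounded.
    """

    avg_length_nt: float = 1250.0
    max_segment_nt: float | None = None

    def __post_init__(self) -> None:
        if self.avg_length_nt <= 0:
            raise ValueError("avg_length_nt must be positive")


DEFAULT_MAX_SEGMENT_FACTOR = 10.0  # default cap = 10 * avg_length_nt


def choose_segment_count(chrom_length_nt: float, avg_length_nt: float = 1250.0) -> int:
    """S = max(1, round-half-up(length / target average length))."""
    if chrom_length_nt < 1:
        raise ValueError("chromosome length must be >= 1 nt")
    if avg_length_nt <= 0:
        raise ValueError("average segment length must be positive")
    return max(1, int(np.floor(chrom_length_nt / avg_length_nt + 0.5)))


@njit(cache=True)
def _dp_kernel(C, A, S, max_len):  # pragma: no cover - exercised via dp_segment
    """Exact DP over S segments; C/A are cumulative sums of z and sum_k z^2."""
    n = C.shape[0] - 1
    K = C.shape[1]
    INF = 1e300
    D_prev = np.full(n + 1, INF)
    D_cur = np.full(n + 1, INF)
    back = np.zeros((S + 1, n + 1), dtype=np.int64)
    D_prev[0] = 0.0
    for s in range(1, S + 1):
        for j in range(n + 1):
            D_cur[j] = INF
        j_lo = s
        j_hi = n - (S - s)
        for j in range(j_lo, j_hi + 1):
            i_lo = j - max_len
            if i_lo < s - 1:
                i_lo = s - 1
            best = INF
            arg = -1
            for i in range(i_lo, j):
                if D_prev[i] >= INF:
                    continue
                ln = j - i
                acc = 0.0
                for k in range(K):
                    d = C[j, k] - C[i, k]
                    acc += d * d
                cost = A[j] - A[i] - acc / ln
                v = D_prev[i] + cost
                if v < best:
                    best = v
                    arg = i
            D_cur[j] = best
            back[s, j] = arg
        for j in range(n + 1):
            D_prev[j] = D_cur[j]
    return D_prev[n], back


def dp_segment(z: np.ndarray, S: int, max_segment_probes: int | None = None):
    """Optimal change-points for one chromosome/strand.

    Parameters
    ----------
    z : (n, K) normalized intensities, probes in genomic order.
    S : number of segments.
    max_segment_probes : optional cap on probes per segment.

    Returns
    -------
    boundaries : int array of length S+1 (0-based, half-open probe-index
        bounds; boundaries[0] = 0, boundaries[S] = n).
    rss : minimal residual sum of squares.

    Ties in RSS are broken toward the leftmost boundary set (each backtracked
    predecessor is the smallest optimal one).
    """
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    n, K = z.shape
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite normalized values")
    if S < 1:
        raise ValueError("S must be >= 1")
    if n < S:
        raise ValueError(f"need at least S={S} probes, got {n}")
    W = n if max_segment_probes is None else int(max_segment_probes)
    if W * S < n:
        raise ValueError(
            f"max segment length {W} probes cannot cover {n} probes with {S} segments"
        )
    C = np.zeros((n + 1, K))
    np.cumsum(z, axis=0, out=C[1:])
    A = np.zeros(n + 1)
    np.cumsum((z * z).sum(axis=1), out=A[1:])
    rss, back = _dp_kernel(C, A, S, W)
    bounds = np.zeros(S + 1, dtype=int)
    bounds[S] = n
    for s in range(S, 0, -1):
        bounds[s - 1] = back[s, bounds[s]]
    return bounds, float(rss)


def fit_segments(
    norm: NormalizedMatrix,
    cfg: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Fit the piecewise-constant model on every chromosome/strand.

    Returns a segment table with 1-based inclusive genomic coordinates,
    per-array mean levels (``level_<array>`` columns), the across-array mean
    level, probe spans and per-fit RSS.  The segment count per chromosome is
    chosen from the chromosome length (``norm.chrom_sizes`` when available,
    else the tiled extent) and the configured average segment length.
    """
    cfg = cfg or SegmentationConfig()
    arrays = norm.arrays
    zmat = norm.z.to_numpy(dtype=float)
    meta = norm.meta
    out = []
    sid = 0
    for (chrom, strand), idx in meta.groupby(["chrom", "strand"], sort=True).indices.items():
        idx = np.sort(idx)
        starts = meta["start"].to_numpy()[idx]
        z = zmat[idx]
        n = starts.size
        length_nt = float(norm.chrom_sizes.get(chrom, starts[-1] + (starts[1] - starts[0] if n > 1 else 1) - 1))
        S = choose_segment_count(length_nt, cfg.avg_length_nt)
        S = min(S, n)
        spacing = float(np.median(np.diff(starts))) if n > 1 else 1.0
        max_nt = cfg.max_segment_nt
        if max_nt is None:
            max_nt = DEFAULT_MAX_SEGMENT_FACTOR * cfg.avg_length_nt
        W = max(2, int(np.ceil(max_nt / spacing)))
        if W * S < n:  # keep the cap feasible for the chosen S
            W = int(np.ceil(n / S)) + 1
        bounds, rss = dp_segment(z, S, max_segment_probes=W)
        chrom_len = int(norm.chrom_sizes.get(chrom, 0))
        for s in range(S):
            lo, hi = bounds[s], bounds[s + 1]
            levels = z[lo:hi].mean(axis=0)
            g_start = int(starts[lo])
            g_end = int(starts[hi] - 1) if hi < n else (chrom_len or int(starts[-1] + spacing - 1))
            sid += 1
            rec = {
                "segment_id": f"seg{sid:05d}",
                "chrom": chrom,
                "strand": strand,
                "start": g_start,
                "end": g_end,
                "first_probe": int(lo),
                "last_probe": int(hi - 1),
                "n_probes": int(hi - lo),
                "rss_fit": rss,
                "mean_level": float(levels.mean()),
            }
            rec.update({f"level_{a}": float(v) for a, v in zip(arrays, levels)})
            out.append(rec)
    table = pd.DataFrame(out)
    table.attrs["arrays"] = arrays
    table.attrs["times"] = np.asarray(norm.times, dtype=float)
    return table


def segment_levels(segments: pd.DataFrame) -> pd.DataFrame:
    """Per-segment, per-time-point expression levels (mean z over probes)."""
    level_cols = [c for c in segments.columns if c.startswith("level_")]
    out = segments[["segment_id", "chrom", "strand", "start", "end"] + level_cols].copy()
    out.columns = ["segment_id", "chrom", "strand", "start", "end"] + [
        c[len("level_"):] for c in level_cols
    ]
    return out


def segments_to_bed(segments: pd.DataFrame, path) -> None:
    """BED6 export (0-based half-open)."""
    with open(path, "w") as fh:
        for row in segments.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.segment_id}\t"
                f"{row.mean_level:.4f}\t{row.strand}\n"
            )
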