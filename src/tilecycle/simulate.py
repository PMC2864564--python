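"""Synthetic genomes, annotations and tiling-array time courses.

The generator emulates the experimental design the rest of the package is
built for: a compact yeast-like genome with annotated ORFs plus planted
unannotated antisense and intergenic transcripts, strand-specific probes
tiled every 8 nt, samples every 5 minutes over ~200 min (two to three cell
cycles), cosine-shaped periodic expression with configurable amplitude and
phase, log-normal per-probe affinities, log-scale additive Gaussian noise and
a DNA-reference channel with three replicates.  Every feature's expression
law is recorded so downstream detection can be scored against known truth.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import write_gff3
from .probes import ProbeMatrix

CATEGORY_TYPES = {"ORF": "gene", "antisense": "antisense_RNA", "intergenic": "ncRNA"}
_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SimConfig:
    """Study-design parameters for the simulator.

    Defaults mirror the platform and sampling scheme being emulated: 8-nt
    strand-specific probe spacing, 25-nt probes, 5-minute sampling over
    200 min, a ~60-min cell cycle, and amplitude/noise ratio 4
    (amplitude 1.0 log2 units, noise SD 0.25).
    """

    chrom_lengths: dict = field(default_factory=lambda: {"chrI": 60_000})
    probe_spacing: int = 8
    probe_length: int = 25
    time_points: tuple = tuple(range(0, 201, 5))
    seed: int = 0
    n_orf: int = 20
    n_orf_periodic: int = 5
    n_antisense: int = 2
    n_antisense_periodic: int = 1
    n_intergenic: int = 2
    n_intergenic_periodic: int = 1
    period: float = 60.0
    baseline: float = 5.0
    baseline_jitter: float = 0.5
    amplitude: float = 1.0
    noise_sd: float = 0.25
    affinity_sd: float = 0.5
    damping: float = 1.0  # per-cycle amplitude retention; 1.0 = synchrony kept
    background_log2: float = 4.0
    ref_log2: float = 4.0
    n_ref_replicates: int = 3
    ref_noise_sd: float = 0.1
    orf_length: tuple = (1200, 2400)  # yeast-like: ~60% of the genome coding
    antisense_frac: tuple = (0.4, 0.8)
    intergenic_length: tuple = (150, 400)
    min_gap: int = 220

    def validate(self) -> None:
        if self.probe_spacing < 1:
            raise ValueError("probe spacing must be >= 1")
        if len(self.time_points) < 8:
            raise ValueError("at least 8 time points required")
        if self.n_orf_periodic > self.n_orf or self.n_antisense_periodic > self.n_antisense \
                or self.n_intergenic_periodic > self.n_intergenic:
            raise ValueError("periodic feature count exceeds category count")
        if self.n_antisense > self.n_orf:
            raise ValueError("each antisense transcript needs a distinct host ORF")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Planted genome, features, expression program and probe affinities."""

    genome: dict
    features: pd.DataFrame  # id, chrom, type, start, end, strand, category
    program: pd.DataFrame   # id, baseline, amplitude, period, phase, periodic
    noise_sd: float
    affinity: dict          # (chrom, strand) -> per-probe multiplicative factor

    def periodic_ids(self) -> list:
        return list(self.program.loc[self.program["periodic"], "id"])


def probe_starts(chrom_length: int, config: SimConfig) -> np.ndarray:
    """1-based start coordinates of probes tiling one strand of a chromosome."""
    last = chrom_length - config.probe_length + 1
    if last < 1:
        return np.array([], dtype=int)
    return np.arange(1, last + 1, config.probe_spacing, dtype=int)


def _allocate(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n items proportional to weights."""
    quota = n * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def _orf_sequence(length: int, rng: np.random.Generator) -> str:
    """ATG + stop-free codons + stop, giving ORFs a realistic reading frame."""
    n_codons = length // 3
    codons = ["ATG"]
    bases = "ACGT"
    while len(codons) < n_codons - 1:
        cod = "".join(rng.choice(list(bases), 3))
        if cod not in _STOPS:
            codons.append(cod)
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


def generate_genome_annotation(config: SimConfig):
    """Build a random genome with planted features.

    Returns ``(fasta_text, gff3_text, truth)``.  ORFs never overlap each
    other on either strand; each antisense transcript overlaps its host ORF
    on the opposite strand; intergenic transcripts overlap no ORF on either
    strand.  Fixing the seed makes the outputs byte-identical.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 1])
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    orf_per_chrom = _allocate(config.n_orf, lengths)
    ig_per_chrom = _allocate(config.n_intergenic, lengths)

    genome = {}
    rows = []
    gaps = {}          # chrom -> list of (gap_start, gap_end) 1-based inclusive
    used = {}          # (chrom, strand) -> list of (start, end)
    orf_index = []

    for ci, chrom in enumerate(chroms):
        L = int(config.chrom_lengths[chrom])
        seq = rng.choice(list("ACGT"), size=L)
        n_c = int(orf_per_chrom[ci])
        lens = 3 * (rng.integers(config.orf_length[0], config.orf_length[1] + 1, n_c) // 3)
        needed = int(lens.sum()) + (n_c + 1) * config.min_gap
        if needed > L:
            raise ValueError(
                f"chromosome {chrom!r} too short ({L} nt) for {n_c} ORFs "
                f"(needs >= {needed} nt)"
            )
        slack = L - needed
        extra = rng.multinomial(slack, np.full(n_c + 1, 1.0 / (n_c + 1))) if n_c >= 0 else []
        pos = 1
        gaps[chrom] = []
        used[(chrom, "+")] = []
        used[(chrom, "-")] = []
        prev_end = 0
        for gi in range(n_c):
            gap = config.min_gap + int(extra[gi])
            start = pos + gap
            end = start + int(lens[gi]) - 1
            strand = "+" if rng.random() < 0.5 else "-"
            gaps[chrom].append((prev_end + 1, start - 1))
            orf_id = f"gene{len(orf_index) + 1:04d}"
            orf_seq = _orf_sequence(int(lens[gi]), rng)
            if strand == "-":
                orf_seq = str(Seq(orf_seq).reverse_complement())
            seq[start - 1:end] = list(orf_seq)
            rows.append((orf_id, chrom, start, end, strand, "ORF"))
            used[(chrom, strand)].append((start, end))
            orf_index.append((orf_id, chrom, start, end, strand))
            prev_end = end
            pos = end
        gaps[chrom].append((prev_end + 1, L))
        genome[chrom] = "".join(seq)

    # antisense transcripts: one per distinct host ORF, opposite strand
    hosts = rng.choice(len(orf_index), size=config.n_antisense, replace=False)
    for ai, hi in enumerate(sorted(hosts)):
        orf_id, chrom, h_start, h_end, h_strand = orf_index[hi]
        strand = "-" if h_strand == "+" else "+"
        h_len = h_end - h_start + 1
        a_len = int(h_len * rng.uniform(*config.antisense_frac))
        style = rng.choice(["contained", "left", "right"], p=[0.6, 0.2, 0.2])
        max_ov = max(10, config.min_gap // 2 - 10)
        if style == "contained":
            start = h_start + int(rng.integers(0, h_len - a_len + 1))
        elif style == "left":
            start = h_start - int(rng.integers(10, max_ov))
        else:
            start = h_end - a_len + 1 + int(rng.integers(10, max_ov))
        end = start + a_len - 1
        start = max(1, start)
        end = min(config.chrom_lengths[chrom], end)
        rows.append((f"as{ai + 1:04d}", chrom, start, end, strand, "antisense"))
        used[(chrom, strand)].append((start, end))

    # intergenic transcripts: inside ORF-free gaps, clear of everything placed
    ig_n = 0
    for ci, chrom in enumerate(chroms):
        for _ in range(int(ig_per_chrom[ci])):
            ig_n += 1
            length = int(rng.integers(*config.intergenic_length))
            placed = False
            order = rng.permutation(len(gaps[chrom]))
            for gidx in order:
                g_start, g_end = gaps[chrom][gidx]
                lo, hi = g_start + 20, g_end - 20
                if hi - lo + 1 < length:
                    continue
                blockers = sorted(
                    (max(s, lo), min(e, hi))
                    for st in "+-"
                    for (s, e) in used[(chrom, st)]
                    if s <= hi and e >= lo
                )
                free, cur = [], lo
                for (bs, be) in blockers:
                    if bs > cur:
                        free.append((cur, bs - 1))
                    cur = max(cur, be + 1)
                if cur <= hi:
                    free.append((cur, hi))
                free = [(a, b) for (a, b) in free if b - a + 1 >= length]
                if not free:
                    continue
                a, b = free[int(rng.integers(len(free)))]
                start = a + int(rng.integers(0, b - a + 1 - length + 1))
                end = start + length - 1
                strand = "+" if rng.random() < 0.5 else "-"
                rows.append((f"ig{ig_n:04d}", chrom, start, end, strand, "intergenic"))
                used[(chrom, strand)].append((start, end))
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"chromosome {chrom!r} has no intergenic gap of {length} nt left"
                )

    features = pd.DataFrame(
        rows, columns=["id", "chrom", "start", "end", "strand", "category"]
    )
    features["type"] = features["category"].map(CATEGORY_TYPES)
    features = features.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)

    program = _expression_program(features, config, rng)
    affinity = {
        (chrom, strand): 2.0 ** rng.normal(
            0.0, config.affinity_sd, probe_starts(config.chrom_lengths[chrom], config).size
        )
        for chrom in chroms
        for strand in "+-"
    }
    truth = GroundTruth(
        genome=genome,
        features=features[["id", "chrom", "type", "start", "end", "strand", "category"]],
        program=program,
        noise_sd=config.noise_sd,
        affinity=affinity,
    )

    buf = io.StringIO()
    SeqIO.write(
        [SeqRecord(Seq(genome[c]), id=c, description="") for c in chroms], buf, "fasta"
    )
    gff = write_gff3(
        features.assign(type=features["category"].map(CATEGORY_TYPES)),
        None,
        chrom_sizes=config.chrom_lengths,
        source="tilecycle-sim",
    )
    return buf.getvalue(), gff, truth


def _expression_program(features: pd.DataFrame, config: SimConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    n_periodic = {
        "ORF": config.n_orf_periodic,
        "antisense": config.n_antisense_periodic,
        "intergenic": config.n_intergenic_periodic,
    }
    recs = []
    for cat, group in features.groupby("category", sort=True):
        ids = list(group["id"])
        k = n_periodic.get(cat, 0)
        periodic_ids = set(rng.choice(ids, size=k, replace=False)) if k else set()
        for fid in ids:
            periodic = fid in periodic_ids
            recs.append(
                {
                    "id": fid,
                    "baseline": config.baseline
                    + rng.uniform(-config.baseline_jitter, config.baseline_jitter),
                    "amplitude": config.amplitude if periodic else 0.0,
                    "period": config.period,
                    "phase": float(rng.uniform(0.0, 1.0)),
                    "periodic": periodic,
                }
            )
    program = pd.DataFrame(recs)
    order = {fid: i for i, fid in enumerate(features["id"])}
    return program.sort_values("id", key=lambda s: s.map(order)).reset_index(drop=True)


def expression_law(program_row, times: np.ndarray, damping: float = 1.0) -> np.ndarray:
    """x(t) = baseline + amplitude * damping^(t/T) * cos(2*pi*(t/T - phase))."""
    t = np.asarray(times, dtype=float)
    cyc = t / program_row["period"]
    amp = program_row["amplitude"] * damping ** cyc
    return program_row["baseline"] + amp * np.cos(2 * np.pi * (cyc - program_row["phase"]))


def generate_timecourse(
    truth: GroundTruth,
    config: SimConfig,
    stream: int = 0,
    times=None,
) -> ProbeMatrix:
    """Simulate raw probe intensities for one hybridization series.

    A probe belongs to a feature when its start coordinate falls inside the
    feature on the probe's strand.  Raw intensity is
    ``affinity_j * 2**(background + sum_f x_f(t_k) + eps)`` with
    ``eps ~ N(0, noise_sd)`` on the log2 scale; DNA-reference intensities are
    ``affinity_j * 2**(ref_level + eps_ref)`` with ``ref_noise_sd``.
    ``stream`` draws an independent noise realization (e.g. a second
    synchronization experiment) from the same seed and ground truth.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 2, int(stream)])
    t = np.asarray(config.time_points if times is None else times, dtype=float)
    if t.size < 8:
        raise ValueError("at least 8 time points required")
    K = t.size

    prog = truth.program.set_index("id")
    blocks = []
    for chrom in truth.genome:
        L = len(truth.genome[chrom])
        starts = probe_starts(L, config)
        for strand in "+-":
            x = np.full((starts.size, K), config.background_log2, dtype=float)
            feats = truth.features[
                (truth.features["chrom"] == chrom) & (truth.features["strand"] == strand)
            ]
            for row in feats.itertuples(index=False):
                lo = np.searchsorted(starts, row.start, side="left")
                hi = np.searchsorted(starts, row.end, side="right")
                if hi > lo:
                    x[lo:hi] += expression_law(prog.loc[row.id], t, config.damping)
            aff = truth.affinity[(chrom, strand)]
            noise = rng.normal(0.0, truth.noise_sd, size=x.shape)
            y = aff[:, None] * 2.0 ** (x + noise)
            ref_noise = rng.normal(
                0.0, config.ref_noise_sd, size=(starts.size, config.n_ref_replicates)
            )
            r = aff[:, None] * 2.0 ** (config.ref_log2 + ref_noise)
            meta = pd.DataFrame(
                {
                    "probe_id": [f"{chrom}_{strand}_{s}" for s in starts],
                    "chrom": chrom,
                    "strand": strand,
                    "start": starts,
                    "unique": True,
                }
            )
            blocks.append((meta, y, r))

    meta = pd.concat([b[0] for b in blocks], ignore_index=True)
    y = np.vstack([b[1] for b in blocks])
    r = np.vstack([b[2] for b in blocks])
    order = np.lexsort(
        (meta["start"].to_numpy(), meta["strand"].to_numpy(), meta["chrom"].to_numpy())
    )
    meta = meta.iloc[order].reset_index(drop=True)
    array_cols = [f"t{int(tt):03d}" for tt in t]
    ref_cols = [f"ref{m + 1}" for m in range(config.n_ref_replicates)]
    return ProbeMatrix(
        meta=meta,
        intensities=pd.DataFrame(y[order], columns=array_cols),
        reference=pd.DataFrame(r[order], columns=ref_cols),
        times=t,
        chrom_sizes={c: len(s) for c, s in truth.genome.items()},
    )


def write_ground_truth(truth: GroundTruth, path) -> None:
    table = truth.features.merge(truth.program, on="id")
    table.to_csv(path, sep="\t", index=False)


def match_planted(truth: GroundTruth, transcripts: pd.DataFrame) -> pd.DataFrame:
    """Match planted features to detected transcripts for recovery scoring.

    Annotated ORFs match by id (detected feature profiles carry annotation
    ids); planted antisense/intergenic features match the same-strand detected
    unannotated transcript with the largest overlap.  Returns the truth
    feature table with a ``matched_id`` column (NaN when undetected).
    """
    matched = []
    unann = transcripts[
        transcripts["category"].isin(["unannotated_antisense", "unannotated_intergenic"])
    ]
    for row in truth.features.itertuples(index=False):
        if row.category == "ORF":
            # annotated features are scored under their own annotation id
            matched.append(row.id)
            continue
        cand = unann[
            (unann["chrom"] == row.chrom) & (unann["strand"] == row.strand)
        ]
        if cand.empty:
            matched.append(None)
            continue
        ov = (
            np.minimum(cand["end"].to_numpy(), row.end)
            - np.maximum(cand["start"].to_numpy(), row.start)
            + 1
        )
        best = int(np.argmax(ov))
        matched.append(cand["id"].iloc[best] if ov[best] > 0 else None)
    out = truth.features.copy()
    out["matched_id"] = matched
    return out
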