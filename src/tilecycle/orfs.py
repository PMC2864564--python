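"""ORF-length coding-potential test for unannotated transcripts.

If an unannotated transcript encoded a protein, open reading frames inside
it would be longer than chance.  The test extracts all ORFs from each
transcript's own strand (the platform is strand-resolved), samples
length-matched background sequences from comparable genomic space --
opposite strands of protein-coding genes for antisense transcripts,
annotation-free intergenic space for intergenic transcripts -- and compares
the two ORF-length distributions with a two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.stats import ks_2samp

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class ORFLengthResult:
    transcript_class: str
    observed: np.ndarray
    background: np.ndarray
    ks_statistic: float
    p_value: float
    n_background_samples: int
    seed: int


def extract_orf_lengths(sequence: str) -> list:
    """ORF lengths (nt) on the given strand, all three frames.

    For every stop codon, the length runs from the most upstream in-frame ATG
    with no intervening stop through the stop codon inclusive, so lengths are
    multiples of 3.  Sequences shorter than 6 nt yield no ORFs.
    """
    seq = sequence.upper()
    lengths = []
    for frame in range(3):
        first_atg = -1
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if codon in _STOPS:
                if first_atg >= 0:
                    lengths.append(i + 3 - first_atg)
                first_atg = -1
            elif codon == "ATG" and first_atg < 0:
                first_atg = i
    return lengths


def _interval_sequence(genome: dict, chrom: str, start: int, end: int, strand: str) -> str:
    seq = genome[chrom][start - 1:end]
    return str(Seq(seq).reverse_complement()) if strand == "-" else seq


def transcript_orf_lengths(transcripts: pd.DataFrame, genome: dict) -> np.ndarray:
    """Pooled ORF lengths over a set of strand-resolved transcripts."""
    out = []
    for row in transcripts.itertuples(index=False):
        out.extend(
            extract_orf_lengths(
                _interval_sequence(genome, row.chrom, row.start, row.end, row.strand)
            )
        )
    return np.asarray(out, dtype=float)


def _intergenic_intervals(features: pd.DataFrame, chrom_sizes: dict, margin: int = 20):
    """Annotation-free intervals per chromosome (both strands clear)."""
    out = []
    for chrom, size in chrom_sizes.items():
        feats = features[features["chrom"] == chrom].sort_values("start")
        cur = 1
        for row in feats.itertuples(index=False):
            if row.start - margin > cur:
                out.append((chrom, cur, row.start - margin - 1))
            cur = max(cur, row.end + margin + 1)
        if cur <= size:
            out.append((chrom, cur, size))
    return out


def sample_background(
    transcript_class: str,
    lengths_to_match,
    genome: dict,
    features: pd.DataFrame,
    n_samples: int = 1000,
    seed: int = 0,
    coding_types=("gene",),
    return_intervals: bool = False,
):
    """ORF lengths from length-matched background sequence samples.

    antisense: intervals drawn uniformly from the strands opposite
    protein-coding genes; intergenic: intervals drawn from annotation-free
    space (random strand).  Interval lengths are drawn with replacement from
    ``lengths_to_match``.  Deterministic given the seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    lengths = np.asarray(lengths_to_match, dtype=int)
    if lengths.size == 0:
        raise ValueError("no transcript lengths to match")
    rng = np.random.default_rng([seed, 211])

    if transcript_class == "antisense":
        coding = features[features["type"].isin(set(coding_types))]
        pool = [
            (row.chrom, row.start, row.end, "-" if row.strand == "+" else "+")
            for row in coding.itertuples(index=False)
        ]
    elif transcript_class == "intergenic":
        chrom_sizes = {c: len(s) for c, s in genome.items()}
        pool = [
            (chrom, s, e, strand)
            for (chrom, s, e) in _intergenic_intervals(features, chrom_sizes)
            for strand in "+-"
        ]
    else:
        raise ValueError(f"unknown transcript class {transcript_class!r}")

    out = []
    intervals = []
    for _ in range(n_samples):
        L = int(lengths[rng.integers(lengths.size)])
        fits = [(c, s, e, st) for (c, s, e, st) in pool if e - s + 1 >= L]
        if not fits:
            raise ValueError(
                f"no eligible {transcript_class} background interval of >= {L} nt "
                f"(pool max {max((e - s + 1 for (_, s, e, _) in pool), default=0)} nt)"
            )
        slack = np.array([e - s + 1 - L + 1 for (_, s, e, _) in fits], dtype=float)
        j = int(rng.choice(len(fits), p=slack / slack.sum()))
        chrom, s, e, strand = fits[j]
        start = s + int(rng.integers(0, e - s + 1 - L + 1))
        intervals.append((chrom, start, start + L - 1, strand))
        out.extend(
            extract_orf_lengths(
                _interval_sequence(genome, chrom, start, start + L - 1, strand)
            )
        )
    result = np.asarray(out, dtype=float)
    if return_intervals:
        frame = pd.DataFrame(intervals, columns=["chrom", "start", "end", "strand"])
        return result, frame
    return result


def ks_compare(observed, background):
    """Two-sample KS test: D = max |ECDF1 - ECDF2|, asymptotic p-value."""
    obs = np.asarray(observed, dtype=float)
    bg = np.asarray(background, dtype=float)
    if obs.size == 0 or bg.size == 0:
        raise ValueError("both samples must be non-empty")
    res = ks_2samp(obs, bg, method="asymp")
    return float(res.statistic), float(res.pvalue)


def coding_potential_test(
    transcripts: pd.DataFrame,
    transcript_class: str,
    genome: dict,
    features: pd.DataFrame,
    n_samples: int = 1000,
    seed: int = 0,
) -> ORFLengthResult:
    """Full test for one transcript class; see module docstring."""
    observed = transcript_orf_lengths(transcripts, genome)
    span = (transcripts["end"] - transcripts["start"] + 1).to_numpy()
    background = sample_background(
        transcript_class, span, genome, features, n_samples=n_samples, seed=seed
    )
    if observed.size == 0 or background.size == 0:
        raise ValueError("no ORFs found in transcripts or background")
    d, p = ks_compare(observed, background)
    return ORFLengthResult(
        transcript_class=transcript_class,
        observed=observed,
        background=background,
        ks_statistic=d,
        p_value=p,
        n_background_samples=n_samples,
        seed=seed,
    )
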