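# Methods

This note documents the models, estimators and design choices behind
`tilecycle`, in the order the pipeline runs them, together with the
assumptions of the synthetic-data generator and the known limitations.

## Synthetic data generator

The generator emulates a strand-specific tiling-array cell-cycle time course
on a compact yeast-like genome. Its defaults are the study conditions the
package is designed for, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| probe spacing | 8 nt | strand-specific tiling resolution |
| probe length | 25 nt | typical oligo length for the platform |
| sampling | every 5 min, 0–200 min (alpha) / 0–215 min (cdc28) | two to three cycles |
| period `T` | 60 min | cell-cycle length used by the expression law |
| amplitude | 1.0 log2 units | periodic regulation strength |
| noise SD | 0.25 log2 units | additive log-scale noise, so amplitude/noise = 4 |
| affinity SD | 0.5 log2 units | per-probe log-normal response factor |
| ORF length | 1,200–2,400 nt | yeast-like: ~60% of the genome coding |
| DNA reference | 3 replicates, SD 0.1 | mirrors triplicate genomic-DNA hybridizations |

Expression of feature *f* follows a cosine law
`x_f(t) = baseline + amplitude · d^(t/T) · cos(2π(t/T − φ))` with phase
`φ ∈ [0,1)`; the damping factor `d` (default 1 = off) can emulate loss of
culture synchrony across cycles, which the real experiments show but do not
quantify. A probe belongs to a feature when its start coordinate lies inside
the feature on the probe's strand. Raw intensity is
`affinity_j · 2^(B0 + Σ_f x_f(t) + ε)` with `ε ~ N(0, noise_sd)`; the DNA
reference is `affinity_j · 2^(R0 + ε_ref)`. ORF sequences carry a real
reading frame (ATG, stop-free codons, stop) so that coding-potential analyses
see realistic sequence composition; antisense features are placed opposite
distinct host ORFs (contained, or overhanging one end), intergenic features
in annotation-free gaps. Same-strand features never overlap.

What the generator does **not** emulate: cross-hybridization, probe
saturation, mismatch probes, cell-cycle phase-specific transcription waves
beyond a single cosine harmonic, or correlated (heteroskedastic) noise.
Passing tests therefore demonstrate correctness of the estimators under the
stated generative model, not performance on raw scanner data.

The planted unannotated transcripts appear in the generated GFF3 (typed
`antisense_RNA` / `ncRNA`) so the ground truth is fully serialized, but the
pipeline's analysis stages deliberately use only the `gene` records as "the
annotation" — in the real experiment the antisense and intergenic RNAs were
unknown to the annotation, and that is the situation being modelled.

## Normalization

The DNA-reference normalization is defined as

    z_jk = log2(max(y_jk − b_k, ε)) − log2(median_m r_jm) + c_k

with `b_k` the 5th percentile of array *k* (additive optical background),
`ε = 1` raw unit as positivity floor, the per-probe median reference
intensity dividing out probe affinity, and `c_k` recentering each array's
median z at 0 (a global calibration constant is available behind a flag).
The cited normalization in the literature is a model-based fit whose formulas
are not restated in the source describing this pipeline; this explicit form
preserves its two roles — background correction and affinity calibration —
with reproducible arithmetic. z is exactly invariant to rescaling an array
when background subtraction is off; with subtraction, invariance holds for
all probes above the positivity floor. Only unique, perfect-match probes are
analyzed; multi-mapping probes are excluded via the probe table's `unique`
flag.

## Segmentation

The time-point-dependent piecewise-constant model is fitted per chromosome
strand by exact dynamic programming over segment costs computed in O(1) from
cumulative sums of z and z². `S = max(1, round(L / 1250 nt))` per chromosome.
The DP is O(S·n·W) with `W` a window equal to the maximum allowed segment
span (default 10× the target average length); the cap bounds runtime on long
chromosomes and is widened automatically if it cannot cover the strand with
S segments. Ties in RSS resolve to the smallest optimal predecessor during
backtracking (leftmost boundaries). Both synchronization datasets are fitted
jointly — shared boundaries, dataset-specific levels — matching the combined
fit of the original design; per-dataset fitting simply means running the
stage per dataset. Exactness is property-tested against exhaustive
enumeration (n ≤ 12, S ≤ 4, K ≤ 3) and the kernel is numba-compiled.

## Expression calling

Background segments are those with no same-strand overlap of an annotated
transcribed feature; overlap is strand-aware because the platform is
strand-specific — a segment opposite a gene measures (usually silent)
antisense abundance and belongs in the background population. The normal
background uses the shorth midpoint (robust to the expressed minority) and
the empirical variance of the lowest 99.9% of the background levels
(sample variance, ddof 1). The threshold is the smallest observed level
whose plug-in FDR — expected null exceedances over observed exceedances,
scanned at the observed levels — is ≤ 0.1%. Expressed means mean level
(across all arrays of both datasets) ≥ θ, boundary inclusive.

A practical consequence, reproduced by the simulator: because the 99.9%
trim removes almost nothing, expressed-but-unannotated segments inflate σ̂
roughly as `σ̂² ≈ σ0² + c·Δ²` (contamination fraction c at offset Δ), so the
procedure only resolves a 0.1% FDR when unannotated expressed transcripts
are a modest fraction (≲8%) of background segments — which matches real
transcriptome proportions and is how the benchmark genome is composed.

Categorization defaults (the referenced prior filter rules are not restated
in the source): annotated if same-strand overlap ≥ 50% of the segment;
unannotated antisense if opposite-strand overlap with a coding gene ≥ 50%;
unannotated intergenic if both strand overlaps < 20%; minimum length 80 nt;
everything else (or not expressed) unassigned. All configurable. Feature
profiles are overlap-length-weighted averages of same-strand expressed
segments, NaN-flagged (never zero-filled) when nothing overlaps.

## Periodicity

*Robust g-test.* Values are rank-transformed (making the statistic invariant
to monotone transforms and insensitive to outliers), centered, and the
periodogram ordinate nearest the cell-cycle frequency is divided by the
total spectral power. The null distribution is simulated by permutation,
which is exact and distribution-free (ranks of an i.i.d. continuous series
are a uniform random permutation) and cached per profile length; p-values
use the add-one correction with 9,999 null draws by default. This is a
rank-based variant in the spirit of the published robust g-test; exact
numerical agreement with that implementation is not claimed. The classical
Fisher-g null `p = Σ (−1)^(k−1) C(m,k)(1−kg)^(m−1)` is provided as an
analytic reference and is verified against 10⁶-draw Monte Carlo in the
tests.

*Permutation Fourier score.* Periodicity p-value `p_per` from within-profile
time shuffles of `F`; regulation p-value `p_reg` as the fraction of
population profiles with at least the profile's SD; combined score
`p_per · p_reg` (smaller = more periodic). The published method's exact
amplitude measure and score fusion are not restated in the source; SD and
the p-product are this package's declared choices, both configurable.

*Calibration and combination.* Cutoffs maximize benchmark recall minus
non-benchmark call rate (Youden-style) over the observed score ranking, ties
resolving to the stricter cutoff; the synthetic benchmark list is the set of
planted periodic genes (capped at 113, the size of the curated benchmark the
design mirrors). "Visual inspection" is represented as an optional curated
call list; combined calls require at least 2 of the 3 methods, or both
computational detectors when no curated list is given. Across datasets, a
transcript is cycling when one dataset makes the combined call and another
shows at least one detector call (with a single dataset the combined call
stands). Multiple-testing control is via the benchmark-calibrated cutoffs,
not p-value FDR.

*Peak time and period.* Peak time is `atan2(Σx sin ωt, Σx cos ωt)` mapped to
0–100% of the cycle (NaN when the profile has no power at the cycle
frequency); it is computed per dataset and reported per dataset. The period
is fitted per dataset by maximizing the amplitude-normalized Fourier score
of the benchmark profiles over a grid (default 45–80 min, 1-min step, ties
to the smallest period).

## Sense–antisense pairs

One SAP per antisense transcript and overlapped opposite-strand gene;
antisense transcripts overlapping two or more genes give a single
`spans_two` record (precedence over end-overlap typing) whose coupling uses
the most-overlapped gene. "Mainly contained" is operationalized as ≥ 90% of
the antisense length inside the sense interval; identical intervals count as
`contains` (logged tie rule). 5′/3′ labels are strand-aware ends of the
sense mRNA. The coupling–overlap association uses Pearson's χ² without
continuity correction on the 5×4 table restricted to non-empty rows/columns,
with a low-expected-count warning and an optional Monte Carlo p-value
(label permutation) for sparse tables. The circular peak-time difference
`Δ = min(|p1−p2|, 100−|p1−p2|)` is reported continuously (0 in-phase, 50
opposite-phase); no in-phase/anti-phase dichotomy is imposed.

## Coding potential

ORF length is the inclusive ATG-through-stop nucleotide count (a multiple
of 3), taking for each stop codon the most upstream in-frame ATG without an
intervening stop; only the transcript's own strand is scanned, since the
platform resolves strands. Background sequences are sampled (default 1,000
draws; the original count is unstated) with lengths drawn with replacement
from the observed transcript lengths: opposite strands of coding genes for
the antisense class, annotation-free space for the intergenic class —
positional matching standing in for explicit k-mer matching, with interval
choice weighted by available slack so sampling is uniform over eligible
positions. The two ORF-length distributions are compared by the asymptotic
two-sample KS test.

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds through
`numpy.random.default_rng` with stage-tagged seed sequences; identical
configuration reproduces byte-identical outputs, which the run manifest
(SHA-256 per output, parameter echo, wall-clock per stage) makes checkable.
Coordinates are 1-based inclusive in memory and in GFF3/TSV, 0-based
half-open only in BED/bedGraph exports. Degenerate inputs fail loudly:
constant arrays (undefined background), zero-variance background levels,
all-flat benchmark profiles, annotations without strands, empty KS samples.
Constant expression profiles get p = 1 (g-test, permutation test) and an
undefined peak time rather than an arbitrary phase.

## Benchmark sizing

The planted-truth recovery benchmark runs 500 transcripts — 470 genes, 20
antisense, 10 intergenic; 45 + 10 + 5 = 60 periodic — at amplitude/noise 4
on an eight-chromosome, ~450-kb genome with 450–750-nt ORFs at yeast-like
density, one synchronization dataset, and the segmentation target length
(700 nt) matched to the scaled gene spacing. These sizes keep a complete
run desk-sized while preserving the proportions that matter to the
estimators (coding fraction, unannotated-to-background ratio, probes per
transcript ≈ 75). On this benchmark the pipeline recovers ≥ 90% of planted
periodic transcripts with no false periodic calls; the suite asserts
exactly this.

## Known limitations

- The rank-periodogram g-test and the SD/p-product Fourier scoring are
  declared variants of the cited methods, not ports; published scores will
  differ numerically even on identical data.
- The plug-in FDR threshold degrades (θ → ∞) when unannotated expressed
  transcripts dominate the background pool; the estimator reports this as an
  infinite threshold rather than guessing.
- The DP window cap trades the exactness guarantee for runtime when a true
  segment would exceed the cap; the default (10× the target length) makes
  this practically irrelevant but it is not impossible.
- Periodicity calls assume evenly spaced, complete time courses; missing
  arrays are not imputed.
- The χ² association test is asymptotic; with the handful of SAPs a small
  simulation yields, the pipeline reports the expected-count warning or
  declines the test instead of quoting an unreliable p-value.
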