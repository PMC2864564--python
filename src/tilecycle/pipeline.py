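"""End-to-end pipeline: simulate -> normalize -> segment -> call -> periodicity
-> SAP -> ORF test, with a reproducibility manifest.

The pipeline is deterministic given its configuration: every stochastic step
draws from a generator derived from the single run seed, and the manifest
records parameter echoes plus SHA-256 checksums of every output table so a
re-run can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .express import (
    background_segment_levels,
    call_expressed,
    categorize_segments,
    category_summary,
    estimate_background_threshold,
    feature_expression,
)
from .orfs import coding_potential_test
from .periodic import (
    calibrate_cutoff,
    merge_dataset_calls,
    optimize_period,
    score_profiles,
)
from .probes import NormalizedMatrix, normalize
from .sap import build_saps, classify_saps, coupling_overlap_association
from .segment import SegmentationConfig, fit_segments, segments_to_bed
from .simulate import (
    GroundTruth,
    SimConfig,
    generate_genome_annotation,
    generate_timecourse,
    write_ground_truth,
)

log = logging.getLogger(__name__)

META_PROFILE_COLS = ("id", "chrom", "strand", "start", "end", "defined", "category")


@dataclass
class RunConfig:
    """Everything a full synthetic run needs; YAML-serializable."""

    sim: SimConfig = field(default_factory=SimConfig)
    datasets: tuple = ("cdc28", "alpha")
    dataset_minutes: dict = field(default_factory=lambda: {"cdc28": 215, "alpha": 200})
    avg_length_nt: float = 1250.0
    max_segment_nt: float | None = None
    target_fdr: float = 0.001
    period_grid: tuple = (45.0, 80.0, 1.0)  # (min, max, step) in minutes
    n_null: int = 9999
    n_perm: int = 200
    benchmark_size: int = 113
    manual_calls: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed != self.sim.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def dataset_times(self, name: str) -> np.ndarray:
        last = self.dataset_minutes.get(name, 200)
        return np.arange(0, last + 1, 5, dtype=float)

    def grid(self) -> np.ndarray:
        lo, hi, step = self.period_grid
        return np.arange(lo, hi + step / 2, step)


def standard_benchmark_config(seed: int = 1) -> RunConfig:
    """The package's standard planted-truth recovery benchmark.

    500 transcripts (470 ORFs, 20 antisense, 10 intergenic; 45 + 10 + 5 = 60
    periodic) at amplitude/noise ratio 4, in the proportions of a real yeast
    transcriptome but on a scaled-down eight-chromosome genome (~450 kb, ORFs
    450-750 nt) so a full run stays desk-sized.  One synchronization dataset
    (cdc28 timing, 5-min sampling over 215 min); the segmentation target
    length is matched to the scaled gene density.
    """
    sim = SimConfig(
        chrom_lengths={f"chr{i + 1:02d}": 56_000 for i in range(8)},
        n_orf=470,
        n_orf_periodic=45,
        n_antisense=20,
        n_antisense_periodic=10,
        n_intergenic=10,
        n_intergenic_periodic=5,
        orf_length=(450, 750),
        intergenic_length=(120, 250),
        min_gap=300,
        seed=seed,
    )
    return RunConfig(
        sim=sim,
        datasets=("cdc28",),
        avg_length_nt=700.0,
        max_segment_nt=2500.0,
        seed=seed,
    )


def recovery_rates(truth: GroundTruth, transcripts: pd.DataFrame, final_calls) -> dict:
    """Sensitivity / false-call rate of periodicity detection vs planted truth."""
    from .simulate import match_planted

    matched = match_planted(truth, transcripts)
    merged = matched.merge(truth.program[["id", "periodic"]], on="id")
    called = set(final_calls[final_calls].index)
    hit = merged["matched_id"].map(lambda m: m in called if m else False)
    n_per = int(merged["periodic"].sum())
    n_non = int((~merged["periodic"]).sum())
    return {
        "sensitivity": float(hit[merged["periodic"]].sum() / n_per),
        "false_call_rate": float(hit[~merged["periodic"]].sum() / n_non),
        "n_periodic": n_per,
        "n_nonperiodic": n_non,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def export_heatmap_tables(profiles: pd.DataFrame, peak_time_by_id: dict) -> pd.DataFrame:
    """Min-max scale each profile row and order rows by peak time.

    Rows without a peak time sort last and are flagged; constant rows are
    emitted as all 0.5 with the flag set.
    """
    value_cols = [c for c in profiles.columns if c not in META_PROFILE_COLS]
    out = profiles.copy()
    out["peak_time"] = [peak_time_by_id.get(i, np.nan) for i in out["id"]]
    out["flagged"] = ~np.isfinite(out["peak_time"])
    x = out[value_cols].to_numpy(dtype=float)
    lo = np.nanmin(x, axis=1, keepdims=True)
    hi = np.nanmax(x, axis=1, keepdims=True)
    span = hi - lo
    flat = (span == 0).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (x - lo) / span
    scaled[flat] = 0.5
    out.loc[flat, "flagged"] = True
    out[value_cols] = scaled
    out = out.sort_values(["peak_time", "id"], kind="mergesort", na_position="last")
    return out[["id", "peak_time", "flagged"] + value_cols].reset_index(drop=True)


def _joint_normalized(per_dataset: dict) -> NormalizedMatrix:
    """Column-concatenate per-dataset z matrices over identical probe frames."""
    names = list(per_dataset)
    first = per_dataset[names[0]]
    z_parts, times = [], []
    for ds in names:
        nm = per_dataset[ds]
        if not nm.meta[["chrom", "strand", "start"]].equals(
            first.meta[["chrom", "strand", "start"]]
        ):
            raise ValueError("datasets tile different probe sets; cannot fit jointly")
        z = nm.z.copy()
        z.columns = [f"{ds}.{c}" for c in z.columns]
        z_parts.append(z)
        times.append(nm.times)
    return NormalizedMatrix(
        meta=first.meta.copy(),
        z=pd.concat(z_parts, axis=1),
        times=np.concatenate(times),
        chrom_sizes=dict(first.chrom_sizes),
    )


def _dataset_cols(columns, ds: str) -> list:
    return [c for c in columns if c.startswith(f"level_{ds}.")]


def _profile_table(frame: pd.DataFrame, cols: list) -> pd.DataFrame:
    keep = [c for c in frame.columns if c in META_PROFILE_COLS]
    return frame[keep + cols]


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage and write all deliverable tables plus a manifest.

    Returns a dict of in-memory results keyed by stage.  On stage failure the
    manifest records the failed stage and partial outputs before the error is
    re-raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "stages": {},
    }
    results: dict = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                outputs = fn() or []
                manifest["stages"][name] = {
                    "status": "ok",
                    "seconds": round(time.perf_counter() - t0, 3),
                    "outputs": {p.name: _sha256(p) for p in outputs},
                }
            except Exception as exc:
                manifest["stages"][name] = {
                    "status": "failed",
                    "seconds": round(time.perf_counter() - t0, 3),
                    "error": f"{type(exc).__name__}: {exc}",
                }
                (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
                raise
            return None
        return deco

    @stage("simulate")
    def _simulate():
        fasta, gff, truth = generate_genome_annotation(config.sim)
        results["truth"] = truth
        (outdir / "genome.fasta").write_text(fasta)
        (outdir / "annotation.gff3").write_text(gff)
        write_ground_truth(truth, outdir / "truth.tsv")
        outputs = [outdir / "genome.fasta", outdir / "annotation.gff3", outdir / "truth.tsv"]
        results["probes"] = {}
        for i, ds in enumerate(config.datasets):
            pm = generate_timecourse(
                truth, config.sim, stream=i, times=config.dataset_times(ds)
            )
            results["probes"][ds] = pm
            pm.to_tsv(outdir / f"probes_{ds}.tsv")
            outputs.append(outdir / f"probes_{ds}.tsv")
        # benchmark: planted periodic ORFs standing in for known cycling genes
        per = truth.features.merge(truth.program, on="id")
        bench = per.loc[(per["category"] == "ORF") & per["periodic"], "id"]
        results["benchmark"] = list(bench.iloc[: config.benchmark_size])
        (outdir / "benchmark.txt").write_text("\n".join(results["benchmark"]) + "\n")
        outputs.append(outdir / "benchmark.txt")
        return outputs

    @stage("normalize")
    def _normalize():
        results["normalized"] = {
            ds: normalize(pm) for ds, pm in results["probes"].items()
        }
        outputs = []
        for ds, nm in results["normalized"].items():
            nm.to_tsv(outdir / f"normalized_{ds}.tsv")
            outputs.append(outdir / f"normalized_{ds}.tsv")
        return outputs

    @stage("segment")
    def _segment():
        joint = _joint_normalized(results["normalized"])
        results["joint"] = joint
        segs = fit_segments(
            joint,
            SegmentationConfig(
                avg_length_nt=config.avg_length_nt,
                max_segment_nt=config.max_segment_nt,
            ),
        )
        results["segments"] = segs
        segs.to_csv(outdir / "segments.tsv", sep="\t", index=False)
        segments_to_bed(segs, outdir / "segments.bed")
        return [outdir / "segments.tsv", outdir / "segments.bed"]

    @stage("call")
    def _call():
        truth: GroundTruth = results["truth"]
        genes = truth.features[truth.features["category"] == "ORF"]
        segs = results["segments"]
        bg = background_segment_levels(segs, genes)
        fit = estimate_background_threshold(
            bg, target_fdr=config.target_fdr,
            all_levels=segs["mean_level"].to_numpy(),
        )
        expressed = call_expressed(segs, fit)
        transcripts = categorize_segments(segs, genes, expressed)
        level_cols = [c for c in segs.columns if c.startswith("level_")]
        transcripts = transcripts.merge(
            segs[["segment_id"] + level_cols].rename(columns={"segment_id": "id"}),
            on="id",
        )
        results["background_fit"] = fit
        results["transcripts"] = transcripts
        transcripts.to_csv(outdir / "transcripts.tsv", sep="\t", index=False)
        category_summary(transcripts).to_csv(
            outdir / "category_summary.tsv", sep="\t", index=False
        )
        profiles = feature_expression(segs, genes, expressed)
        results["gene_profiles"] = profiles
        profiles.to_csv(outdir / "feature_profiles.tsv", sep="\t", index=False)
        return [
            outdir / "transcripts.tsv",
            outdir / "category_summary.tsv",
            outdir / "feature_profiles.tsv",
        ]

    @stage("periodicity")
    def _periodicity():
        transcripts = results["transcripts"]
        genes = results["gene_profiles"]
        unann = transcripts[
            transcripts["category"].isin(
                ["unannotated_antisense", "unannotated_intergenic"]
            )
        ]
        manual = set(config.manual_calls)
        bench_all = results["benchmark"]
        scores_by_ds, combined_by_ds, support_by_ds = {}, {}, {}
        peak_by_ds = {}
        outputs = []
        for ds in config.datasets:
            cols = _dataset_cols(genes.columns, ds)
            prof = pd.concat(
                [_profile_table(genes, cols), _profile_table(unann, cols)],
                ignore_index=True,
            )
            times = config.dataset_times(ds)
            bench_prof = prof[prof["id"].isin(bench_all) & prof[cols].notna().all(axis=1)]
            period = optimize_period(
                bench_prof[cols].to_numpy(dtype=float), times, config.grid()
            )
            sc = score_profiles(
                prof, times, period=period,
                n_null=config.n_null, n_perm=config.n_perm, seed=config.seed,
            )
            bench = [b for b in bench_all if b in set(sc["id"])]
            if not bench:
                raise ValueError("no benchmark transcript was scored")
            cut_g = calibrate_cutoff(sc.set_index("id")["p_g"], bench)
            cut_dl = calibrate_cutoff(sc.set_index("id")["dl_score"], bench)
            sc["call_g"] = sc["p_g"] <= cut_g
            sc["call_dl"] = sc["dl_score"] <= cut_dl
            sc["call_manual"] = sc["id"].isin(manual) if manual else False
            two_of_three = (
                sc["call_g"].astype(int) + sc["call_dl"].astype(int)
                + sc["call_manual"].astype(int)
            ) >= 2 if manual else (sc["call_g"] & sc["call_dl"])
            sc["combined_call"] = two_of_three
            sc["cutoff_g"] = cut_g
            sc["cutoff_dl"] = cut_dl
            scores_by_ds[ds] = sc
            combined_by_ds[ds] = sc.set_index("id")["combined_call"]
            support_by_ds[ds] = sc.set_index("id").eval("call_g or call_dl")
            peak_by_ds[ds] = sc.set_index("id")["peak_time"]
            sc.to_csv(outdir / f"periodicity_{ds}.tsv", sep="\t", index=False)
            outputs.append(outdir / f"periodicity_{ds}.tsv")
            log.info("dataset %s: period %.1f min, cutoffs g<=%.4g dl<=%.4g",
                     ds, period, cut_g, cut_dl)
        final = merge_dataset_calls(combined_by_ds, support_by_ds)
        results["scores"] = scores_by_ds
        results["final_calls"] = final
        results["peak_times"] = peak_by_ds
        final.rename("cycling").rename_axis("id").reset_index().to_csv(
            outdir / "final_calls.tsv", sep="\t", index=False
        )
        outputs.append(outdir / "final_calls.tsv")

        ds0 = config.datasets[0]
        cols = _dataset_cols(genes.columns, ds0)
        prof0 = pd.concat(
            [_profile_table(genes, cols), _profile_table(unann, cols)],
            ignore_index=True,
        )
        cycling = prof0[prof0["id"].isin(final[final].index)]
        heat = export_heatmap_tables(cycling, peak_by_ds[ds0].to_dict())
        heat.to_csv(outdir / "heatmap.tsv", sep="\t", index=False)
        outputs.append(outdir / "heatmap.tsv")
        return outputs

    @stage("sap")
    def _sap():
        truth: GroundTruth = results["truth"]
        genes = truth.features[truth.features["category"] == "ORF"]
        transcripts = results["transcripts"]
        antisense = transcripts[transcripts["category"] == "unannotated_antisense"]
        final = results["final_calls"]
        periodic_ids = set(final[final].index)
        saps = build_saps(antisense, genes)
        ds0 = config.datasets[0]
        saps = classify_saps(
            saps,
            periodic_antisense_ids=periodic_ids,
            periodic_sense_ids=periodic_ids,
            peak_times=results["peak_times"][ds0].to_dict(),
        )
        results["saps"] = saps
        saps.to_csv(outdir / "saps.tsv", sep="\t", index=False)
        outputs = [outdir / "saps.tsv"]
        summary: dict = {"n_saps": int(len(saps))}
        if len(saps):
            try:
                table, chi2, dfree, p, warn = coupling_overlap_association(saps)
                table.to_csv(outdir / "coupling_overlap_table.tsv", sep="\t")
                outputs.append(outdir / "coupling_overlap_table.tsv")
                summary.update(
                    chi2=chi2, df=dfree, p_value=p, low_expected_counts=warn
                )
            except ValueError as exc:  # too few pairs for a meaningful test
                summary["association_note"] = str(exc)
        results["sap_summary"] = summary
        (outdir / "sap_summary.json").write_text(json.dumps(summary, indent=2))
        outputs.append(outdir / "sap_summary.json")
        return outputs

    @stage("orf_test")
    def _orf_test():
        truth: GroundTruth = results["truth"]
        genes = truth.features[truth.features["category"] == "ORF"]
        transcripts = results["transcripts"]
        summary = {}
        for cls, cat in [
            ("antisense", "unannotated_antisense"),
            ("intergenic", "unannotated_intergenic"),
        ]:
            sub = transcripts[transcripts["category"] == cat]
            if sub.empty:
                summary[cls] = {"note": "no transcripts detected in this class"}
                continue
            res = coding_potential_test(
                sub, cls, truth.genome, genes,
                n_samples=min(1000, 50 * len(sub)), seed=config.seed,
            )
            summary[cls] = {
                "n_transcripts": int(len(sub)),
                "n_observed_orfs": int(res.observed.size),
                "n_background_orfs": int(res.background.size),
                "ks_statistic": res.ks_statistic,
                "p_value": res.p_value,
            }
        results["orf_test"] = summary
        (outdir / "orf_test.json").write_text(json.dumps(summary, indent=2))
        return [outdir / "orf_test.json"]

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
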