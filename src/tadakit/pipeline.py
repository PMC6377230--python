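"""End-to-end pipeline: simulate -> profile -> peaks -> differential ->
interval statistics -> metaprofiles, with a JSON run manifest.

The default run reproduces the full analysis graph on a synthetic
experiment where open chromatin gates transcription-factor binding by
construction, then scores how well the pipeline recovers that truth.
Stage seeds are derived as hash(global_seed, stage_name, ...) so adding a
stage never perturbs earlier stages' draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .differential import (
    DifferentialResult,
    InvalidDesignError,
    build_consensus,
    count_affinity,
    test_differential,
)
from .gatc import (
    AlignedReadSet,
    FragmentCounts,
    count_fragments,
    coverage_track,
    extend_reads,
    normalize_decile_track,
)
from .intervals import closest_fisher, mc_overlap, mc_signal_ratio, overlap
from .metaprofile import mean_profile, pairwise_pearson, reference_point_matrix
from .peaks import PeakCallConfig, PeakSet, call_peaks_accessibility, call_peaks_ratio
from .synthetic import (
    LINEAGES,
    SimConfig,
    SimulatedExperiment,
    _derive_seed,
    simulate_experiment,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "verify_outputs"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run; defaults are the study conditions."""

    sim: SimConfig = field(default_factory=SimConfig)
    pseudocount: float = 0.5
    extension: int = 300
    peak_q: float = 0.05
    merge_gap: int = 1
    min_fragments: int = 2
    local_lambda_windows: tuple[int, ...] = (5000, 10000)
    consensus_min_samples: int = 2
    fdr_max: float = 0.01
    min_fold: float = 2.0
    mc_overlap_iters: int = 100
    mc_signal_iters: int = 1000
    signal_half_width: int = 2000
    closest_distance: int = 2000
    profile_half_width: int = 5000
    profile_bin: int = 50
    correlation_bin: int = 1000
    seed: int = 0
    write_reads: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        self.local_lambda_windows = tuple(self.local_lambda_windows)
        # the global seed drives the simulation too
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["local_lambda_windows"] = list(self.local_lambda_windows)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def peak_config(self) -> PeakCallConfig:
        return PeakCallConfig(
            q_threshold=self.peak_q,
            merge_gap=self.merge_gap,
            min_fragments=self.min_fragments,
            local_lambda_windows=self.local_lambda_windows,
        )


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sha256_arrays(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        a = np.asarray(a)
        h.update(str(a.dtype).encode())
        h.update(np.ascontiguousarray(a).tobytes() if a.dtype != object
                 else "\x00".join(map(str, a.ravel())).encode())
    return h.hexdigest()


def _truth_peakset(experiment: SimulatedExperiment, label: str) -> PeakSet:
    sub = experiment.truth.intervals(label)
    return PeakSet(
        name=f"truth_{label}",
        chrom=sub["chrom"].to_numpy(dtype=object),
        start=sub["start"].to_numpy(),
        end=sub["end"].to_numpy(),
    )


def _recovery(predicted: PeakSet, truth: PeakSet) -> dict:
    """Recall/precision of predicted peaks against truth intervals (>=1 bp)."""
    if len(predicted) == 0 or len(truth) == 0:
        return {
            "recall": 0.0, "precision": 0.0,
            "n_predicted": len(predicted), "n_truth": len(truth),
        }
    res = overlap(truth, predicted)
    return {
        "recall": res.frac_a,          # truth intervals hit by a prediction
        "precision": res.frac_b,       # predictions hitting a truth interval
        "n_predicted": len(predicted),
        "n_truth": len(truth),
    }


def _stage(name: str):
    """Decorator-free stage guard: wrap the callable, re-raise with context."""

    class _Guard:
        def __init__(self, stage_name: str):
            self.stage_name = stage_name

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {self.stage_name!r} failed: {exc}") from exc
            return False

    return _Guard(name)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full analysis graph; return the run manifest (also
    written to ``outdir``/manifest.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": {},
        "data_hashes": {},
        "files": {},
    }

    with _stage("simulate"):
        experiment = simulate_experiment(config.sim)
        fragments = experiment.fragments
        chrom_lengths = {
            c: int(fragments.boundaries[c][-1]) for c in fragments.chrom_names
        }
        tio.write_fasta(experiment.genome, outdir / "genome.fa")
        experiment.truth.domains.to_csv(
            outdir / "truth_domains.tsv", sep="\t", index=False
        )
        truth_bed = experiment.truth.domains[["chrom", "start", "end", "label"]]
        truth_bed.to_csv(outdir / "truth_domains.bed", sep="\t",
                         index=False, header=False)
        if config.write_reads:
            for key, reads in experiment.reads.items():
                lineage, channel, rep = key
                tio.reads_to_bed(
                    reads, outdir / f"reads_{lineage}_{channel}_rep{rep}.bed"
                )
        manifest["stages"]["simulate"] = {
            "n_fragments": int(fragments.n_fragments),
            "n_reads": {f"{k[0]}_{k[1]}_rep{k[2]}": len(v)
                        for k, v in experiment.reads.items()},
        }
        for key, reads in experiment.reads.items():
            manifest["data_hashes"][f"reads_{key[0]}_{key[1]}_rep{key[2]}"] = (
                _sha256_arrays(reads.chrom, reads.start, reads.end, reads.strand)
            )

    with _stage("profile"):
        counts: dict[tuple[str, str, int], FragmentCounts] = {}
        extended: dict[tuple[str, str, int], AlignedReadSet] = {}
        gatc_map = None
        from .gatc import scan_gatc

        gatc_map = scan_gatc(experiment.genome)
        for key, reads in experiment.reads.items():
            ext = extend_reads(reads, gatc_map, config.extension)
            extended[key] = ext
            counts[key] = count_fragments(ext, fragments, channel=key[1])

        pooled: dict[tuple[str, str], FragmentCounts] = {}
        ratio_tracks = {}
        access_tracks = {}
        for lineage in LINEAGES:
            for channel in ("dam_only", "dam_fusion"):
                reps = [counts[(lineage, channel, r)]
                        for r in range(1, config.sim.n_replicates + 1)]
                pooled[(lineage, channel)] = FragmentCounts(
                    counts=np.sum([c.counts for c in reps], axis=0),
                    library_size=sum(c.library_size for c in reps),
                    label=f"{lineage}_{channel}_pooled",
                    channel=channel,
                )
            track = normalize_decile_track(
                pooled[(lineage, "dam_fusion")], pooled[(lineage, "dam_only")],
                fragments, config.pseudocount,
            )
            ratio_tracks[lineage] = track
            tio.write_ratio_bedgraph(track, outdir / f"ratio_{lineage}.bedgraph")
            acc = coverage_track(pooled[(lineage, "dam_only")], fragments)
            access_tracks[lineage] = acc
            tio.write_ratio_bedgraph(acc, outdir / f"accessibility_{lineage}.bedgraph")
        manifest["stages"]["profile"] = {
            f"norm_factor_{lin}": float(ratio_tracks[lin].factor)
            for lin in LINEAGES
        }

    with _stage("callpeaks"):
        pcfg = config.peak_config()
        tada_peaks: dict[str, list[PeakSet]] = {lin: [] for lin in LINEAGES}
        catada_peaks: dict[str, list[PeakSet]] = {lin: [] for lin in LINEAGES}
        for lineage in LINEAGES:
            dam_pooled = pooled[(lineage, "dam_only")]
            for rep in range(1, config.sim.n_replicates + 1):
                ps = call_peaks_ratio(
                    counts[(lineage, "dam_fusion", rep)], dam_pooled,
                    fragments, pcfg, name=f"tada_{lineage}_rep{rep}",
                )
                tada_peaks[lineage].append(ps)
                tio.write_narrowpeak(ps, outdir / f"tada_{lineage}_rep{rep}.narrowPeak")
                cs = call_peaks_accessibility(
                    counts[(lineage, "dam_only", rep)], fragments, pcfg,
                    name=f"catada_{lineage}_rep{rep}",
                )
                catada_peaks[lineage].append(cs)
                tio.write_narrowpeak(cs, outdir / f"catada_{lineage}_rep{rep}.narrowPeak")
        manifest["stages"]["callpeaks"] = {
            "n_tada": {lin: [len(p) for p in tada_peaks[lin]] for lin in LINEAGES},
            "n_catada": {lin: [len(p) for p in catada_peaks[lin]] for lin in LINEAGES},
        }

    with _stage("differential"):
        if config.sim.n_replicates < 2:
            raise InvalidDesignError(
                "differential testing needs >= 2 replicates per lineage"
            )
        results: dict[str, DifferentialResult] = {}
        for assay, peaksets, channel in (
            ("binding", tada_peaks, "dam_fusion"),
            ("accessibility", catada_peaks, "dam_only"),
        ):
            all_sets = peaksets["A"] + peaksets["B"]
            consensus = build_consensus(all_sets, config.consensus_min_samples)
            if len(consensus) == 0:
                raise PipelineError(
                    f"stage 'differential' failed: no consensus peaks ({assay})"
                )
            read_sets = [extended[("A", channel, r)]
                         for r in range(1, config.sim.n_replicates + 1)]
            read_sets += [extended[("B", channel, r)]
                          for r in range(1, config.sim.n_replicates + 1)]
            groups = (["A"] * config.sim.n_replicates
                      + ["B"] * config.sim.n_replicates)
            mat = count_affinity(consensus, read_sets, groups)
            res = test_differential(
                mat, "A", "B", fdr_max=config.fdr_max, min_fold=config.min_fold
            )
            results[assay] = res
            res.table.to_csv(outdir / f"differential_{assay}.tsv",
                             sep="\t", index=False)
            for cls, lin in (("enriched_A", "A"), ("enriched_B", "B")):
                ps = res.class_peaks(cls, name=f"{assay}_{cls}")
                df = pd.DataFrame({
                    "chrom": ps.chrom.astype(str),
                    "start": ps.start, "end": ps.end,
                })
                df.to_csv(outdir / f"{assay}_{cls}.bed", sep="\t",
                          index=False, header=False)
        manifest["stages"]["differential"] = {
            assay: {
                "n_consensus": int(len(res.table)),
                "n_enriched_A": int((res.table["class"] == "enriched_A").sum()),
                "n_enriched_B": int((res.table["class"] == "enriched_B").sum()),
                "dispersion": float(res.dispersion),
            }
            for assay, res in results.items()
        }

    with _stage("recovery"):
        recovery = {}
        for assay, truth_label_a, truth_label_b in (
            ("binding", "bound_A", "bound_B"),
            ("accessibility", "open_A", "open_B"),
        ):
            res = results[assay]
            for cls, label in (("enriched_A", truth_label_a),
                               ("enriched_B", truth_label_b)):
                pred = res.class_peaks(cls)
                truth = _truth_peakset(experiment, label)
                recovery[f"{assay}_{cls}"] = _recovery(pred, truth)
        manifest["stages"]["recovery"] = recovery

    with _stage("overlap_test"):
        mc = {}
        for lineage in LINEAGES:
            bind = results["binding"].class_peaks(f"enriched_{lineage}")
            acc = results["accessibility"].class_peaks(f"enriched_{lineage}")
            if len(bind) == 0 or len(acc) == 0:
                raise PipelineError(
                    f"stage 'overlap_test' failed: empty differential set "
                    f"for lineage {lineage}"
                )
            ov = overlap(bind, acc)
            res = mc_overlap(
                bind, acc, chrom_lengths,
                n_iter=config.mc_overlap_iters,
                seed=_derive_seed(config.seed, "mc_overlap", lineage),
            )
            payload = res.to_dict()
            payload["observed_fraction"] = ov.frac_a
            payload["n_binding_peaks"] = ov.n_a
            payload["n_accessibility_peaks"] = ov.n_b
            mc[lineage] = payload
            with open(outdir / f"mc_overlap_{lineage}.json", "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
        manifest["stages"]["overlap_test"] = mc

    with _stage("signal_test"):
        bind_a = results["binding"].class_peaks("enriched_A")
        bind_b = results["binding"].class_peaks("enriched_B")
        sig = access_tracks["A"]
        res = mc_signal_ratio(
            sig, bind_a, bind_b,
            n_iter=config.mc_signal_iters,
            seed=_derive_seed(config.seed, "mc_signal"),
            half_width=config.signal_half_width,
        )
        with open(outdir / "signal_ratio.json", "w") as fh:
            json.dump(res.to_dict(), fh, indent=2, sort_keys=True)
        manifest["stages"]["signal_test"] = res.to_dict()

    with _stage("closest_test"):
        acc_a = results["accessibility"].class_peaks("enriched_A")
        cres = closest_fisher(
            bind_a, bind_b, acc_a, distance=config.closest_distance
        )
        payload = {
            "within_a": cres.within_a, "within_b": cres.within_b,
            "n_a": cres.n_a, "n_b": cres.n_b,
            "distance": cres.distance, "fisher_p": cres.fisher_p,
            "table": [list(row) for row in cres.table],
        }
        with open(outdir / "closest_fisher.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        manifest["stages"]["closest_test"] = payload

    with _stage("metaprofile"):
        profiles = {}
        for lineage, regions in (("A", bind_a), ("B", bind_b)):
            mat = reference_point_matrix(
                access_tracks["A"], regions,
                config.profile_half_width, config.profile_bin,
            )
            prof = mean_profile(mat)
            df = pd.DataFrame({"offset": mat.bin_offsets, "mean_signal": prof})
            df.to_csv(outdir / f"profile_accessibilityA_at_bind{lineage}.tsv",
                      sep="\t", index=False)
            center = prof[mat.n_bins // 2 - 1: mat.n_bins // 2 + 1]
            edge = np.nanmean(np.concatenate([prof[:10], prof[-10:]]))
            profiles[lineage] = {
                "center_mean": float(np.nanmean(center)),
                "edge_mean": float(edge),
            }
        manifest["stages"]["metaprofile"] = profiles

    with _stage("correlate"):
        fusion_sets = [experiment.reads[(lin, "dam_fusion", r)]
                       for lin in LINEAGES
                       for r in range(1, config.sim.n_replicates + 1)]
        corr = pairwise_pearson(fusion_sets, chrom_lengths, config.correlation_bin)
        pd.DataFrame(
            corr.r, index=corr.sample_names, columns=corr.sample_names
        ).to_csv(outdir / "correlation.tsv", sep="\t")
        n = config.sim.n_replicates
        within = []
        for block in range(2):
            for i in range(n):
                for j in range(i + 1, n):
                    within.append(corr.r[block * n + i, block * n + j])
        across = [corr.r[i, j] for i in range(n) for j in range(n, 2 * n)]
        manifest["stages"]["correlate"] = {
            "mean_within_lineage_r": float(np.mean(within)),
            "mean_across_lineage_r": float(np.mean(across)),
            "n_bins_used": corr.n_bins_used,
        }

    for path in sorted(outdir.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        manifest["files"][path.name] = _sha256_file(path)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def verify_outputs(outdir: str | Path) -> dict[str, bool]:
    """Re-parse every emitted file with the package's own readers."""
    outdir = Path(outdir)
    status: dict[str, bool] = {}
    for path in sorted(outdir.iterdir()):
        if path.is_dir():
            continue
        name = path.name
        try:
            if name.endswith(".fa"):
                tio.read_fasta(path)
            elif name.endswith(".narrowPeak"):
                tio.read_narrowpeak(path)
            elif name.endswith(".bedgraph"):
                tio.read_bedgraph(path)
            elif name.endswith(".bed"):
                tio.peaks_from_bed(path)
            elif name.endswith(".tsv"):
                pd.read_csv(path, sep="\t")
            elif name.endswith(".json"):
                with open(path) as fh:
                    json.load(fh)
            else:
                continue
            status[name] = True
        except Exception:
            status[name] = False
    return status
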