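"""End-to-end synthetic experiment: simulate, call, compare, assign, discover.

One master seed drives the whole run; rerunning with the same configuration
reproduces every output byte for byte. Each stage writes plain-text BED/TSV
artifacts plus a run log and a manifest, and the planted truth is scored
against the called peaks at the end.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import (
    chipchip_caller,
    chipseq_caller,
    formats_io,
    location_analysis,
    motif_analysis,
    peakset_ops,
    replicate_qc,
    synthetic_data,
)
from .chipchip_caller import MayacamasConfig
from .chipseq_caller import BroadCallConfig
from .formats_io import PeakSet
from .synthetic_data import SimConfig

logger = logging.getLogger("znfpipe")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    mayacamas: MayacamasConfig = field(default_factory=MayacamasConfig)
    broad: BroadCallConfig = field(default_factory=BroadCallConfig)
    stringencies: list[tuple[float, float]] = field(
        default_factory=lambda: [(1.00, 0.99), (1.00, 0.95)]
    )
    array_levels: list[float] = field(
        default_factory=lambda: list(chipchip_caller.PERCENTILE_LEVELS)
    )
    seed: int = 0

    def __post_init__(self):
        self.sim = dataclasses.replace(self.sim, seed=self.seed)


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage; returns a report dict and writes all artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    report: dict = {}

    def emit(name: str):
        written.append(name)
        return out / name

    log_lines = [f"seed\t{config.seed}"]
    for section in ("sim", "mayacamas", "broad"):
        for f in dataclasses.fields(getattr(config, section)):
            log_lines.append(
                f"{section}.{f.name}\t{getattr(getattr(config, section), f.name)}"
            )

    stage = "simulate"
    try:
        genome, genes, truth = synthetic_data.make_genome(config.sim)
        formats_io.write_fasta(genome, emit("genome.fa"))
        formats_io.write_gene_table(genes, emit("genes.tsv"))
        synthetic_data.write_truth(truth, emit("truth.tsv"))
        track = synthetic_data.simulate_array(truth, config.sim)
        formats_io.write_array_track(track, emit("array_track.tsv"))
        chip = synthetic_data.simulate_tags(truth, config.sim, "chip", "all")
        input_lib = synthetic_data.simulate_tags(truth, config.sim, "input")
        sharp_chip = synthetic_data.simulate_tags(truth, config.sim, "chip", "sharp")
        formats_io.write_tags(chip, emit("chip.tags"))
        formats_io.write_tags(input_lib, emit("input.tags"))

        stage = "chipchip"
        smoothed = chipchip_caller.smooth_track(
            track, config.mayacamas.smooth_halfwidth_oligos
        )
        array_peaks: dict[float, PeakSet] = {}
        for level in config.array_levels:
            cfg = dataclasses.replace(config.mayacamas, percentile_level=level)
            ps = chipchip_caller.call_chipchip_peaks(smoothed, cfg)
            array_peaks[level] = ps
            formats_io.write_bed(ps, emit(f"array_peaks_top{level:g}.bed"))
            report[f"n_array_peaks_top{level:g}"] = len(ps)

        stage = "chipseq"
        broad_peaks = chipseq_caller.call_chipseq_peaks(
            chip, input_lib, config.sim.chrom_lengths, config.broad
        )
        formats_io.write_bed(broad_peaks, emit("broad_peaks.bed"))
        sharp_peaks = chipseq_caller.call_chipseq_peaks(
            sharp_chip, input_lib, config.sim.chrom_lengths, config.broad
        )
        formats_io.write_bed(sharp_peaks, emit("sharp_peaks.bed"))
        report["n_broad_peaks"] = len(broad_peaks)
        report["n_sharp_peaks"] = len(sharp_peaks)

        stage = "replicate_qc"
        reps = synthetic_data.make_replicates(truth, config.sim, n=2)
        rep_peaks = [
            chipseq_caller.call_chipseq_peaks(
                r, input_lib, config.sim.chrom_lengths, config.broad
            )
            for r in reps
        ]
        qc = replicate_qc.encode_overlap(*rep_peaks)
        _write_tsv(
            emit("replicate_overlap.tsv"),
            ["frac_a_in_b", "frac_b_in_a", "truncated_n"],
            [[f"{qc.frac_a_in_b:.4f}", f"{qc.frac_b_in_a:.4f}", qc.truncated_n]],
        )
        report["replicate_overlap"] = (qc.frac_a_in_b, qc.frac_b_in_a)

        stage = "peakset_ops"
        n_ab, n_ba = peakset_ops.overlap_counts(broad_peaks, sharp_peaks)
        _write_tsv(
            emit("overlap_counts.tsv"),
            ["set_a", "set_b", "n_a_overlapping_b", "n_b_overlapping_a"],
            [["broad", "sharp", n_ab, n_ba]],
        )
        per_chrom = peakset_ops.per_chromosome_counts(sharp_peaks, genes)
        per_chrom.to_csv(emit("per_chromosome_counts.tsv"), sep="\t", index=False)
        if len(broad_peaks) and len(sharp_peaks):
            top10 = peakset_ops.top_fraction(broad_peaks, 0.10)
            profile = peakset_ops.distance_to_nearest(top10, sharp_peaks)
            profile.histogram(100).to_csv(
                emit("distance_histogram.tsv"), sep="\t", index=False
            )
            valid = profile.valid()
            report["median_abs_distance_bp"] = (
                float(np.median(np.abs(valid))) if valid.size else float("nan")
            )

        stage = "location_analysis"
        assignments = location_analysis.assign_targets(sharp_peaks, genes)
        _write_tsv(
            emit("target_assignments.tsv"),
            ["chrom", "start", "end", "gene_id", "mode", "context", "distance_bp"],
            [
                [a.peak.interval.chrom, a.peak.interval.start, a.peak.interval.end,
                 a.gene_id, a.mode, a.context, a.distance_bp]
                for a in assignments
            ],
        )
        hist = location_analysis.finger_count_histogram(assignments, genes)
        hist.to_csv(emit("finger_count_histogram.tsv"), sep="\t", index=False)
        expr_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(9001,))
        )
        expression = {
            g.gene_id: float(expr_rng.lognormal(3.0, 1.0)) for g in genes
        }
        quintiles = location_analysis.expression_quintile_profile(
            assignments, expression
        )
        _write_tsv(
            emit("expression_quintiles.tsv"),
            ["quintile", "n_bound_genes"],
            [[q + 1, int(n)] for q, n in enumerate(quintiles)],
        )
        report["n_assignments"] = len(assignments)

        stage = "motif_analysis"
        if len(sharp_peaks):
            fg = motif_analysis.extract_peak_sequences(sharp_peaks, genome)
            bg = motif_analysis.build_background_set(genes, sharp_peaks, genome)
            motifs = motif_analysis.discover_motifs(fg, bg, seed=config.seed)
            report["n_motifs"] = len(motifs)
            motif_rows = []
            for m in motifs:
                motif_analysis.write_pwm(m.pwm, emit(f"{m.pwm.name}.pwm"))
                motif_rows.append(
                    [m.pwm.name, m.pwm.consensus, m.n_occurrences,
                     f"{m.stringency.core_cut:.4f}", f"{m.stringency.pwm_cut:.4f}"]
                )
            _write_tsv(
                emit("motifs.tsv"),
                ["name", "consensus", "n_occurrences", "core_cut", "pwm_cut"],
                motif_rows,
            )
            if motifs:
                top = motifs[0]
                scan_rows = []
                for core_cut, pwm_cut in config.stringencies:
                    hits = motif_analysis.scan_sequences(
                        genome, top.pwm,
                        motif_analysis.StringencyPair(core_cut, pwm_cut),
                    )
                    n_at, n_total, frac = motif_analysis.classify_hits(
                        hits, genes, motif_length=len(top.pwm)
                    )
                    scan_rows.append(
                        [f"{core_cut:.2f}/{pwm_cut:.2f}", n_total, n_at,
                         "NA" if frac is None else f"{frac:.4f}"]
                    )
                    report[f"n_hits_{core_cut:.2f}/{pwm_cut:.2f}"] = n_total
                    report[f"frac_at_znf_{core_cut:.2f}/{pwm_cut:.2f}"] = frac
                _write_tsv(
                    emit("genome_scan.tsv"),
                    ["stringency", "n_hits", "n_at_znf", "frac_at_znf"],
                    scan_rows,
                )
            if len(motifs) >= 2:
                merged = motif_analysis.merge_reverse_oriented(
                    motifs[0].pwm, motifs[1].pwm
                )
                report["merged_consensus"] = merged
                _write_tsv(
                    emit("merged_motif.tsv"),
                    ["merged_consensus", "length"],
                    [[merged or "NA", len(merged) if merged else 0]],
                )

        stage = "scoring"
        score_rows = []
        for label, called, planted, mode in [
            ("broad_vs_domains", broad_peaks, truth.domain_intervals(), "jaccard"),
            ("sharp_vs_sites", sharp_peaks, truth.sharp_intervals(), "center"),
        ]:
            s = synthetic_data.score_against_truth(called, planted, mode=mode)
            score_rows.append(
                [label, int(s["n_planted"]), int(s["n_called"]),
                 f"{s['recall']:.4f}", f"{s['precision']:.4f}"]
            )
            report[f"{label}_recall"] = s["recall"]
            report[f"{label}_precision"] = s["precision"]
        _write_tsv(
            emit("truth_scoring.tsv"),
            ["comparison", "n_planted", "n_called", "recall", "precision"],
            score_rows,
        )
    except Exception as exc:
        logger.error("pipeline stage '%s' failed: %s", stage, exc)
        raise PipelineError(stage, exc) from exc

    with open(emit("run_log.tsv"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    with open(out / "MANIFEST.txt", "w") as fh:
        fh.write("\n".join(sorted(written)) + "\n")
    report["outputs"] = sorted(written)
    return report
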