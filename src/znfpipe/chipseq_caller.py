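"""Broad-domain ChIP-seq caller: binned fragment coverage, heavy smoothing,
empirical-FDR height cutoff against a depth-scaled input library.

Tags (read 5' positions) are extended to the library fragment length,
per-bp coverage is averaged into 30 bp bins, and each bin is smoothed as the
mean of all bins within 600 bp on either side. The statistically significant
height cutoff h* is the lowest observed ChIP bin value whose empirical FDR —
the depth-scaled number of input bins at or above h over the number of ChIP
bins at or above h — does not surpass the target rate (default 0.01). Peaks
are maximal runs of bins at or above h* that reach a minimum length (default
150 bp, approximating the minimal chromatin fragment size).

The original three-step design also tested each peak's significance over
background; that step is intentionally absent here, as broad-domain data
makes it unnecessary. Input normalization is global depth scaling (no
CNV-aware correction; see the methods note).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .formats_io import GenomicInterval, PeakSet, TagLibrary, ValidationError

logger = logging.getLogger("znfpipe")

#: sentinel returned by fdr_height_cutoff when no height reaches the FDR target
NO_SIGNAL = None


@dataclass
class BroadCallConfig:
    bin_step_bp: int = 30
    smooth_flank_bp: int = 600
    fdr: float = 0.01
    min_length_bp: int = 150
    fragment_length_bp: int = 150

    def __post_init__(self):
        if self.bin_step_bp <= 0 or self.smooth_flank_bp % self.bin_step_bp != 0:
            raise ValidationError("bin_step_bp must divide smooth_flank_bp")
        if not 0.0 < self.fdr < 1.0:
            raise ValidationError("fdr must be in (0, 1)")
        if self.min_length_bp < self.bin_step_bp:
            raise ValidationError("min_length_bp must be >= bin_step_bp")


@dataclass
class BinnedTrack:
    """Smoothed mean coverage per bin; bin i starts at i * bin_step."""

    values: dict[str, np.ndarray]
    bin_step: int = 30

    def grid_signature(self) -> tuple:
        return (self.bin_step, tuple(sorted(
            (c, len(v)) for c, v in self.values.items()
        )))

    def all_values(self) -> np.ndarray:
        if not self.values:
            return np.empty(0)
        return np.concatenate([self.values[c] for c in sorted(self.values)])


def normalize_background(chip: TagLibrary, input_lib: TagLibrary) -> float:
    """Global depth scale factor: input bin values are multiplied by
    chip.depth / input.depth before the FDR computation."""
    if chip.depth == 0 or input_lib.depth == 0:
        raise ValidationError("cannot normalize with a zero-depth library")
    return chip.depth / input_lib.depth


def _fragment_coverage(
    tags: TagLibrary, chrom: str, length: int, frag: int
) -> np.ndarray:
    """Per-bp count of extended fragments overlapping each position."""
    mask = tags.chroms == chrom
    starts = tags.starts[mask]
    strands = tags.strands[mask]
    plus = strands == "+"
    frag_lo = np.where(plus, starts, starts - frag + 1)
    frag_hi = frag_lo + frag
    if len(frag_lo) and (frag_lo.min() < 0 or frag_hi.max() > length):
        warnings.warn(
            f"{chrom}: fragments extend past chromosome bounds; clipped",
            stacklevel=2,
        )
    frag_lo = np.clip(frag_lo, 0, length)
    frag_hi = np.clip(frag_hi, 0, length)
    diff = np.zeros(length + 1, dtype=np.float64)
    np.add.at(diff, frag_lo, 1.0)
    np.add.at(diff, frag_hi, -1.0)
    return np.cumsum(diff[:-1])


def bin_and_smooth(
    tags: TagLibrary,
    chrom_lengths: dict[str, int],
    config: BroadCallConfig,
) -> BinnedTrack:
    """Fragment coverage -> 30 bp bin means -> +/-600 bp smoothed bin means.

    The smoothed value of a bin is the mean of the raw values of all bins
    whose start lies within [bin_start - flank, bin_start + flank]; edge bins
    average over the bins that exist.
    """
    step = config.bin_step_bp
    flank_bins = config.smooth_flank_bp // step
    values: dict[str, np.ndarray] = {}
    for chrom, length in sorted(chrom_lengths.items()):
        cov = _fragment_coverage(tags, chrom, length, config.fragment_length_bp)
        n_bins = (length + step - 1) // step
        padded = np.zeros(n_bins * step)
        padded[:length] = cov
        raw = padded.reshape(n_bins, step).mean(axis=1)
        # last partial bin: mean over actual bp, not padded zeros
        if length % step:
            raw[-1] = cov[(n_bins - 1) * step:].mean()
        csum = np.concatenate([[0.0], np.cumsum(raw)])
        idx = np.arange(n_bins)
        lo = np.maximum(0, idx - flank_bins)
        hi = np.minimum(n_bins, idx + flank_bins + 1)
        values[chrom] = (csum[hi] - csum[lo]) / (hi - lo)
    return BinnedTrack(values=values, bin_step=step)


def fdr_height_cutoff(
    chip: BinnedTrack,
    input_track: BinnedTrack,
    scale: float,
    fdr: float = 0.01,
) -> float | None:
    """Lowest observed ChIP bin value h with empirical FDR(h) <= target.

    FDR(h) = (scale * #input bins >= h) / (#chip bins >= h), evaluated over
    the ascending grid of observed ChIP bin values. Returns NO_SIGNAL (None)
    when no height qualifies.
    """
    if chip.grid_signature() != input_track.grid_signature():
        raise ValidationError("chip and input tracks are on different bin grids")
    chip_vals = np.sort(chip.all_values())
    input_vals = np.sort(input_track.all_values())
    n_chip = len(chip_vals)
    candidates = np.unique(chip_vals)
    # counts >= h via searchsorted on the ascending sorted arrays
    n_chip_ge = n_chip - np.searchsorted(chip_vals, candidates, side="left")
    n_input_ge = len(input_vals) - np.searchsorted(input_vals, candidates, side="left")
    fdr_at = scale * n_input_ge / n_chip_ge
    ok = np.flatnonzero(fdr_at <= fdr)
    if ok.size == 0:
        logger.info("fdr_height_cutoff: no height reaches FDR <= %g", fdr)
        return NO_SIGNAL
    return float(candidates[ok[0]])


def call_broad_peaks(
    chip: BinnedTrack,
    cutoff: float | None,
    config: BroadCallConfig,
) -> PeakSet:
    """Maximal runs of bins >= h*, kept if run length >= min_length_bp.

    Run length = (last bin_start - first bin_start) + bin_step. Peak height is
    the maximum bin value; ranking is by height, ties by coordinate.
    """
    if cutoff is NO_SIGNAL:
        return PeakSet(name="broad_peaks", peaks=[], source="no signal")
    step = chip.bin_step
    intervals, heights = [], []
    for chrom in sorted(chip.values):
        v = chip.values[chrom]
        above = np.concatenate([[False], v >= cutoff, [False]])
        run_starts = np.flatnonzero(above[1:] & ~above[:-1])
        run_ends = np.flatnonzero(~above[1:] & above[:-1])  # exclusive bin idx
        for b0, b1 in zip(run_starts, run_ends):
            length = (b1 - b0) * step
            if length < config.min_length_bp:
                continue
            intervals.append(GenomicInterval(chrom, int(b0 * step), int(b1 * step)))
            heights.append(float(v[b0:b1].max()))
    return PeakSet.from_intervals(
        name="broad_peaks", intervals=intervals, heights=heights,
        source=f"call_broad_peaks(h*={cutoff})",
    )


def call_chipseq_peaks(
    chip_tags: TagLibrary,
    input_tags: TagLibrary,
    chrom_lengths: dict[str, int],
    config: BroadCallConfig | None = None,
) -> PeakSet:
    """End-to-end broad calling: normalize, bin/smooth both libraries,
    find the FDR height cutoff, and emit length-filtered peaks."""
    config = config or BroadCallConfig()
    scale = normalize_background(chip_tags, input_tags)
    chip_track = bin_and_smooth(chip_tags, chrom_lengths, config)
    input_track = bin_and_smooth(input_tags, chrom_lengths, config)
    h_star = fdr_height_cutoff(chip_track, input_track, scale, config.fdr)
    logger.info(
        "chipseq caller: scale=%.4g h*=%s", scale,
        "no-signal" if h_star is NO_SIGNAL else f"{h_star:.4g}",
    )
    return call_broad_peaks(chip_track, h_star, config)
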