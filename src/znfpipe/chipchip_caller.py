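"""Tiling-array broad-peak caller for histone-mark-style ChIP-chip data.

The procedure: smooth probe log2 ratios with a sliding average in probe-index
space (five oligos on either side of the center oligo), take a top-percentile
height cutoff over the smoothed values, then call maximal runs of
above-threshold probes as peaks. Repetitive regions leave holes in the tiling
grid, so up to a fixed number of expected-but-absent probe positions may be
bridged inside one peak region; a present probe below threshold always
terminates a run. Each emitted region must span a minimum width and contain at
least half of the oligos expected from the tiling interval.

Percentile levels in routine use: top 5% for spreading histone marks
(H3K9me3), top 1% for site-specific factors (KAP1, SETDB1), top 0.5% for
sparse factors (G9a).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .formats_io import ArrayTrack, GenomicInterval, Peak, PeakSet, ValidationError

logger = logging.getLogger("znfpipe")

PERCENTILE_LEVELS = (0.05, 0.01, 0.005)


@dataclass
class MayacamasConfig:
    """Parameters of the tiling-array caller."""

    smooth_halfwidth_oligos: int = 5
    percentile_level: float = 0.01
    min_span_bp: int = 800
    max_missing_oligos: int = 6
    min_expected_fraction: float = 0.5
    tile_interval_bp: int = 100

    def __post_init__(self):
        if self.tile_interval_bp <= 0:
            raise ValidationError("tile_interval_bp must be positive")
        for name in ("smooth_halfwidth_oligos", "min_span_bp", "max_missing_oligos"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 < self.percentile_level <= 1.0:
            raise ValidationError("percentile_level must be in (0, 1]")


def smooth_track(track: ArrayTrack, halfwidth: int = 5) -> ArrayTrack:
    """Sliding average over up to ``2*halfwidth + 1`` probes in index space.

    At chromosome ends the window simply contains fewer probes; chromosomes are
    never mixed. Index-space windows mean that missing probes widen the bp
    footprint of the window instead of shrinking its sample count.
    """
    smoothed = {}
    for chrom, (starts, ends, values) in track.probes.items():
        n = len(values)
        if n == 0:
            smoothed[chrom] = (starts, ends, values)
            continue
        csum = np.concatenate([[0.0], np.cumsum(values)])
        idx = np.arange(n)
        lo = np.maximum(0, idx - halfwidth)
        hi = np.minimum(n, idx + halfwidth + 1)
        means = (csum[hi] - csum[lo]) / (hi - lo)
        smoothed[chrom] = (starts, ends, means)
    return ArrayTrack(probes=smoothed, tile_interval=track.tile_interval)


def percentile_cutoff(smoothed: ArrayTrack, level: float) -> float:
    """Smallest value v with |{probes >= v}| = ceil(level * N).

    "Above threshold" downstream always means value >= v.
    """
    if not 0.0 < level <= 1.0:
        raise ValidationError(f"percentile level must be in (0, 1], got {level}")
    values = smoothed.all_values()
    if values.size == 0:
        raise ValidationError("cannot take a percentile of an empty track")
    k = math.ceil(level * values.size)
    return float(np.partition(values, values.size - k)[values.size - k])


def call_chipchip_peaks(
    smoothed: ArrayTrack,
    config: MayacamasConfig,
    cutoff: float | None = None,
) -> PeakSet:
    """Call broad peaks on a smoothed track.

    A peak is a maximal run of above-threshold probes in which at most
    ``max_missing_oligos`` expected grid positions are absent; a present probe
    below threshold terminates the run. Emitted regions span
    [first probe_start, last probe_end) >= ``min_span_bp`` and contain at
    least ``min_expected_fraction`` of the floor(span/tile)+1 expected oligos.
    Peak height is the maximum smoothed value in the run.
    """
    if cutoff is None:
        cutoff = percentile_cutoff(smoothed, config.percentile_level)
    tile = config.tile_interval_bp
    intervals: list[GenomicInterval] = []
    heights: list[float] = []
    per_chrom_counts: dict[str, int] = {}
    for chrom in smoothed.chroms():
        starts, ends, values = smoothed.probes[chrom]
        above = values >= cutoff
        n = len(starts)
        i = 0
        while i < n:
            if not above[i]:
                i += 1
                continue
            # grow the run greedily while the missing-oligo budget holds
            j = i
            missing = 0
            while j + 1 < n and above[j + 1]:
                gap = (starts[j + 1] - starts[j]) // tile - 1
                if missing + max(0, gap) > config.max_missing_oligos:
                    break
                missing += max(0, gap)
                j += 1
            span = int(ends[j] - starts[i])
            n_present = j - i + 1
            n_expected = span // tile + 1
            if (
                span >= config.min_span_bp
                and n_present >= config.min_expected_fraction * n_expected
            ):
                intervals.append(GenomicInterval(chrom, int(starts[i]), int(ends[j])))
                heights.append(float(values[i:j + 1].max()))
                per_chrom_counts[chrom] = per_chrom_counts.get(chrom, 0) + 1
            i = j + 1
    logger.info(
        "chipchip caller: cutoff=%.4g, peaks per chromosome: %s",
        cutoff, per_chrom_counts,
    )
    return PeakSet.from_intervals(
        name="chipchip_peaks",
        intervals=intervals,
        heights=heights,
        source=f"call_chipchip_peaks(level={config.percentile_level})",
    )
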