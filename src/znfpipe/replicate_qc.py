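"""Replicate consistency scoring (ENCODE-style top-40% overlap rule) and the
qPCR fold-enrichment utility.

The overlap rule: truncate both replicates' ranked peak lists to the length of
the shorter one, take the top 40% of one replicate's truncated list, and
report the fraction of those peaks that overlap (by at least 1 bp) any peak
of the other replicate's truncated list; then the same with the replicates
swapped. Well-behaved replicates score near 1.0 in both directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .formats_io import Peak, PeakSet, ValidationError
from .peakset_ops import _overlap_flags


@dataclass
class OverlapReport:
    frac_a_in_b: float
    frac_b_in_a: float
    truncated_n: int

    def __post_init__(self):
        for v in (self.frac_a_in_b, self.frac_b_in_a):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"overlap fraction out of [0,1]: {v}")


def _top_ranked(peaks: list[Peak], k: int) -> list[Peak]:
    return sorted(peaks, key=lambda p: p.rank)[:k]


def encode_overlap(
    rep_a: PeakSet, rep_b: PeakSet, top_frac: float = 0.40
) -> OverlapReport:
    """Top-``top_frac`` overlap of two ranked replicates, both directions."""
    if len(rep_a) == 0 or len(rep_b) == 0:
        raise ValidationError("encode_overlap requires non-empty peak sets")
    if not 0.0 < top_frac <= 1.0:
        raise ValidationError(f"top_frac must be in (0,1], got {top_frac}")
    n = min(len(rep_a), len(rep_b))
    trunc_a = _top_ranked(rep_a.peaks, n)
    trunc_b = _top_ranked(rep_b.peaks, n)
    k = math.ceil(top_frac * n)

    def _frac(top: list[Peak], other: list[Peak]) -> float:
        top_k = _top_ranked(top, k)
        flags = _overlap_flags(
            [p.interval for p in top_k], [p.interval for p in other]
        )
        return sum(flags) / len(top_k)

    return OverlapReport(
        frac_a_in_b=_frac(trunc_a, trunc_b),
        frac_b_in_a=_frac(trunc_b, trunc_a),
        truncated_n=n,
    )


def qpcr_fold_enrichment(ct_input: float, ct_chip: float) -> float:
    """Fold enrichment = 2 ** (cT_input - cT_chip)."""
    if not (math.isfinite(ct_input) and math.isfinite(ct_chip)):
        raise ValidationError("cT values must be finite")
    return 2.0 ** (ct_input - ct_chip)
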