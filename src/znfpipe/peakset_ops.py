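"""Peak-set algebra: overlap counts, per-chromosome distributions,
top-fraction selection and distance-to-nearest-peak profiles.

These operations back the standard comparisons of a co-localization study:
Venn-style overlap counts between marks, the per-chromosome distribution of
binding sites against the C2H2 gene census, selection of the strongest
fraction of a peak list, and the profile of distances from each query peak
center to the center of the nearest subject peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import GeneModel, GenomicInterval, PeakSet, ValidationError


def _overlap_flags(
    queries: list[GenomicInterval], subjects: list[GenomicInterval]
) -> list[bool]:
    """For each query interval, whether it intersects (>= 1 bp) any subject.

    Sweep per chromosome: with subjects sorted by start, a query [s, e)
    overlaps some subject iff among subjects starting before e there is one
    ending after s — answered with a prefix-max of subject ends.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in subjects:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    prepared = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda x: x.start)
        starts = np.array([x.start for x in ivs])
        ends_prefix_max = np.maximum.accumulate([x.end for x in ivs])
        prepared[chrom] = (starts, ends_prefix_max)
    flags = []
    for q in queries:
        if q.chrom not in prepared:
            flags.append(False)
            continue
        starts, ends_max = prepared[q.chrom]
        k = np.searchsorted(starts, q.end, side="left")  # subjects with start < end
        flags.append(bool(k > 0 and ends_max[k - 1] > q.start))
    return flags


def overlap_counts(a: PeakSet, b: PeakSet) -> tuple[int, int]:
    """(#a peaks intersecting any b peak, #b peaks intersecting any a peak)."""
    a_iv = [p.interval for p in a]
    b_iv = [p.interval for p in b]
    return sum(_overlap_flags(a_iv, b_iv)), sum(_overlap_flags(b_iv, a_iv))


def per_chromosome_counts(a: PeakSet, genes: list[GeneModel]) -> pd.DataFrame:
    """Rows (chrom, n_peaks, n_c2h2_genes), one per chromosome present in
    either input; column sums equal |a| and the C2H2 gene count."""
    peak_counts: dict[str, int] = {}
    for p in a:
        peak_counts[p.interval.chrom] = peak_counts.get(p.interval.chrom, 0) + 1
    gene_counts: dict[str, int] = {}
    for g in genes:
        if g.is_c2h2:
            gene_counts[g.interval.chrom] = gene_counts.get(g.interval.chrom, 0) + 1
    chroms = sorted(set(peak_counts) | set(gene_counts))
    return pd.DataFrame(
        {
            "chrom": chroms,
            "n_peaks": [peak_counts.get(c, 0) for c in chroms],
            "n_c2h2_genes": [gene_counts.get(c, 0) for c in chroms],
        }
    )


def top_fraction(a: PeakSet, frac: float) -> PeakSet:
    """The ceil(frac * |a|) highest peaks (ties by coordinate), re-ranked."""
    if len(a) == 0:
        raise ValidationError("top_fraction of an empty peak set")
    if not 0.0 < frac <= 1.0:
        raise ValidationError(f"frac must be in (0,1], got {frac}")
    k = math.ceil(frac * len(a))
    chosen = sorted(a.peaks, key=lambda p: p.rank)[:k]
    return PeakSet.from_intervals(
        name=f"{a.name}_top{frac:g}",
        intervals=[p.interval for p in chosen],
        heights=[p.height for p in chosen],
        source=f"top_fraction({a.name}, {frac})",
    )


@dataclass
class DistanceProfile:
    """Signed distances from query peak centers to nearest subject centers.

    ``distances`` is aligned with the query's peaks (coordinate order); NaN
    marks query peaks on chromosomes where the subject has no peak.
    """

    distances: np.ndarray
    query_label: str = "query"
    subject_label: str = "subject"

    n_missing: int = field(init=False)

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=np.float64)
        self.n_missing = int(np.isnan(self.distances).sum())

    def valid(self) -> np.ndarray:
        return self.distances[~np.isnan(self.distances)]

    def histogram(self, bin_width: int = 100) -> pd.DataFrame:
        """Counts of distances in ``bin_width`` bp bins centered on zero."""
        d = self.valid()
        if d.size == 0:
            return pd.DataFrame({"bin_start": [], "bin_end": [], "count": []})
        lo = math.floor(d.min() / bin_width) * bin_width
        hi = math.ceil((d.max() + 1) / bin_width) * bin_width
        edges = np.arange(lo, hi + bin_width, bin_width)
        counts, _ = np.histogram(d, bins=edges)
        return pd.DataFrame(
            {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
        )


def distance_to_nearest(query: PeakSet, subject: PeakSet) -> DistanceProfile:
    """Signed distance (query center - subject center) to the nearest subject
    peak center, per query peak; nearest by absolute distance, ties resolved
    toward the smaller subject coordinate. Centers are floor midpoints."""
    if len(query) == 0 or len(subject) == 0:
        raise ValidationError("distance_to_nearest requires non-empty sets")
    subj_centers: dict[str, np.ndarray] = {}
    for p in subject:
        subj_centers.setdefault(p.interval.chrom, []).append(p.interval.center)
    subj_centers = {c: np.sort(np.array(v)) for c, v in subj_centers.items()}
    out = np.full(len(query), np.nan)
    for i, p in enumerate(query.peaks):
        centers = subj_centers.get(p.interval.chrom)
        if centers is None:
            continue
        qc = p.interval.center
        j = np.searchsorted(centers, qc)
        best = None
        # left neighbor first so equal |distance| resolves to the smaller coord
        for cand in (j - 1, j):
            if 0 <= cand < len(centers):
                d = qc - int(centers[cand])
                if best is None or abs(d) < abs(best):
                    best = d
        out[i] = best
    return DistanceProfile(
        distances=out, query_label=query.name, subject_label=subject.name
    )
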