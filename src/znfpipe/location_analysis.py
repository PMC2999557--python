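"""Two-pass assignment of binding sites to genes, peak context classification,
finger-count histograms and expression-quintile profiles.

Standard location-analysis tools link a binding site to the nearest
transcription start site. That misclassifies factors that bind inside 3'
exons of densely packed gene clusters, where the nearest TSS often belongs to
the *neighboring* gene. The two-pass rule fixes this: pass 1 assigns every
peak that overlaps a gene body to that gene (greatest overlap wins); only the
remaining peaks are linked to the gene with the nearest TSS in pass 2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import GeneModel, Peak, PeakSet, ValidationError

logger = logging.getLogger("znfpipe")

CONTEXTS = ("final_exon", "internal_exon", "intron", "upstream", "downstream")


@dataclass
class TargetAssignment:
    peak: Peak
    gene_id: str
    mode: str  # within_gene | nearest_tss
    context: str  # one of CONTEXTS
    distance_bp: int  # 0 when within_gene; peak-center-to-TSS otherwise

    def __post_init__(self):
        if self.mode not in ("within_gene", "nearest_tss"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.context not in CONTEXTS:
            raise ValidationError(f"unknown context {self.context!r}")
        if self.distance_bp < 0:
            raise ValidationError("distance must be >= 0")


def _within_gene_context(peak: Peak, gene: GeneModel) -> str:
    final = gene.final_exon
    if peak.interval.overlaps(final):
        return "final_exon"
    if any(peak.interval.overlaps(ex) for ex in gene.exons):
        return "internal_exon"
    return "intron"


def _tss_context(peak: Peak, gene: GeneModel) -> str:
    center = peak.interval.center
    if gene.strand == "+":
        return "upstream" if center < gene.tss else "downstream"
    return "upstream" if center > gene.tss else "downstream"


def assign_targets(
    peaks: PeakSet, genes: list[GeneModel]
) -> list[TargetAssignment]:
    """Assign every peak to exactly one gene.

    Pass 1: peaks overlapping >= 1 gene body go to the gene with the greatest
    overlap (ties: smaller gene start, then gene_id). Pass 2: remaining peaks
    go to the same-chromosome gene whose strand-aware TSS is nearest to the
    peak center. Context is computed against the assigned gene's exons; the
    final exon is the 3'-most exon in transcription order.
    """
    if not genes:
        raise ValidationError("assign_targets requires a non-empty gene list")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)

    assignments: list[TargetAssignment] = []
    n_skipped = 0
    for peak in peaks:
        chrom_genes = by_chrom.get(peak.interval.chrom, [])
        if not chrom_genes:
            n_skipped += 1
            continue
        overlapping = [
            (g, peak.interval.overlap_bp(g.interval))
            for g in chrom_genes
            if peak.interval.overlaps(g.interval)
        ]
        if overlapping:
            gene = min(
                overlapping,
                key=lambda t: (-t[1], t[0].interval.start, t[0].gene_id),
            )[0]
            assignments.append(
                TargetAssignment(
                    peak=peak,
                    gene_id=gene.gene_id,
                    mode="within_gene",
                    context=_within_gene_context(peak, gene),
                    distance_bp=0,
                )
            )
        else:
            center = peak.interval.center
            gene = min(
                chrom_genes,
                key=lambda g: (abs(center - g.tss), g.interval.start, g.gene_id),
            )
            assignments.append(
                TargetAssignment(
                    peak=peak,
                    gene_id=gene.gene_id,
                    mode="nearest_tss",
                    context=_tss_context(peak, gene),
                    distance_bp=abs(center - gene.tss),
                )
            )
    if n_skipped:
        warnings.warn(
            f"{n_skipped} peak(s) on chromosomes with no annotated gene "
            "were left unassigned",
            stacklevel=2,
        )
    return assignments


def finger_count_histogram(
    assignments: list[TargetAssignment],
    genes: list[GeneModel],
    bin_width: int = 1,
) -> pd.DataFrame:
    """Counts of bound vs all C2H2 genes per finger-count bin.

    Each C2H2 gene is counted once in n_all_c2h2 and once in n_bound_c2h2 iff
    it carries >= 1 assignment. Bins are [b, b + bin_width) with b a multiple
    of bin_width.
    """
    if bin_width < 1:
        raise ValidationError("bin_width must be >= 1")
    bound_ids = {a.gene_id for a in assignments}
    rows: dict[int, list[int]] = {}
    for g in genes:
        if not g.is_c2h2:
            continue
        b = (g.finger_count // bin_width) * bin_width
        row = rows.setdefault(b, [0, 0])
        row[1] += 1
        if g.gene_id in bound_ids:
            row[0] += 1
    bins = sorted(rows)
    return pd.DataFrame(
        {
            "finger_count_bin": bins,
            "n_bound_c2h2": [rows[b][0] for b in bins],
            "n_all_c2h2": [rows[b][1] for b in bins],
        }
    )


def expression_quintile_profile(
    assignments: list[TargetAssignment],
    expression: dict[str, float] | pd.Series,
) -> np.ndarray:
    """Counts of bound genes per expression quintile (length-5 array).

    Quintile boundaries are the 20/40/60/80th percentiles of the full
    expression table; a gene whose level equals a boundary falls in the lower
    quintile. Bound genes absent from the table are ignored.
    """
    expr = pd.Series(expression, dtype=float)
    if expr.empty:
        raise ValidationError("expression table is empty")
    boundaries = np.percentile(expr.to_numpy(), [20, 40, 60, 80])
    counts = np.zeros(5, dtype=int)
    for gid in {a.gene_id for a in assignments}:
        if gid in expr.index:
            q = int(np.searchsorted(boundaries, expr[gid], side="left"))
            counts[q] += 1
    return counts
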