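"""Domain types and readers/writers for the tabular formats the pipeline exchanges.

All coordinates everywhere are 0-based half-open (BED-native). 1-based
coordinates appear only in human-readable log messages.

File dialects
-------------
BED         : 3-5 tab-separated columns (chrom, start, end[, name[, height]]).
array track : 4 columns (chrom, probe_start, probe_end, log2_ratio).
tag file    : 3 columns (chrom, start, strand), start = read 5' position.
gene table  : refFlat-style columns
              gene_id, chrom, strand, tx_start, tx_end, exon_starts, exon_ends
              plus optional attribute columns is_c2h2, finger_count, has_krab.
              exon_starts/exon_ends are comma-separated lists.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("znfpipe")

STRANDS = ("+", "-")


class ParseError(ValueError):
    """A line in an input file could not be parsed."""


class ValidationError(ValueError):
    """An object violates one of its invariants."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Floor midpoint of the interval."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def jaccard(self, other: "GenomicInterval") -> float:
        inter = self.overlap_bp(other)
        if inter == 0:
            return 0.0
        union = len(self) + len(other) - inter
        return inter / union


@dataclass(frozen=True)
class Peak:
    """Ranked enriched region; ``height`` is the caller's summit statistic."""

    interval: GenomicInterval
    height: float
    rank: int

    def __post_init__(self):
        if not math.isfinite(self.height):
            raise ValidationError(f"peak height must be finite, got {self.height}")
        if self.rank < 1:
            raise ValidationError(f"rank must be >= 1, got {self.rank}")


@dataclass
class PeakSet:
    """Disjoint ranked peaks, sorted by (chrom, start).

    Ranks are 1..N by descending height, ties broken by (chrom, start).
    """

    name: str
    peaks: list[Peak] = field(default_factory=list)
    source: str = ""

    def __post_init__(self):
        self.peaks = _sort_and_rank(self.peaks)
        self._check_disjoint()

    def _check_disjoint(self) -> None:
        prev: Peak | None = None
        for p in self.peaks:
            if (
                prev is not None
                and p.interval.chrom == prev.interval.chrom
                and p.interval.start < prev.interval.end
            ):
                raise ValidationError(
                    f"overlapping peaks in '{self.name}': "
                    f"{prev.interval} and {p.interval}"
                )
            prev = p

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def by_rank(self) -> list[Peak]:
        return sorted(self.peaks, key=lambda p: p.rank)

    @classmethod
    def from_intervals(
        cls,
        name: str,
        intervals: list[GenomicInterval],
        heights: list[float] | None = None,
        source: str = "",
    ) -> "PeakSet":
        if heights is None:
            heights = [0.0] * len(intervals)
        peaks = [
            Peak(iv, float(h), rank=i + 1)
            for i, (iv, h) in enumerate(zip(intervals, heights, strict=True))
        ]
        return cls(name=name, peaks=peaks, source=source)


def _sort_and_rank(peaks: list[Peak]) -> list[Peak]:
    """Recompute ranks (descending height, ties by coordinate) and sort."""
    by_height = sorted(
        peaks, key=lambda p: (-p.height, p.interval.chrom, p.interval.start)
    )
    ranked = [replace(p, rank=i + 1) for i, p in enumerate(by_height)]
    return sorted(ranked, key=lambda p: (p.interval.chrom, p.interval.start))


@dataclass
class ArrayTrack:
    """Ordered tiling-array probe measurements per chromosome.

    ``probes`` maps chrom -> (starts, ends, values) as int/int/float arrays with
    strictly increasing starts. ``tile_interval`` is the expected probe spacing
    of the array design in bp.
    """

    probes: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    tile_interval: int = 100

    def __post_init__(self):
        clean = {}
        for chrom, (starts, ends, values) in self.probes.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if len(starts) and np.any(np.diff(starts) <= 0):
                raise ValidationError(
                    f"duplicate probe starts on {chrom}"
                )
            if not np.all(np.isfinite(values)):
                raise ValidationError(f"non-finite probe values on {chrom}")
            clean[chrom] = (starts, ends, values)
        self.probes = clean

    @property
    def n_probes(self) -> int:
        return sum(len(s) for s, _, _ in self.probes.values())

    def all_values(self) -> np.ndarray:
        if not self.probes:
            return np.empty(0)
        return np.concatenate([v for _, _, v in self.probes.values()])

    def chroms(self) -> list[str]:
        return sorted(self.probes)


@dataclass
class TagLibrary:
    """Uniquely-mapped read 5' positions with strand."""

    chroms: np.ndarray  # str array
    starts: np.ndarray  # int64
    strands: np.ndarray  # '+'/'-'

    def __post_init__(self):
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.strands = np.asarray(self.strands, dtype=object)
        if not (len(self.chroms) == len(self.starts) == len(self.strands)):
            raise ValidationError("tag columns have unequal lengths")
        if len(self.starts) and self.starts.min() < 0:
            raise ValidationError("tag positions must be >= 0")
        bad = set(np.unique(self.strands)) - set(STRANDS) if len(self.strands) else set()
        if bad:
            raise ParseError(f"unknown strand symbol(s): {sorted(bad)}")

    @property
    def depth(self) -> int:
        return len(self.starts)


@dataclass
class GeneModel:
    """Annotated gene with exon structure and zinc-finger attributes.

    Exons are stored in genomic coordinate order; transcription order is
    genomic order on '+' genes and reversed on '-' genes.
    """

    gene_id: str
    interval: GenomicInterval
    strand: str
    exons: list[GenomicInterval]
    is_c2h2: bool = False
    finger_count: int = 0
    has_krab: bool = False

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ParseError(f"unknown strand symbol: {self.strand!r}")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValidationError(f"{self.gene_id}: exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValidationError(f"{self.gene_id}: exon outside gene bounds")
            if ex.start < prev_end:
                raise ValidationError(f"{self.gene_id}: overlapping/unordered exons")
            prev_end = ex.end
        if not self.is_c2h2 and self.finger_count != 0:
            raise ValidationError(
                f"{self.gene_id}: finger_count must be 0 for non-C2H2 genes"
            )
        if self.finger_count < 0:
            raise ValidationError(f"{self.gene_id}: negative finger_count")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start (bp)."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def final_exon(self) -> GenomicInterval:
        """3'-most exon in transcription order."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

# Heights are printed with %.6g; round-trips are exact to 6 significant digits.
_HEIGHT_FMT = "%.6g"


def read_bed(path, name: str | None = None) -> PeakSet:
    """Read a 3-5 column BED file into a sorted, re-ranked PeakSet.

    The optional 5th column is parsed as the peak height; absent heights
    default to 0. Ranks are recomputed from heights (ties by coordinate).
    """
    intervals: list[GenomicInterval] = []
    heights: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            height = 0.0
            if len(fields) >= 5:
                try:
                    height = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad height") from exc
            intervals.append(GenomicInterval(fields[0], start, end))
            heights.append(height)
    return PeakSet.from_intervals(
        name=name or str(path), intervals=intervals, heights=heights,
        source=f"read_bed({path})",
    )


def write_bed(peakset: PeakSet, path) -> None:
    """Write BED5 lines (chrom, start, end, name, height)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peakset.peaks, 1):
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{peakset.name}_{i}\t{_HEIGHT_FMT % p.height}\n"
            )


# ---------------------------------------------------------------------------
# Array track
# ---------------------------------------------------------------------------

def read_array_track(path, tile_interval: int = 100) -> ArrayTrack:
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad probe row") from exc
            per_chrom.setdefault(fields[0], []).append((start, end, value))
    probes = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        starts, ends, values = zip(*rows)
        probes[chrom] = (np.array(starts), np.array(ends), np.array(values))
    return ArrayTrack(probes=probes, tile_interval=tile_interval)


def write_array_track(track: ArrayTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            starts, ends, values = track.probes[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# Tags
# ---------------------------------------------------------------------------

def read_tags(path) -> TagLibrary:
    chroms, starts, strands = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields")
            if fields[2] not in STRANDS:
                raise ParseError(
                    f"{path}:{lineno}: unknown strand symbol {fields[2]!r}"
                )
            try:
                starts.append(int(fields[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad position") from exc
            chroms.append(fields[0])
            strands.append(fields[2])
    return TagLibrary(
        chroms=np.array(chroms, dtype=object),
        starts=np.array(starts, dtype=np.int64),
        strands=np.array(strands, dtype=object),
    )


def write_tags(lib: TagLibrary, path) -> None:
    with open(path, "w") as fh:
        for c, s, st in zip(lib.chroms, lib.starts, lib.strands):
            fh.write(f"{c}\t{s}\t{st}\n")


# ---------------------------------------------------------------------------
# Gene table
# ---------------------------------------------------------------------------

_GENE_COLS = ("gene_id", "chrom", "strand", "tx_start", "tx_end",
              "exon_starts", "exon_ends")
_ATTR_COLS = ("is_c2h2", "finger_count", "has_krab")


def read_gene_table(path) -> list[GeneModel]:
    """Read a refFlat-style gene table with optional zinc-finger attributes.

    Missing attribute columns default to false/0 with a warning.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for col in _GENE_COLS:
            if col not in header:
                raise ParseError(f"{path}: missing column {col!r}")
        missing_attrs = [c for c in _ATTR_COLS if c not in header]
        if missing_attrs:
            warnings.warn(
                f"{path}: attribute columns {missing_attrs} absent; "
                "defaulting to false/0",
                stacklevel=2,
            )
        idx = {c: header.index(c) for c in header}
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                chrom = fields[idx["chrom"]]
                tx_start = int(fields[idx["tx_start"]])
                tx_end = int(fields[idx["tx_end"]])
                exon_starts = [
                    int(x) for x in fields[idx["exon_starts"]].split(",") if x
                ]
                exon_ends = [
                    int(x) for x in fields[idx["exon_ends"]].split(",") if x
                ]
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: bad gene row") from exc
            if len(exon_starts) != len(exon_ends):
                raise ParseError(f"{path}:{lineno}: exon list length mismatch")
            exons = [
                GenomicInterval(chrom, s, e)
                for s, e in zip(exon_starts, exon_ends)
            ]
            genes.append(
                GeneModel(
                    gene_id=fields[idx["gene_id"]],
                    interval=GenomicInterval(chrom, tx_start, tx_end),
                    strand=fields[idx["strand"]],
                    exons=exons,
                    is_c2h2=(
                        fields[idx["is_c2h2"]] in ("1", "True", "true")
                        if "is_c2h2" in idx else False
                    ),
                    finger_count=(
                        int(fields[idx["finger_count"]])
                        if "finger_count" in idx else 0
                    ),
                    has_krab=(
                        fields[idx["has_krab"]] in ("1", "True", "true")
                        if "has_krab" in idx else False
                    ),
                )
            )
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start))
    return genes


def write_gene_table(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLS + _ATTR_COLS) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.interval.chrom}\t{g.strand}\t"
                f"{g.interval.start}\t{g.interval.end}\t"
                f"{','.join(str(e.start) for e in g.exons)}\t"
                f"{','.join(str(e.end) for e in g.exons)}\t"
                f"{int(g.is_c2h2)}\t{g.finger_count}\t{int(g.has_krab)}\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a genome FASTA into {chrom: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(genome: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")
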