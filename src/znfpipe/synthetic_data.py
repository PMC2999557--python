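"""Synthetic genomes, annotations, array tracks and tag libraries with known truth.

The simulator emulates the data shape of a KRAB-ZNF / H3K9me3 chromatin study:
clustered multi-exon C2H2 zinc-finger genes whose final exons carry tandem
finger/linker coding repeats; a "bound" subset of those genes carries a
canonical 29 bp linker/H2-helix motif inside each repeat; broad enriched
chromatin domains sit over the bound 3' exons, with a sharp site-specific
peak at each domain center. Tiling-array log2 ratios and ChIP/input tag
libraries are sampled from that planted truth, which is returned alongside
every artifact so any caller can be scored for recall and precision.

Randomness: a single master seed; every consumer draws from sub-streams
spawned with numpy's SeedSequence, so all outputs are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from .formats_io import (
    ArrayTrack,
    GeneModel,
    GenomicInterval,
    PeakSet,
    TagLibrary,
    ValidationError,
)

logger = logging.getLogger("znfpipe")

BASES = np.array(["A", "C", "G", "T"])

# Canonical planted 29mer: a fixed packaged sequence standing in for the
# conserved linker / H2-helix coding motif of C2H2 fingers. All downstream
# checks compare against this planted truth, so any fixed 29 bp string works.
CANONICAL_29MER = "TGGAGAAACCCTTTGAGTGTAAAGAATGT"

# Divergent linker used in unbound C2H2 genes: differs from the canonical
# 29mer at 11 fixed positions (>= 8 mismatches guaranteed).
DIVERGENT_29MER = "TCGGGGAACACATTCGACTGAATGGATGA"

_FINGER_UNIT_BP = 84  # one finger + linker coding unit (28 codons)


def _n_mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b, strict=True))


assert _n_mismatches(CANONICAL_29MER, DIVERGENT_29MER) >= 8


@dataclass
class SimConfig:
    """All knobs of the simulation, with defaults matching the study conditions
    at desk scale: one 5 Mb zinc-finger-cluster chromosome, ~2 kb broad domains
    at 5-fold enrichment, 500k ChIP and input tags, 100 bp array tiling."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr19": 5_000_000}
    )
    cluster_chrom: str | None = None  # default: first chromosome (sorted)
    n_genes: int = 120
    frac_c2h2: float = 0.6
    finger_count_distribution: dict[int, float] = field(
        default_factory=lambda: {k: 1.0 for k in range(6, 19)}
    )
    frac_bound: float = 0.5
    domain_width_bp: int = 2_000
    domain_fold: float = 5.0
    sharp_width_bp: int = 200
    sharp_fold: float = 8.0
    array_noise_sd: float = 0.25
    probe_missing_prob: float = 0.05
    tile_interval_bp: int = 100
    probe_length_bp: int = 50
    n_chip_tags: int = 500_000
    n_input_tags: int = 500_000
    fragment_length_bp: int = 150
    motif_mutation_rate: float = 0.10

    def __post_init__(self):
        for name in ("frac_c2h2", "frac_bound", "probe_missing_prob",
                     "motif_mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if self.domain_fold < 1 or self.sharp_fold < 1:
            raise ValidationError("enrichment folds must be >= 1")
        if any(length <= 0 for length in self.chrom_lengths.values()):
            raise ValidationError("chromosome lengths must be positive")
        if self.cluster_chrom is None:
            self.cluster_chrom = sorted(self.chrom_lengths)[0]
        if self.cluster_chrom not in self.chrom_lengths:
            raise ValidationError(
                f"cluster_chrom {self.cluster_chrom!r} not in chrom_lengths"
            )


@dataclass
class TruthSet:
    """Planted truth emitted alongside every simulated artifact."""

    domains: list[tuple[GenomicInterval, float]]
    sharp_sites: list[tuple[GenomicInterval, float]]
    motif_insertions: list[tuple[str, int, str]]  # (gene_id, genomic offset, strand)
    bound_gene_ids: set[str]

    def domain_intervals(self) -> list[GenomicInterval]:
        return [iv for iv, _ in self.domains]

    def sharp_intervals(self) -> list[GenomicInterval]:
        return [iv for iv, _ in self.sharp_sites]


def _rng_for(config: SimConfig, stream: str) -> np.random.Generator:
    """Deterministic named sub-stream of the master seed."""
    digest = hashlib.sha256(stream.encode()).digest()
    key = int.from_bytes(digest[:4], "little") % (2**31)
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(key,))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------

def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hit):
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def make_genome(
    config: SimConfig,
) -> tuple[dict[str, str], list[GeneModel], TruthSet]:
    """Build a genome FASTA dict, gene table and TruthSet.

    Genes are placed in clusters on ``cluster_chrom`` (the zinc-finger-cluster
    chromosome). Each gene has 3 upstream exons plus a final exon of
    ``finger_count`` tandem 84 bp finger/linker units. In bound C2H2 genes the
    unit embeds the canonical 29mer, independently mutated per copy at
    ``motif_mutation_rate``; unbound C2H2 genes carry a divergent linker
    (>= 8 mismatches to the canonical 29mer).
    """
    rng = _rng_for(config, "genome")
    chrom_seqs = {
        chrom: rng.integers(0, 4, size=length)
        for chrom, length in config.chrom_lengths.items()
    }

    n_c2h2 = int(round(config.n_genes * config.frac_c2h2))
    fc_keys = sorted(config.finger_count_distribution)
    fc_w = np.array([config.finger_count_distribution[k] for k in fc_keys], float)
    fc_w /= fc_w.sum()
    finger_counts = rng.choice(fc_keys, size=n_c2h2, p=fc_w)
    n_bound = int(round(n_c2h2 * config.frac_bound))

    genes: list[GeneModel] = []
    domains: list[tuple[GenomicInterval, float]] = []
    sharp_sites: list[tuple[GenomicInterval, float]] = []
    motif_insertions: list[tuple[str, int, str]] = []
    bound_gene_ids: set[str] = set()

    chrom = config.cluster_chrom
    chrom_len = config.chrom_lengths[chrom]
    seq_arr = chrom_seqs[chrom]

    exon_len, intron_len = 150, 500
    genes_per_cluster = 10
    intra_gap, cluster_gap = 2_000, 20_000

    pos = 10_000
    c2h2_i = 0
    for gi in range(config.n_genes):
        gene_id = f"gene{gi:04d}"
        is_c2h2 = gi < n_c2h2  # C2H2 genes first, then the rest
        if is_c2h2:
            fingers = int(finger_counts[c2h2_i])
            bound = c2h2_i < n_bound
            c2h2_i += 1
        else:
            fingers, bound = 0, False
        final_len = fingers * _FINGER_UNIT_BP if is_c2h2 else exon_len
        strand = "+" if rng.random() < 0.5 else "-"

        # genomic layout: 3 short exons, introns, final exon (transcription
        # order; flipped genomically on '-' genes)
        lens = [exon_len, exon_len, exon_len, final_len]
        if strand == "-":
            lens = lens[::-1]
        exon_ivs = []
        p = pos
        for L in lens:
            exon_ivs.append(GenomicInterval(chrom, p, p + L))
            p += L + intron_len
        gene_end = exon_ivs[-1].end
        if gene_end > chrom_len - 10_000:
            raise ValidationError(
                f"genes do not fit in {chrom} ({chrom_len} bp); "
                "reduce n_genes or enlarge the chromosome"
            )
        gene = GeneModel(
            gene_id=gene_id,
            interval=GenomicInterval(chrom, pos, gene_end),
            strand=strand,
            exons=exon_ivs,
            is_c2h2=is_c2h2,
            finger_count=fingers,
            has_krab=bool(is_c2h2 and rng.random() < 0.7),
        )
        genes.append(gene)

        if is_c2h2:
            final = gene.final_exon
            # one finger/linker unit, repeated in tandem; per-gene random
            # scaffold outside the 29 bp linker segment
            scaffold = "".join(BASES[rng.integers(0, 4, _FINGER_UNIT_BP)])
            linker_off = 20  # fixed offset of the 29mer within the unit
            for rep in range(fingers):
                unit = scaffold
                if bound:
                    copy = _mutate(CANONICAL_29MER, config.motif_mutation_rate, rng)
                else:
                    copy = DIVERGENT_29MER
                unit = unit[:linker_off] + copy + unit[linker_off + 29:]
                if strand == "-":
                    genomic_unit = _revcomp(unit)
                    unit_start = final.end - (rep + 1) * _FINGER_UNIT_BP
                    motif_start = unit_start + _FINGER_UNIT_BP - linker_off - 29
                else:
                    genomic_unit = unit
                    unit_start = final.start + rep * _FINGER_UNIT_BP
                    motif_start = unit_start + linker_off
                idx = np.searchsorted(BASES, list(genomic_unit))
                seq_arr[unit_start:unit_start + _FINGER_UNIT_BP] = idx
                if bound:
                    motif_insertions.append((gene_id, int(motif_start), strand))
            if bound:
                bound_gene_ids.add(gene_id)
                center = final.center
                half = config.domain_width_bp // 2
                dom = GenomicInterval(
                    chrom, max(0, center - half), min(chrom_len, center + half)
                )
                domains.append((dom, config.domain_fold))
                sh = config.sharp_width_bp // 2
                sharp_sites.append(
                    (GenomicInterval(chrom, center - sh, center + sh),
                     config.sharp_fold)
                )

        pos = gene_end + (
            cluster_gap if (gi + 1) % genes_per_cluster == 0 else intra_gap
        )

    genome = {c: "".join(BASES[a]) for c, a in chrom_seqs.items()}
    truth = TruthSet(
        domains=domains,
        sharp_sites=sharp_sites,
        motif_insertions=motif_insertions,
        bound_gene_ids=bound_gene_ids,
    )
    logger.info(
        "make_genome: %d genes (%d C2H2, %d bound), %d planted domains",
        len(genes), n_c2h2, len(bound_gene_ids), len(domains),
    )
    return genome, genes, truth


# ---------------------------------------------------------------------------
# Array simulation
# ---------------------------------------------------------------------------

def simulate_array(truth: TruthSet, config: SimConfig) -> ArrayTrack:
    """Tiling-array log2 ratios: log2(domain_fold) plus Gaussian noise over
    planted domains, pure noise elsewhere; probes dropped independently with
    ``probe_missing_prob``. A probe is "inside" a domain when its midpoint is.
    """
    rng = _rng_for(config, "array")
    probes: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, length in sorted(config.chrom_lengths.items()):
        starts = np.arange(0, length - config.probe_length_bp,
                           config.tile_interval_bp, dtype=np.int64)
        ends = starts + config.probe_length_bp
        mids = (starts + ends) // 2
        values = rng.normal(0.0, config.array_noise_sd, size=len(starts))
        for iv, fold in truth.domains:
            if iv.chrom != chrom:
                continue
            inside = (mids >= iv.start) & (mids < iv.end)
            values[inside] += np.log2(fold)
        keep = rng.random(len(starts)) >= config.probe_missing_prob
        probes[chrom] = (starts[keep], ends[keep], values[keep])
    return ArrayTrack(probes=probes, tile_interval=config.tile_interval_bp)


# ---------------------------------------------------------------------------
# Tag simulation
# ---------------------------------------------------------------------------

def _intensity(
    truth: TruthSet, config: SimConfig, channel: str, features: str
) -> dict[str, np.ndarray]:
    """Per-bp fragment-center sampling weights (piecewise constant)."""
    weights = {
        chrom: np.ones(length, dtype=np.float64)
        for chrom, length in config.chrom_lengths.items()
    }
    if channel == "chip":
        feats: list[tuple[GenomicInterval, float]] = []
        if features in ("all", "domains"):
            feats += truth.domains
        if features in ("all", "sharp"):
            feats += truth.sharp_sites
        for iv, fold in feats:
            weights[iv.chrom][iv.start:iv.end] *= fold
    total = sum(float(w.sum()) for w in weights.values())
    if total <= 0:
        raise ValidationError("total sampling intensity is zero")
    return weights


def simulate_tags(
    truth: TruthSet,
    config: SimConfig,
    channel: str = "chip",
    features: str = "all",
    rng: np.random.Generator | None = None,
) -> TagLibrary:
    """Sample a tag library of exactly n_{chip,input}_tags read 5' positions.

    Fragment centers are drawn from a piecewise-constant intensity (uniform
    for the input channel; multiplied by the planted enrichment folds over
    domains and/or sharp sites for ChIP). Each fragment of
    ``fragment_length_bp`` is read from a random end: '+' tags start at the
    fragment's left end (upstream of the center), '-' tags at its right end.
    """
    if channel not in ("chip", "input"):
        raise ValidationError(f"unknown channel {channel!r}")
    if rng is None:
        rng = _rng_for(config, f"tags:{channel}:{features}")
    n_tags = config.n_chip_tags if channel == "chip" else config.n_input_tags
    weights = _intensity(truth, config, channel, features)
    chrom_names = sorted(weights)
    chrom_w = np.array([weights[c].sum() for c in chrom_names])
    per_chrom = rng.multinomial(n_tags, chrom_w / chrom_w.sum())

    frag = config.fragment_length_bp
    all_chroms, all_starts, all_strands = [], [], []
    for chrom, n in zip(chrom_names, per_chrom):
        if n == 0:
            continue
        w = weights[chrom]
        cum = np.cumsum(w)
        u = rng.random(n) * cum[-1]
        centers = np.searchsorted(cum, u, side="right")
        strands = rng.integers(0, 2, size=n)  # 0 = '+', 1 = '-'
        left = centers - frag // 2
        starts = np.where(strands == 0, left, left + frag - 1)
        starts = np.clip(starts, 0, config.chrom_lengths[chrom] - 1)
        all_chroms.append(np.full(n, chrom, dtype=object))
        all_starts.append(starts.astype(np.int64))
        all_strands.append(np.where(strands == 0, "+", "-").astype(object))
    return TagLibrary(
        chroms=np.concatenate(all_chroms) if all_chroms else np.empty(0, object),
        starts=np.concatenate(all_starts) if all_starts else np.empty(0, np.int64),
        strands=np.concatenate(all_strands) if all_strands else np.empty(0, object),
    )


def make_replicates(
    truth: TruthSet,
    config: SimConfig,
    n: int = 2,
    channel: str = "chip",
    features: str = "all",
) -> list[TagLibrary]:
    """Independent tag draws from one intensity — biological replicates."""
    if n < 2:
        raise ValidationError(f"need n >= 2 replicates, got {n}")
    children = np.random.SeedSequence(config.seed).spawn(n)
    return [
        simulate_tags(
            truth, config, channel=channel, features=features,
            rng=np.random.default_rng(child),
        )
        for child in children
    ]


def make_motif_fixture(
    seed: int,
    n_fg: int = 337,
    n_planted: int = 200,
    seq_len: int = 100,
    mutation_rate: float = 0.10,
    n_bg: int = 90,
    bg_len: int = 600,
    motif: str = CANONICAL_29MER,
    edge_margin: int = 5,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], set[str]]:
    """Peak-sequence-shaped motif-discovery fixture with planted truth.

    Returns (fg, bg, planted_ids): ``n_fg`` foreground sequences of
    ``seq_len`` nt, the first ``n_planted`` carrying one copy of ``motif``
    (mutated per position at ``mutation_rate``) at a random offset and
    strand; ``n_bg`` motif-free background sequences of ``bg_len`` nt drawn
    from the same uniform base composition. Peak sequences are extracted
    around peak midpoints, where the binding site is interior to the window;
    copies are therefore planted at least ``edge_margin`` bp from each edge.
    """
    rng = np.random.default_rng(seed)
    fg: list[tuple[str, str]] = []
    planted_ids: set[str] = set()
    for i in range(n_fg):
        seq = "".join(BASES[rng.integers(0, 4, seq_len)])
        sid = f"fg_{i}"
        if i < n_planted:
            copy = _mutate(motif, mutation_rate, rng)
            if rng.random() < 0.5:
                copy = _revcomp(copy)
            off = int(rng.integers(
                edge_margin, seq_len - len(copy) - edge_margin + 1
            ))
            seq = seq[:off] + copy + seq[off + len(copy):]
            planted_ids.add(sid)
        fg.append((sid, seq))
    bg = [
        (f"bg_{j}", "".join(BASES[rng.integers(0, 4, bg_len)]))
        for j in range(n_bg)
    ]
    return fg, bg, planted_ids


# ---------------------------------------------------------------------------
# Scoring against truth
# ---------------------------------------------------------------------------

def score_against_truth(
    called: PeakSet,
    planted: list[GenomicInterval],
    min_jaccard: float = 0.5,
    mode: str = "jaccard",
    max_center_dist: int = 1_000,
) -> dict[str, float]:
    """Per-region recall and precision of a called PeakSet vs planted truth.

    mode="jaccard": a planted region is recovered if some called peak reaches
    Jaccard >= ``min_jaccard`` with it (appropriate for broad domains).
    mode="center": matched when the peak center lies within
    ``max_center_dist`` bp of the planted center (appropriate for point
    sources much narrower than the caller's smoothing footprint).
    """
    if mode == "jaccard":
        def match(p: GenomicInterval, t: GenomicInterval) -> bool:
            return p.jaccard(t) >= min_jaccard
    elif mode == "center":
        def match(p: GenomicInterval, t: GenomicInterval) -> bool:
            return p.chrom == t.chrom and abs(p.center - t.center) <= max_center_dist
    else:
        raise ValidationError(f"unknown scoring mode {mode!r}")
    recovered = sum(
        any(match(p.interval, t) for p in called) for t in planted
    )
    true_pos = sum(
        any(match(p.interval, t) for t in planted) for p in called
    )
    recall = recovered / len(planted) if planted else float("nan")
    precision = true_pos / len(called) if len(called) else float("nan")
    return {
        "n_planted": float(len(planted)),
        "n_called": float(len(called)),
        "recall": recall,
        "precision": precision,
    }


def write_truth(truth: TruthSet, path) -> None:
    """Tab-separated truth manifest (one feature per line)."""
    with open(path, "w") as fh:
        fh.write("kind\tchrom\tstart\tend\tvalue\tstrand\n")
        for iv, fold in truth.domains:
            fh.write(f"domain\t{iv.chrom}\t{iv.start}\t{iv.end}\t{fold}\t.\n")
        for iv, fold in truth.sharp_sites:
            fh.write(f"sharp_site\t{iv.chrom}\t{iv.start}\t{iv.end}\t{fold}\t.\n")
        for gene_id, off, strand in truth.motif_insertions:
            fh.write(f"motif\t{gene_id}\t{off}\t{off + 29}\t.\t{strand}\n")
        for gid in sorted(truth.bound_gene_ids):
            fh.write(f"bound_gene\t{gid}\t.\t.\t.\t.\n")
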