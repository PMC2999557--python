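"""Motif pipeline: peak-sequence extraction, C2H2-3'-exon background
construction, k-mer-seeded PWM discovery with bootstrap-fitted score cutoffs,
core/PWM-score scanning at stringency pairs, genome-wide hit classification,
and reverse-orientation consensus merging.

Motif finding inside zinc-finger 3' exons is confounded: every C2H2 final
exon is built from finger/linker coding repeats, so against a standard
background the coding repeats themselves dominate. The background here is
therefore the set of final exons of C2H2 genes *not* bound in the experiment,
so only motifs enriched in bound versus unbound coding repeats survive.

Scores follow the matrix-library convention: the summed log-probability of a
window is min-max normalized over the worst/best attainable window, for the
whole matrix (PWM score) and for the 5 consecutive most-informative columns
(core score). A stringency pair (core_cut, pwm_cut) like (1.00, 0.95) keeps
windows whose core is a perfect match and whose full-matrix score is >= 0.95.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .formats_io import GeneModel, PeakSet, ValidationError
from .peakset_ops import _overlap_flags
from .formats_io import GenomicInterval

logger = logging.getLogger("znfpipe")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT_ORDER = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT index space
CORE_WIDTH = 5


def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3, anything else -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


# ---------------------------------------------------------------------------
# PWM
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """Position weight matrix over {A,C,G,T} with designated core columns."""

    counts: np.ndarray  # (L, 4) raw aligned counts
    probs: np.ndarray  # (L, 4) pseudocount-adjusted probabilities
    background: np.ndarray  # (4,)
    name: str = "motif"

    core_start: int = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValidationError("PWM probabilities must be (L, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0):
            raise ValidationError("PWM columns must sum to 1")
        if np.any(self.probs <= 0) or np.any(self.probs >= 1):
            raise ValidationError("PWM needs pseudocounts: probs must be in (0,1)")
        if len(self) < CORE_WIDTH:
            raise ValidationError(f"PWM shorter than the {CORE_WIDTH}-column core")
        ic = self.information_content()
        sums = np.convolve(ic, np.ones(CORE_WIDTH), mode="valid")
        self.core_start = int(np.argmax(sums))

    def __len__(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.25,
        name: str = "motif",
    ) -> "PWM":
        counts = np.asarray(counts, dtype=np.float64)
        adj = counts + pseudocount
        probs = adj / adj.sum(axis=1, keepdims=True)
        if background is None:
            background = np.full(4, 0.25)
        return cls(counts=counts, probs=probs,
                   background=np.asarray(background, float), name=name)

    def information_content(self) -> np.ndarray:
        """Per-column Shannon information (2 - entropy), in bits."""
        return 2.0 + (self.probs * np.log2(self.probs)).sum(axis=1)

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            counts=self.counts[::-1, _COMPLEMENT_ORDER],
            probs=self.probs[::-1, _COMPLEMENT_ORDER],
            background=self.background[_COMPLEMENT_ORDER],
            name=f"{self.name}_rc",
        )


@dataclass
class StringencyPair:
    """(core score cutoff, PWM score cutoff), both in [0, 1]."""

    core_cut: float
    pwm_cut: float

    def __post_init__(self):
        for v in (self.core_cut, self.pwm_cut):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"stringency cutoff out of [0,1]: {v}")


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int  # 0-based window start in forward coordinates
    strand: str
    core_score: float
    pwm_score: float


@dataclass
class DiscoveredMotif:
    pwm: PWM
    stringency: StringencyPair
    n_occurrences: int  # foreground sequences with >=1 hit at the fitted cutoffs
    seed_kmers: list[str]


# ---------------------------------------------------------------------------
# Scoring and scanning
# ---------------------------------------------------------------------------

def _window_scores(
    encoded: np.ndarray, log_probs: np.ndarray, cols: slice
) -> np.ndarray:
    """Summed log-prob of every window over the selected matrix columns;
    windows containing a non-ACGT symbol score -inf."""
    lp = log_probs[cols]
    L_full = log_probs.shape[0]
    L = lp.shape[0]
    col0 = cols.start or 0
    n_win = len(encoded) - L_full + 1
    if n_win <= 0:
        return np.empty(0)
    lp5 = np.concatenate([lp, np.full((L, 1), -np.inf)], axis=1)  # col 4 = N
    scores = np.zeros(n_win)
    for i in range(L):
        scores += lp5[i, encoded[col0 + i:col0 + i + n_win]]
    return scores


def _normalized_scores(encoded: np.ndarray, pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """(pwm_scores, core_scores) for all forward windows, min-max normalized."""
    lp = np.log(pwm.probs)
    full = slice(0, len(pwm))
    core = slice(pwm.core_start, pwm.core_start + CORE_WIDTH)

    def norm(cols: slice) -> np.ndarray:
        s = _window_scores(encoded, lp, cols)
        sub = lp[cols]
        smin, smax = sub.min(axis=1).sum(), sub.max(axis=1).sum()
        if smax == smin:
            return np.where(np.isfinite(s), 1.0, -np.inf)
        return (s - smin) / (smax - smin)

    return norm(full), norm(core)


def score_window(seq: str, pwm: PWM, offset: int, strand: str = "+") -> MotifHit:
    """Score one window of ``seq`` at ``offset`` on the given strand."""
    window = seq[offset:offset + len(pwm)]
    if len(window) < len(pwm):
        raise ValidationError("window extends past sequence end")
    if strand == "-":
        window = revcomp(window)
    enc = _encode(window)
    pwm_s, core_s = _normalized_scores(enc, pwm)
    return MotifHit(
        seq_id="", offset=offset, strand=strand,
        core_score=float(core_s[0]), pwm_score=float(pwm_s[0]),
    )


def _strand_scores(encoded: np.ndarray, pwm: PWM):
    """Yield (strand, pwm_scores, core_scores) for forward-coordinate windows."""
    yield ("+",) + _normalized_scores(encoded, pwm)
    yield ("-",) + _normalized_scores(encoded, pwm.reverse_complement())


def best_hit(seq_id: str, seq: str, pwm: PWM) -> MotifHit | None:
    """Highest-PWM-score window over both strands; ties prefer the smaller
    offset and then the '+' strand. None if no scorable window exists."""
    if len(seq) < len(pwm):
        raise ValidationError("sequence shorter than the matrix")
    enc = _encode(seq)
    best: MotifHit | None = None
    for strand in ("+", "-"):
        p = pwm if strand == "+" else pwm.reverse_complement()
        pwm_s, core_s = _normalized_scores(enc, p)
        if pwm_s.size == 0 or not np.isfinite(pwm_s).any():
            continue
        off = int(np.nanargmax(np.where(np.isfinite(pwm_s), pwm_s, -np.inf)))
        cand = MotifHit(seq_id, off, strand, float(core_s[off]), float(pwm_s[off]))
        if best is None or cand.pwm_score > best.pwm_score or (
            cand.pwm_score == best.pwm_score and cand.offset < best.offset
        ):
            best = cand
    return best


def scan_sequences(
    seqs: dict[str, str] | list[tuple[str, str]],
    pwm: PWM,
    stringency: StringencyPair,
) -> list[MotifHit]:
    """All windows (both strands) with core_score >= core_cut and
    pwm_score >= pwm_cut; overlapping hits are allowed."""
    items = seqs.items() if isinstance(seqs, dict) else seqs
    hits: list[MotifHit] = []
    for seq_id, seq in items:
        if len(seq) < len(pwm):
            continue
        enc = _encode(seq)
        for strand, pwm_s, core_s in _strand_scores(enc, pwm):
            keep = np.flatnonzero(
                (core_s >= stringency.core_cut) & (pwm_s >= stringency.pwm_cut)
            )
            hits.extend(
                MotifHit(seq_id, int(o), strand,
                         float(core_s[o]), float(pwm_s[o]))
                for o in keep
            )
    hits.sort(key=lambda h: (h.seq_id, h.offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Sequence extraction and background construction
# ---------------------------------------------------------------------------

def extract_peak_sequences(
    peaks: PeakSet, genome: dict[str, str], halfwidth: int = 50
) -> list[tuple[str, str]]:
    """The [mid - halfwidth, mid + halfwidth) forward-strand substring around
    each peak midpoint; peaks too close to a contig edge are skipped."""
    out = []
    n_skipped = 0
    for i, p in enumerate(peaks.by_rank(), 1):
        chrom = p.interval.chrom
        if chrom not in genome:
            raise ValidationError(f"chromosome {chrom!r} absent from genome")
        mid = p.interval.center
        lo, hi = mid - halfwidth, mid + halfwidth
        if lo < 0 or hi > len(genome[chrom]):
            n_skipped += 1
            continue
        out.append((f"peak_{i}", genome[chrom][lo:hi]))
    if n_skipped:
        warnings.warn(
            f"{n_skipped} peak(s) skipped: window extends past a contig edge",
            stacklevel=2,
        )
    return out


def build_background_set(
    genes: list[GeneModel], peaks: PeakSet, genome: dict[str, str]
) -> list[tuple[str, str]]:
    """Final-exon sequences of C2H2 genes whose body intersects no peak."""
    peak_ivs = [p.interval for p in peaks]
    c2h2 = [g for g in genes if g.is_c2h2]
    flags = _overlap_flags([g.interval for g in c2h2], peak_ivs)
    out = []
    for g, bound in zip(c2h2, flags):
        if bound:
            continue
        fe = g.final_exon
        if fe.chrom not in genome:
            raise ValidationError(f"chromosome {fe.chrom!r} absent from genome")
        seq = genome[fe.chrom][fe.start:fe.end]
        if g.strand == "-":
            seq = revcomp(seq)
        out.append((g.gene_id, seq))
    if not out:
        raise ValidationError(
            "no unbound C2H2 gene available for the background set; "
            "a larger annotation is needed"
        )
    return out


# ---------------------------------------------------------------------------
# De novo discovery
# ---------------------------------------------------------------------------

def _window_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer code of every k-window; -1 where the window has a
    non-ACGT symbol."""
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for i in range(k):
        b = enc[i:i + n].astype(np.int64)
        codes = codes * 4 + np.where(b < 4, b, 0)
        bad |= b == 4
    codes[bad] = -1
    return codes


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def _kmer_counts(seqs: list[str], k: int) -> tuple[dict[int, int], int]:
    """Strand-combined k-mer code counts and the number of valid windows
    (both strands)."""
    all_codes = []
    for seq in seqs:
        for s in (seq, revcomp(seq)):
            all_codes.append(_window_codes(_encode(s), k))
    if not all_codes:
        return {}, 0
    codes = np.concatenate(all_codes)
    codes = codes[codes >= 0]
    uniq, n = np.unique(codes, return_counts=True)
    return dict(zip(uniq.tolist(), n.tolist())), int(codes.size)


def _occurrences(seqs: list[str], kmer: str) -> list[tuple[int, int, str]]:
    """(seq index, offset, strand) of every match of ``kmer`` on either strand
    (forward coordinates)."""
    k = len(kmer)
    code = int(_window_codes(_encode(kmer), k)[0])
    rc = revcomp(kmer)
    rc_code = int(_window_codes(_encode(rc), k)[0])
    occ = []
    for si, seq in enumerate(seqs):
        codes = _window_codes(_encode(seq), k)
        for i in np.flatnonzero(codes == code):
            occ.append((si, int(i), "+"))
        if rc_code != code:
            for i in np.flatnonzero(codes == rc_code):
                occ.append((si, int(i), "-"))
    return occ


def _bg_nucleotide_freqs(bg_seqs: list[str]) -> np.ndarray:
    counts = np.zeros(4)
    for seq in bg_seqs:
        enc = _encode(seq)
        for b in range(4):
            counts[b] += int((enc == b).sum())
    total = counts.sum()
    return counts / total if total else np.full(4, 0.25)


def _column_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Mean per-column Pearson correlation of two aligned (n, 4) prob blocks."""
    corrs = []
    for ca, cb in zip(a, b):
        sa, sb = ca - ca.mean(), cb - cb.mean()
        na, nb = np.linalg.norm(sa), np.linalg.norm(sb)
        if na < 1e-12 or nb < 1e-12:
            corrs.append(1.0 if na < 1e-12 and nb < 1e-12 else 0.0)
        else:
            corrs.append(float(sa @ sb / (na * nb)))
    return float(np.mean(corrs))


def _try_merge_pair(
    a: "_Candidate", b: "_Candidate", min_corr: float, min_overlap: int = 4
) -> "_Candidate | None":
    """Merge b (either orientation) into a at the longest ungapped alignment
    whose mean per-column correlation reaches ``min_corr``; None otherwise.

    Among qualifying alignments the longest overlap wins (ties by
    correlation): a short chance overlap must not preempt the true extended
    alignment of two fragments of one motif.
    """
    best = None  # (overlap, corr, orientation counts, shift)
    la = len(a.counts)
    pa = (a.counts + 0.25) / (a.counts + 0.25).sum(axis=1, keepdims=True)
    for counts_b in (b.counts, b.counts[::-1, _COMPLEMENT_ORDER]):
        lb = len(counts_b)
        pb = (counts_b + 0.25) / (counts_b + 0.25).sum(axis=1, keepdims=True)
        for shift in range(-(lb - min_overlap), la - min_overlap + 1):
            lo, hi = max(0, shift), min(la, shift + lb)
            if hi - lo < min_overlap:
                continue
            corr = _column_correlation(pa[lo:hi], pb[lo - shift:hi - shift])
            if corr < min_corr:
                continue
            key = (hi - lo, corr)
            if best is None or key > best[:2]:
                best = (hi - lo, corr, counts_b, shift)
    if best is None:
        return None
    _, _, counts_b, shift = best
    lb = len(counts_b)
    lo, hi = min(0, shift), max(la, shift + lb)
    merged = np.zeros((hi - lo, 4))
    merged[-lo:len(a.counts) - lo] += a.counts
    merged[shift - lo:shift - lo + lb] += counts_b
    # the longer (more specific) seed defines the clean occurrence list
    primary = max(
        (a, b), key=lambda c: (len(c.seed_kmers[0]), len(c.primary_seq_indices))
    ).primary_seq_indices
    return _Candidate(
        counts=merged,
        seed_kmers=sorted(
            a.seed_kmers + b.seed_kmers, key=lambda s: -len(s)
        ),
        seq_indices=a.seq_indices | b.seq_indices,
        primary_seq_indices=primary,
    )


@dataclass
class _Candidate:
    counts: np.ndarray
    seed_kmers: list[str]
    seq_indices: set[int]
    primary_seq_indices: set[int]


def discover_motifs(
    fg: list[tuple[str, str]],
    bg: list[tuple[str, str]],
    k_range: range = range(6, 13),
    seed: int = 0,
    max_rounds: int = 30,
    p_threshold: float = 1e-6,
    min_count: int = 3,
    flank: int = 3,
    merge_corr: float = 0.8,
    n_bootstrap: int = 100,
    pseudocount: float = 0.25,
) -> list[DiscoveredMotif]:
    """k-mer-seeded PWM discovery against an explicit background set.

    Rounds: (1) count every k-mer (both strands) in foreground and background;
    (2) score enrichment with a one-sided binomial test of foreground
    occurrences against the background per-position rate, Bonferroni-corrected
    over 4^k; (3) take the top k-mer passing ``p_threshold``, align its
    foreground occurrences with +/-``flank`` bp flanks into a pseudocount-PWM,
    mask the occurrences, repeat. Discovered PWMs whose best ungapped
    alignment (either orientation) reaches mean per-column Pearson correlation
    >= ``merge_corr`` are merged over their union span. Score cutoffs are the
    bootstrap 5th-percentile core/PWM scores of the occurrence-bearing
    foreground sequences re-scanned with the final matrix.

    Deterministic for a fixed seed; returns [] when nothing is enriched.
    """
    if not fg or not bg:
        raise ValidationError("discover_motifs requires non-empty fg and bg")
    rng = np.random.default_rng(seed)
    fg_ids = [sid for sid, _ in fg]
    fg_orig = [seq.upper() for _, seq in fg]
    fg_work = list(fg_orig)
    bg_seqs = [seq.upper() for _, seq in bg]
    background = _bg_nucleotide_freqs(bg_seqs)

    bg_counts = {k: _kmer_counts(bg_seqs, k) for k in k_range}

    candidates: list[_Candidate] = []
    for _ in range(max_rounds):
        best = None  # (adjusted p, -count, k, code)
        for k in k_range:
            fg_k, n_fg_windows = _kmer_counts(fg_work, k)
            bgc, n_bg_windows = bg_counts[k]
            if n_fg_windows == 0:
                continue
            codes = np.array(sorted(fg_k), dtype=np.int64)
            ns = np.array([fg_k[c] for c in codes.tolist()])
            keep = ns >= min_count
            codes, ns = codes[keep], ns[keep]
            if codes.size == 0:
                continue
            # The bg rate is estimated from a finite window count; flooring it
            # at the bg base-composition rate of the k-mer keeps sampling
            # noise in rare bg k-mers from fabricating enrichment.
            log_bg = np.log(background)
            comp_rate = np.array(
                [
                    math.exp(sum(log_bg[int(d)] for d in _encode(_decode(int(c), k))))
                    for c in codes
                ]
            )
            p_bg = np.maximum(
                np.array(
                    [(bgc.get(int(c), 0) + 0.5) / (n_bg_windows + 1.0) for c in codes]
                ),
                comp_rate,
            )
            p_raw = stats.binom.sf(ns - 1, n_fg_windows, p_bg)
            p_adj = np.minimum(1.0, p_raw * 4.0 ** k)
            for c, n, p in zip(codes.tolist(), ns.tolist(), p_adj.tolist()):
                key = (p, -n, k, c)
                if p <= p_threshold and (best is None or key < best):
                    best = key
        if best is None:
            break
        _, _, k, code = best
        kmer = _decode(code, k)
        occ = _occurrences(fg_work, kmer)
        counts = np.zeros((k + 2 * flank, 4))
        seq_indices = set()
        for si, off, strand in occ:
            lo, hi = off - flank, off + k + flank
            if lo < 0 or hi > len(fg_work[si]):
                continue
            window = fg_work[si][lo:hi]
            if strand == "-":
                window = revcomp(window)
            enc = _encode(window)
            for pos, b in enumerate(enc):
                if b < 4:
                    counts[pos, b] += 1
            seq_indices.add(si)
        # mask the seed occurrences so later rounds find the flanking signal
        for si, off, _ in occ:
            s = fg_work[si]
            fg_work[si] = s[:off] + "N" * k + s[off + k:]
        if counts.sum() == 0:
            continue
        candidates.append(
            _Candidate(
                counts=counts,
                seed_kmers=[kmer],
                seq_indices=seq_indices,
                primary_seq_indices=set(seq_indices),
            )
        )

    if not candidates:
        return []

    # greedy merging of similar candidates into longer matrices
    merged = True
    while merged and len(candidates) > 1:
        merged = False
        for i in range(len(candidates)):
            for j in range(i + 1, len(candidates)):
                m = _try_merge_pair(candidates[i], candidates[j], merge_corr)
                if m is not None:
                    candidates = [
                        c for idx, c in enumerate(candidates) if idx not in (i, j)
                    ] + [m]
                    merged = True
                    break
            if merged:
                break

    motifs: list[DiscoveredMotif] = []
    for ci, cand in enumerate(candidates):
        pwm = PWM.from_counts(
            cand.counts, background=background, pseudocount=pseudocount,
            name=f"motif_{ci + 1}",
        )
        # Cutoff fitting: the background set is the negative control — a
        # foreground sequence is treated as motif-positive when its best hit
        # outscores every background sequence's best hit. The stringency pair
        # is the bootstrap 5th percentile of the positives' core/PWM scores,
        # so a scan at the fitted cutoffs recovers ~95% of comparable sites.
        bg_hits = [
            best_hit("", s, pwm) for s in bg_seqs if len(s) >= len(pwm)
        ]
        bg_best = max(
            (h.pwm_score for h in bg_hits if h is not None), default=0.0
        )
        fg_hits = [
            best_hit("", s, pwm) for s in fg_orig if len(s) >= len(pwm)
        ]
        positives = [
            h for h in fg_hits if h is not None and h.pwm_score >= bg_best
        ]
        if not positives:
            occ_seqs = [
                fg_orig[si] for si in sorted(cand.primary_seq_indices)
                if len(fg_orig[si]) >= len(pwm)
            ]
            positives = [
                h for h in (best_hit("", s, pwm) for s in occ_seqs)
                if h is not None
            ]
        if not positives:
            continue
        pwm_scores = np.array([h.pwm_score for h in positives])
        core_scores = np.array([h.core_score for h in positives])
        boot_p, boot_c = [], []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, len(pwm_scores), size=len(pwm_scores))
            cc, cp = _joint_cutoffs(core_scores[idx], pwm_scores[idx])
            boot_c.append(cc)
            boot_p.append(cp)
        stringency = StringencyPair(
            core_cut=float(np.clip(np.mean(boot_c), 0, 1)),
            pwm_cut=float(np.clip(np.mean(boot_p), 0, 1)),
        )
        with_hit = sum(
            1
            for _, seq in zip(fg_ids, fg_orig)
            if len(seq) >= len(pwm)
            and _has_hit(seq, pwm, stringency)
        )
        motifs.append(
            DiscoveredMotif(
                pwm=pwm,
                stringency=stringency,
                n_occurrences=with_hit,
                seed_kmers=cand.seed_kmers,
            )
        )
    motifs.sort(key=lambda m: -m.n_occurrences)
    logger.info(
        "discover_motifs: %d motifs (occurrences: %s)",
        len(motifs), [m.n_occurrences for m in motifs],
    )
    return motifs


def _joint_cutoffs(
    core_scores: np.ndarray, pwm_scores: np.ndarray, coverage: float = 0.95
) -> tuple[float, float]:
    """Largest marginal percentile whose (core, PWM) cutoff pair jointly
    admits ``coverage`` of the scored occurrences. The two 5th-percentile
    tails only partly overlap, so cutting both marginals at 5% would reject
    more than 5% of true sites; the percentile is relaxed until the pair
    passes the target coverage."""
    for t in np.linspace(5.0, 0.0, 51):
        cc = float(np.percentile(core_scores, t))
        cp = float(np.percentile(pwm_scores, t))
        if np.mean((core_scores >= cc) & (pwm_scores >= cp)) >= coverage:
            return cc, cp
    return float(core_scores.min()), float(pwm_scores.min())


def _has_hit(seq: str, pwm: PWM, stringency: StringencyPair) -> bool:
    enc = _encode(seq)
    for _, pwm_s, core_s in _strand_scores(enc, pwm):
        if np.any((core_s >= stringency.core_cut) & (pwm_s >= stringency.pwm_cut)):
            return True
    return False


# ---------------------------------------------------------------------------
# Hit classification and reverse-orientation merging
# ---------------------------------------------------------------------------

def classify_hits(
    hits: list[MotifHit],
    genes: list[GeneModel],
    motif_length: int,
    window_bp: int = 1_000,
) -> tuple[int, int, float | None]:
    """(n hits at a C2H2 gene, n total, fraction). A hit is "at" a ZNF gene
    when its window intersects the gene body extended by ``window_bp`` on each
    side; hit seq_ids are chromosome names. Fraction is None when there are
    no hits."""
    if not hits:
        return 0, 0, None
    extended = [
        GenomicInterval(
            g.interval.chrom,
            max(0, g.interval.start - window_bp),
            g.interval.end + window_bp,
        )
        for g in genes
        if g.is_c2h2
    ]
    queries = [
        GenomicInterval(h.seq_id, h.offset, h.offset + motif_length) for h in hits
    ]
    flags = _overlap_flags(queries, extended)
    n_at = sum(flags)
    return n_at, len(hits), n_at / len(hits)


def merge_reverse_oriented(
    pwm_a: PWM,
    pwm_b: PWM,
    min_overlap: int = 4,
    min_identity: float = 0.9,
) -> str | None:
    """Merge two motifs whose consensi overlap in reverse orientation.

    Slides the reverse-complement of consensus(A) against consensus(B) over
    every ungapped offset with overlap >= ``min_overlap``; at the
    largest-overlap offset whose overlap identity reaches ``min_identity``,
    returns the union-span consensus (length LB + LA - overlap for
    end-to-end arrangements). Returns None when no offset qualifies.
    """
    cons_b = pwm_b.consensus
    rc_a = revcomp(pwm_a.consensus)
    lb, la = len(cons_b), len(rc_a)
    best = None  # (overlap, shift)
    for shift in range(-(la - min_overlap), lb - min_overlap + 1):
        lo, hi = max(0, shift), min(lb, shift + la)
        overlap = hi - lo
        if overlap < min_overlap:
            continue
        matches = sum(
            cons_b[i] == rc_a[i - shift] for i in range(lo, hi)
        )
        if matches / overlap >= min_identity:
            if best is None or overlap > best[0]:
                best = (overlap, shift)
    if best is None:
        return None
    _, shift = best
    lo, hi = min(0, shift), max(lb, shift + la)
    out = []
    for pos in range(lo, hi):
        if 0 <= pos < lb:
            out.append(cons_b[pos])
        else:
            out.append(rc_a[pos - shift])
    return "".join(out)


# ---------------------------------------------------------------------------
# TRANSFAC-like PWM text format
# ---------------------------------------------------------------------------

def write_pwm(pwm: PWM, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ID {pwm.name}\nP0\tA\tC\tG\tT\n")
        for i, row in enumerate(pwm.counts, 1):
            fh.write(f"{i:02d}\t" + "\t".join(f"{v:g}" for v in row) + "\n")
        fh.write("//\n")


def read_pwm(path, background: np.ndarray | None = None) -> PWM:
    counts, name = [], "motif"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("ID"):
                name = line.split(None, 1)[1]
            elif line[:2].isdigit():
                counts.append([float(x) for x in line.split("\t")[1:5]])
    if not counts:
        raise ValidationError(f"{path}: no matrix rows found")
    return PWM.from_counts(np.array(counts), background=background, name=name)
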