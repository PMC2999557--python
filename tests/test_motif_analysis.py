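import numpy as np
import pytest

from znfpipe import (
    PWM,
    GeneModel,
    GenomicInterval,
    PeakSet,
    StringencyPair,
    ValidationError,
    best_hit,
    build_background_set,
    classify_hits,
    discover_motifs,
    extract_peak_sequences,
    merge_reverse_oriented,
    read_pwm,
    revcomp,
    scan_sequences,
    score_window,
    write_pwm,
)
from znfpipe.synthetic_data import CANONICAL_29MER, make_motif_fixture

BASES = "ACGT"


def pwm_from_consensus(consensus, strength=20.0, name="m"):
    counts = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        counts[i, BASES.index(b)] = strength
    return PWM.from_counts(counts, name=name)


def brute_best_hit(seq, pwm):
    """Exhaustive both-strand scan with direct per-window scoring (oracle)."""
    L = len(pwm)
    lp = np.log(pwm.probs)
    smin, smax = lp.min(axis=1).sum(), lp.max(axis=1).sum()
    best = None
    for strand in "+-":
        for off in range(len(seq) - L + 1):
            w = seq[off:off + L]
            if strand == "-":
                w = revcomp(w)
            if set(w) - set(BASES):
                continue
            s = sum(lp[i, BASES.index(w[i])] for i in range(L))
            score = (s - smin) / (smax - smin)
            key = (-score, off, strand)
            if best is None or key < best[0]:
                best = (key, off, strand, score)
    return best[1:]


class TestScoring:
    def test_consensus_scores_one(self, rng):
        cons = "".join(rng.choice(list(BASES), 12))
        pwm = pwm_from_consensus(cons)
        hit = score_window(cons, pwm, 0)
        assert hit.pwm_score == pytest.approx(1.0)
        assert hit.core_score == pytest.approx(1.0)

    def test_worst_sequence_scores_zero(self):
        pwm = pwm_from_consensus("ACGTACGTAC")
        worst = "".join(
            BASES[int(np.argmin(col))] for col in pwm.probs
        )
        hit = score_window(worst, pwm, 0)
        assert hit.pwm_score == pytest.approx(0.0)

    def test_best_hit_matches_exhaustive_scan(self, rng):
        pwm = pwm_from_consensus("TGGAGAAACCCT", strength=8)
        seq = "".join(rng.choice(list(BASES), 2_000))
        got = best_hit("s", seq, pwm)
        off, strand, score = brute_best_hit(seq, pwm)
        assert (got.offset, got.strand) == (off, strand)
        assert got.pwm_score == pytest.approx(score)

    def test_non_acgt_window_skipped(self):
        pwm = pwm_from_consensus("ACGTA")
        hit = best_hit("s", "NNNNNACGTA", pwm)
        assert hit.offset == 5 and hit.pwm_score == pytest.approx(1.0)

    def test_reverse_complement_mirror_property(self, rng):
        """Scanning a sequence and its reverse complement gives mirror hits."""
        pwm = pwm_from_consensus("TGGAGAAACC", strength=6)
        seq = "".join(rng.choice(list(BASES), 500))
        st = StringencyPair(0.0, 0.7)
        fwd = scan_sequences([("s", seq)], pwm, st)
        rev = scan_sequences([("s", revcomp(seq))], pwm, st)
        L = len(pwm)
        mirrored = {
            (len(seq) - L - h.offset, "+-"[h.strand == "+"], round(h.pwm_score, 9))
            for h in rev
        }
        assert {
            (h.offset, h.strand, round(h.pwm_score, 9)) for h in fwd
        } == mirrored


class TestScan:
    def test_planted_exact_copies_found(self, rng):
        cons = "TGGAGAAACCCT"
        pwm = pwm_from_consensus(cons)
        seq = "".join(rng.choice(list(BASES), 1_000))
        offs = [100, 400, 800]
        for o in offs:
            seq = seq[:o] + cons + seq[o + len(cons):]
        hits = scan_sequences([("s", seq)], pwm, StringencyPair(1.0, 0.95))
        found = {h.offset for h in hits if h.strand == "+"}
        assert set(offs) <= found

    def test_high_stringency_hits_subset_of_low(self, rng):
        pwm = pwm_from_consensus("TGGAGAAACC", strength=5)
        seqs = [("s", "".join(rng.choice(list(BASES), 3_000)))]
        strict = scan_sequences(seqs, pwm, StringencyPair(1.00, 0.99))
        loose = scan_sequences(seqs, pwm, StringencyPair(1.00, 0.95))
        assert set(map(tuple.__call__, map(lambda h: (h.seq_id, h.offset, h.strand), strict))) <= set(
            map(lambda h: (h.seq_id, h.offset, h.strand), loose)
        )

    def test_empty_sequence_list(self):
        pwm = pwm_from_consensus("ACGTT")
        assert scan_sequences([], pwm, StringencyPair(0.5, 0.5)) == []


class TestExtractionAndBackground:
    def test_extracted_windows_are_100nt_genome_slices(self, rng):
        genome = {"chr1": "".join(rng.choice(list(BASES), 10_000))}
        peaks = PeakSet.from_intervals(
            "p", [GenomicInterval("chr1", 2_000, 2_400),
                  GenomicInterval("chr1", 5_000, 5_100)]
        )
        seqs = extract_peak_sequences(peaks, genome, halfwidth=50)
        assert all(len(s) == 100 for _, s in seqs)
        mid = (2_000 + 2_400) // 2
        assert seqs[0][1] in (genome["chr1"][mid - 50:mid + 50],
                              genome["chr1"][5_000:5_100])

    def test_edge_peak_skipped_with_warning(self, rng):
        genome = {"chr1": "".join(rng.choice(list(BASES), 1_000))}
        peaks = PeakSet.from_intervals("p", [GenomicInterval("chr1", 0, 40)])
        with pytest.warns(UserWarning, match="skipped"):
            assert extract_peak_sequences(peaks, genome) == []

    def test_background_excludes_bound_and_non_c2h2(self, rng):
        genome = {"chr1": "".join(rng.choice(list(BASES), 20_000))}
        def g(gid, start, c2h2):
            return GeneModel(
                gid, GenomicInterval("chr1", start, start + 1_000), "+",
                [GenomicInterval("chr1", start, start + 200),
                 GenomicInterval("chr1", start + 600, start + 1_000)],
                is_c2h2=c2h2, finger_count=5 if c2h2 else 0,
            )
        genes = [g("bound", 0, True), g("free", 5_000, True), g("plain", 10_000, False)]
        peaks = PeakSet.from_intervals("p", [GenomicInterval("chr1", 100, 300)])
        bg = build_background_set(genes, peaks, genome)
        assert [gid for gid, _ in bg] == ["free"]
        assert bg[0][1] == genome["chr1"][5_600:6_000]

    def test_no_eligible_background_rejected(self, rng):
        genome = {"chr1": "".join(rng.choice(list(BASES), 2_000))}
        genes = [
            GeneModel("b", GenomicInterval("chr1", 0, 1_000), "+",
                      [GenomicInterval("chr1", 0, 1_000)], is_c2h2=True,
                      finger_count=3)
        ]
        peaks = PeakSet.from_intervals("p", [GenomicInterval("chr1", 100, 300)])
        with pytest.raises(ValidationError, match="larger annotation"):
            build_background_set(genes, peaks, genome)


class TestDiscovery:
    def test_same_seed_reproduces_motifs_and_cutoffs(self):
        fg, bg, _ = make_motif_fixture(seed=2, n_fg=80, n_planted=50, n_bg=30,
                                       bg_len=300)
        m1 = discover_motifs(fg, bg, seed=9)
        m2 = discover_motifs(fg, bg, seed=9)
        assert len(m1) == len(m2) >= 1
        for a, b in zip(m1, m2):
            np.testing.assert_array_equal(a.pwm.probs, b.pwm.probs)
            assert a.stringency == b.stringency
            assert a.n_occurrences == b.n_occurrences

    def test_planted_motif_recovered_small_scale(self):
        fg, bg, planted = make_motif_fixture(seed=4, n_fg=80, n_planted=50,
                                             n_bg=30, bg_len=300)
        motifs = discover_motifs(fg, bg, seed=4)
        top = motifs[0]
        # consensus aligns to the planted 29mer in one orientation: at least
        # 80% of the alignable columns match
        best = 0
        for c in (top.pwm.consensus, revcomp(top.pwm.consensus)):
            for shift in range(-len(c) + 1, 29):
                best = max(best, sum(
                    1 for i in range(29)
                    if 0 <= i - shift < len(c) and c[i - shift] == CANONICAL_29MER[i]
                ))
        assert best >= 0.8 * min(29, len(top.pwm))

    def test_null_foreground_finds_nothing(self):
        fg, bg, _ = make_motif_fixture(seed=6, n_fg=80, n_planted=0, n_bg=30,
                                       bg_len=300)
        assert discover_motifs(fg, bg, seed=6) == []

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValidationError):
            discover_motifs([], [("b", "ACGT" * 10)], seed=0)


class TestClassifyHits:
    def make_genes(self):
        return [
            GeneModel("z", GenomicInterval("chr1", 10_000, 12_000), "+",
                      [GenomicInterval("chr1", 10_000, 12_000)],
                      is_c2h2=True, finger_count=4),
        ]

    def test_all_hits_inside_gene_bodies(self):
        from znfpipe import MotifHit
        hits = [MotifHit("chr1", 10_500 + i * 100, "+", 1.0, 1.0) for i in range(5)]
        n_at, n_total, frac = classify_hits(hits, self.make_genes(), motif_length=29)
        assert (n_at, n_total, frac) == (5, 5, 1.0)

    def test_no_genes_gives_zero_fraction(self):
        from znfpipe import MotifHit
        hits = [MotifHit("chr1", 100, "+", 1.0, 1.0)]
        assert classify_hits(hits, [], motif_length=29) == (0, 1, 0.0)

    def test_no_hits_is_undefined(self):
        assert classify_hits([], self.make_genes(), motif_length=29) == (0, 0, None)

    def test_window_extension_counts_flanking_hit(self):
        from znfpipe import MotifHit
        near = [MotifHit("chr1", 9_200, "+", 1.0, 1.0)]  # 800 bp upstream
        n_at, _, _ = classify_hits(near, self.make_genes(), motif_length=29,
                                   window_bp=1_000)
        assert n_at == 1
        far = [MotifHit("chr1", 8_000, "+", 1.0, 1.0)]
        n_at, _, _ = classify_hits(far, self.make_genes(), motif_length=29,
                                   window_bp=1_000)
        assert n_at == 0


class TestMerge:
    def test_seventeen_plus_eighteen_merge_to_29(self):
        """An 18-mer whose 3' end equals the 5' end of the reverse orientation
        of a 17-mer reconstructs the full 29 bp consensus (18 + 17 - 6)."""
        target = CANONICAL_29MER
        cons_b = target[:18]
        cons_a = revcomp(target[12:])  # 17-mer; revcomp(A) = target[12:29]
        merged = merge_reverse_oriented(
            pwm_from_consensus(cons_a, name="A"),
            pwm_from_consensus(cons_b, name="B"),
        )
        assert merged == target
        assert len(merged) == 29

    def test_self_reverse_complement_full_overlap(self):
        cons_b = "TGGAGAAACCCTTTGAGT"
        a = pwm_from_consensus(revcomp(cons_b))
        merged = merge_reverse_oriented(a, pwm_from_consensus(cons_b))
        assert merged == cons_b

    @staticmethod
    def brute_qualifies(cons_a, cons_b, min_ov=6, min_id=0.9):
        """Independent check: any ungapped reverse-orientation overlap of
        length >= min_ov with identity >= min_id?"""
        rc_a = revcomp(cons_a)
        lb, la = len(cons_b), len(rc_a)
        for shift in range(-(la - min_ov), lb - min_ov + 1):
            lo, hi = max(0, shift), min(lb, shift + la)
            if hi - lo < min_ov:
                continue
            matches = sum(cons_b[i] == rc_a[i - shift] for i in range(lo, hi))
            if matches / (hi - lo) >= min_id:
                return True
        return False

    def test_random_consensi_merge_iff_overlap_exists(self, rng):
        """Random pairs merge exactly when the brute-force predicate finds a
        qualifying reverse-orientation overlap (almost always: none)."""
        outcomes = []
        for _ in range(20):
            ca = "".join(rng.choice(list(BASES), 15))
            cb = "".join(rng.choice(list(BASES), 15))
            merged = merge_reverse_oriented(
                pwm_from_consensus(ca), pwm_from_consensus(cb), min_overlap=6
            )
            assert (merged is not None) == self.brute_qualifies(ca, cb)
            outcomes.append(merged)
        # the identity threshold is unmet with overwhelming probability
        assert outcomes.count(None) >= 18


class TestPwmIO:
    def test_round_trip(self, tmp_path, rng):
        counts = rng.integers(0, 30, size=(12, 4)).astype(float)
        pwm = PWM.from_counts(counts, name="m7")
        path = tmp_path / "m.pwm"
        write_pwm(pwm, path)
        back = read_pwm(path)
        assert back.name == "m7"
        np.testing.assert_allclose(back.counts, counts)
        assert back.consensus == pwm.consensus
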