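"""SSR scanning, repeat-pair finding, plastome structure, identity."""

import numpy as np
import pytest

from genomeskim.records import SequenceRecord, revcomp
from genomeskim.repeats import (
    DEFAULT_MIN_UNITS,
    classify_vs_repeat_library,
    detect_quadripartite,
    find_repeats,
    pairwise_identity,
    scan_ssrs,
    ssr_primer_feasibility,
)
from genomeskim.simulate import ReadSimParams, simulate_reads


def _rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _min_period(motif):
    for q in range(1, len(motif) + 1):
        if all(motif[i] == motif[i - q] for i in range(q, len(motif))):
            return q
    return len(motif)


def ssr_oracle(seq: str, min_units=DEFAULT_MIN_UNITS):
    """Brute-force enumeration of maximal perfect tandem repeats.

    Independent of the scanner: every (start, period) is tested literally
    for left-maximality and full-unit count.
    """
    out = set()
    L = len(seq)
    for p, need in min_units.items():
        for start in range(L - 2 * p + 1):
            motif = seq[start : start + p]
            if "N" in motif or _min_period(motif) != p:
                continue
            # left-maximal: the periodic region cannot extend one base left
            if start > 0 and start - 1 + p < L and seq[start - 1] == seq[start - 1 + p]:
                continue
            n = 0
            while seq[start + n * p : start + (n + 1) * p] == motif:
                n += 1
            if n >= need:
                out.add((start, start + n * p, motif, n))
    return out


class TestScanSsrs:
    def test_dinucleotide_locus_with_flanks(self):
        rng = np.random.default_rng(70)
        left, right = _rand_seq(rng, 80), _rand_seq(rng, 80)
        # guard flanks so the planted run stays maximal
        contig = SequenceRecord("c", left + "C" + "TA" * 6 + "C" + right)
        loci = [l for l in scan_ssrs([contig]) if l.n_units >= 6]
        locus = next(l for l in loci if l.motif_observed == "TA")
        assert (locus.motif, locus.n_units) == ("AT", 6)  # canonical rotation
        assert contig.bases[locus.start : locus.end] == "TA" * 6

    def test_trinucleotide_below_minimum_not_reported(self):
        contig = SequenceRecord("c", "C" * 80 + "AGGAGGAGG" + "T" * 80)
        assert all(l.motif_observed != "AGG" for l in scan_ssrs([contig]))
        contig4 = SequenceRecord("c", "C" * 80 + "AGGAGGAGGAGG" + "T" * 80)
        assert any(l.motif_observed == "AGG" and l.n_units == 4
                   for l in scan_ssrs([contig4]))

    def test_run_attributed_to_shortest_period(self):
        contig = SequenceRecord("c", "GGC" + "AT" * 6 + "CGG" + "A" * 150)
        loci = [l for l in scan_ssrs([contig]) if l.start == 3]
        assert len(loci) == 1 and len(loci[0].motif_observed) == 2

    def test_short_contigs_skipped(self):
        contig = SequenceRecord("c", "C" + "TA" * 10 + "G")
        assert scan_ssrs([contig], min_contig_len=150) == []
        assert len(scan_ssrs([contig], min_contig_len=10)) == 1

    def test_matches_bruteforce_oracle_on_random_sequences(self):
        rng = np.random.default_rng(71)
        for i in range(10):
            seq = _rand_seq(rng, 10_000)
            got = {
                (l.start, l.end, l.motif_observed, l.n_units)
                for l in scan_ssrs([SequenceRecord("c", seq)], min_contig_len=1)
            }
            assert got == ssr_oracle(seq)

    def test_contig_order_invariance(self, mock_genome):
        records, _ = mock_genome
        nuclear = next(r for r in records if r.id == "nuclear_1")
        half = len(nuclear.bases) // 2
        a = SequenceRecord("a", nuclear.bases[:half])
        b = SequenceRecord("b", nuclear.bases[half:])
        key = lambda l: (l.contig_id, l.start, l.motif_observed, l.n_units)
        assert sorted(map(key, scan_ssrs([a, b]))) == sorted(map(key, scan_ssrs([b, a])))

    def test_planted_loci_recovered(self, mock_genome):
        records, truth = mock_genome
        nuclear = next(r for r in records if r.id == "nuclear_1")
        found = {
            (l.start, l.end, l.motif_observed, l.n_units)
            for l in scan_ssrs([nuclear], min_contig_len=1)
        }
        for _, s, e, motif, units in truth.ssr_loci:
            assert (s, e, motif, units) in found


class TestPrimerFeasibility:
    def _locus(self, contig_id, start, motif, units):
        from genomeskim.repeats import SsrLocus

        return SsrLocus(contig_id, start, start + len(motif) * units,
                        motif, motif, units)

    def test_centered_locus_in_150bp_contig_feasible(self):
        rng = np.random.default_rng(72)
        contig = SequenceRecord("c", _rand_seq(rng, 69) + "TA" * 6 + _rand_seq(rng, 69))
        assert ssr_primer_feasibility(self._locus("c", 69, "TA", 6), contig)

    def test_locus_near_contig_end_infeasible(self):
        rng = np.random.default_rng(73)
        contig = SequenceRecord("c", _rand_seq(rng, 150) + "TA" * 6 + "GCACG")
        assert not ssr_primer_feasibility(self._locus("c", 150, "TA", 6), contig)

    def test_matches_bruteforce_window_oracle(self):
        rng = np.random.default_rng(74)
        for _ in range(300):
            L = int(rng.integers(40, 400))
            span = int(rng.integers(8, 40)) // 2 * 2
            start = int(rng.integers(0, L - span + 1))
            contig = SequenceRecord("c", "A" * L)
            locus = self._locus("c", start, "TA", span // 2)
            oracle = any(
                a <= start - 18 and b >= start + span + 18
                for a in range(0, L + 1)
                for b in range(a + 100, min(a + 450, L) + 1)
            )
            assert ssr_primer_feasibility(locus, contig) == oracle


class TestFindRepeats:
    @staticmethod
    def _plant_two_copies(rng, elem, gap=300, pad=200, inverted=False):
        """Two copies of elem whose flank pairs are guaranteed mismatches,
        so maximal extension ends exactly at the element boundaries.

        For an inverted pair the extension compares copy A's left flank
        with the complement of copy B's right flank (and vice versa), so
        the guard bases differ between the two orientations.
        """
        second = revcomp(elem) if inverted else elem
        lb, rb = ("A", "G") if inverted else ("C", "T")
        s = (
            _rand_seq(rng, pad) + "A" + elem + "G"
            + _rand_seq(rng, gap) + lb + second + rb
            + _rand_seq(rng, pad)
        )
        a = (pad + 1, pad + 1 + len(elem))
        b = (pad + 1 + len(elem) + 1 + gap + 1,
             pad + 1 + len(elem) + 1 + gap + 1 + len(elem))
        return s, a, b

    def test_planted_exact_direct_repeat(self):
        rng = np.random.default_rng(75)
        elem = _rand_seq(rng, 66)
        s, a, b = self._plant_two_copies(rng, elem)
        pairs = [p for p in find_repeats(s, min_len=30, min_identity=0.85)
                 if p.kind == "direct" and p.length >= 60]
        assert len(pairs) == 1
        (p,) = pairs
        assert (p.span_a, p.span_b, p.length, p.identity) == (a, b, 66, 1.0)
        assert s[slice(*p.span_a)] == s[slice(*p.span_b)] == elem

    def test_planted_exact_inverted_repeat(self):
        rng = np.random.default_rng(76)
        arm = _rand_seq(rng, 32)
        s, a, b = self._plant_two_copies(rng, arm, gap=120, pad=150, inverted=True)
        pairs = [p for p in find_repeats(s, min_len=30, min_identity=0.85,
                                         kinds=("inverted",)) if p.length >= 31]
        assert len(pairs) == 1
        (p,) = pairs
        assert (p.span_a, p.span_b, p.length) == (a, b, 32)
        assert s[slice(*p.span_b)] == revcomp(s[slice(*p.span_a)])

    def test_strictly_greater_length_rule(self):
        rng = np.random.default_rng(77)
        elem = _rand_seq(rng, 30)
        s, a, b = self._plant_two_copies(rng, elem, gap=150, pad=120)
        strict = [p for p in find_repeats(s, min_len=30, min_identity=0.99)
                  if p.span_a == a]
        loose = [p for p in find_repeats(s, min_len=30, min_identity=0.99,
                                         strict_greater=False) if p.span_a == a]
        assert strict == []  # 30 bp is not "greater than 30 bp"
        assert len(loose) == 1 and loose[0].length == 30

    def test_planted_pairs_recovered_on_5kb(self, mock_genome):
        records, truth = mock_genome
        nuclear = next(r for r in records if r.id == "nuclear_1")
        pairs = find_repeats(nuclear.bases[:60_000], min_len=30, min_identity=0.85)
        direct = [p for p in pairs if p.kind == "direct"]
        for fam, sid, sa, sb, length in truth.repeat_pairs:
            if sb + length > 60_000:
                continue
            covering = [
                p for p in direct
                if p.span_a[0] <= sa and sa + length <= p.span_a[1] + 1
                and p.span_b[0] <= sb and sb + length <= p.span_b[1] + 1
            ]
            assert covering, (fam, sa, sb)

    def test_reverse_complement_reflection_symmetry(self):
        rng = np.random.default_rng(78)
        elem = _rand_seq(rng, 50)
        s = _rand_seq(rng, 120) + elem + _rand_seq(rng, 200) + elem + _rand_seq(rng, 120)
        n = len(s)
        fwd = find_repeats(s, min_len=30, min_identity=0.9)
        rev = find_repeats(revcomp(s), min_len=30, min_identity=0.9)
        reflect = lambda span: (n - span[1], n - span[0])
        fwd_keys = {(p.kind, *sorted((p.span_a, p.span_b))) for p in fwd}
        rev_keys = {
            (p.kind, *sorted((reflect(p.span_a), reflect(p.span_b)))) for p in rev
        }
        assert fwd_keys == rev_keys


class TestQuadripartite:
    def test_constructed_plastome_recovered_exactly(self):
        rng = np.random.default_rng(79)
        lsc, ir, ssc = _rand_seq(rng, 2000), _rand_seq(rng, 300), _rand_seq(rng, 400)
        plastome = SequenceRecord("p", lsc + ir + ssc + revcomp(ir), circular=True)
        q = detect_quadripartite(plastome, min_ir_len=100)
        assert (q.lsc_len, q.ir_len, q.ssc_len) == (2000, 300, 400)
        assert q.lsc_len + 2 * q.ir_len + q.ssc_len == len(plastome.bases)

    def test_default_mock_plastome(self, genome_by_id, mock_genome):
        _, truth = mock_genome
        q = detect_quadripartite(genome_by_id["plastome"])
        (a0, a1), _ = truth.ir_span["plastome"]
        assert q.has_ir and q.ir_len == a1 - a0
        assert q.lsc_len + 2 * q.ir_len + q.ssc_len == len(genome_by_id["plastome"].bases)

    def test_no_inverted_repeat_reported_not_raised(self):
        rng = np.random.default_rng(80)
        seq = SequenceRecord("p", _rand_seq(rng, 5000), circular=True)
        q = detect_quadripartite(seq)
        assert not q.has_ir and q.ir_len == 0


class TestRepeatLibrary:
    def test_identical_query_hits_and_divergent_misses(self):
        rng = np.random.default_rng(81)
        elem = _rand_seq(rng, 300)
        library = [SequenceRecord("copia:1", elem)]
        hit_q = SequenceRecord("q1", elem[50:90])
        miss = list(elem[100:140])
        positions = rng.choice(40, size=16, replace=False)  # 60% identity
        for j in positions:
            miss[j] = "ACGT"[("ACGT".index(miss[j]) + 1) % 4]
        miss_q = SequenceRecord("q2", "".join(miss))
        frac, fams = classify_vs_repeat_library([hit_q, miss_q], library)
        assert frac == 0.5 and fams == {"copia": 1}

    def test_planted_fraction_recovered(self, mock_genome):
        """0.25% of reads drawn from library elements -> hit fraction ~0.0025."""
        records, truth = mock_genome
        nuclear = next(r for r in records if r.id == "nuclear_1")
        rng = np.random.default_rng(82)
        library = [SequenceRecord(f"fam{k}:1", _rand_seq(rng, 250)) for k in range(3)]
        n = 8000
        reads, _ = simulate_reads(
            [nuclear], truth, ReadSimParams(total_bases=n * 40, seed=83, error_rate=0.0),
            fractions={"nuclear": 1.0},
        )
        planted = rng.choice(n, size=int(0.0025 * n), replace=False)
        for i in planted:
            lib = library[int(rng.integers(3))]
            start = int(rng.integers(0, 210))
            reads[i] = SequenceRecord(reads[i].id, lib.bases[start : start + 40])
        frac, _ = classify_vs_repeat_library(reads, library)
        sd = np.sqrt(0.0025 * 0.9975 / n)
        assert abs(frac - 0.0025) < 3 * sd + 1e-9


class TestPairwiseIdentity:
    def test_gapped_columns_removed(self):
        assert pairwise_identity("AC-GT", "ACTGT") == 1.0
        assert pairwise_identity("ACGT", "ACGT") == 1.0

    def test_matches_direct_count_on_random_alignments(self):
        rng = np.random.default_rng(84)
        alpha = np.array(list("ACGT-"))
        for _ in range(200):
            L = int(rng.integers(2, 80))
            a = "".join(alpha[rng.integers(0, 5, L)])
            b = "".join(alpha[rng.integers(0, 5, L)])
            cols = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not cols:
                with pytest.raises(ValueError):
                    pairwise_identity(a, b)
                continue
            expect = sum(x == y for x, y in cols) / len(cols)
            assert pairwise_identity(a, b) == pytest.approx(expect)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("ACGT", "ACG")
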