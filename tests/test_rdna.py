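"""rDNA polymorphism quantification: filtering, discordance, calibration."""

import numpy as np
import pytest

from genomeskim.align import place_reads
from genomeskim.consensus import Pileup, build_pileup, consensus_string
from genomeskim.rdna import (
    call_polymorphic,
    control_error_profile,
    discordance_profile,
    quality_filter_for_polymorphism,
)
from genomeskim.records import SequenceRecord
from genomeskim.simulate import ReadSimParams, simulate_reads


def _pileup(colcounts: list[dict], ref_id="ref") -> Pileup:
    pile = Pileup(ref_id, len(colcounts))
    for pos, counts in enumerate(colcounts):
        for base, c in counts.items():
            pile.counts["ACGTN".index(base), pos] = c
    return pile


class TestQualityFilter:
    def test_mean_below_threshold_discards(self):
        read = SequenceRecord("r", "ACGTACGTAC", [19] * 9 + [28])  # mean 19.9
        assert quality_filter_for_polymorphism([read]) == []

    def test_low_quality_base_masked_to_n(self):
        read = SequenceRecord("r", "ACG", [40, 19, 40])
        (out,) = quality_filter_for_polymorphism([read])
        assert out.bases == "ANG" and len(out.bases) == 3

    def test_removed_fraction_tracks_quality_model(self):
        """~0.1% of reads under Q20 mean -> ~0.1% removed (binomial tolerance)."""
        rng = np.random.default_rng(50)
        n = 20000
        low = rng.random(n) < 0.001
        reads = [
            SequenceRecord(f"r{i}", "ACGT" * 10, [10 if low[i] else 30] * 40)
            for i in range(n)
        ]
        kept = quality_filter_for_polymorphism(reads)
        removed = n - len(kept)
        sd = np.sqrt(0.001 * 0.999 * n)
        assert abs(removed - 0.001 * n) <= 3 * sd + 1e-9


class TestDiscordance:
    def test_simple_proportions(self):
        pile = _pileup([{"A": 98, "G": 2}, {"A": 100}])
        prof = discordance_profile(pile, "AA")
        assert prof.proportion[0] == pytest.approx(0.02)
        assert prof.proportion[1] == 0.0

    def test_n_bases_excluded_and_uncovered_missing(self):
        pile = _pileup([{"A": 90, "N": 10}, {}, {"N": 5}])
        prof = discordance_profile(pile, "AAA")
        assert prof.depth_effective.tolist() == [90, 0, 0]
        assert prof.proportion[0] == 0.0
        assert np.isnan(prof.proportion[1]) and np.isnan(prof.proportion[2])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            discordance_profile(_pileup([{"A": 1}]), "AA")

    def test_invariant_to_read_order_and_strand(self, mock_genome):
        records, truth = mock_genome
        fives = next(r for r in records if r.id == "rdna_5S")
        reads, _ = simulate_reads(
            [fives], truth, ReadSimParams(mean_coverage=80, seed=51, error_rate=0.0),
            fractions={"rdna": 1.0},
        )
        def profile(rs):
            pile = build_pileup(place_reads(rs, fives), rs, fives)
            return discordance_profile(pile, consensus_string(pile))
        a = profile(reads)
        b = profile(list(reversed(reads)))
        np.testing.assert_allclose(a.proportion, b.proportion)

    def test_binomial_recovery_of_minor_fractions(self, mock_genome):
        """Observed discordance tracks planted minor-copy fractions at 400x."""
        records, truth = mock_genome
        fives = next(r for r in records if r.id == "rdna_5S")
        reads, _ = simulate_reads(
            [fives], truth, ReadSimParams(mean_coverage=400, seed=52, error_rate=0.0),
            fractions={"rdna": 1.0},
        )
        pile = build_pileup(place_reads(reads, fives), reads, fives)
        prof = discordance_profile(pile, fives.bases)
        for site in truth.poly_sites["rdna_5S"]:
            f = site.realized_fraction
            d = prof.depth_effective[site.pos]
            sd = np.sqrt(f * (1 - f) / d)
            assert abs(prof.proportion[site.pos] - f) < 4 * sd + 1e-9


class TestCallPolymorphic:
    def test_percent_to_one_decimal(self):
        pile = _pileup([{"A": 100}] * 100)
        for pos in range(7):
            pile.counts[2, pos] = 5  # 5% G at 7 positions
        prof = discordance_profile(pile, "A" * 100)
        positions, pct = call_polymorphic(prof, 0.02)
        assert positions == list(range(7))
        assert pct["all"] == 7.0
        _, pct0 = call_polymorphic(discordance_profile(_pileup([{"A": 9}] * 50), "A" * 50))
        assert pct0["all"] == 0.0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(53)
        cols = []
        for _ in range(300):
            minor = int(rng.integers(0, 30))
            cols.append({"A": 400 - minor, "C": minor})
        prof = discordance_profile(_pileup(cols), "A" * 300)
        prev = None
        for thr in (0.08, 0.04, 0.02, 0.01):
            calls, _ = call_polymorphic(prof, thr)
            if prev is not None:
                assert set(prev) <= set(calls)  # lowering never removes a call
            prev = calls

    def test_per_region_percentages(self):
        cols = [{"A": 100}] * 200
        prof = discordance_profile(_pileup(cols), "A" * 200)
        prof.proportion[10] = 0.5
        prof.proportion[150] = 0.5
        _, pct = call_polymorphic(prof, 0.02,
                                  regions=[("18S", 0, 100), ("ITS1", 100, 200)])
        assert pct == {"18S": 1.0, "ITS1": 1.0}


class TestControlProfile:
    def test_error_free_control_has_zero_mean(self, mock_genome):
        records, truth = mock_genome
        ctrl = next(r for r in records if r.id == "control")
        reads, _ = simulate_reads(
            [ctrl], truth, ReadSimParams(mean_coverage=60, seed=54, error_rate=0.0),
            fractions={"control": 1.0},
        )
        pile = build_pileup(place_reads(reads, ctrl), reads, ctrl)
        prof = discordance_profile(pile, consensus_string(pile))
        cep = control_error_profile(prof)
        assert cep.overall_mean_discordance == 0.0
        assert cep.n_positions_above(0.007) == 0

    def test_planted_systematic_error_site_identified(self, mock_genome):
        """A 17%-discordant position surfaces as max_position, not removed."""
        records, truth = mock_genome
        ctrl = next(r for r in records if r.id == "control")
        reads, prov = simulate_reads(
            [ctrl], truth, ReadSimParams(mean_coverage=200, seed=55, error_rate=0.0),
            fractions={"control": 1.0},
        )
        target = 500
        flipped = []
        for rec, row in zip(reads, prov.itertuples()):
            off = target - row.start
            if 0 <= off < row.length and len(flipped) % 100 < 17:
                if row.strand == "-":
                    off = row.length - 1 - off
                    alt = "G" if rec.bases[off] != "G" else "C"
                else:
                    alt = "C" if rec.bases[off] != "C" else "G"
                rec2 = SequenceRecord(rec.id, rec.bases[:off] + alt + rec.bases[off + 1:],
                                      rec.quality)
                flipped.append(rec2)
            else:
                flipped.append(rec)
        pile = build_pileup(place_reads(flipped, ctrl), flipped, ctrl)
        prof = discordance_profile(pile, ctrl.bases)
        cep = control_error_profile(prof)
        pos, prop = cep.max_position
        assert pos == target
        assert 0.10 < prop < 0.25
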