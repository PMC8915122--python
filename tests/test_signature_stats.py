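"""Overlap/phasing signatures against exhaustive pair-counting oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srnakit.alignments_io import Alignment
from srnakit.signature_stats import (dicer_z, first_base_bias,
                                     overlap_histogram, overlap_len,
                                     phasing_stats, pingpong_z)
from srnakit import synthetic_data as sd
from conftest import random_reads
from _oracles import brute_overlap_counts, brute_phasing_counts


def _pair(plus_fp, plus_len, minus_fp, minus_len, contig="c"):
    return (Alignment(contig, plus_fp, plus_fp + plus_len, "+"),
            Alignment(contig, minus_fp - minus_len + 1, minus_fp + 1, "-"))


class TestOverlapLen:
    def test_pingpong_register(self):
        p, m = _pair(100, 28, 109, 28)
        assert overlap_len(p, m) == 10

    def test_dicer_register_two_nt_overhangs(self):
        # 21-mers overlapping 19 nt leave 2-nt 3' overhangs on both ends
        p = Alignment("c", 100, 121, "+")
        m = Alignment("c", 98, 119, "-")
        assert overlap_len(p, m) == 19
        assert p.three_prime() - m.five_prime() == 2
        assert p.five_prime() - m.three_prime() == 2

    @settings(derandomize=True, max_examples=200)
    @given(plus_fp=st.integers(0, 500), plus_len=st.integers(15, 32),
           minus_fp=st.integers(0, 500), minus_len=st.integers(15, 32))
    def test_overlap_defined_iff_mutual_containment(self, plus_fp, plus_len,
                                                    minus_fp, minus_len):
        # o is defined exactly when each 5' end falls inside the partner's span
        p = Alignment("c", plus_fp, plus_fp + plus_len, "+")
        m = Alignment("c", minus_fp - minus_len + 1, minus_fp + 1, "-")
        o = overlap_len(p, m)
        in_spans = (p.start <= minus_fp < p.end) and (m.start <= plus_fp < m.end)
        if in_spans:
            assert o == minus_fp - plus_fp + 1
        else:
            assert o is None

    def test_disjoint_and_invalid(self):
        p, m = _pair(100, 28, 95, 28)       # minus 5' left of plus 5'
        assert overlap_len(p, m) is None
        p2, m2 = _pair(100, 20, 140, 20)    # beyond span
        assert overlap_len(p2, m2) is None
        with pytest.raises(ValueError):
            overlap_len(m, p)


class TestOverlapHistogram:
    def test_single_pair(self):
        p, m = _pair(100, 28, 109, 30)
        hist = overlap_histogram([p, m])
        assert hist.counts[9] == 1 and hist.counts.sum() == 1

    @pytest.mark.parametrize("same_len,qlen,mode", [
        (False, None, "per-alignment"),
        (True, None, "per-alignment"),
        (False, 21, "per-alignment"),
        (False, None, "per-species"),
    ])
    def test_matches_brute_force(self, rng, genome, same_len, qlen, mode):
        reads = random_reads(rng, 1500, genome=genome)
        hist = overlap_histogram(reads, o_max=30, same_length_only=same_len,
                                 query_len=qlen, mode=mode)
        oracle = brute_overlap_counts(reads, 30, same_len, qlen,
                                      per_species=(mode == "per-species"))
        assert np.array_equal(hist.counts, oracle)

    def test_strand_symmetry(self, rng, genome):
        reads = random_reads(rng, 800, genome=genome)
        L = 100_000
        flipped = [Alignment(r.contig, L - r.end, L - r.start,
                             "-" if r.strand == "+" else "+",
                             None, r.n_hits, r.count) for r in reads]
        h1 = overlap_histogram(reads)
        h2 = overlap_histogram(flipped)
        assert np.array_equal(h1.counts, h2.counts)

    def test_per_species_invariant_under_duplication(self, rng, genome):
        reads = random_reads(rng, 400, genome=genome)
        h1 = overlap_histogram(reads, mode="per-species")
        h2 = overlap_histogram(reads + reads, mode="per-species")
        assert np.array_equal(h1.counts, h2.counts)

    def test_per_alignment_duplication_scales_counts_not_z(self, rng, genome):
        # duplicating the multiset quadruples every pair count and therefore
        # leaves the z-score (a scale-free statistic) unchanged
        reads = random_reads(rng, 400, genome=genome)
        h1 = overlap_histogram(reads)
        h2 = overlap_histogram(reads + reads)
        assert np.array_equal(h2.counts, 4 * h1.counts)
        assert np.allclose(h2.z, h1.z)


class TestConvenienceScores:
    def test_pingpong_z_simulation(self, genome):
        alns, _ = sd.simulate_pingpong_locus(genome, "ctg1", 5000, depth=500,
                                             pingpong_fraction=0.5, seed=1)
        assert pingpong_z(alns) > 3

    def test_single_read_not_available(self):
        assert pingpong_z([Alignment("c", 0, 28, "+")]) is None

    def test_dicer_z_on_ladder(self, genome):
        alns, _ = sd.simulate_sirna_ladder(genome, "ctg1", 5000, seed=2)
        hist = overlap_histogram([r for r in alns if r.length == 21], o_max=21,
                                 same_length_only=True, query_len=21)
        assert int(np.argmax(hist.z)) + 1 == 19
        assert dicer_z(alns, 21) > 3

    def test_dicer_z_insignificant_on_pingpong(self, genome):
        alns, _ = sd.simulate_pingpong_locus(genome, "ctg1", 5000, depth=500, seed=3)
        z = dicer_z(alns, 21)
        assert z is None or z < 2

    def test_dicer_z_single_duplex_counts(self):
        p = Alignment("c", 100, 121, "+")
        m = Alignment("c", 98, 119, "-")
        hist = overlap_histogram([p, m], o_max=21, same_length_only=True, query_len=21)
        assert hist.counts[18] == 1


class TestFirstBaseBias:
    def test_fraction(self):
        reads = [Alignment("c", i, i + 20, "+", ("T" if i < 8 else "A") * 20)
                 for i in range(10)]
        assert first_base_bias(reads) == pytest.approx(0.8)

    def test_all_n_not_available(self):
        reads = [Alignment("c", 0, 20, "+", "N" + "A" * 19)]
        assert first_base_bias(reads) is None

    def test_recovers_simulated_bias(self, genome):
        alns, _ = sd.simulate_phased_locus(genome, "ctg1", 5000, span_len=32_000,
                                           depth=1000, u1_bias=0.7, seed=4)
        assert 0.66 <= first_base_bias(alns) <= 0.74


class TestPhasing:
    @pytest.mark.parametrize("gap", [1, 2, 3])
    def test_argmax_at_simulated_gap(self, genome, gap):
        alns, _ = sd.simulate_phased_locus(genome, "ctg1", 5000, gap=gap, seed=gap)
        prof = phasing_stats(alns)
        assert int(np.argmax(prof.z)) == gap

    def test_u_profile_peaks_at_next_read(self, genome):
        # 30-mers, gap 1: next read's 1U sits at 1-indexed offset 31
        alns, _ = sd.simulate_phased_locus(genome, "ctg1", 5000, read_len=30,
                                           gap=1, u1_bias=0.95, seed=5)
        prof = phasing_stats(alns, genome=genome)
        assert prof.u_profile[0] > 0.85            # own first base
        assert int(np.argmax(prof.u_profile[1:])) + 2 == 31

    def test_matches_oracle_on_random_reads(self, rng, genome):
        reads = random_reads(rng, 1000, genome=genome)
        prof = phasing_stats(reads)
        assert np.array_equal(prof.distance_counts, brute_phasing_counts(reads))

    def test_too_few_positions_not_available(self):
        prof = phasing_stats([Alignment("c", 0, 28, "+")])
        assert prof.z is None
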