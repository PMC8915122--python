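"""Coverage islands, merging, size profiles, clustering."""

import numpy as np
import pytest

from srnakit.alignments_io import Alignment
from srnakit.locus_discovery import (Locus, cluster_base_bias, cluster_loci,
                                     coverage_track, find_loci,
                                     normalize_expression, size_profile)
from srnakit import synthetic_data as sd


def _track_from_islands(islands, n=10_000, depth=300):
    t = np.zeros(n)
    for s, e in islands:
        t[s:e] = depth
    return {"chr1": t}


def _brute_find(track, min_cov, merge_window):
    """Per-base scan oracle: islands then left-to-right merge."""
    out = []
    for contig in sorted(track):
        d = track[contig]
        islands = []
        inside = False
        for i, v in enumerate(d):
            if v >= min_cov and not inside:
                islands.append([i, i + 1])
                inside = True
            elif v >= min_cov:
                islands[-1][1] = i + 1
            else:
                inside = False
        merged = []
        for s, e in islands:
            if merged and s - merged[-1][1] < merge_window:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        out += [(contig, s, e) for s, e in merged]
    return out


class TestCoverage:
    def test_overlapping_reads_sum(self):
        alns = [Alignment("c", 100, 125, "+"), Alignment("c", 110, 135, "-")]
        t = coverage_track(alns)["c"]
        assert t[105] == 1 and t[115] == 2 and t[130] == 1

    def test_empty_input(self):
        assert coverage_track([], {"c": 50})["c"].sum() == 0

    def test_hits_weighting(self):
        alns = [Alignment("c", 0, 20, "+", n_hits=4)]
        assert coverage_track(alns, weight_mode="hits")["c"][10] == pytest.approx(0.25)


class TestFindLoci:
    def test_merge_boundary(self):
        # gap 300 < 500 merges into one locus spanning both islands
        loci = find_loci(_track_from_islands([(0, 100), (400, 500)]), min_cov=200)
        assert [(l.start, l.end) for l in loci] == [(0, 500)]
        # gap 600 >= 500 stays split
        loci = find_loci(_track_from_islands([(0, 100), (700, 800)]), min_cov=200)
        assert [(l.start, l.end) for l in loci] == [(0, 100), (700, 800)]

    def test_depth_threshold_boundary(self):
        t = np.zeros(5000)
        t[100:200] = 250
        t[1000:1100] = 199   # just under threshold
        t[2000:2100] = 200
        loci = find_loci({"chr1": t}, min_cov=200)
        assert [(l.start, l.end) for l in loci] == [(100, 200), (2000, 2100)]

    def test_matches_brute_force_oracle_on_random_tracks(self, rng):
        for _ in range(20):
            n = int(rng.integers(1000, 20_000))
            t = rng.integers(0, 30, size=n).astype(float)
            # sprinkle plateaus to create islands
            for _ in range(int(rng.integers(1, 8))):
                s = int(rng.integers(n - 200))
                t[s:s + int(rng.integers(10, 200))] += rng.integers(5, 40)
            min_cov = int(rng.integers(10, 50))
            mw = int(rng.integers(1, 800))
            got = [(l.contig, l.start, l.end)
                   for l in find_loci({"chr1": t}, min_cov=min_cov, merge_window=mw)]
            assert got == _brute_find({"chr1": t}, min_cov, mw)

    def test_merging_idempotent(self, rng):
        t = rng.integers(0, 400, size=20_000).astype(float)
        loci = find_loci({"chr1": t}, min_cov=200, merge_window=500)
        rebuilt = np.zeros(20_000)
        for l in loci:
            rebuilt[l.start:l.end] = 200
        again = find_loci({"chr1": rebuilt}, min_cov=200, merge_window=500)
        assert [(l.start, l.end) for l in again] == [(l.start, l.end) for l in loci]

    def test_read_assignment_by_overlap(self):
        alns = [Alignment("chr1", 95, 120, "+"), Alignment("chr1", 600, 630, "-")]
        loci = find_loci(_track_from_islands([(100, 200)]), alns, min_cov=200)
        assert len(loci[0].reads) == 1 and loci[0].reads[0].start == 95


class TestSizeProfiles:
    def test_single_length(self):
        loc = Locus("c", 0, 100, [Alignment("c", 0, 22, "+")] * 10)
        counts, frac = size_profile(loc)
        assert frac[22 - 15] == 1.0 and counts.sum() == 10

    def test_simulated_modes(self, genome):
        pp, t1 = sd.simulate_pingpong_locus(genome, "ctg1", 5000, depth=400, seed=1)
        counts, _ = size_profile(Locus("ctg1", t1.start, t1.end, pp))
        assert 29 <= 15 + int(np.argmax(counts)) <= 31
        mi, t2 = sd.simulate_mirna_locus(genome, "ctg1", 20_000, seed=2)
        counts, _ = size_profile(Locus("ctg1", t2.start, t2.end, mi))
        assert 21 <= 15 + int(np.argmax(counts)) <= 23


class TestClustering:
    def test_separable_populations_pure(self):
        a = np.zeros((30, 18)); a[:, 22 - 15] = 1
        b = np.zeros((30, 18)); b[:, 30 - 15] = 1
        assign = cluster_loci(np.vstack([a, b]), k=2)
        assert len(set(assign.labels[:30])) == 1
        assert len(set(assign.labels[30:])) == 1
        assert assign.labels[0] != assign.labels[30]
        # labels ordered by descending mean length: 30-mers are cluster 1
        assert assign.labels[30] == 1

    def test_partition_property(self, rng):
        profiles = rng.dirichlet(np.ones(18), size=40)
        assign = cluster_loci(profiles, k=5)
        assert sum(len(assign.members(c)) for c in range(1, assign.k + 1)) == 40

    def test_k_exceeding_loci_fails(self):
        with pytest.raises(ValueError):
            cluster_loci(np.ones((3, 18)) / 18, k=9)


class TestBaseBias:
    def test_pure_first_base(self):
        reads = [Alignment("c", i, i + 20, "+", "T" + "A" * 19) for i in range(10)]
        freq, ic = cluster_base_bias([Locus("c", 0, 100, reads)])
        assert freq[0, 3] == 1.0          # T column
        assert ic[0] == pytest.approx(2.0)

    def test_uniform_bases_zero_information(self):
        reads = [Alignment("c", i, i + 20, "+", b * 20)
                 for i, b in enumerate("ACGT")]
        freq, ic = cluster_base_bias([Locus("c", 0, 100, reads)])
        assert np.allclose(freq[0], 0.25) and ic[0] == pytest.approx(0.0)

    def test_simulated_u1_bias(self, genome):
        alns, _ = sd.simulate_phased_locus(genome, "ctg1", 5000, span_len=32_000,
                                           depth=2000, u1_bias=0.8, seed=3)
        freq, _ = cluster_base_bias([Locus("ctg1", 0, 99_000, alns)])
        assert 0.77 <= freq[0, 3] <= 0.83


class TestNormalization:
    def test_rpm_and_log(self):
        rpm, log = normalize_expression([500, 0], 1e6)
        assert rpm[0] == 500 and log[1] == 0.0
        # scale invariance across libraries with equal fractions
        rpm_a, _ = normalize_expression([50], 1e5)
        rpm_b, _ = normalize_expression([500], 1e6)
        assert rpm_a[0] == rpm_b[0]
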