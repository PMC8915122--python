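"""Hairpin duplex geometry, triage rules, short-loop scan."""

import numpy as np
import pytest

from srnakit.alignments_io import revcomp
from srnakit.mirna_curation import (HairpinCandidate, classify_mirna,
                                    duplex_overhangs, five_prime_precision,
                                    hairpin_candidate_from_truth,
                                    quantify_mirna, short_loop_scan)
from srnakit import synthetic_data as sd
from _oracles import brute_short_loops


class TestDuplexOverhangs:
    def test_canonical_two_nt(self):
        assert duplex_overhangs((100, 122), (140, 162), "+", (98, 162)) == (2, 2)

    def test_blunt_duplex(self):
        # same arms, register shifted so every terminal base pairs
        assert duplex_overhangs((100, 122), (140, 162), "+", (100, 162)) == (0, 0)

    def test_minus_strand_mirror(self):
        # reflect the canonical case through x -> 300 - x
        mature = (300 - 122, 300 - 100)
        star = (300 - 162, 300 - 140)
        precursor = (300 - 162, 300 - 98)
        assert duplex_overhangs(mature, star, "-", precursor) == (2, 2)

    def test_overlapping_arms_fail(self):
        with pytest.raises(ValueError):
            duplex_overhangs((100, 130), (120, 150), "+", (95, 155))

    def test_synthetic_hairpin_geometry(self, genome):
        _, t = sd.simulate_mirna_locus(genome, "ctg1", 5000, arm_len=20,
                                       loop_len=8, seed=4)
        p = t.params
        assert duplex_overhangs(p["mature"], p["star"], "+", p["precursor"]) == (2, 2)


class TestPrecision:
    def test_modal_share(self):
        assert five_prime_precision({100: 95, 101: 5}) == pytest.approx(0.95)
        assert five_prime_precision({100: 1, 101: 1, 102: 1, 103: 1}) == pytest.approx(0.25)
        assert five_prime_precision({}) is None

    def test_recovers_simulated_precision(self, genome):
        alns, t = sd.simulate_mirna_locus(genome, "ctg1", 5000, depth=400,
                                          precision_5p=0.95, star_frac=0.0, seed=5)
        cand = hairpin_candidate_from_truth(t, alns)
        assert 0.92 <= five_prime_precision(cand.mature_pileup) <= 0.98


def _candidate(overhang_ok: bool, precision: float, star: int) -> HairpinCandidate:
    """Boundary-value candidate: arms (100,122)/(140,162); precursor (98,162)
    yields (2,2) overhangs, shifting it one base breaks them."""
    precursor = (98, 162) if overhang_ok else (97, 162)
    n_major = int(round(precision * 1000))
    return HairpinCandidate(
        "c", precursor, "+", (100, 122), (140, 162),
        mature_pileup={100: n_major, 101: 1000 - n_major},
        star_pileup={140: star},
    )


class TestClassify:
    @pytest.mark.parametrize("overhang_ok,precision,star,label", [
        (True, 0.95, 20, "confident"),
        (True, 0.95, 5, "candidate"),       # star coverage does not exceed 8
        (True, 0.901, 9, "confident"),      # just above both cuts
        (True, 0.901, 8, "candidate"),
        (True, 0.90, 9, "candidate"),       # >90% is strict
        (True, 0.90, 8, "candidate"),
        (False, 0.901, 9, "candidate"),     # precision only
        (False, 0.901, 8, "candidate"),
        (False, 0.90, 9, "false_positive"), # fails both hallmarks
        (False, 0.40, 0, "false_positive"),
    ])
    def test_truth_table(self, overhang_ok, precision, star, label):
        verdict = classify_mirna(_candidate(overhang_ok, precision, star))
        assert verdict.label == label
        assert verdict.overhang_ok is overhang_ok

    def test_pure_function_of_inputs(self):
        v1 = classify_mirna(_candidate(True, 0.95, 20))
        v2 = classify_mirna(_candidate(True, 0.95, 20))
        assert (v1.label, v1.overhangs, v1.precision) == (v2.label, v2.overhangs, v2.precision)

    def test_missing_mature_pileup_fails(self):
        cand = _candidate(True, 0.95, 20)
        cand.mature_pileup = {}
        with pytest.raises(ValueError):
            classify_mirna(cand)

    def test_simulated_hairpin_confident(self, genome):
        alns, t = sd.simulate_mirna_locus(genome, "ctg1", 5000, depth=400,
                                          precision_5p=0.98, star_frac=0.15, seed=6)
        verdict = classify_mirna(hairpin_candidate_from_truth(t, alns))
        assert verdict.label == "confident"


class TestShortLoopScan:
    def test_constructed_four_base_loop(self):
        stem = "GATTACAGATTACAGATTACAG"   # 22 nt, ends in G so no outward extension
        seq = "AA" + stem + "GAAA" + revcomp(stem) + "AA"
        hits = short_loop_scan(seq, min_stem=22)
        assert hits == [(22, 4, 2)]

    def test_mismatch_breaks_stem(self):
        stem = "GATTACAGATTACAGATTACAG"
        bad = stem[:10] + "C" + stem[11:]  # point mismatch mid-stem
        seq = "AA" + bad + "GAAA" + revcomp(stem) + "AA"
        assert short_loop_scan(seq, min_stem=22) == []

    def test_three_base_loop(self):
        stem = "GATTACAGATTACAGATTACAG"
        seq = "TT" + stem + "AAA" + revcomp(stem) + "TT"
        hits = short_loop_scan(seq, min_stem=20)
        assert any(h[1] == 3 and h[0] >= 22 for h in hits)

    def test_matches_brute_force_on_random_sequence(self, rng):
        for trial in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            got = short_loop_scan(seq, min_stem=4)
            assert got == brute_short_loops(seq, min_stem=4)

    def test_gu_mode_extends_stems(self):
        # G:U pair at the stem base only counts in permissive mode
        stem = "GATTACAGATTACAGATTACA"
        seq = "G" + stem + "GAAA" + revcomp(stem) + "T"
        strict = short_loop_scan(seq, min_stem=len(stem))
        permissive = short_loop_scan(seq, min_stem=len(stem) + 1, allow_gu=True)
        assert max(h[0] for h in strict) == len(stem)
        assert max(h[0] for h in permissive) == len(stem) + 1


class TestQuantify:
    def test_rpm_matrix_and_bound(self):
        mat = quantify_mirna([500, 0], [1e6])
        assert mat[0, 0] == pytest.approx(np.log2(501))
        assert mat[1, 0] == 0.0
        rpm_total = (2 ** quantify_mirna([300, 200], [1e6]) - 1).sum()
        assert rpm_total <= 1e6
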