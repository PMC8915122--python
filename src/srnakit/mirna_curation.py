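"""miRNA hairpin curation.

Candidate hairpins (from an external predictor such as miRDeep2, or from the
synthetic generator) are triaged by two RNase III hallmarks:

1. the mature:star duplex carries 2-nt 3' overhangs on both ends
   (Drosha/Dicer cleavage), and
2. >90% of mature-arm reads share a single 5' base (processing precision).

Candidates passing both with star-arm coverage above eight reads are
*confident*; passing both with low star coverage, or exactly one hallmark,
makes a *candidate*; failing both makes a *false positive*. A separate scan
finds the unusual perfect-stem hairpins with minimal (3-4 nt) loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignments_io import revcomp

PRECISION_THRESHOLD = 0.90     # strictly greater-than passes
STAR_COVERAGE_THRESHOLD = 8    # strictly greater-than makes "confident"
STAR_5P_TOLERANCE = 2          # star reads counted within +/-2 nt of star 5'


@dataclass
class HairpinCandidate:
    contig: str
    precursor: tuple[int, int]          # 0-based half-open, outermost paired bases +/- symmetric pad
    strand: str
    mature: tuple[int, int]
    star: tuple[int, int]
    mature_pileup: dict[int, int] = field(default_factory=dict)  # 5' genome pos -> read count
    star_pileup: dict[int, int] = field(default_factory=dict)
    precursor_seq: str | None = None


@dataclass
class CurationVerdict:
    overhang_ok: bool
    precision_ok: bool
    star_coverage: int
    label: str                          # confident | candidate | false_positive
    reasons: list[str] = field(default_factory=list)
    overhangs: tuple[int, int] | None = None
    precision: float | None = None


def duplex_overhangs(mature_iv: tuple[int, int], star_iv: tuple[int, int],
                     strand: str, precursor_iv: tuple[int, int]) -> tuple[int, int]:
    """3' overhang lengths at the two ends of the implied mature:star duplex.

    Geometry (documented here because it is easy to get wrong): the two arms
    pair antiparallel through the hairpin stem. For an idealized precursor
    whose outermost bases pair (any symmetric extension preserves this),
    genome position x on one arm pairs with position C - x, where
    C = precursor_start + precursor_end - 1. On a + strand hairpin with the
    5' arm [a1,a2) and 3' arm [b1,b2):

    * base-side end: the 3' arm's 3' base is b2-1 while the last paired base
      across from a1 is C-a1, so its 3' overhang is a1 + b2 - 1 - C;
    * loop-side end: the 5' arm's 3' base is a2-1 against the pairing partner
      of b1 at C-b1, giving overhang a2 + b1 - 1 - C.

    A canonical Dicer/Drosha duplex returns (2, 2). Minus-strand hairpins are
    reflected into the + orientation first. Raises on overlapping arms.
    """
    (a1, a2), (b1, b2) = sorted([tuple(mature_iv), tuple(star_iv)])
    if b1 < a2:
        raise ValueError("hairpin arms overlap")
    p1, p2 = precursor_iv
    if strand == "-":
        # reflect through x -> -x (half-open intervals flip ends)
        return duplex_overhangs((1 - b2, 1 - b1), (1 - a2, 1 - a1), "+", (1 - p2, 1 - p1))
    C = p1 + p2 - 1
    return (a1 + b2 - 1 - C, a2 + b1 - 1 - C)


def five_prime_precision(arm_pileup: dict[int, int]) -> float | None:
    """Share of arm reads whose 5' end sits at the modal 5' position."""
    total = sum(arm_pileup.values())
    if total == 0:
        return None
    return max(arm_pileup.values()) / total


def star_coverage(candidate: HairpinCandidate,
                  tolerance: int = STAR_5P_TOLERANCE) -> int:
    """Reads whose 5' end lies within ``tolerance`` nt of the star arm's
    annotated 5' end."""
    star_fp = candidate.star[0] if candidate.strand == "+" else candidate.star[1] - 1
    return sum(c for p, c in candidate.star_pileup.items() if abs(p - star_fp) <= tolerance)


def classify_mirna(candidate: HairpinCandidate,
                   precision_threshold: float = PRECISION_THRESHOLD,
                   star_threshold: int = STAR_COVERAGE_THRESHOLD) -> CurationVerdict:
    """Triage one hairpin into confident / candidate / false_positive.

    confident  = 2-nt overhangs on both duplex ends AND mature 5' precision
                 strictly > 90% AND star coverage strictly > 8 reads;
    candidate  = exactly one of the two hallmarks, or both with star
                 coverage <= 8;
    false_positive = neither hallmark.
    """
    if not candidate.mature_pileup:
        raise ValueError("mature arm has no read pileup")
    overhangs = duplex_overhangs(candidate.mature, candidate.star,
                                 candidate.strand, candidate.precursor)
    precision = five_prime_precision(candidate.mature_pileup)
    star_cov = star_coverage(candidate)
    overhang_ok = overhangs == (2, 2)
    precision_ok = precision is not None and precision > precision_threshold
    reasons = []
    if not overhang_ok:
        reasons.append(f"duplex overhangs {overhangs} != (2, 2)")
    if not precision_ok:
        shown = "n/a" if precision is None else f"{precision:.3f}"
        reasons.append(f"5' precision {shown} <= {precision_threshold}")
    if overhang_ok and precision_ok:
        if star_cov > star_threshold:
            label = "confident"
        else:
            label = "candidate"
            reasons.append(f"star coverage {star_cov} <= {star_threshold}")
    elif overhang_ok or precision_ok:
        label = "candidate"
    else:
        label = "false_positive"
    return CurationVerdict(overhang_ok, precision_ok, star_cov, label, reasons,
                           overhangs, precision)


_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


def short_loop_scan(precursor_seq: str, min_stem: int = 18,
                    loop_sizes: tuple[int, ...] = (3, 4),
                    allow_gu: bool = False) -> list[tuple[int, int, int]]:
    """Find maximal perfect inverted repeats with a minimal (3-4 nt) loop.

    Returns (stem_len, loop_len, stem_start) for every maximal bulge-free
    stem of >= ``min_stem`` Watson-Crick pairs (G:U optionally allowed)
    enclosing a loop of exactly a permitted size. These perfect short-loop
    hairpins resemble miR-451 precursors but are diced conventionally.
    """
    seq = precursor_seq.upper().replace("U", "T")
    n = len(seq)

    def pairs(x: str, y: str) -> bool:
        if _WC.get(x) == y:
            return True
        return allow_gu and {x, y} == {"G", "T"}

    hits = []
    for loop_len in loop_sizes:
        for loop_start in range(1, n - loop_len):
            i, j = loop_start - 1, loop_start + loop_len
            stem = 0
            while i >= 0 and j < n and pairs(seq[i], seq[j]):
                stem += 1
                i -= 1
                j += 1
            if stem >= min_stem:
                hits.append((stem, loop_len, i + 1))
    return sorted(set(hits), key=lambda h: (h[2], h[1]))


def quantify_mirna(mature_counts, library_totals) -> "np.ndarray":
    """log2(RPM + 1) matrix of mature-arm counts, candidates x libraries."""
    import numpy as np
    from .locus_discovery import normalize_expression

    mature_counts = np.asarray(mature_counts, dtype=float)
    if mature_counts.ndim == 1:
        mature_counts = mature_counts[:, None]
    out = np.zeros_like(mature_counts)
    for j, total in enumerate(np.atleast_1d(library_totals)):
        _, out[:, j] = normalize_expression(mature_counts[:, j], float(total))
    return out


def hairpin_candidate_from_truth(truth, alignments) -> HairpinCandidate:
    """Build a curation candidate from a synthetic miRNA locus truth record."""
    p = truth.params
    cand = HairpinCandidate(truth.contig, tuple(p["precursor"]), p.get("strand", "+"),
                            tuple(p["mature"]), tuple(p["star"]))
    m1, m2 = cand.mature
    s1, s2 = cand.star
    for a in alignments:
        if a.contig != truth.contig:
            continue
        fp = a.five_prime()
        mid = (a.start + a.end) // 2
        if m1 <= mid < m2 or (m1 <= a.start < m2):
            cand.mature_pileup[fp] = cand.mature_pileup.get(fp, 0) + a.count
        elif s1 <= mid < s2 or (s1 <= a.start < s2):
            cand.star_pileup[fp] = cand.star_pileup.get(fp, 0) + a.count
    return cand
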