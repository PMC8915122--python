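"""Endogenous-siRNA absence scan.

Searches the 20-23 nt size class for the hallmarks of processive Dicer
cleavage of long dsRNA: loci with balanced strand usage, same-length
opposite-strand pairs overlapping by (length - 2) nt, 21/21-nt pairs at a
19-nt overlap, a short:long read-count ratio favouring Dicer products, and
head-to-tail phased runs of duplexes. In a genome without an siRNA pathway
the Dicer-signature z-scores show no enrichment among the mixed/equal
strand-ratio loci; a genuine dsRNA-derived ladder ranks at the top of the
scan when present.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict
from typing import Sequence

import numpy as np
from statsmodels.stats.proportion import proportions_ztest

from .alignments_io import Alignment
from .locus_discovery import Locus, coverage_track, find_loci
from .signature_stats import overlap_histogram, pingpong_z

SIRNA_READ_RANGE = (20, 23)
LONG_READ_RANGE = (26, 32)
MIN_COV_SIRNA = 30          # strictly greater-than
SIZES = (20, 21, 22, 23)


@dataclass
class SirnaLocusReport:
    locus_id: str
    contig: str
    start: int
    end: int
    strand_bin: str                         # bias | mixed | equal
    strand_ratio: float
    z_dicer: dict[int, float | None]        # per read length 20..23
    z_pingpong: float | None
    n_2121_pairs: int
    n_2121_pairs_species: int
    short_long_log_ratio: float
    rpkm: float
    phased_run_count: int
    distributive_pair_count: int


def find_sirna_loci(alignments: Sequence[Alignment], min_cov: float = MIN_COV_SIRNA,
                    exclude: Sequence[tuple[str, int, int]] = (),
                    merge_window: int = 0,
                    contig_lengths: dict[str, int] | None = None) -> list[Locus]:
    """Coverage islands of 20-23 nt reads with depth strictly > min_cov,
    dropping any locus that intersects the miRNA exclusion intervals."""
    lo, hi = SIRNA_READ_RANGE
    short = [a for a in alignments if lo <= a.length <= hi]
    track = coverage_track(short, contig_lengths)
    loci = find_loci(track, short, min_cov=min_cov + 1, merge_window=max(merge_window, 1))
    excl = defaultdict(list)
    for contig, s, e in exclude:
        excl[contig].append((s, e))
    kept = []
    for loc in loci:
        if any(loc.start < e and loc.end > s for s, e in excl.get(loc.contig, ())):
            continue
        kept.append(loc)
    return kept


def strand_bin(locus: Locus) -> tuple[str, float]:
    """Bin the max/min strand ratio: equal for 1-1.1, mixed for 1.2-1.9, bias
    for >= 2-fold. The definition leaves gaps at (1.1, 1.2) and (1.9, 2.0);
    gap values go to mixed and bias respectively, and the raw ratio is
    always returned for re-binning."""
    plus, minus = locus.strand_counts
    r = max(plus, minus) / max(min(plus, minus), 1)
    if r <= 1.1:
        return "equal", r
    if r <= 1.9:
        return "mixed", r
    return "bias", r


def per_size_overlap_matrix(locus: Locus, sizes: Sequence[int] = SIZES,
                            o_min: int = 4) -> dict[int, np.ndarray | None]:
    """Same-length overlap z-score rows per read length: z[L][o] for
    o = o_min..L (None for lengths with < 2 reads). The ping-pong register
    is o=10 and the Dicer register o=L-2."""
    out: dict[int, np.ndarray | None] = {}
    for L in sizes:
        subset = [r for r in locus.reads if r.length == L]
        if len(subset) < 2:
            out[L] = None
            continue
        hist = overlap_histogram(subset, o_max=L, same_length_only=True, query_len=L)
        window = hist.counts[o_min - 1:]
        sd = window.std()
        out[L] = None if sd == 0 else (window - window.mean()) / sd
    return out


def count_2121_pairs(locus: Locus) -> tuple[int, int]:
    """Opposite-strand pairs of 21-nt reads overlapping by exactly 19 nt
    (a 21-mer duplex with 2-nt 3' overhangs); returned per-alignment and
    per-species (distinct reads)."""
    subset = [r for r in locus.reads if r.length == 21]
    n_aln = int(overlap_histogram(subset, o_max=21, same_length_only=True,
                                  query_len=21).counts[18])
    n_sp = int(overlap_histogram(subset, o_max=21, same_length_only=True,
                                 query_len=21, mode="per-species").counts[18])
    return n_aln, n_sp


def short_long_ratio(locus: Locus) -> float:
    """log2((20-23 nt count + 1) / (26-32 nt count + 1))."""
    c_short = sum(r.count for r in locus.reads
                  if SIRNA_READ_RANGE[0] <= r.length <= SIRNA_READ_RANGE[1])
    c_long = sum(r.count for r in locus.reads
                 if LONG_READ_RANGE[0] <= r.length <= LONG_READ_RANGE[1])
    return float(np.log2((c_short + 1) / (c_long + 1)))


def phased_runs(locus: Locus, L: int = 21) -> tuple[int, int]:
    """Phased duplex runs vs distributive (isolated) duplexes.

    A duplex anchor is a plus-strand L-mer 5' position holding at least one
    (L-2)-overlap partner. Processive dicing of one dsRNA leaves consecutive
    anchors exactly L apart (head-to-tail register on each strand); chains of
    >= 3 anchors count as phased runs, shorter chains as distributive
    duplexes."""
    subset = [r for r in locus.reads if r.length == L]
    minus_fp = {r.five_prime() for r in subset if r.strand == "-"}
    anchors = sorted({r.five_prime() for r in subset
                      if r.strand == "+" and (r.five_prime() + L - 3) in minus_fp})
    runs = 0
    distributive = 0
    chain = 1
    for prev, nxt in zip(anchors, anchors[1:]):
        if nxt - prev == L:
            chain += 1
        else:
            runs += chain >= 3
            distributive += chain if chain < 3 else 0
            chain = 1
    if anchors:
        runs += chain >= 3
        distributive += chain if chain < 3 else 0
    return runs, distributive


def rpkm(locus: Locus, library_mapped_total: float) -> float:
    if library_mapped_total <= 0 or locus.length == 0:
        return 0.0
    return locus.total_count * 1e9 / (library_mapped_total * locus.length)


def scan_locus(locus: Locus, library_mapped_total: float = 1e6) -> SirnaLocusReport:
    sbin, ratio = strand_bin(locus)
    matrix = per_size_overlap_matrix(locus)
    z_dicer = {}
    for L, row in matrix.items():
        z_dicer[L] = None if row is None else float(row[(L - 2) - 4])
    pp = pingpong_z(locus.reads) if len(locus.reads) >= 2 else None
    n_aln, n_sp = count_2121_pairs(locus)
    runs, distrib = phased_runs(locus)
    return SirnaLocusReport(
        locus_id=locus.locus_id, contig=locus.contig, start=locus.start,
        end=locus.end, strand_bin=sbin, strand_ratio=ratio, z_dicer=z_dicer,
        z_pingpong=pp, n_2121_pairs=n_aln, n_2121_pairs_species=n_sp,
        short_long_log_ratio=short_long_ratio(locus),
        rpkm=rpkm(locus, library_mapped_total),
        phased_run_count=runs, distributive_pair_count=distrib,
    )


def dicer_strand_enrichment(reports: Sequence[SirnaLocusReport],
                            L: int = 21) -> tuple[float, float, float]:
    """Test whether Dicer-signature loci are enriched for mixed/equal strand
    usage (they would be if dual-strand transcripts were being diced).

    Returns (base mixed/equal rate, mixed/equal rate among dicer-z-positive
    loci, one-sided two-proportion p-value for enrichment). A large p-value
    is the siRNA-absence outcome.
    """
    me = np.array([r.strand_bin in ("mixed", "equal") for r in reports])
    pos = np.array([(r.z_dicer.get(L) or 0) > 0 for r in reports])
    if len(reports) == 0 or pos.sum() == 0:
        return float(me.mean()) if len(reports) else float("nan"), float("nan"), 1.0
    base = me.mean()
    in_pos = me[pos].mean()
    stat, pval = proportions_ztest(count=[me[pos].sum(), me.sum()],
                                   nobs=[pos.sum(), len(reports)],
                                   alternative="larger")
    return float(base), float(in_pos), float(pval)


def rank_loci(reports: Sequence[SirnaLocusReport], L: int = 21) -> list[SirnaLocusReport]:
    """Sort by (dicer z at L, 21/21 pair count) descending — a true siRNA
    ladder rises to the top."""
    return sorted(reports,
                  key=lambda r: ((r.z_dicer.get(L) if r.z_dicer.get(L) is not None else -np.inf),
                                 r.n_2121_pairs),
                  reverse=True)
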