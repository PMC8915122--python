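"""Small-RNA biogenesis signature statistics.

The geometric signatures scored here are the field's standard diagnostics:

* **Ping-pong**: opposite-strand read pairs whose 5' ends overlap by exactly
  10 nt, the footprint of reciprocal PIWI slicing.
* **Dicer**: same-length opposite-strand pairs overlapping by (length - 2) nt,
  i.e. a duplex with 2-nt 3' overhangs on both ends.
* **Phasing (Zucchini)**: same-strand reads arranged head-to-tail, the next
  read's 5' base 1-3 nt past the upstream read's 3' base, with a 1U bias.

Each signature is summarized as a z-score of the signal bin against the full
overlap/distance window (population SD, signal bin included in the
background), the convention used by standard ping-pong scoring tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter, defaultdict
from typing import Iterable, Sequence

import numpy as np

from .alignments_io import Alignment

O_MAX_DEFAULT = 30
D_MAX_DEFAULT = 30
U_WINDOW_DEFAULT = 35


def _zscores(counts: np.ndarray) -> np.ndarray | None:
    """z over the whole window with population SD; None when SD == 0."""
    mean = counts.mean()
    sd = counts.std()  # population (ddof=0)
    if sd == 0:
        return None
    return (counts - mean) / sd


@dataclass
class OverlapHistogram:
    """Counts of opposite-strand pairs per 5'-5' overlap length 1..o_max."""

    counts: np.ndarray          # index o-1 holds overlap o
    o_max: int
    mode: str                   # per-alignment | per-species
    same_length_only: bool = False
    query_len: int | None = None

    @property
    def z(self) -> np.ndarray | None:
        return _zscores(self.counts)

    def z_at(self, o: int) -> float | None:
        z = self.z
        return None if z is None else float(z[o - 1])


@dataclass
class PhasingProfile:
    """3'-to-next-5' distance histogram (same strand) and positional
    U-fraction over a 5'-anchored window."""

    distance_counts: np.ndarray    # index d holds distance d, d = 0..d_max
    d_max: int
    u_profile: np.ndarray | None   # fraction of U at 1-indexed offsets 1..window
    n_positions: int

    @property
    def z(self) -> np.ndarray | None:
        return _zscores(self.distance_counts)

    def z_at(self, d: int) -> float | None:
        z = self.z
        return None if z is None else float(z[d])


def overlap_len(plus_read: Alignment, minus_read: Alignment) -> int | None:
    """5'-5' overlap of an opposite-strand pair, or None if not overlapping.

    Defined as (minus 5') - (plus 5') + 1 when both 5' ends fall inside the
    partner's span; a 10-nt value is the ping-pong register, L-2 for two
    L-mers is the Dicer register.
    """
    if plus_read.strand != "+" or minus_read.strand != "-":
        raise ValueError("expects (plus_read, minus_read) on + and - strands")
    if plus_read.contig != minus_read.contig:
        return None
    o = minus_read.five_prime() - plus_read.five_prime() + 1
    if o < 1 or o > min(plus_read.length, minus_read.length):
        return None
    return o


def _collapse_species(reads: Iterable[Alignment]) -> list[Alignment]:
    seen = {}
    for r in reads:
        key = (r.contig, r.start, r.end, r.strand, r.sequence)
        if key not in seen:
            seen[key] = Alignment(r.contig, r.start, r.end, r.strand, r.sequence,
                                  r.n_hits, 1)
    return list(seen.values())


def overlap_histogram(reads: Sequence[Alignment], o_max: int = O_MAX_DEFAULT,
                      same_length_only: bool = False,
                      query_len: int | None = None,
                      mode: str = "per-alignment") -> OverlapHistogram:
    """Histogram of all opposite-strand pair 5'-5' overlaps in 1..o_max.

    Pairs are enumerated with a 5'-position index (equivalent to the
    exhaustive all-pairs count). ``query_len`` restricts both mates to one
    read length; ``same_length_only`` restricts to equal-length mates.
    ``per-species`` mode collapses identical reads before counting.
    """
    if mode not in ("per-alignment", "per-species"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "per-species":
        reads = _collapse_species(reads)
    counts = np.zeros(o_max, dtype=float)
    # index minus reads by (contig, five_prime)
    minus_idx: dict[tuple[str, int], list[Alignment]] = defaultdict(list)
    plus_reads = []
    for r in reads:
        if query_len is not None and r.length != query_len:
            continue
        if r.strand == "-":
            minus_idx[(r.contig, r.five_prime())].append(r)
        else:
            plus_reads.append(r)
    for p in plus_reads:
        fp = p.five_prime()
        for o in range(1, min(o_max, p.length) + 1):
            for m in minus_idx.get((p.contig, fp + o - 1), ()):
                if o > m.length:
                    continue
                if same_length_only and m.length != p.length:
                    continue
                counts[o - 1] += p.count * m.count
    return OverlapHistogram(counts, o_max, mode, same_length_only, query_len)


def pingpong_z(reads: Sequence[Alignment], o_max: int = O_MAX_DEFAULT,
               same_length_only: bool = False,
               mode: str = "per-alignment") -> float | None:
    """z-score of the 10-nt 5'-5' overlap (ping-pong signature)."""
    if len(reads) < 2:
        return None
    return overlap_histogram(reads, o_max, same_length_only, mode=mode).z_at(10)


def dicer_z(reads: Sequence[Alignment], L: int, o_max: int = O_MAX_DEFAULT,
            mode: str = "per-alignment") -> float | None:
    """z-score of the (L-2)-nt overlap among length-L pairs (Dicer signature)."""
    subset = [r for r in reads if r.length == L]
    if len(subset) < 2:
        return None
    hist = overlap_histogram(subset, o_max, same_length_only=True, query_len=L,
                             mode=mode)
    return hist.z_at(L - 2)


def first_base_bias(reads: Sequence[Alignment], base: str = "T") -> float | None:
    """Fraction of reads whose first (5') base is ``base``; reads whose first
    base is N (or without sequence) are excluded from the denominator."""
    num = den = 0
    for r in reads:
        if r.sequence is None or r.sequence[0] == "N":
            continue
        den += r.count
        if r.sequence[0] == base.upper().replace("U", "T"):
            num += r.count
    return None if den == 0 else num / den


def _modal_length(lengths: Counter) -> int:
    # most frequent read length at a 5' position; ties -> longest
    best = max(lengths.items(), key=lambda kv: (kv[1], kv[0]))
    return best[0]


def phasing_stats(reads: Sequence[Alignment], d_max: int = D_MAX_DEFAULT,
                  genome=None, window: int = U_WINDOW_DEFAULT,
                  strand: str | None = None) -> PhasingProfile:
    """Phasing distances and positional U profile.

    Distances are computed per strand between consecutive *distinct* 5'
    positions: d = (next 5') - (previous 3'), so immediately adjacent reads
    give d = 1; multiplicity is ignored (phasing is positional) and the 3'
    end at a position is taken from its modal read length. Histograms from
    the two strands are summed unless ``strand`` selects one.

    The U profile anchors each distinct 5' position and records the genome
    base (on the read's strand) at 1-indexed offsets 1..window, so offset 1
    is the read's own first base; ``genome`` must expose
    ``slice(contig, start, end)`` (a :class:`srnakit.synthetic_data.Genome`
    or an equivalent FASTA wrapper). When ``genome`` is None the profile is
    computed from read sequences alone, padded to each read's length.
    """
    counts = np.zeros(d_max + 1, dtype=float)
    u_hits = np.zeros(window, dtype=float)
    u_tot = np.zeros(window, dtype=float)
    n_positions = 0
    strands = [strand] if strand else ["+", "-"]
    for st in strands:
        by_pos: dict[tuple[str, int], Counter] = defaultdict(Counter)
        anchors: list[Alignment] = []
        for r in reads:
            if r.strand != st:
                continue
            key = (r.contig, r.five_prime())
            if key not in by_pos:
                anchors.append(r)
            by_pos[key][r.length] += 1
        n_positions += len(by_pos)
        per_contig: dict[str, list[int]] = defaultdict(list)
        for (contig, fp) in by_pos:
            per_contig[contig].append(fp)
        for contig, fps in per_contig.items():
            fps.sort(reverse=(st == "-"))
            for prev_fp, next_fp in zip(fps, fps[1:]):
                plen = _modal_length(by_pos[(contig, prev_fp)])
                prev_three = prev_fp + plen - 1 if st == "+" else prev_fp - plen + 1
                d = (next_fp - prev_three) if st == "+" else (prev_three - next_fp)
                if 0 <= d <= d_max:
                    counts[d] += 1
        for r in anchors:
            _accumulate_u(r, genome, window, u_hits, u_tot)
    u_profile = np.divide(u_hits, u_tot, out=np.full(window, np.nan), where=u_tot > 0)
    if n_positions < 2:
        return PhasingProfile(counts, d_max, u_profile, n_positions)
    return PhasingProfile(counts, d_max, u_profile, n_positions)


def _accumulate_u(r: Alignment, genome, window: int, u_hits, u_tot) -> None:
    from .alignments_io import revcomp
    if genome is not None:
        fp = r.five_prime()
        if r.strand == "+":
            seq = genome.slice(r.contig, fp, fp + window)
        else:
            lo = max(fp - window + 1, 0)
            seq = revcomp(genome.slice(r.contig, lo, fp + 1))
    elif r.sequence is not None:
        seq = r.sequence[:window]
    else:
        return
    for i, b in enumerate(seq):
        if b == "N":
            continue
        u_tot[i] += 1
        if b == "T":
            u_hits[i] += 1
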