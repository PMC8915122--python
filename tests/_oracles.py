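"""Independent reference implementations used to validate the fast paths.

These are exhaustive all-pairs computations (numpy broadcasting over every
plus x minus read combination) and nearest-neighbour scans, deliberately
structured unlike the indexed implementations they check.
"""

from __future__ import annotations

import numpy as np

from srnakit.alignments_io import revcomp


def dedupe_species(reads):
    seen = set()
    out = []
    for r in reads:
        key = (r.contig, r.start, r.end, r.strand, r.sequence)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def brute_overlap_counts(reads, o_max=30, same_length_only=False,
                         query_len=None, per_species=False) -> np.ndarray:
    """All-pairs 5'-5' overlap histogram over every (plus, minus) pair."""
    if per_species:
        reads = dedupe_species(reads)
    plus = [r for r in reads if r.strand == "+"]
    minus = [r for r in reads if r.strand == "-"]
    if query_len is not None:
        plus = [r for r in plus if r.length == query_len]
        minus = [r for r in minus if r.length == query_len]
    counts = np.zeros(o_max)
    if not plus or not minus:
        return counts
    contigs = {c: i for i, c in enumerate(sorted({r.contig for r in reads}))}
    pc = np.array([contigs[r.contig] for r in plus])
    mc = np.array([contigs[r.contig] for r in minus])
    pf = np.array([r.five_prime() for r in plus])
    mf = np.array([r.five_prime() for r in minus])
    pl = np.array([r.length for r in plus])
    ml = np.array([r.length for r in minus])
    pw = np.array([1 if per_species else r.count for r in plus], dtype=float)
    mw = np.array([1 if per_species else r.count for r in minus], dtype=float)

    o = mf[None, :] - pf[:, None] + 1
    valid = (pc[:, None] == mc[None, :]) & (o >= 1)
    valid &= o <= np.minimum(pl[:, None], ml[None, :])
    valid &= o <= o_max
    if same_length_only:
        valid &= pl[:, None] == ml[None, :]
    w = pw[:, None] * mw[None, :]
    np.add.at(counts, (o[valid] - 1).astype(int), w[valid])
    return counts


def brute_phasing_counts(reads, d_max=30) -> np.ndarray:
    """3'-to-next-5' distances via nearest-downstream search over all
    distinct 5' positions (O(n^2) per strand), modal read length per
    position with ties to the longest."""
    counts = np.zeros(d_max + 1)
    for strand in "+-":
        for contig in sorted({r.contig for r in reads}):
            sub = [r for r in reads if r.strand == strand and r.contig == contig]
            lengths: dict[int, dict[int, int]] = {}
            for r in sub:
                lengths.setdefault(r.five_prime(), {}).setdefault(r.length, 0)
                lengths[r.five_prime()][r.length] += 1
            fps = list(lengths)
            sign = 1 if strand == "+" else -1
            for fp in fps:
                downstream = [q for q in fps if sign * (q - fp) > 0]
                if not downstream:
                    continue
                nxt = min(downstream, key=lambda q: sign * (q - fp))
                modal = max(lengths[fp].items(), key=lambda kv: (kv[1], kv[0]))[0]
                three = fp + sign * (modal - 1)
                d = sign * (nxt - three)
                if 0 <= d <= d_max:
                    counts[d] += 1
    return counts


def brute_short_loops(seq, min_stem, loop_sizes=(3, 4), allow_gu=False):
    """Enumerate every (stem_start, stem_len, loop_len) triple; keep perfect
    inverted repeats of >= min_stem pairs that cannot be extended outward."""
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    wc = {"A": "T", "T": "A", "C": "G", "G": "C"}

    def pairs(x, y):
        return wc.get(x) == y or (allow_gu and {x, y} == {"G", "T"})

    hits = set()
    for start in range(n):
        for loop in loop_sizes:
            for stem in range(min_stem, (n - loop) // 2 + 1):
                end = start + 2 * stem + loop
                if end > n:
                    break
                left = seq[start:start + stem]
                right = seq[start + stem + loop:end]
                if not all(pairs(left[i], right[stem - 1 - i]) for i in range(stem)):
                    continue
                extendable = start > 0 and end < n and pairs(seq[start - 1], seq[end])
                if not extendable:
                    hits.add((stem, loop, start))
    # a shorter stem nested in a reported maximal stem is not itself maximal
    maximal = set()
    for stem, loop, start in hits:
        inner = any(s2 > stem and start2 + (s2 - stem) == start and loop2 == loop
                    for s2, loop2, start2 in hits)
        if not inner:
            maximal.add((stem, loop, start))
    return sorted(maximal, key=lambda h: (h[2], h[1]))
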