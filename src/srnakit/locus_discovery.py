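"""Small-RNA locus discovery and size-profile clustering.

Loci are coverage islands: maximal runs of per-base depth >= a threshold,
with islands closer than a merge window fused and reads assigned by overlap.
Per-locus read-length profiles (15-32 nt) are clustered hierarchically
(Ward/Euclidean) to separate miRNA-sized, piRNA-sized and debris loci, and
per-cluster positional base frequencies summarize nucleotide bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage, fcluster

from .alignments_io import Alignment

MIN_COV_DEFAULT = 200       # per-base depth threshold for a locus
MERGE_WINDOW_DEFAULT = 500  # islands with gap < this merge
SIZE_RANGE = (15, 32)       # read lengths profiled per locus


@dataclass
class Locus:
    contig: str
    start: int
    end: int
    reads: list[Alignment] = field(default_factory=list)
    locus_id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def total_count(self) -> int:
        return sum(r.count for r in self.reads)

    @property
    def strand_counts(self) -> tuple[int, int]:
        plus = sum(r.count for r in self.reads if r.strand == "+")
        minus = sum(r.count for r in self.reads if r.strand == "-")
        return plus, minus

    @property
    def depth(self) -> float:
        """Maximum per-base coverage inside the locus."""
        if not self.reads:
            return 0.0
        diff = np.zeros(self.length + 1)
        for r in self.reads:
            s = max(r.start, self.start) - self.start
            e = min(r.end, self.end) - self.start
            if e > s:
                diff[s] += r.count
                diff[e] -= r.count
        return float(np.cumsum(diff[:-1]).max())


def coverage_track(alignments: Iterable[Alignment], contig_lengths: dict[str, int] | None = None,
                   weight_mode: str = "alignment") -> dict[str, np.ndarray]:
    """Per-contig per-base depth, strands combined.

    ``alignment`` mode counts every alignment (times its collapsed count);
    ``hits`` mode weights each by 1/n_hits so a multimapper contributes one
    read in total across its placements.
    """
    if weight_mode not in ("alignment", "hits"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    ends: dict[str, int] = dict(contig_lengths or {})
    per_contig: dict[str, list[tuple[int, int, float]]] = defaultdict(list)
    for a in alignments:
        w = a.count / a.n_hits if weight_mode == "hits" else float(a.count)
        per_contig[a.contig].append((a.start, a.end, w))
        ends[a.contig] = max(ends.get(a.contig, 0), a.end)
    track = {}
    for contig in per_contig if contig_lengths is None else ends:
        n = ends.get(contig, 0)
        diff = np.zeros(n + 1)
        for s, e, w in per_contig.get(contig, ()):
            diff[s] += w
            diff[e] -= w
        track[contig] = np.cumsum(diff[:-1])
    return track


def find_loci(track: dict[str, np.ndarray], alignments: Iterable[Alignment] = (),
              min_cov: float = MIN_COV_DEFAULT,
              merge_window: int = MERGE_WINDOW_DEFAULT) -> list[Locus]:
    """Coverage islands with depth >= min_cov, merged when the gap between
    islands is strictly less than ``merge_window``; reads are assigned to a
    locus when their span intersects it (after merging a read can only touch
    one locus)."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    loci: list[Locus] = []
    for contig in sorted(track):
        depth = np.asarray(track[contig])
        above = depth >= min_cov
        if not above.any():
            continue
        runs = _runs(above)
        merged: list[list[int]] = []
        for s, e in runs:
            if merged and s - merged[-1][1] < merge_window:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            loci.append(Locus(contig, int(s), int(e)))
    by_contig: dict[str, list[Locus]] = defaultdict(list)
    for loc in loci:
        by_contig[loc.contig].append(loc)
    for lst in by_contig.values():
        lst.sort(key=lambda l: l.start)
    for a in alignments:
        for loc in by_contig.get(a.contig, ()):
            if a.start < loc.end and a.end > loc.start:
                loc.reads.append(a)
                break  # merging guarantees a read touches at most one locus
    for i, loc in enumerate(sorted(loci, key=lambda l: (l.contig, l.start)), start=1):
        loc.locus_id = f"locus_{i}"
    return sorted(loci, key=lambda l: (l.contig, l.start))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(np.int8), [0]))))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]


def size_profile(locus: Locus, size_range: tuple[int, int] = SIZE_RANGE) -> tuple[np.ndarray, np.ndarray]:
    """Counts (and row-normalized fractions) of read lengths 15..32 nt."""
    lo, hi = size_range
    counts = np.zeros(hi - lo + 1)
    for r in locus.reads:
        if lo <= r.length <= hi:
            counts[r.length - lo] += r.count
    total = counts.sum()
    if total == 0:
        raise ValueError(f"locus {locus.locus_id or locus.start} has no reads in {lo}..{hi} nt")
    return counts, counts / total


@dataclass
class ClusterAssignment:
    labels: np.ndarray                      # locus index -> cluster 1..k
    k: int
    mean_profiles: np.ndarray               # k x n_sizes, row-normalized means
    size_range: tuple[int, int] = SIZE_RANGE

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def cluster_loci(profiles: np.ndarray, k: int = 9, method: str = "ward") -> ClusterAssignment:
    """Hierarchical clustering (Ward, Euclidean) of row-normalized size
    profiles, cut at k clusters; cluster indices are relabeled 1..k by
    descending mean read length so labels are stable across runs."""
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2:
        raise ValueError("profiles must be 2-D (loci x sizes)")
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds number of loci ({len(profiles)})")
    Z = linkage(profiles, method=method, metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    sizes = np.arange(SIZE_RANGE[0], SIZE_RANGE[0] + profiles.shape[1])
    mean_len = {}
    for c in np.unique(raw):
        mp = profiles[raw == c].mean(axis=0)
        mean_len[c] = float((mp * sizes).sum() / mp.sum())
    order = sorted(mean_len, key=lambda c: -mean_len[c])
    relabel = {old: new for new, old in enumerate(order, start=1)}
    labels = np.array([relabel[c] for c in raw])
    mean_profiles = np.zeros((len(order), profiles.shape[1]))
    for c in range(1, len(order) + 1):
        mp = profiles[labels == c].mean(axis=0)
        mean_profiles[c - 1] = mp / mp.sum()
    return ClusterAssignment(labels, int(labels.max()), mean_profiles)


def cluster_base_bias(loci: Sequence[Locus], positions: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Positional base-frequency matrix (positions x ACGT) over all reads of
    the given loci, plus per-position information content in bits
    (2 + sum f log2 f); reads with N at a scored position are skipped there."""
    reads = [r for loc in loci for r in loc.reads if r.sequence is not None]
    if not reads:
        raise ValueError("no reads with sequence in cluster")
    base_idx = {b: i for i, b in enumerate("ACGT")}
    freq = np.zeros((positions, 4))
    for r in reads:
        for i, b in enumerate(r.sequence[:positions]):
            j = base_idx.get(b)
            if j is not None:
                freq[i, j] += r.count
    totals = freq.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freq = np.where(totals > 0, freq / totals, 0.0)
    logf = np.log2(freq, out=np.zeros_like(freq), where=freq > 0)
    ic = 2.0 + (freq * logf).sum(axis=1)
    return freq, ic


def normalize_expression(locus_counts: Sequence[float] | np.ndarray,
                         library_mapped_total: float) -> tuple[np.ndarray, np.ndarray]:
    """Reads-per-million and heatmap-ready log2(RPM + 1)."""
    if library_mapped_total <= 0:
        raise ValueError("library_mapped_total must be > 0")
    rpm = np.asarray(locus_counts, dtype=float) * 1e6 / library_mapped_total
    return rpm, np.log2(rpm + 1.0)
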