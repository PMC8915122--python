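"""Alignment and annotation I/O.

Normalizes small-RNA read alignments from SAM/BAM or a 6-column BED dialect
(read sequence in the name field, number of genome hits in the score field)
into a single internal convention: 0-based half-open coordinates, sequences
stored in read orientation (5'->3', U as T). Gene/exon structure is read from
GFF3 and introns are derived as gene span minus the union of exons.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pysam
from intervaltree import IntervalTree

logger = logging.getLogger("srnakit")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: read lengths handled by the pipeline (filters are applied by callers)
MIN_READ_LEN = 15
MAX_READ_LEN = 32
MAX_HITS_DEFAULT = 100


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Alignment:
    """One mapped read.

    ``start``/``end`` are 0-based half-open genome coordinates; ``sequence``
    is in read orientation (the reverse complement of the reference slice for
    minus-strand alignments). ``n_hits`` is the read's number of genome
    alignments, ``count`` its collapsed multiplicity.
    """

    contig: str
    start: int
    end: int
    strand: str
    sequence: str | None = None
    n_hits: int = 1
    count: int = 1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -: {self.strand!r}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != span {self.length}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def five_prime(self) -> int:
        """Genome coordinate of the read's 5' base."""
        return self.start if self.strand == "+" else self.end - 1

    def three_prime(self) -> int:
        """Genome coordinate of the read's 3' base."""
        return self.end - 1 if self.strand == "+" else self.start


_BED_COLS = 6
_COUNT_SUFFIX = re.compile(r"[_x](\d+)$")


def load_alignments(
    path: str | os.PathLike,
    min_len: int = MIN_READ_LEN,
    max_len: int = MAX_READ_LEN,
    max_hits: int = MAX_HITS_DEFAULT,
) -> Iterator[Alignment]:
    """Stream alignments from SAM/BAM or the BED dialect.

    Reads outside ``[min_len, max_len]`` or with more than ``max_hits``
    genome alignments are dropped (highly redundant multimappers carry no
    locus information).
    """
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    if max_hits < 1:
        raise ValueError("max_hits must be >= 1")
    path = os.fspath(path)
    if path.endswith((".bed", ".bed.gz")):
        yield from _load_bed(path, min_len, max_len, max_hits)
    else:
        yield from _load_sam(path, min_len, max_len, max_hits)


def _load_sam(path: str, min_len: int, max_len: int, max_hits: int) -> Iterator[Alignment]:
    warned_nh = False
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for i, rec in enumerate(fh, start=1):
            if rec.is_unmapped:
                continue
            try:
                start = rec.reference_start
                end = rec.reference_end
                if end is None:
                    raise ValueError("no aligned span")
                strand = "-" if rec.is_reverse else "+"
                seq = rec.query_sequence
                if seq is not None:
                    seq = seq.upper().replace("U", "T")
                    if rec.is_reverse:
                        # SAM stores SEQ in reference orientation
                        seq = revcomp(seq)
                if rec.has_tag("NH"):
                    n_hits = int(rec.get_tag("NH"))
                else:
                    n_hits = 1
                    if not warned_nh:
                        logger.warning("%s: NH tag absent, assuming unique hits", path)
                        warned_nh = True
                count = 1
                m = _COUNT_SUFFIX.search(rec.query_name or "")
                if m:
                    count = max(int(m.group(1)), 1)
                aln = Alignment(rec.reference_name, start, end, strand, seq, n_hits, count)
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: unparseable record at line/record {i}: {exc}") from exc
            if min_len <= aln.length <= max_len and aln.n_hits <= max_hits:
                yield aln


def _load_bed(path: str, min_len: int, max_len: int, max_hits: int) -> Iterator[Alignment]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < _BED_COLS:
                raise ValueError(f"{path}:{lineno}: expected >= {_BED_COLS} columns")
            try:
                contig, start, end, name, score, strand = parts[:_BED_COLS]
                seq = name.upper().replace("U", "T") if re.fullmatch(r"[ACGTUNacgtun]+", name) else None
                n_hits = int(float(score)) if score not in (".", "") else 1
                aln = Alignment(contig, int(start), int(end), strand, seq, max(n_hits, 1))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable record: {exc}") from exc
            if min_len <= aln.length <= max_len and aln.n_hits <= max_hits:
                yield aln


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

@dataclass
class Gene:
    gene_id: str
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gene span minus the union of exons, as 0-based half-open intervals."""
        if not self.exons:
            return []
        merged: list[list[int]] = []
        for s, e in sorted(self.exons):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        introns = []
        prev_end = self.start
        for s, e in merged:
            if s > prev_end:
                introns.append((prev_end, s))
            prev_end = max(prev_end, e)
        if prev_end < self.end:
            introns.append((prev_end, self.end))
        # leading/trailing gene sequence without exons is UTR-less padding in
        # malformed annotations; treat it as intron only between exons
        if introns and merged:
            first_exon_start = merged[0][0]
            last_exon_end = merged[-1][1]
            introns = [iv for iv in introns if iv[0] >= first_exon_start and iv[1] <= last_exon_end]
        return introns


class AnnotationSet:
    """Genes, exons and derived introns with fast interval lookup."""

    def __init__(self, genes: Sequence[Gene]):
        self.genes = list(genes)
        self._gene_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        self._intron_trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._gene_trees.setdefault(g.contig, IntervalTree()).addi(g.start, g.end, g)
            for s, e in g.exons:
                self._exon_trees.setdefault(g.contig, IntervalTree()).addi(s, e, g)
            for s, e in g.introns:
                self._intron_trees.setdefault(g.contig, IntervalTree()).addi(s, e, g)

    def genes_overlapping(self, contig: str, start: int, end: int) -> list[Gene]:
        tree = self._gene_trees.get(contig)
        return [iv.data for iv in tree.overlap(start, end)] if tree else []

    def exons_overlapping(self, contig: str, start: int, end: int) -> list[tuple[int, int]]:
        tree = self._exon_trees.get(contig)
        return [(iv.begin, iv.end) for iv in tree.overlap(start, end)] if tree else []

    def introns_containing(self, contig: str, start: int, end: int) -> list[tuple[int, int]]:
        """Introns that fully contain [start, end)."""
        tree = self._intron_trees.get(contig)
        if not tree:
            return []
        return [(iv.begin, iv.end) for iv in tree.overlap(start, end)
                if iv.begin <= start and end <= iv.end]


_GFF_ATTR = re.compile(r"(\w+)=([^;]+)")


def load_annotations(gff3_path: str | os.PathLike) -> AnnotationSet:
    """Parse gene/exon features from GFF3 (1-based closed -> 0-based half-open)."""
    genes: dict[str, Gene] = {}
    exon_rows: list[tuple[str, str, int, int]] = []  # parent, contig, start, end
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{gff3_path}:{lineno}: expected 9 GFF3 columns")
            contig, _src, ftype, start1, end1, _score, strand, _phase, attrs = parts
            start, end = int(start1) - 1, int(end1)
            attr = dict(_GFF_ATTR.findall(attrs))
            if ftype == "gene":
                gid = attr.get("ID", f"gene_{lineno}")
                genes[gid] = Gene(gid, contig, start, end, strand)
            elif ftype == "exon":
                parent = attr.get("Parent", attr.get("ID", ""))
                # exons may point at an mRNA; accept gene-id prefix match
                exon_rows.append((parent, contig, start, end))
    for parent, contig, start, end in exon_rows:
        gene = genes.get(parent) or genes.get(parent.rsplit(".", 1)[0])
        if gene is None:
            # attach to any gene containing the exon
            hits = [g for g in genes.values() if g.contig == contig and g.start <= start and end <= g.end]
            if not hits:
                logger.warning("exon %s:%d-%d has no parent gene; skipped", contig, start, end)
                continue
            gene = hits[0]
        if start < gene.start or end > gene.end:
            logger.warning("exon outside gene %s; clipped", gene.gene_id)
            start, end = max(start, gene.start), min(end, gene.end)
        if end > start:
            gene.exons.append((start, end))
    return AnnotationSet(list(genes.values()))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def _sorted_records(records, key):
    records = list(records)
    if records != sorted(records, key=key):
        logger.info("records not sorted; sorting before write")
        records = sorted(records, key=key)
    return records


def write_bed(records: Iterable, path: str | os.PathLike) -> None:
    """Write BED6. Records may be Alignment objects or (contig, start, end,
    name, score, strand) tuples; Alignment names carry the read sequence."""
    rows = []
    for i, rec in enumerate(records, start=1):
        if isinstance(rec, Alignment):
            rows.append((rec.contig, rec.start, rec.end, rec.sequence or f"aln_{i}",
                         rec.n_hits, rec.strand))
        else:
            rows.append(tuple(rec))
    rows = _sorted_records(rows, key=lambda r: (r[0], int(r[1]), int(r[2])))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(_fmt(x) for x in r) + "\n")


def write_bedgraph(track: dict, path: str | os.PathLike) -> None:
    """Write a depth track (contig -> per-base vector) as bedgraph, merging
    adjacent equal-depth bins; zero-depth runs are omitted."""
    with open(path, "w") as fh:
        for contig in sorted(track):
            depth = track[contig]
            run_start = 0
            run_val = depth[0] if len(depth) else 0
            for i in range(1, len(depth) + 1):
                val = depth[i] if i < len(depth) else None
                if val != run_val:
                    if run_val != 0:
                        fh.write(f"{contig}\t{run_start}\t{i}\t{_fmt(float(run_val))}\n")
                    run_start, run_val = i, val


def write_tsv(records: Iterable[dict], path: str | os.PathLike, columns: Sequence[str] | None = None) -> None:
    """Write dict records as a TSV with a header line (header-only if empty)."""
    records = list(records)
    if columns is None:
        columns = list(records[0].keys()) if records else ["empty"]
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for rec in records:
            fh.write("\t".join(_fmt(rec.get(c, "")) for c in columns) + "\n")


def write_sam(alignments: Iterable[Alignment], path: str | os.PathLike,
              contig_lengths: dict[str, int]) -> None:
    """Write alignments as SAM (NH tag carries hit counts; read multiplicity
    is encoded in the name as ``read_<i>_x<count>``)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in contig_lengths.items()],
    }
    tid = {c: i for i, c in enumerate(contig_lengths)}
    with pysam.AlignmentFile(os.fspath(path), "wh", header=header) as fh:
        for i, aln in enumerate(alignments, start=1):
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = f"read_{i}_x{aln.count}"
            rec.flag = 16 if aln.strand == "-" else 0
            rec.reference_id = tid[aln.contig]
            rec.reference_start = aln.start
            rec.mapping_quality = 255
            rec.cigarstring = f"{aln.length}M"
            seq = aln.sequence
            if seq is not None:
                rec.query_sequence = revcomp(seq) if aln.strand == "-" else seq
            rec.set_tag("NH", aln.n_hits)
            fh.write(rec)
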