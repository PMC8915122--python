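"""Synthetic small-RNA data generator.

Builds toy genomes and read alignments for every locus class the pipeline
classifies — miRNA hairpins with 2-nt 3' overhang duplexes, ping-pong piRNA
loci (10-nt 5'-5' opposite-strand overlaps), phased (Zucchini-type) piRNA
trains, uni-strand piRNA loci, repeat-peak loci with reads stacked at a few
positions, degradation debris, and processively diced siRNA ladders — each
with a truth record carrying the generative parameters so downstream tests
can assert recovery without hard-coded constants.

Reads are emitted error-free: every signature scored downstream is a property
of alignment geometry and of the genome sequence, which the generator edits
in place (e.g. forcing a U at a read's first position) before sequences are
extracted. All randomness flows from a single integer seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alignments_io import Alignment, Gene, AnnotationSet, revcomp, write_sam, write_bed

_BASES = np.array(list("ACGT"))

#: default piRNA read-length distribution (nt -> weight), peaked at 29-30 nt
PIRNA_LEN_DIST: dict[int, float] = {
    26: 0.04, 27: 0.08, 28: 0.15, 29: 0.25, 30: 0.25, 31: 0.15, 32: 0.08,
}

#: piRNA population with a heavy trimmed (20-23 nt) tail, emulating the
#: short-read loci the siRNA scan picks up in a genome without siRNAs
TRIMMED_PIRNA_LEN_DIST: dict[int, float] = {
    20: 0.10, 21: 0.15, 22: 0.15, 23: 0.10,
    26: 0.05, 27: 0.08, 28: 0.10, 29: 0.12, 30: 0.12, 31: 0.08, 32: 0.05,
}


class Genome:
    """Mutable toy genome: contig name -> sequence."""

    def __init__(self, contigs: dict[str, str]):
        self._seq = {c: bytearray(s.encode()) for c, s in contigs.items()}

    @property
    def contigs(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seq.items()}

    def slice(self, contig: str, start: int, end: int) -> str:
        return self._seq[contig][start:end].decode()

    def set(self, contig: str, pos: int, base: str) -> None:
        self._seq[contig][pos] = ord(base)

    def write(self, contig: str, pos: int, seq: str) -> None:
        self._seq[contig][pos:pos + len(seq)] = seq.encode()

    def read_sequence(self, aln: Alignment) -> str:
        s = self.slice(aln.contig, aln.start, aln.end)
        return revcomp(s) if aln.strand == "-" else s

    def to_fasta(self, path: str | os.PathLike, width: int = 70) -> None:
        with open(path, "w") as fh:
            for contig in self._seq:
                fh.write(f">{contig}\n")
                seq = self._seq[contig].decode()
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


@dataclass
class SyntheticTruth:
    """Generative ground truth for one simulated locus."""

    locus_id: str
    cls: str  # miRNA | pingpong_piRNA | phased_piRNA | unistrand_piRNA | repeat_peak_piRNA | debris | sirna_ladder
    contig: str
    start: int
    end: int
    params: dict = field(default_factory=dict)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def make_genome(n_contigs: int = 1, contig_len: int = 100_000, gc: float = 0.4,
                seed: int | np.random.Generator = 0) -> Genome:
    """I.i.d. random genome with the requested GC fraction."""
    if contig_len < 10_000:
        raise ValueError("contig_len must be >= 10,000")
    rng = _rng(seed)
    return Genome({f"ctg{i + 1}": _random_seq(rng, contig_len, gc) for i in range(n_contigs)})


def _biased_first_base(rng, genome: Genome, contig: str, five_prime: int,
                       strand: str, base: str, prob: float) -> None:
    """Force the genome so a read anchored at ``five_prime`` starts with
    ``base`` with exactly probability ``prob`` (otherwise a uniform non-base)."""
    others = [b for b in "ACGT" if b != base]
    chosen = base if rng.random() < prob else others[rng.integers(len(others))]
    genome.set(contig, five_prime, chosen if strand == "+" else revcomp(chosen))


def _extract(genome: Genome, placements: list[tuple[str, int, int, str]],
             n_hits: int = 1) -> list[Alignment]:
    out = []
    for contig, start, end, strand in placements:
        aln = Alignment(contig, start, end, strand, n_hits=n_hits)
        out.append(Alignment(contig, start, end, strand,
                             genome.read_sequence(aln), n_hits=n_hits))
    return out


# ---------------------------------------------------------------------------
# locus simulators
# ---------------------------------------------------------------------------

def simulate_mirna_locus(genome: Genome, contig: str, at: int,
                         arm_len: int = 22, loop_len: int = 15, depth: int = 300,
                         precision_5p: float = 0.95, star_frac: float = 0.15,
                         seed: int | np.random.Generator = 0,
                         locus_id: str = "mir") -> tuple[list[Alignment], SyntheticTruth]:
    """Write a perfect inverted-repeat hairpin and emit mature/star reads.

    The star arm is placed so the mature:star duplex carries exactly 2-nt 3'
    overhangs on both ends — the RNase III (Drosha/Dicer) cleavage geometry.
    Mature reads share one 5' base with probability ``precision_5p`` (the
    remainder shift +/-1 nt).
    """
    if not 18 <= arm_len <= 25:
        raise ValueError("arm_len must be in 18..25")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    rng = _rng(seed)
    h, n, l = at, arm_len, loop_len
    stem = _random_seq(rng, n)
    genome.write(contig, h, stem + _random_seq(rng, l) + revcomp(stem))
    # pairing register of the idealized hairpin: genome x pairs with C - x
    C = 2 * h + 2 * n + l - 1
    mature = (h, h + n)
    star = (C - mature[1] + 3, C - mature[0] + 3)   # both 3' overhangs = 2 nt
    precursor = (h - 2, h + 2 * n + l + 2)

    n_star = int(round(star_frac * depth))
    placements: list[tuple[str, int, int, str]] = []
    for _ in range(depth - n_star):
        fp = mature[0]
        if rng.random() >= precision_5p:
            fp += int(rng.choice([-1, 1]))
        placements.append((contig, fp, fp + n, "+"))
    placements += [(contig, star[0], star[1], "+")] * n_star
    truth = SyntheticTruth(locus_id, "miRNA", contig, precursor[0], precursor[1],
                           dict(mature=mature, star=star, precursor=precursor,
                                arm_len=arm_len, loop_len=loop_len, depth=depth,
                                precision_5p=precision_5p, star_frac=star_frac,
                                strand="+"))
    return _extract(genome, placements), truth


def _draw_lengths(rng, size: int, read_len_dist: dict[int, float] | None) -> np.ndarray:
    dist = read_len_dist or PIRNA_LEN_DIST
    lens = np.array(sorted(dist))
    p = np.array([dist[k] for k in lens], dtype=float)
    return rng.choice(lens, size=size, p=p / p.sum())


def simulate_pingpong_locus(genome: Genome, contig: str, at: int,
                            span_len: int = 2000, depth: int = 500,
                            pingpong_fraction: float = 0.5,
                            u1_bias: float = 0.7, a10_bias: float = 0.7,
                            read_len_dist: dict[int, float] | None = None,
                            bg_plus_frac: float = 0.5,
                            seed: int | np.random.Generator = 0,
                            locus_id: str = "pp") -> tuple[list[Alignment], SyntheticTruth]:
    """Dual-strand piRNA locus with ping-pong amplification geometry.

    ``pingpong_fraction`` of reads come as opposite-strand pairs whose 5' ends
    overlap by exactly 10 nt; the plus partner starts with U with probability
    ``u1_bias`` and the shared genome base under the minus partner's 5' end is
    set to A with probability ``a10_bias`` (which simultaneously creates the
    responder's position-10 A and the guide's 1U — the ping-pong couple).
    """
    if span_len < 1000:
        raise ValueError("span_len must be >= 1000")
    rng = _rng(seed)
    n_pairs = int(round(depth * pingpong_fraction / 2))
    n_bg = depth - 2 * n_pairs
    lo, hi = at + 35, at + span_len - 45
    placements: list[tuple[str, int, int, str]] = []
    for _ in range(n_pairs):
        lp, lm = _draw_lengths(rng, 2, read_len_dist)
        p = int(rng.integers(lo, hi))
        _biased_first_base(rng, genome, contig, p, "+", "T", u1_bias)
        _biased_first_base(rng, genome, contig, p + 9, "+", "A", a10_bias)
        placements.append((contig, p, p + int(lp), "+"))
        placements.append((contig, p + 10 - int(lm), p + 10, "-"))
    for _ in range(n_bg):
        ln = int(_draw_lengths(rng, 1, read_len_dist)[0])
        p = int(rng.integers(lo, hi))
        strand = "+" if rng.random() < bg_plus_frac else "-"
        fp = p if strand == "+" else p + ln - 1
        _biased_first_base(rng, genome, contig, fp, strand, "T", u1_bias)
        placements.append((contig, p, p + ln, strand))
    truth = SyntheticTruth(locus_id, "pingpong_piRNA", contig, at, at + span_len,
                           dict(depth=depth, pingpong_fraction=pingpong_fraction,
                                u1_bias=u1_bias, a10_bias=a10_bias, span_len=span_len,
                                bg_plus_frac=bg_plus_frac))
    return _extract(genome, placements), truth


def simulate_phased_locus(genome: Genome, contig: str, at: int,
                          span_len: int = 3000, depth: int = 500,
                          read_len: int = 30, gap: int = 1, u1_bias: float = 0.9,
                          strand: str = "+",
                          seed: int | np.random.Generator = 0,
                          locus_id: str = "ph") -> tuple[list[Alignment], SyntheticTruth]:
    """Single-strand head-to-tail phased piRNA train.

    Consecutive 5' positions sit ``read_len - 1 + gap`` apart, so the distance
    from an upstream read's 3' base to the next read's 5' base is exactly
    ``gap`` (1-3 nt, the Zucchini processing footprint). First bases are U
    with probability ``u1_bias``, decided once per 5' position.
    """
    if gap not in (1, 2, 3):
        raise ValueError("gap must be 1, 2 or 3")
    rng = _rng(seed)
    step = read_len - 1 + gap
    positions = list(range(at, at + span_len - read_len, step))
    for p in positions:
        fp = p if strand == "+" else p + read_len - 1
        _biased_first_base(rng, genome, contig, fp, strand, "T", u1_bias)
    # round-robin depth so every position is occupied when depth >= #positions
    counts = np.full(len(positions), depth // len(positions), dtype=int)
    extra = rng.permutation(len(positions))[: depth % len(positions)]
    counts[extra] += 1
    placements = []
    for p, c in zip(positions, counts):
        placements += [(contig, p, p + read_len, strand)] * int(c)
    truth = SyntheticTruth(locus_id, "phased_piRNA", contig, at, at + span_len,
                           dict(depth=depth, read_len=read_len, gap=gap,
                                u1_bias=u1_bias, strand=strand,
                                n_positions=len(positions)))
    return _extract(genome, placements), truth


def simulate_unistrand_locus(genome: Genome, contig: str, at: int,
                             span_len: int = 2000, depth: int = 400,
                             u1_bias: float = 0.7, minor_frac: float = 0.04,
                             read_len_dist: dict[int, float] | None = None,
                             seed: int | np.random.Generator = 0,
                             locus_id: str = "us") -> tuple[list[Alignment], SyntheticTruth]:
    """piRNA locus with near-exclusive single-strand expression.

    A small ``minor_frac`` of reads are placed as exact 10-nt-overlap partners
    on the opposite strand (residual ping-pong), keeping the plus:minus ratio
    far above the 10x uni-strand threshold.
    """
    rng = _rng(seed)
    n_minor = int(round(minor_frac * depth))
    lo, hi = at + 35, at + span_len - 45
    placements = []
    majors = []
    for _ in range(depth - n_minor):
        ln = int(_draw_lengths(rng, 1, read_len_dist)[0])
        p = int(rng.integers(lo, hi))
        _biased_first_base(rng, genome, contig, p, "+", "T", u1_bias)
        placements.append((contig, p, p + ln, "+"))
        majors.append(p)
    for _ in range(n_minor):
        p = majors[int(rng.integers(len(majors)))]
        lm = int(_draw_lengths(rng, 1, read_len_dist)[0])
        placements.append((contig, p + 10 - lm, p + 10, "-"))
    truth = SyntheticTruth(locus_id, "unistrand_piRNA", contig, at, at + span_len,
                           dict(depth=depth, u1_bias=u1_bias, minor_frac=minor_frac,
                                span_len=span_len, strand="+"))
    return _extract(genome, placements), truth


def simulate_repeat_peak_locus(genome: Genome, contig: str, at: int,
                               n_peaks: int = 5, peak_depth: int = 100,
                               unit_len: int = 300, read_len: int = 28,
                               distinct_peaks: bool = False, dual_frac: float = 0.0,
                               seed: int | np.random.Generator = 0,
                               locus_id: str = "rp") -> tuple[list[Alignment], SyntheticTruth]:
    """Tandem-repeat ("non-arthropod") locus: reads stack at exactly
    ``n_peaks`` 5' positions, one per repeat unit.

    With ``distinct_peaks`` the units carry point differences so each peak's
    read sequence is distinct (multi-read motif); otherwise all peaks share
    one sequence (single-read repeat). ``dual_frac`` of each peak's reads go
    to the opposite strand at ping-pong register (partial 10-nt overlaps, as
    repeat loci show).
    """
    if n_peaks < 3:
        raise ValueError("n_peaks must be >= 3")
    rng = _rng(seed)
    unit = _random_seq(rng, unit_len)
    offset = 10
    peak_positions = []
    for i in range(n_peaks):
        u = unit
        if distinct_peaks and i > 0:
            # one substitution per unit at a peak-specific position inside the
            # read window, so every peak's read sequence is distinct
            j = offset + (i - 1) % read_len
            u = u[:j] + {"A": "C", "C": "G", "G": "T", "T": "A"}[u[j]] + u[j + 1:]
        genome.write(contig, at + i * unit_len, u)
        peak_positions.append(at + i * unit_len + offset)
    placements = []
    n_dual = int(round(dual_frac * peak_depth))
    for p in peak_positions:
        placements += [(contig, p, p + read_len, "+")] * (peak_depth - n_dual)
        placements += [(contig, p + 10 - read_len, p + 10, "-")] * n_dual
    truth = SyntheticTruth(locus_id, "repeat_peak_piRNA", contig, at, at + n_peaks * unit_len,
                           dict(n_peaks=n_peaks, peak_depth=peak_depth, unit_len=unit_len,
                                read_len=read_len, peak_positions=peak_positions,
                                distinct_peaks=distinct_peaks, dual_frac=dual_frac))
    return _extract(genome, placements), truth


def simulate_debris(genome: Genome, contig: str, at: int,
                    span_len: int = 2000, depth: int = 300,
                    len_range: tuple[int, int] = (15, 20),
                    seed: int | np.random.Generator = 0,
                    locus_id: str = "db") -> tuple[list[Alignment], SyntheticTruth]:
    """Degradation debris: short reads at uniform positions/strands, no
    engineered signature."""
    rng = _rng(seed)
    placements = []
    for _ in range(depth):
        ln = int(rng.integers(len_range[0], len_range[1] + 1))
        p = int(rng.integers(at, at + span_len - ln))
        strand = "+" if rng.random() < 0.5 else "-"
        placements.append((contig, p, p + ln, strand))
    truth = SyntheticTruth(locus_id, "debris", contig, at, at + span_len,
                           dict(depth=depth, len_range=len_range, span_len=span_len))
    return _extract(genome, placements), truth


def simulate_sirna_ladder(genome: Genome, contig: str, at: int,
                          n_duplexes: int = 10, read_len: int = 21,
                          per_duplex: int = 5, phased: bool = True,
                          spacing: int = 100,
                          seed: int | np.random.Generator = 0,
                          locus_id: str = "si") -> tuple[list[Alignment], SyntheticTruth]:
    """Processively diced siRNA ladder: same-length duplexes with 2-nt 3'
    overhangs (5' ends overlap by ``read_len - 2``), head-to-tail when
    ``phased`` (consecutive plus-strand 5' positions ``read_len`` apart),
    otherwise isolated duplexes ``spacing`` apart (distributive dicing)."""
    step = read_len if phased else spacing
    placements = []
    starts = [at + i * step for i in range(n_duplexes)]
    for s in starts:
        placements += [(contig, s, s + read_len, "+")] * per_duplex
        # minus partner 5' at s + read_len - 3: overlap = read_len - 2
        placements += [(contig, s - 2, s + read_len - 2, "-")] * per_duplex
    end = starts[-1] + read_len
    truth = SyntheticTruth(locus_id, "sirna_ladder", contig, at - 2, end,
                           dict(n_duplexes=n_duplexes, read_len=read_len,
                                per_duplex=per_duplex, phased=phased, spacing=spacing))
    return _extract(genome, placements), truth


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

_SIMULATORS = {
    "miRNA": simulate_mirna_locus,
    "pingpong_piRNA": simulate_pingpong_locus,
    "phased_piRNA": simulate_phased_locus,
    "unistrand_piRNA": simulate_unistrand_locus,
    "repeat_peak_piRNA": simulate_repeat_peak_locus,
    "debris": simulate_debris,
}

_SLOT = 8000          # genome allotted per locus; spans stay <= 3 kb
_CONTEXTS = ("intergenic", "genic", "intronic")


@dataclass
class Cohort:
    genome: Genome
    alignments: list[Alignment]
    truths: list[SyntheticTruth]
    annotations: AnnotationSet
    genes: list[Gene]


def simulate_cohort(seed: int = 0, n_per_class: int | dict[str, int] = 20,
                    include_sirna_ladder: bool = False) -> Cohort:
    """Full synthetic study: genome + annotations + reads + truth labels.

    Loci of every generative class are laid out on three contigs with > 2 kb
    spacing (beyond the 500-bp merge window), and genes are placed so each
    class cycles through intergenic / genic / intronic contexts, recorded in
    the truth parameters.
    """
    rng = np.random.default_rng(seed)
    classes = list(_SIMULATORS)
    counts = {c: n_per_class for c in classes} if isinstance(n_per_class, int) else dict(n_per_class)
    plan = [(cls, i) for cls in classes for i in range(counts.get(cls, 0))]
    if include_sirna_ladder:
        plan.append(("sirna_ladder", 0))
    n_contigs = 3
    per_contig = (len(plan) + n_contigs - 1) // n_contigs
    genome = make_genome(n_contigs, max(per_contig * _SLOT + _SLOT, 10_000), gc=0.4, seed=rng)

    alignments: list[Alignment] = []
    truths: list[SyntheticTruth] = []
    genes: list[Gene] = []
    for idx, (cls, _rep) in enumerate(plan):
        contig = f"ctg{idx % n_contigs + 1}"
        at = (idx // n_contigs) * _SLOT + _SLOT // 2
        lid = f"{cls}_{idx}"
        if cls == "sirna_ladder":
            alns, truth = simulate_sirna_ladder(genome, contig, at, seed=rng, locus_id=lid)
        elif cls == "repeat_peak_piRNA":
            alns, truth = simulate_repeat_peak_locus(
                genome, contig, at, distinct_peaks=bool(idx % 2),
                dual_frac=0.15 if idx % 4 == 0 else 0.0, seed=rng, locus_id=lid)
        else:
            alns, truth = _SIMULATORS[cls](genome, contig, at, seed=rng, locus_id=lid)
        context = _CONTEXTS[idx % len(_CONTEXTS)]
        truth.params["context"] = context
        gene = _place_gene(contig, truth, context, idx)
        if gene is not None:
            genes.append(gene)
        alignments.extend(alns)
        truths.append(truth)
    return Cohort(genome, alignments, truths, AnnotationSet(genes), genes)


def _place_gene(contig: str, truth: SyntheticTruth, context: str, idx: int) -> Gene | None:
    """Engineer the annotation so the locus lands in the requested context."""
    pad = 800
    s, e = truth.start, truth.end
    if context == "intergenic":
        return None
    if context == "genic":
        # exon overlapping the locus body
        g = Gene(f"gene_{idx}", contig, s - pad, e + pad, "+")
        g.exons = [(s - pad, s - pad + 200), (s + (e - s) // 2 - 100, s + (e - s) // 2 + 100),
                   (e + pad - 200, e + pad)]
        return g
    # intronic: exons only at the gene's flanks, one large intron contains the locus
    g = Gene(f"gene_{idx}", contig, s - pad, e + pad, "+")
    g.exons = [(s - pad, s - pad + 150), (e + pad - 150, e + pad)]
    return g


def simulate_trimmed_pirna_cohort(seed: int = 0, n_loci: int = 45,
                                  biased_frac: float = 0.67,
                                  depth: int = 2800, span_len: int = 1000,
                                  include_ladder: bool = False) -> Cohort:
    """Cohort for the siRNA-absence scan: piRNA loci whose reads carry a
    heavy trimmed 20-23 nt tail but NO Dicer-ladder geometry.

    All loci are ping-pong loci with both strands populated; ``biased_frac``
    of them skew their background transcription to one strand (landing in
    the "bias" strand-ratio bin, ~2x) while the rest stay balanced
    (mixed/equal), so Dicer-signature positivity is mechanistically
    comparable across bins. With ``include_ladder`` one genuine processively
    diced siRNA ladder is appended, which the scan must rank first.
    """
    rng = np.random.default_rng(seed)
    plan = ["biased" if i < round(biased_frac * n_loci) else "balanced"
            for i in range(n_loci)]
    rng.shuffle(plan)
    if include_ladder:
        plan.append("sirna_ladder")
    n_contigs = 3
    per_contig = (len(plan) + n_contigs - 1) // n_contigs
    genome = make_genome(n_contigs, max(per_contig * _SLOT + _SLOT, 10_000), gc=0.4, seed=rng)
    alignments: list[Alignment] = []
    truths: list[SyntheticTruth] = []
    for idx, kind in enumerate(plan):
        contig = f"ctg{idx % n_contigs + 1}"
        at = (idx // n_contigs) * _SLOT + _SLOT // 2
        lid = f"{kind}_{idx}"
        if kind == "sirna_ladder":
            alns, truth = simulate_sirna_ladder(
                genome, contig, at, n_duplexes=12, per_duplex=25, seed=rng,
                locus_id=lid)
        else:
            alns, truth = simulate_pingpong_locus(
                genome, contig, at, span_len=span_len, depth=depth,
                pingpong_fraction=0.5, read_len_dist=TRIMMED_PIRNA_LEN_DIST,
                bg_plus_frac=0.9 if kind == "biased" else 0.5,
                seed=rng, locus_id=lid)
        alignments.extend(alns)
        truths.append(truth)
    return Cohort(genome, alignments, truths, AnnotationSet([]), [])


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_truth_tsv(truths: Sequence[SyntheticTruth], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tclass\tcontig\tstart\tend\tparams\n")
        for t in truths:
            fh.write(f"{t.locus_id}\t{t.cls}\t{t.contig}\t{t.start}\t{t.end}\t{t.params!r}\n")


def write_gff3(genes: Sequence[Gene], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.contig}\tsrnakit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            for i, (s, e) in enumerate(sorted(g.exons), start=1):
                fh.write(f"{g.contig}\tsrnakit\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}.e{i};Parent={g.gene_id}\n")


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write genome.fa, reads.sam, reads.bed, truth.tsv, annotations.gff3."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {k: os.path.join(out_dir, v) for k, v in
             dict(genome="genome.fa", sam="reads.sam", bed="reads.bed",
                  truth="truth.tsv", gff="annotations.gff3").items()}
    cohort.genome.to_fasta(paths["genome"])
    alns = sorted(cohort.alignments, key=lambda a: (a.contig, a.start, a.end, a.strand))
    write_sam(alns, paths["sam"], cohort.genome.contigs)
    write_bed(alns, paths["bed"])
    write_truth_tsv(cohort.truths, paths["truth"])
    write_gff3(cohort.genes, paths["gff"])
    return paths
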