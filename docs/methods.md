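# Methods

This note records the statistical conventions, the generative model behind
the synthetic data, and the design choices made where the underlying
procedures are genuinely open — in enough detail that every number the
package produces can be traced to a definition.

## Coordinate and sequence conventions

All internal coordinates are 0-based half-open; SAM and GFF3 (1-based) are
converted only at format boundaries. Read sequences are stored in read
orientation, 5′→3′, with U as T; minus-strand SAM records are
reverse-complemented on ingest. A read's 5′ base is `start` on the plus
strand and `end − 1` on the minus strand. Multimapper counts come from the
NH tag (SAM) or the score column (BED dialect); records without NH are
treated as unique and logged once. Reads containing N are kept for interval
statistics but excluded from nucleotide-bias denominators, avoiding biased
base counts.

## Overlap statistics

For a plus/minus read pair the 5′–5′ overlap is
`o = five_prime(minus) − five_prime(plus) + 1`, defined only when each 5′
end lies within the partner's span (equivalently 1 ≤ o ≤ min of the two
lengths). Histograms count all opposite-strand pairs for o = 1..30 via a
5′-position index; the result is provably identical to exhaustive all-pairs
counting, which the tests verify against an independent numpy-broadcast
oracle on random loci up to 2,000 reads.

z-scores use the whole window as background — `z[o] = (c[o] − mean)/sd`
with population SD and the signal bin included — the convention of standard
ping-pong scoring tools. Two consequences worth knowing: (i) with a
dominant signal bin, z saturates near √(window − 1) ≈ 5.4, so values
around 5 mean "essentially all pairs at this register", and (ii) z is
scale-free — duplicating every read leaves it unchanged — and for a fixed
locus span it *decreases* with depth once background pairs (quadratic in
depth) outgrow engineered signal pairs (linear). Pair counting defaults to
per-alignment (weighted by collapsed counts); a per-species mode collapses
identical reads first, making the statistic invariant to amplification.
Whether ping-pong counting should be restricted to equal-length mates is
ambiguous in the field's usage; both modes are exposed
(`same_length_only`), and the Dicer score is always same-length by
definition (`o = L − 2` among L-mers).

## Phasing

Distances are positional, not abundance-weighted: multiple reads at one 5′
position collapse to a single position, whose 3′ end is taken from the
modal read length there (ties broken toward the longer read). For
consecutive distinct 5′ positions on one strand,
`d = five_prime(next) − three_prime(prev)`, so immediately adjacent reads
give d = 1; Zucchini processing shows up at d = 1–3. With 30-mers at gap 1,
consecutive 5′ starts are 30 nt apart and the 5′-anchored U profile
(1-indexed, offset 1 = the read's own first base) re-peaks at offset 31 —
the next read's 1U. The U profile reads the genome base on the read's
strand so it extends past each read's 3′ end; without a genome it falls
back to read sequences.

## Hairpin duplex geometry

The mature:star duplex overhangs are computed from the antiparallel pairing
register of the hairpin: for an idealized precursor whose outermost bases
pair, genome position x pairs with `C − x`, `C = precursor_start +
precursor_end − 1` (any symmetric extension of the precursor preserves C).
The two 3′ overhangs are then `a1 + b2 − 1 − C` (base-side) and
`a2 + b1 − 1 − C` (loop-side) for arms `[a1,a2)`, `[b1,b2)`; minus-strand
hairpins are reflected first. A canonical Drosha/Dicer product gives
(2, 2). Thresholds are read literally: 5′ precision must strictly exceed
0.90, star coverage must strictly exceed 8 reads (i.e. ≥ 9), with star
reads counted within ±2 nt of the annotated star 5′ end. Precision is
assessed on the mature arm only by default. The short-loop scan requires
strict Watson–Crick stems (G:U off by default, available as a flag) because
the phenomenon of interest is *perfect* short-loop hairpins; hairpin
*discovery* is deliberately out of scope — candidates enter from an
external predictor or the generator.

## Locus discovery

"Coverage ≥ 200 reads" is read as a per-base depth threshold on the
combined-strand track (the natural meaning of filtering a bedgraph), and
the 500-bp merge is strict: islands with gap < 500 merge, a gap of exactly
500 stays split. Reads are assigned to a locus by any overlap; after
merging, a read can touch at most one locus. Multimapping coverage defaults
to one unit per alignment, with a 1/n_hits-weighted mode available — both
are provided because the right choice depends on library complexity.
Clustering of row-normalized size profiles uses Ward linkage on Euclidean
distance with cluster labels re-indexed by descending mean read length so
that "cluster 1" is always the longest-read group.

## piRNA classification

Selection requires locus length > 1,000 bp and at least one exact 10-nt
overlap pair among 15–31 nt reads (an optional z threshold is available;
one literal pair is the default because selection precedes scoring). Strand
bins use a single pseudocount on the minority strand: < 5× no bias, 5–10×
(inclusive) strand-biased, > 10× uni-strand. Genic context takes precedence
over intronic when a locus touches both exon and intron; intronic requires
complete containment in one intron. The repeat-peak ("non-arthropod") call
is operationalized as a peak concentration index — the share of reads at
the top-10 5′ positions — with a locus called repeat-peak when PCI ≥ 0.8
*and* distinct 5′ positions ≤ 5 % of locus length; both raw metrics are
reported so any call can be audited, and loci under 50 reads are left in
the default class with a low-depth flag. Repeat typing: one sequence
holding ≥ 50 % of reads is a single-read repeat, otherwise a multi-read
motif; ≥ 10 % minority-strand reads makes a locus dual-strand.

## siRNA scan

The 20–23 nt locus search uses a strict > 30 depth threshold. The
strand-ratio bins are taken as stated (equal 1–1.1, mixed 1.2–1.9, bias
≥ 2×) and the definition's gaps are resolved explicitly — (1.1, 1.2) to
mixed, (1.9, 2.0) to bias — with the raw ratio always emitted for
re-binning. Phased runs are counted over duplex anchors: plus-strand
21-mer 5′ positions holding a 19-nt-overlap partner, chained when exactly
21 nt apart (the head-to-tail register processive dicing leaves); chains of
≥ 3 anchors are runs, shorter chains distributive duplexes. The absence
statement is a one-sided two-proportion z-test: among Dicer-z-positive
loci, is the mixed/equal share higher than the cohort's base rate? A large
p-value (α = 0.01) is the expected outcome in a genome without siRNAs, and
the scan's power is demonstrated separately by spiking in one true ladder,
which must rank first by (Dicer z, 21/21 pair count).

## Synthetic data: what it emulates and what it does not

The generator writes locus structures into an i.i.d. random genome
(GC = 0.4 by default) and emits error-free reads whose sequences are
extracted from the (edited) genome, so every signature is a genuine
property of the alignments, never of hard-coded read strings. Defaults are
chosen to mirror the data regimes the pipeline targets: piRNA read lengths
peaked at 29–30 nt (26–32 range), miRNA arms of 22 nt with 2-nt-overhang
star placement and 95 % 5′ precision, ping-pong loci with half their reads
in exact 10-nt-overlap pairs and 0.7 U1/A10 biases (the canonical
asymmetry), phased trains at gaps 1–3 with 0.9 U1 bias decided once per
position, repeat loci of ≥ 3 identical-sequence peaks, and 15–20 nt debris
with no engineered structure. First-base biases are exact probabilities
(the alternative base is drawn from the three non-target bases), so
recovery tests can use binomial bounds directly.

Not emulated: sequencing errors, quality scores, adapters, PCR duplicates,
true multimapping (n_hits is carried but placements are single), transposon
sequence families, expression dynamics across libraries, and polymorphism
within repeat units. Passing tests therefore demonstrate the correctness of
the geometry and statistics, not robustness to alignment noise — on real
data the upstream aligner and its parameters own those errors.

Cohort sizes are scaled to the package's test harness: 20 loci per class,
per-locus depths of 300–600 reads, and discovery at min_cov = 3 for the
end-to-end cohort (per-base coverage scales with depth × read length /
span, so the literal 200-read threshold corresponds to far deeper
libraries; the 200/500 boundary semantics are exercised exactly on
constructed tracks). The siRNA-scan cohort uses 45 one-kb loci at depth
2,800 with a heavy trimmed 20–23 nt tail, two-thirds of them
strand-skewed, so Dicer-signature positivity is mechanistically comparable
across strand bins.

## Numerical details and degenerate inputs

z-scores are reported as not-available when the window SD is zero (fewer
than two reads, or a single occupied bin pattern that is constant);
first-base bias is not-available when no read has a scored first base;
empty clusters and empty loci raise. Bedgraph output merges adjacent
equal-depth bins and omits zero runs; TSV writers emit a header even for
empty record sets; floats print to six significant digits. All generator
randomness flows from one integer seed through `numpy.random.default_rng`,
and identical seeds produce byte-identical FASTA/SAM/BED/TSV outputs.
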