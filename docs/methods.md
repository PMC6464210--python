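# Methods

This note documents the models, conventions and numerical choices
behind plastotype, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinate model

All internal intervals are 0-based half-open on the forward strand of
the record they belong to; user-facing TSV/GFF3 output is converted to
1-based inclusive (the convention of the plastome literature), BED
stays 0-based half-open. Because plastomes are circular, an interval
may span the origin; this is encoded as `start > end` and means
`[start, L) ∪ [0, end)`. Ambiguity codes other than N are mapped to N
on input with a logged warning, because every downstream scanner
assumes a five-letter alphabet; N is treated as "no evidence"
throughout (it never matches in repeat or IR detection and never counts
as a substitution).

## Quadripartite structure detection

The inverted repeats are defined as the longest pair of disjoint,
exactly reverse-complementary substrings on the circle. Detection
seeds k-mer matches (k = 20 for the default 1,000 bp minimum IR)
between the genome and its reverse complement, extends each seed
maximally in both directions with circular wrap, de-duplicates by
diagonal and keeps the longest disjoint pair, ties broken by leftmost
start. The shorter inter-IR arc is the SSC, the longer the LSC, and
IRb is the repeat copy immediately following the LSC, giving the
canonical LSC–IRb–SSC–IRa order. Exactness is deliberate: assembled
plastome IRs are exact by construction, and an exact criterion makes
the detector deterministic and testable; a mismatch-tolerant mode is
out of scope. If no pair reaches the minimum length a structured
"no-IR" result is returned with the whole genome as single copy, not an
exception.

GC content is (G+C)/(A+C+G+T) with N excluded from both counts; an
all-N sequence has undefined GC (`None`). The whole-genome GC is
exactly the length-weighted mean of the compartment values, which the
tests assert to 1e-9.

## Gene census and region extraction

Genes are counted once per name: a gene whose features lie entirely
within both IRs is merged into one entry and also reported in a
separate duplicated list, matching how published plastome tables count
(e.g. 114 unique genes with 18 IR-duplicated entries). Trans-spliced
genes are treated as independent features for spacer purposes (their
exons are not concatenated across the genome).

Three region classes are extracted: protein-coding genes (concatenated
exons), introns (gaps between consecutive exons of a multi-exon
feature, numbered along the strand), and intergenic spacers (maximal
gaps between consecutive feature footprints in circular order, named
`upstream–downstream` with an en-dash, since gene names themselves
contain hyphens). Abutting or overlapping features produce no spacer;
zero-length spacers are never emitted. A spacer duplicated by the IRs
is emitted once with an `IR-duplicate` tag (the IRa mirror is dropped
when its reverse complement matches an IRb spacer). Genes straddling a
compartment boundary take the compartment of their midpoint; spacers
that straddle report `junction`.

## Variability statistic (S/P, I/P)

For each region aligned across genomes, `S` is the number of columns
holding at least two distinct non-gap, non-N nucleotides and `I` the
number of indel events, both expressed as fractions of the aligned
length `P`. An indel event is a maximal run of consecutive columns in
which the same subset of sequences is gapped, so a deletion shared
identically by several genomes counts once; a per-sequence counting
mode is available (`indel_mode="per-sequence"`) since the literature
rarely states its convention. Columns whose only variation involves N
contribute to neither statistic.

The internal aligner substitutes for an external multiple aligner on
the near-identical sequences this pipeline deals in: each sequence is
aligned to the first (reference) by an optimal global pairwise
alignment with affine gaps (match +1, mismatch −2; a gap of length g
scores −(5 + 2g)), and the pairwise alignments are merged on reference
coordinates with the once-a-gap-always-a-gap rule, insertions
left-aligned within their block. This reference-based progressive
scheme is exact for isolated variants and adequate below ~2 kb at high
identity; it is not a general-purpose MSA, and pre-computed alignments
can be passed through instead (`mode="prealigned"`). The pairwise step
is verified against an exhaustive affine-gap optimum on all short
pairs in the tests.

The hotspot filter keeps regions with aligned length between 500 and
1,500 bp (the practical Sanger amplicon window, applied to `P` since
aligned and raw lengths differ negligibly here) whose S/P **or** I/P
strictly exceeds the mean of their category (coding vs noncoding),
sorted by S/P descending with name tie-breaks. Strict inequality means
a region sitting exactly at the mean is excluded.

## SSR scanning and census

A cpSSR locus is a maximal perfect run of a primitive motif (length
1–6) whose whole-copy count reaches the per-motif-length minimum —
defaults 10, 6, 5, 5, 5, 5 for mono- through hexanucleotides, the
conventional plastome settings. Primitivity suppresses degenerate
re-reports (poly-A is never also AA×n); overlapping runs of distinct
primitive motifs are both reported. Maximality means one more base on
either side breaks the periodicity. N never participates. Motif
classes are canonical under rotation and strand: the class is the
lexicographically smallest rotation of the motif or its reverse
complement, labelled with its reverse-complement partner (or, for
self-reverse-complementary classes such as AT, the next orbit member),
giving A/T, C/G, AT/TA, AC/GT, AG/CT.

Circular genomes additionally scan a 60 bp window wrapped past the
origin (six times the mononucleotide minimum, enough for any
threshold-length repeat crossing the junction) and replace truncated
linear fragments with the full wrapped locus. Consecutive loci
separated by at most 100 bp (the conventional compound-SSR
interruption, configurable) are flagged as one compound group; the
member loci stay in the totals. IRa and IRb are both scanned, and a
locus and its IR mirror are both reported, matching how published
censuses tally the repeats separately. Census percentages are
recomputed from counts at two decimals, half-up.

## Diagnostic-locus discovery

Whole-genome comparison of ~150 kb near-identical genomes uses unique
shared k-mer anchors (k = 21, unique in every genome, greedily chained
co-linearly and thinned to non-overlap) rather than full dynamic
programming; the inter-anchor gaps (≤10 kb) are aligned with the
internal aligner. If the anchor chain covers less than 90 % of the
reference the input is too divergent for this scheme and an error
advises externally aligned input. Variant columns become SNP loci;
maximal identical-gap-pattern runs become indel events. An indel whose
alleles are all whole-copy multiples of one primitive motif adjacent to
a motif run in the reference is re-expressed as an SSR-length locus
with per-genome repeat counts — homopolymer length variants, the
dominant plastome polymorphism class, are therefore reported as counts
rather than raw indels.

A locus is *diagnostic* when its alleles are constant within every
labelled group and differ between at least one pair of groups. This
fixed-difference criterion has no frequency tolerance because the
intended samples are clonal cultivars; a single within-group
disagreement disqualifies a locus.

## Marker definition and genotyping

An SSR-length locus is packaged as a marker: the flanking bases on each
side of the repeat (default 20 bp), trimmed of any locus-facing bases
that would extend the run (otherwise the repeat count would be
ambiguous), a genotype table mapping repeat count to (genotype,
chemotype) — shipped as human-editable JSON so new alleles can be added
without code change — and an optional primer pair. The default table
maps 11 repeats to Genotype A / patchoulol-type and 10 to Genotype B /
pogostone-type.

Typing tries each read on both strands, locates the left flank within a
Hamming tolerance (default 2), counts exact whole copies of the motif,
and verifies the right flank immediately after the run; an interrupted
run fails the right-flank check and excludes that read. The consensus
is the modal per-read count, with ties undetermined: replication
slippage shifts counts by ±1 symmetrically, so the mode is the
maximum-likelihood choice and a mean would not even be an integer. For
slippage probability p < 0.5 the modal count converges to the truth as
reads accumulate; at p = 0.2 with 15 reads the error probability is
negligible, which the end-to-end tests exercise over 50 samples.

In-silico PCR matches each primer within a mismatch budget (default 1)
except the three 3'-terminal bases, which must match exactly — an
approximation of the polymerase extension requirement. Both strands
are searched, convergent site pairs within the product cap (default
5,000 bp) are emitted in forward-primer orientation, circular templates
are searched past the origin, and more than ten products triggers a
non-specificity warning.

## Synthetic data: what it emulates, and what it does not

The generator builds a base genome LSC + IRb + SSC + revcomp(IRb) with
the four junction bases forced non-complementary so the planted IR pair
is exactly maximal. Defaults are study-shaped: 20 kb LSC, 4 kb IRs,
3 kb SSC, 20 genes (multi-exon and IR-duplicated genes included, laid
out as a miniature plastid gene catalogue so region names like
`ycf3–trnS-GGA` exist by construction), 8 planted SSRs across
compartments and contexts, a diagnostic A-homopolymer of 10 vs 11
repeats in the ycf3–trnS-GGA spacer, three cultivars in two groups
(two pogostone-type, one patchoulol-type), three background
substitutions private to one member of the two-sample group (so they
are within-group polymorphic and must never surface as diagnostic),
slippage p = 0.2 and 15 reads per sample.

Background sequence is rejection-sampled against the SSR thresholds:
offending runs are resampled until a scan finds nothing, so the planted
loci are provably the only loci and precision/recall are measurable
exactly. After assembly, every emitted genome is re-scanned and the
build is retried with a derived seed if any chance structure slipped
through. Identical spec + seed give byte-identical output (the
generator uses Python's deterministic string-seeded PRNG, never
hash-dependent seeding).

Limitations: synthetic genomes are GC-balanced (~50 %) rather than
AT-rich like real plastomes, their background is repeat-free by
construction (real spacers are AT-rich and repeat-dense), slippage is
limited to ±1 repeat (the dominant empirical mode; larger shifts are
excluded so the modal-consensus property is provable at p < 0.5), and
reads carry no substitution errors outside the tolerance the flank
matching absorbs. Passing on synthetic data therefore demonstrates the
correctness of the algorithms under their stated models, not robustness
to assembly artefacts, imperfect repeats or heterogeneous error
profiles.

## Problem sizes and determinism

The test suite and the acceptance script run on the 31 kb default
genomes: 20 replicate cultivar sets for structure and SSR recovery,
one 50-sample set for end-to-end genotyping, and 200 spiked random
sequences (≤2 kb) for the scanner-versus-enumeration check. These
sizes exercise every code path — circular wrap, IR mirrors, multi-exon
genes, compound SSRs — while keeping a full run in tens of seconds on
one CPU. All randomness flows from explicit integer seeds; re-running
any stage with the same manifest reproduces byte-identical outputs.
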