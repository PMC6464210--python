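"""Quadripartite structure detection and region extraction.

Angiosperm plastomes are circular molecules partitioned into a large
single-copy region (LSC), a small single-copy region (SSC) and two
exactly reverse-complementary inverted repeats (IRb, IRa), in the
canonical order LSC - IRb - SSC - IRa.  The detector finds the longest
pair of disjoint, exactly reverse-complementary substrings on the
circle by seeded k-mer matching against the reverse complement with
maximal extension (circular wrap allowed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from .coords import CoordinateInterval, FeatureAnnotation, PlastomeRecord, revcomp

logger = logging.getLogger(__name__)

#: spacer names join the flanking gene names with an en-dash, as in
#: plastome literature ("ycf3–trnS-GGA"); gene names themselves may
#: contain ASCII hyphens.
IGS_SEP = "–"


@dataclass
class QuadripartiteStructure:
    """LSC/IRb/SSC/IRa intervals plus per-region GC contents."""

    found: bool
    genome_length: int
    lsc: CoordinateInterval | None = None
    irb: CoordinateInterval | None = None
    ssc: CoordinateInterval | None = None
    ira: CoordinateInterval | None = None
    gc_whole: float | None = None
    gc_lsc: float | None = None
    gc_ssc: float | None = None
    gc_ir: float | None = None

    @property
    def ir_length(self) -> int:
        return self.irb.length(self.genome_length) if self.irb else 0

    def compartment_of(self, pos: int) -> str | None:
        for name in ("lsc", "irb", "ssc", "ira"):
            iv = getattr(self, name)
            if iv is not None and iv.contains(pos):
                return {"lsc": "LSC", "irb": "IRb", "ssc": "SSC", "ira": "IRa"}[name]
        return None

    def as_row(self, identifier: str, n_genes=None) -> dict[str, object]:
        def fmt_gc(x):
            return f"{x * 100:.1f}%" if x is not None else "NA"

        row: dict[str, object] = {
            "sample": identifier,
            "size_bp": self.genome_length,
            "LSC_bp": self.lsc.length(self.genome_length) if self.lsc else self.genome_length,
            "SSC_bp": self.ssc.length(self.genome_length) if self.ssc else 0,
            "IR_bp": self.ir_length,
            "GC_overall": fmt_gc(self.gc_whole),
            "GC_LSC": fmt_gc(self.gc_lsc),
            "GC_SSC": fmt_gc(self.gc_ssc),
            "GC_IR": fmt_gc(self.gc_ir),
        }
        if n_genes is not None:
            row.update(n_genes)
        return row


def gc_content(sequence: str) -> float | None:
    """(G+C) / (A+C+G+T); N excluded from both counts; None if no ACGT bases."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        return None
    return gc / denom


def _arcs_overlap(s1: int, m1: int, s2: int, m2: int, L: int) -> bool:
    """Do circular arcs [s1, s1+m1) and [s2, s2+m2) (mod L) intersect?"""
    d = (s2 - s1) % L
    if d < m1:
        return True
    return (s1 - s2) % L < m2


def _interval_from_arc(start: int, length: int, L: int) -> CoordinateInterval:
    end = start + length
    if end <= L:
        return CoordinateInterval(start, end)
    return CoordinateInterval(start, end - L)


def detect_quadripartite(
    record: PlastomeRecord, min_ir_length: int = 1000
) -> QuadripartiteStructure:
    """Find the inverted-repeat pair and derive the quadripartite layout.

    The longest pair of disjoint, exactly reverse-complementary
    substrings on the circle is taken as IRa/IRb (ties broken by
    leftmost start); the shorter inter-IR arc is the SSC, the longer the
    LSC, and IRb is the repeat copy immediately following the LSC.  If
    no pair of at least ``min_ir_length`` exists a structured "no-IR"
    result is returned with the whole genome treated as single-copy.
    """
    S = record.sequence
    L = len(S)
    whole_gc = gc_content(S)
    no_ir = QuadripartiteStructure(
        found=False,
        genome_length=L,
        lsc=CoordinateInterval(0, L),
        gc_whole=whole_gc,
        gc_lsc=whole_gc,
    )
    k = max(8, min(20, min_ir_length))
    if L < 2 * min_ir_length:
        return no_ir
    R = revcomp(S)

    index: dict[str, list[int]] = {}
    for i in range(L - k + 1):
        kmer = S[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)

    best: tuple[int, int, int] | None = None  # (length, segA_start, segB_start)
    covered: dict[int, list[tuple[int, int]]] = {}

    for j in range(0, L - k + 1, k):
        kmer = R[j : j + k]
        if "N" in kmer:
            continue
        for i in index.get(kmer, ()):
            diag = (i - j) % L
            spans = covered.get(diag)
            if spans and any(a <= j < b for a, b in spans):
                continue
            # maximal extension with circular wrap, capped at L total
            ext_r = 0
            while ext_r + k < L:
                a = S[(i + k + ext_r) % L]
                if a == "N" or a != R[(j + k + ext_r) % L]:
                    break
                ext_r += 1
            ext_l = 0
            while ext_l + ext_r + k < L:
                a = S[(i - 1 - ext_l) % L]
                if a == "N" or a != R[(j - 1 - ext_l) % L]:
                    break
                ext_l += 1
            mlen = k + ext_l + ext_r
            i0 = (i - ext_l) % L
            j0 = (j - ext_l) % L
            covered.setdefault(diag, []).append((j0, j0 + mlen))
            if mlen < min_ir_length:
                continue
            # R[j0 : j0+mlen] is the reverse complement of S[L-j0-mlen : L-j0]
            seg2 = (L - j0 - mlen) % L
            if _arcs_overlap(i0, mlen, seg2, mlen, L):
                continue  # self-overlapping palindrome, not an IR pair
            sA, sB = sorted((i0, seg2))
            cand = (mlen, sA, sB)
            if best is None or (cand[0], -cand[1]) > (best[0], -best[1]):
                best = cand

    if best is None:
        return no_ir
    mlen, sA, sB = best
    arc1_start, arc1_len = (sA + mlen) % L, (sB - sA - mlen) % L
    arc2_start, arc2_len = (sB + mlen) % L, (sA - sB - mlen) % L
    if arc1_len >= arc2_len:
        lsc_start, lsc_len, ssc_start, ssc_len = arc1_start, arc1_len, arc2_start, arc2_len
        irb_start, ira_start = sB, sA
    else:
        lsc_start, lsc_len, ssc_start, ssc_len = arc2_start, arc2_len, arc1_start, arc1_len
        irb_start, ira_start = sA, sB
    if lsc_len == 0 or ssc_len == 0:
        return no_ir

    lsc = _interval_from_arc(lsc_start, lsc_len, L)
    ssc = _interval_from_arc(ssc_start, ssc_len, L)
    irb = _interval_from_arc(irb_start, mlen, L)
    ira = _interval_from_arc(ira_start, mlen, L)
    assert irb.extract(S) == revcomp(ira.extract(S)), "IR identity violated"
    return QuadripartiteStructure(
        found=True,
        genome_length=L,
        lsc=lsc,
        irb=irb,
        ssc=ssc,
        ira=ira,
        gc_whole=whole_gc,
        gc_lsc=gc_content(lsc.extract(S)),
        gc_ssc=gc_content(ssc.extract(S)),
        gc_ir=gc_content(irb.extract(S)),
    )


@dataclass
class GeneCensus:
    """Unique-gene counts by kind plus the IR-duplicated gene list."""

    total: int
    pcg: int
    trna: int
    rrna: int
    duplicated: list[str]
    feature_copies: int


def _feature_in_ir(feat: FeatureAnnotation, structure: QuadripartiteStructure) -> bool:
    if not structure.found:
        return False
    for iv in feat.intervals:
        for ir in (structure.ira, structure.irb):
            if ir.contains_interval(iv):
                break
        else:
            return False
    return True


def gene_census(
    record: PlastomeRecord, structure: QuadripartiteStructure | None = None
) -> GeneCensus:
    """Count unique genes by name (IR duplicates merged), broken down by kind."""
    by_name: dict[str, list[FeatureAnnotation]] = {}
    for feat in record.annotations:
        by_name.setdefault(feat.name, []).append(feat)
    kinds = {"CDS": 0, "tRNA": 0, "rRNA": 0}
    duplicated = []
    for name in sorted(by_name):
        feats = by_name[name]
        kinds[feats[0].kind] += 1
        if structure is not None and sum(_feature_in_ir(f, structure) for f in feats) >= 2:
            duplicated.append(name)
    return GeneCensus(
        total=sum(kinds.values()),
        pcg=kinds["CDS"],
        trna=kinds["tRNA"],
        rrna=kinds["rRNA"],
        duplicated=duplicated,
        feature_copies=len(record.annotations),
    )


@dataclass(frozen=True)
class RegionRecord:
    """One extracted molecular region (gene, intron or intergenic spacer)."""

    name: str
    category: str  # PCG | intron | IGS
    interval: CoordinateInterval
    sequence: str
    compartment: str | None = None
    copy_tag: str = "unique"


def _compartment(
    iv: CoordinateInterval, structure: QuadripartiteStructure | None, L: int
) -> str | None:
    if structure is None or not structure.found:
        return None
    comp_start = structure.compartment_of(iv.start)
    last = iv.end - 1 if not iv.spans_origin else (iv.end - 1) % L
    comp_end = structure.compartment_of(last)
    if comp_start != comp_end:
        return "junction"
    return comp_start


def _validate_exon_order(feat: FeatureAnnotation) -> None:
    ivs = feat.intervals
    starts = [iv.start for iv in ivs]
    ordered = starts == sorted(starts) if feat.strand == "+" else starts == sorted(
        starts, reverse=True
    )
    for a, b in zip(sorted(ivs, key=lambda x: x.start), sorted(ivs, key=lambda x: x.start)[1:]):
        if b.start < a.end:
            raise ValueError(f"feature {feat.name}: overlapping exon intervals")
    if not ordered:
        raise ValueError(f"feature {feat.name}: exons out of order along the strand")


def extract_regions(
    record: PlastomeRecord, structure: QuadripartiteStructure | None = None
) -> list[RegionRecord]:
    """Extract the three region classes: PCGs, introns and intergenic spacers.

    PCG = concatenated exon sequence per unique protein-coding gene;
    introns are the gaps between consecutive exons of multi-exon
    features (named gene.intron1, ... along the strand); IGS are maximal
    gaps between consecutive feature footprints in circular order, named
    "upstream–downstream".  Regions duplicated by the IRs are emitted
    once, tagged ``IR-duplicate``.  Abutting or overlapping features
    produce no spacer.
    """
    L = len(record.sequence)
    for feat in record.annotations:
        _validate_exon_order(feat)

    regions: list[RegionRecord] = []

    # one representative feature per gene name (leftmost copy)
    by_name: dict[str, list[FeatureAnnotation]] = {}
    for feat in record.annotations:
        by_name.setdefault(feat.name, []).append(feat)
    for name in sorted(by_name):
        feats = sorted(by_name[name], key=lambda f: f.span().start)
        rep = feats[0]
        n_ir_copies = (
            sum(_feature_in_ir(f, structure) for f in feats) if structure else 0
        )
        tag = "IR-duplicate" if n_ir_copies >= 2 else "unique"
        if rep.kind == "CDS":
            span = rep.span()
            regions.append(
                RegionRecord(
                    name,
                    "PCG",
                    span,
                    record.feature_sequence(rep),
                    _compartment(span, structure, L),
                    tag,
                )
            )
        # introns of any multi-exon feature (CDS or tRNA)
        exons = rep.genomic_sorted()
        if len(exons) > 1:
            gaps = []
            for a, b in zip(exons, exons[1:]):
                if b.start > a.end:
                    gaps.append(CoordinateInterval(a.end, b.start, rep.strand))
            if rep.strand == "-":
                gaps.reverse()  # intron numbering follows the strand
            for idx, gap in enumerate(gaps, start=1):
                regions.append(
                    RegionRecord(
                        f"{name}.intron{idx}",
                        "intron",
                        gap,
                        record.fetch(gap),
                        _compartment(gap, structure, L),
                        tag,
                    )
                )

    # intergenic spacers between consecutive feature footprints on the circle
    footprints = sorted(
        ((f.span(), f.name) for f in record.annotations), key=lambda t: t[0].start
    )
    blocks: list[list] = []  # [start, end, first_name, last_name]
    for span, name in footprints:
        if blocks and span.start <= blocks[-1][1]:
            if span.end > blocks[-1][1]:
                blocks[-1][1] = span.end
                blocks[-1][3] = name
        else:
            blocks.append([span.start, span.end, name, name])

    def _circular_gap(gs: int, ge: int) -> CoordinateInterval | None:
        glen = (ge - gs) % L
        if glen == 0:
            return None
        gs %= L
        if gs + glen <= L:
            return CoordinateInterval(gs, gs + glen)
        return CoordinateInterval(gs, (gs + glen) % L)

    for i, blk in enumerate(blocks):
        nxt = blocks[(i + 1) % len(blocks)]
        if i < len(blocks) - 1:
            if nxt[0] <= blk[1]:
                continue  # abutting or overlapping features: no IGS
            iv = CoordinateInterval(blk[1], nxt[0])
        else:  # wrap-around gap (also the single-block case)
            iv = _circular_gap(blk[1], nxt[0])
            if iv is None:
                continue
        regions.append(
            RegionRecord(
                f"{blk[3]}{IGS_SEP}{nxt[2]}",
                "IGS",
                iv,
                iv.extract(record.sequence),
                _compartment(iv, structure, L),
                "unique",
            )
        )

    # drop the IRa mirror of each IRb spacer, tagging the surviving copy
    if structure is not None and structure.found:
        ira, irb = structure.ira, structure.irb
        irb_igs = {
            r.sequence
            for r in regions
            if r.category == "IGS" and irb.contains_interval(r.interval)
        }
        ira_igs = {
            r.sequence
            for r in regions
            if r.category == "IGS" and ira.contains_interval(r.interval)
        }
        out: list[RegionRecord] = []
        for r in regions:
            if (
                r.category == "IGS"
                and ira.contains_interval(r.interval)
                and revcomp(r.sequence) in irb_igs
            ):
                continue
            if (
                r.category == "IGS"
                and irb.contains_interval(r.interval)
                and revcomp(r.sequence) in ira_igs
            ):
                r = RegionRecord(
                    r.name, r.category, r.interval, r.sequence, r.compartment, "IR-duplicate"
                )
            out.append(r)
        regions = out
    return sorted(regions, key=lambda r: (r.interval.start, r.name))
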