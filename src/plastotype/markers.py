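"""Group-diagnostic locus discovery, in-silico PCR and amplicon genotyping.

The discovery step compares near-identical whole plastomes via unique
shared k-mer anchors (k = 21 by default) chained co-linearly, with the
inter-anchor gaps aligned by the internal aligner.  Variant columns are
classified as SNPs, indels, or — when the alleles are length variants of
a tandem repeat — SSR-length loci expressed as repeat counts.  A locus
is diagnostic when its alleles are constant within every labelled group
and differ between at least one pair of groups (a fixed difference,
appropriate for clonal cultivars).

Genotyping counts the repeat between two marker flanks in each amplicon
read and takes the modal count across reads as the consensus (ties are
undetermined), because replication-slippage noise is symmetric around
the true length.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .coords import CoordinateInterval, PlastomeRecord, revcomp
from .ssr import is_primitive
from .structure import extract_regions
from .variability import align_region

logger = logging.getLogger(__name__)

ANCHOR_K = 21
MAX_ANCHOR_GAP = 10_000


@dataclass
class GroupedGenomeSet:
    """Labelled genomes: at least one record per group, at least two groups."""

    records: list[PlastomeRecord]
    groups: dict[str, str]  # record identifier -> group label

    def __post_init__(self) -> None:
        missing = [r.identifier for r in self.records if r.identifier not in self.groups]
        if missing:
            raise ValueError(f"records without a group label: {missing}")
        if len(set(self.groups.values())) < 2:
            raise ValueError("need at least two groups")


@dataclass(frozen=True)
class DiagnosticLocus:
    """A variant whose alleles perfectly partition the groups."""

    kind: str  # SNP | indel | SSR-length
    reference_id: str
    interval: CoordinateInterval  # on the reference record
    context: str
    alleles: dict  # group label -> base / sequence / repeat count
    motif: str | None = None  # for SSR-length loci


@dataclass
class MarkerDefinition:
    """A packaged SSR-length marker: flanks, motif, genotype table, primers."""

    name: str
    left_flank: str
    right_flank: str
    motif: str
    genotype_table: dict[int, tuple[str, str]]  # repeat count -> (genotype, chemotype)
    primers: tuple[str, str] | None = None
    flank_mismatch_tolerance: int = 2

    def __post_init__(self) -> None:
        if len(self.left_flank) < 18 or len(self.right_flank) < 18:
            logger.warning(
                "marker %s: flank shorter than 18 bp; typing may be unspecific",
                self.name,
            )

    def to_json(self, path: str | Path) -> None:
        doc = {
            "name": self.name,
            "left_flank": self.left_flank,
            "right_flank": self.right_flank,
            "motif": self.motif,
            "genotype_table": {
                str(k): {"genotype": g, "chemotype": c}
                for k, (g, c) in self.genotype_table.items()
            },
            "primers": list(self.primers) if self.primers else None,
            "flank_mismatch_tolerance": self.flank_mismatch_tolerance,
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkerDefinition":
        doc = json.loads(Path(path).read_text())
        return cls(
            name=doc["name"],
            left_flank=doc["left_flank"],
            right_flank=doc["right_flank"],
            motif=doc["motif"],
            genotype_table={
                int(k): (v["genotype"], v["chemotype"])
                for k, v in doc["genotype_table"].items()
            },
            primers=tuple(doc["primers"]) if doc.get("primers") else None,
            flank_mismatch_tolerance=doc.get("flank_mismatch_tolerance", 2),
        )


@dataclass
class GenotypeCall:
    """Typing result for one sample's amplicon reads."""

    sample: str
    per_read_counts: list[int]
    consensus: int | None
    genotype: str
    chemotype: str
    strand_found: str | None
    evidence: int
    reason: str = ""


@dataclass(frozen=True)
class AmpliconProduct:
    """One in-silico PCR product, reported in forward-primer orientation."""

    template_id: str
    interval: CoordinateInterval
    length: int
    sequence: str


# ---------------------------------------------------------------------------
# anchor-based whole-genome comparison


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    counts: Counter[str] = Counter()
    for i in range(len(seq) - k + 1):
        counts[seq[i : i + k]] += 1
    pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if counts[kmer] == 1 and "N" not in kmer:
            pos[kmer] = i
    return pos


def _anchor_chain(
    seqs: Mapping[str, str], reference: str, k: int
) -> list[dict[str, int]]:
    """Non-overlapping co-linear anchors: k-mers unique in every genome."""
    maps = {sid: _unique_kmers(s, k) for sid, s in seqs.items()}
    ref_map = maps[reference]
    shared = set(ref_map)
    for sid, m in maps.items():
        shared &= set(m)
    anchors = []
    last = {sid: -k for sid in seqs}
    for kmer in sorted(shared, key=lambda km: ref_map[km]):
        pos = {sid: maps[sid][kmer] for sid in seqs}
        if all(pos[sid] >= last[sid] + k for sid in seqs):
            anchors.append(pos)
            last = pos
    return anchors


def discover_diagnostic_loci(
    genomes: GroupedGenomeSet,
    reference: str | None = None,
    k: int = ANCHOR_K,
    max_gap: int = MAX_ANCHOR_GAP,
    min_coverage: float = 0.9,
) -> list[DiagnosticLocus]:
    """Scan near-identical labelled genomes for fixed differences.

    Returns only loci whose alleles perfectly partition the groups,
    mapped to reference coordinates and named by the containing region
    when the reference carries annotations.
    """
    records = {r.identifier: r for r in genomes.records}
    reference = reference or genomes.records[0].identifier
    if reference not in records:
        raise ValueError(f"reference {reference!r} not among the records")
    order = [reference] + [rid for rid in records if rid != reference]
    seqs = {rid: records[rid].sequence for rid in order}
    ref_seq = seqs[reference]
    Lr = len(ref_seq)

    anchors = _anchor_chain(seqs, reference, k)
    if not anchors:
        raise ValueError(
            "no shared unique anchors; genomes too divergent — supply an "
            "external alignment instead"
        )
    covered = len(anchors) * k
    segments = []  # (ref_gap_start, per-genome gap strings)
    for a, b in zip(anchors, anchors[1:]):
        gaps = {sid: seqs[sid][a[sid] + k : b[sid]] for sid in order}
        if any(len(g) > max_gap for g in gaps.values()):
            continue
        covered += len(gaps[reference])
        segments.append((a[reference] + k, gaps))
    # leading and trailing unanchored stretches
    head = {sid: seqs[sid][: anchors[0][sid]] for sid in order}
    tail = {sid: seqs[sid][anchors[-1][sid] + k :] for sid in order}
    if all(len(g) <= max_gap for g in head.values()):
        covered += len(head[reference])
        segments.insert(0, (0, head))
    if all(len(g) <= max_gap for g in tail.values()):
        covered += len(tail[reference])
        segments.append((anchors[-1][reference] + k, tail))
    if covered / Lr < min_coverage:
        raise ValueError(
            f"anchor chain covers only {covered / Lr:.1%} of the reference; "
            "supply externally aligned input"
        )

    raw_loci: list[DiagnosticLocus] = []
    group_of = genomes.groups
    for ref_gap_start, gaps in segments:
        gap_strings = [gaps[sid] for sid in order]
        if len(set(gap_strings)) == 1:
            continue
        raw_loci.extend(
            _call_segment_variants(
                order, gap_strings, ref_gap_start, reference, ref_seq
            )
        )

    diagnostic: list[DiagnosticLocus] = []
    regions = None
    if records[reference].annotations:
        regions = extract_regions(records[reference])
    for locus in raw_loci:
        per_group: dict[str, set] = {}
        for sid, allele in locus.alleles.items():
            per_group.setdefault(group_of[sid], set()).add(allele)
        if any(len(v) != 1 for v in per_group.values()):
            continue  # polymorphic within a group
        collapsed = {g: next(iter(v)) for g, v in per_group.items()}
        if len(set(collapsed.values())) < 2:
            continue  # same allele everywhere
        context = locus.context
        if regions:
            for reg in regions:
                if reg.interval.contains_interval(locus.interval):
                    context = reg.name
                    break
        diagnostic.append(
            DiagnosticLocus(
                locus.kind, reference, locus.interval, context, collapsed, locus.motif
            )
        )
    return sorted(diagnostic, key=lambda l: l.interval.start)


def _call_segment_variants(
    order: Sequence[str],
    gap_strings: Sequence[str],
    ref_gap_start: int,
    reference_id: str,
    ref_seq: str,
) -> list[DiagnosticLocus]:
    """Variants within one inter-anchor segment (per-genome alleles)."""
    aligned = align_region("segment", list(order), list(gap_strings))
    rows = aligned.sequences
    ncol = aligned.aligned_length
    ref_row = rows[0]
    # ref coordinate of each column (position of the ref base, or of the
    # next ref base for insertion columns)
    ref_pos = []
    rp = ref_gap_start
    for col in range(ncol):
        ref_pos.append(rp)
        if ref_row[col] != "-":
            rp += 1

    loci: list[DiagnosticLocus] = []
    # SNP columns
    for col in range(ncol):
        column = [r[col] for r in rows]
        if "-" in column:
            continue
        bases = {c for c in column if c != "N"}
        if len(bases) >= 2:
            alleles = {sid: rows[i][col] for i, sid in enumerate(order)}
            loci.append(
                DiagnosticLocus(
                    "SNP",
                    reference_id,
                    CoordinateInterval(ref_pos[col], ref_pos[col] + 1),
                    "",
                    alleles,
                )
            )
    # indel events: maximal runs of identical gap pattern
    col = 0
    while col < ncol:
        pattern = frozenset(i for i, r in enumerate(rows) if r[col] == "-")
        if not pattern:
            col += 1
            continue
        start = col
        while col < ncol and frozenset(
            i for i, r in enumerate(rows) if r[col] == "-"
        ) == pattern:
            col += 1
        loci.append(
            _classify_indel_event(
                order, rows, start, col, ref_pos, reference_id, ref_seq
            )
        )
    return loci


def _repeat_run(seq: str, pos: int, motif: str) -> tuple[int, int]:
    """(run_start, copies) of the maximal motif run covering/adjacent to pos."""
    m = len(motif)
    start = pos
    while start - m >= 0 and seq[start - m : start] == motif:
        start -= m
    if seq[start : start + m] != motif:
        # pos may sit just past the run; back off by one motif
        if start - m >= 0 and seq[start - m : start] == motif:
            start -= m
    copies = 0
    while seq[start + copies * m : start + (copies + 1) * m] == motif:
        copies += 1
    return start, copies


def _classify_indel_event(
    order: Sequence[str],
    rows: Sequence[str],
    c0: int,
    c1: int,
    ref_pos: Sequence[int],
    reference_id: str,
    ref_seq: str,
) -> DiagnosticLocus:
    """Re-express a tandem-repeat length difference as repeat counts,
    otherwise report a plain indel with per-genome allele strings."""
    alleles_str = {
        sid: rows[i][c0:c1].replace("-", "") for i, sid in enumerate(order)
    }
    event_iv = CoordinateInterval(ref_pos[c0], max(ref_pos[c0] + 1, ref_pos[c1 - 1] + 1))
    longest = max(alleles_str.values(), key=len)
    for m in range(1, 7):
        if len(longest) % m != 0 or len(longest) == 0:
            continue
        motif = longest[:m]
        if not is_primitive(motif) or longest != motif * (len(longest) // m):
            continue
        if all(
            len(a) % m == 0 and a == motif * (len(a) // m) for a in alleles_str.values()
        ):
            run_start, ref_copies = _repeat_run(ref_seq, ref_pos[c0], motif)
            if ref_copies >= 2:
                ref_allele = alleles_str[reference_id]
                counts = {
                    sid: ref_copies + (len(a) - len(ref_allele)) // m
                    for sid, a in alleles_str.items()
                }
                interval = CoordinateInterval(run_start, run_start + ref_copies * m)
                return DiagnosticLocus(
                    "SSR-length", reference_id, interval, "", counts, motif
                )
    return DiagnosticLocus("indel", reference_id, event_iv, "", alleles_str)


# ---------------------------------------------------------------------------
# marker packaging


def build_marker_definition(
    locus: DiagnosticLocus,
    reference: PlastomeRecord,
    flank_length: int = 20,
    genotype_table: Mapping[int, tuple[str, str]] | None = None,
    primers: tuple[str, str] | None = None,
    name: str | None = None,
    flank_mismatch_tolerance: int = 2,
) -> MarkerDefinition:
    """Extract typing flanks around an SSR-length locus from the reference.

    Flank bases that would extend the repeat run are trimmed from the
    locus-facing ends (the trimmed shortfall is logged).
    """
    if locus.kind != "SSR-length":
        raise ValueError("marker definitions are built from SSR-length loci")
    seq = reference.sequence
    iv = locus.interval
    motif = locus.motif or seq[iv.start : iv.start + 1]
    m = len(motif)
    ls, le = iv.start - flank_length, iv.start
    rs, re_ = iv.end, iv.end + flank_length
    if ls < 0 or re_ > len(seq):
        raise ValueError("flank window extends beyond the reference sequence")
    left, right = seq[ls:le], seq[rs:re_]
    if "N" in left or "N" in right:
        raise ValueError("flank window contains N")
    t = 0
    while left and left[-1] == motif[(m - 1 - t) % m]:
        left = left[:-1]
        t += 1
    u = 0
    while right and right[0] == motif[u % m]:
        right = right[1:]
        u += 1
    if t or u:
        logger.info(
            "marker flanks trimmed by %d/%d repeat-continuing bases", t, u
        )
    table = dict(genotype_table) if genotype_table else {}
    if not table:
        for group, allele in locus.alleles.items():
            table[int(allele)] = (f"Genotype-{allele}", group)
    return MarkerDefinition(
        name=name or f"{locus.context or 'locus'}_{iv.start + 1}",
        left_flank=left,
        right_flank=right,
        motif=motif,
        genotype_table=table,
        primers=primers,
        flank_mismatch_tolerance=flank_mismatch_tolerance,
    )


# ---------------------------------------------------------------------------
# in-silico PCR


def _hamming_ok(a: str, b: str, max_mm: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > max_mm:
                return False
    return True


def _primer_sites(
    seq: str, primer: str, max_mm: int, exact_end: str, limit: int | None = None
) -> list[int]:
    """Start positions where the primer matches within ``max_mm`` mismatches.

    ``exact_end`` is 'right' when the primer's 3' terminus maps to the
    rightmost bases of the site (forward orientation) and 'left' when it
    maps to the leftmost (a reverse-complemented site); the terminal
    three bases must match exactly.
    """
    n, p = len(seq), len(primer)
    stop = (limit if limit is not None else n) - 0
    sites = []
    if exact_end == "right":
        tail = primer[-3:]
        for i in range(min(stop, n - p + 1)):
            if seq[i + p - 3 : i + p] == tail and _hamming_ok(seq[i : i + p], primer, max_mm):
                sites.append(i)
    else:
        head = primer[:3]
        for i in range(min(stop, n - p + 1)):
            if seq[i : i + 3] == head and _hamming_ok(seq[i : i + p], primer, max_mm):
                sites.append(i)
    return sites


def in_silico_pcr(
    template: PlastomeRecord,
    forward: str,
    reverse: str,
    max_mismatches: int = 1,
    max_product: int = 5000,
) -> list[AmpliconProduct]:
    """Locate convergent primer sites and emit every would-be product.

    Both strands are searched; the three 3'-terminal bases of each
    primer must match exactly (the polymerase-extension requirement).
    Circular templates are handled by extending the search past the
    origin.  Products are reported in forward-primer orientation.
    """
    forward, reverse = forward.upper(), reverse.upper()
    if len(forward) < 15 or len(reverse) < 15:
        raise ValueError("primers must be at least 15 bp")
    L = len(template.sequence)
    seq = template.sequence + (
        template.sequence[: min(max_product, L)] if template.circular else ""
    )
    rev_rc = revcomp(reverse)
    fwd_rc = revcomp(forward)

    products: dict[tuple[int, int], AmpliconProduct] = {}

    def add(start: int, seg: str, flipped: bool) -> None:
        gstart = start % L
        key = (gstart, len(seg))
        if key in products:
            return
        end = (gstart + len(seg)) % L if template.circular else gstart + len(seg)
        if end == 0:
            end = L
        iv = CoordinateInterval(gstart, end, "-" if flipped else "+")
        products[key] = AmpliconProduct(template.identifier, iv, len(seg), seg)

    # forward primer on '+', reverse primer downstream on '-'
    fwd_sites = _primer_sites(seq, forward, max_mismatches, "right", limit=L)
    rev_sites = _primer_sites(seq, rev_rc, max_mismatches, "left")
    for i in fwd_sites:
        for j in rev_sites:
            if j < i:
                continue
            plen = j + len(rev_rc) - i
            if 0 < plen <= max_product:
                add(i, seq[i : i + plen], flipped=False)
    # forward primer on '-', reverse primer upstream on '+'
    fwdrc_sites = _primer_sites(seq, fwd_rc, max_mismatches, "left")
    revp_sites = _primer_sites(seq, reverse, max_mismatches, "right", limit=L)
    for i in revp_sites:
        for j in fwdrc_sites:
            if j < i:
                continue
            plen = j + len(fwd_rc) - i
            if 0 < plen <= max_product:
                add(i, revcomp(seq[i : i + plen]), flipped=True)

    out = sorted(products.values(), key=lambda p: (p.interval.start, p.length))
    if len(out) > 10:
        logger.warning(
            "%d products for this primer pair — primers look non-specific", len(out)
        )
    return out


# ---------------------------------------------------------------------------
# genotyping


def _find_approx(haystack: str, needle: str, max_mm: int) -> int:
    """Leftmost best approximate occurrence (Hamming) or -1."""
    best, best_mm = -1, max_mm + 1
    n, p = len(haystack), len(needle)
    for i in range(n - p + 1):
        mm = 0
        for x, y in zip(haystack[i : i + p], needle):
            if x != y:
                mm += 1
                if mm >= best_mm:
                    break
        else:
            if mm < best_mm:
                best, best_mm = i, mm
                if mm == 0:
                    break
    return best


def _count_repeat_in_read(read: str, marker: MarkerDefinition) -> tuple[int | None, str]:
    """(repeat count, reason) for one oriented read; count None on failure."""
    tol = marker.flank_mismatch_tolerance
    pos = _find_approx(read, marker.left_flank, tol)
    if pos < 0:
        return None, "left flank not found"
    run_start = pos + len(marker.left_flank)
    m = len(marker.motif)
    c = 0
    while read[run_start + c * m : run_start + (c + 1) * m] == marker.motif:
        c += 1
    if c == 0:
        return None, "no repeat after left flank"
    right_at = run_start + c * m
    window = read[right_at : right_at + len(marker.right_flank)]
    if len(window) < len(marker.right_flank) or not _hamming_ok(
        window, marker.right_flank, tol
    ):
        return None, "right flank mismatch (interrupted run?)"
    return c, ""


def call_genotype(
    reads: Sequence[tuple[str, str]], marker: MarkerDefinition, sample: str = "sample"
) -> GenotypeCall:
    """Type one sample from its amplicon reads.

    Each read is tried on both strands; usable reads contribute one
    repeat count and the modal count is the consensus (tie ->
    undetermined).  Genotype and chemotype come only from the marker's
    genotype table; counts absent from the table are 'unknown'.
    """
    counts: list[int] = []
    strands: list[str] = []
    reasons: Counter[str] = Counter()
    for rid, read in reads:
        read = read.upper()
        c, why = _count_repeat_in_read(read, marker)
        strand = "+"
        if c is None:
            c, why2 = _count_repeat_in_read(revcomp(read), marker)
            strand = "-"
            why = why if c is None else ""
        if c is None:
            reasons[why] += 1
            logger.debug("read %s unusable: %s", rid, why)
            continue
        counts.append(c)
        strands.append(strand)
    if not counts:
        reason = "; ".join(f"{k} (x{v})" for k, v in reasons.most_common()) or "no reads"
        return GenotypeCall(sample, [], None, "unknown", "unknown", None, 0, reason)
    tally = Counter(counts).most_common()
    if len(tally) > 1 and tally[0][1] == tally[1][1]:
        return GenotypeCall(
            sample, counts, None, "unknown", "unknown", None, len(counts),
            "tie between modal repeat counts",
        )
    consensus = tally[0][0]
    genotype, chemotype = marker.genotype_table.get(consensus, ("unknown", "unknown"))
    strand = Counter(strands).most_common(1)[0][0]
    reason = "" if genotype != "unknown" else f"repeat count {consensus} not in table"
    return GenotypeCall(
        sample, counts, consensus, genotype, chemotype, strand, len(counts), reason
    )
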