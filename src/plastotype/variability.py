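"""Per-region variability statistics (S/P and I/P) and hotspot filtering.

For each homologous region aligned across genomes, S counts alignment
columns holding at least two distinct non-gap nucleotides and I counts
distinct indel events; both are reported as fractions of the aligned
length P.  An indel event is a maximal run of consecutive columns in
which the same subset of sequences is gapped, so an identical deletion
shared by several genomes counts once.  Columns whose only variation
involves N contribute to neither statistic: ambiguity is not evidence.

The internal aligner (a reference-based progressive scheme over optimal
pairwise global alignments with affine gap costs) substitutes for an
external multiple aligner on the near-identical sequences this pipeline
deals in; pre-computed alignments can be passed through instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import mean
from typing import Mapping, Sequence

from Bio import Align

logger = logging.getLogger(__name__)

#: scoring defaults: match +1, mismatch -2; a gap of length g scores -(5 + 2g)
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -2, -5, -2


def make_pairwise_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    # biopython charges open_gap_score for the first gapped position
    aligner.open_gap_score = GAP_OPEN + GAP_EXTEND
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def pairwise_align(a: str, b: str) -> tuple[float, str, str]:
    """Optimal global alignment of two sequences; (score, gapped_a, gapped_b)."""
    if not a or not b:  # degenerate: one single gap run (or nothing at all)
        n = max(len(a), len(b))
        score = 0 if n == 0 else GAP_OPEN + GAP_EXTEND * n
        return score, a or "-" * n, b or "-" * n
    aligner = make_pairwise_aligner()
    aln = aligner.align(a, b)[0]
    return aln.score, str(aln[0]), str(aln[1])


@dataclass
class AlignedRegion:
    """A gapped multiple alignment of one region across genomes."""

    name: str
    category: str  # coding | noncoding (free text allowed)
    identifiers: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError(f"region {self.name}: need >=2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"region {self.name}: unequal aligned lengths {sorted(lengths)}")
        for col in range(len(self.sequences[0])):
            if all(s[col] == "-" for s in self.sequences):
                raise ValueError(f"region {self.name}: all-gap column {col}")

    @property
    def aligned_length(self) -> int:
        return len(self.sequences[0])


def _strip_allgap_columns(seqs: list[str]) -> list[str]:
    keep = [i for i in range(len(seqs[0])) if any(s[i] != "-" for s in seqs)]
    return ["".join(s[i] for i in keep) for s in seqs]


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / n


def align_region(
    name: str,
    identifiers: Sequence[str],
    sequences: Sequence[str],
    category: str = "noncoding",
) -> AlignedRegion:
    """Progressively align near-identical sequences into one AlignedRegion.

    The first sequence acts as the reference: every other sequence is
    aligned to it pairwise (optimal affine-gap global alignment) and the
    pairwise alignments are merged column-wise on reference coordinates
    with the usual once-a-gap-always-a-gap rule; insertions relative to
    the reference are left-aligned within their insertion block.
    """
    if len(sequences) < 2:
        raise ValueError(f"region {name}: need >=2 sequences to align")
    ref = sequences[0]
    if len(ref) >= 20 and min(_identity(ref, s) for s in sequences[1:]) < 0.5:
        logger.warning("region %s: sequences <50%% identical; internal aligner "
                       "is intended for near-identical inputs", name)
    Lr = len(ref)
    # per-sequence: inserted strings before each ref position (index 0..Lr),
    # and the aligned character at each ref position ('-' for deletion)
    inserts: list[list[str]] = []
    at_ref: list[list[str]] = []
    for s in sequences[1:]:
        _, ga, gb = pairwise_align(ref, s)
        ins = [""] * (Lr + 1)
        chars = []
        rpos = 0
        for ca, cb in zip(ga, gb):
            if ca == "-":
                ins[rpos] += cb
            else:
                chars.append(cb)
                rpos += 1
        inserts.append(ins)
        at_ref.append(chars)
    block = [max(len(ins[i]) for ins in inserts) for i in range(Lr + 1)]
    rows: list[str] = []
    # reference row
    ref_row = []
    for i in range(Lr):
        ref_row.append("-" * block[i] + ref[i])
    ref_row.append("-" * block[Lr])
    rows.append("".join(ref_row))
    for ins, chars in zip(inserts, at_ref):
        row = []
        for i in range(Lr):
            row.append(ins[i].ljust(block[i], "-") + chars[i])
        row.append(ins[Lr].ljust(block[Lr], "-"))
        rows.append("".join(row))
    rows = _strip_allgap_columns(rows)
    return AlignedRegion(name, category, list(identifiers), rows)


def align_regions(
    named_sequences: Mapping[str, Sequence[tuple[str, str]]],
    categories: Mapping[str, str] | None = None,
    mode: str = "internal",
) -> list[AlignedRegion]:
    """Align every region present in at least two genomes.

    ``named_sequences`` maps region name -> [(sample_id, sequence), ...].
    In ``prealigned`` mode the sequences are validated (equal gapped
    lengths) and passed through with all-gap columns stripped.
    """
    if mode not in ("internal", "prealigned"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    out: list[AlignedRegion] = []
    for name in sorted(named_sequences):
        pairs = list(named_sequences[name])
        if len(pairs) < 2:
            logger.warning("region %s present in <2 genomes; skipped", name)
            continue
        ids = [p[0] for p in pairs]
        seqs = [p[1].upper() for p in pairs]
        category = (categories or {}).get(name, "noncoding")
        if mode == "prealigned":
            lengths = {len(s) for s in seqs}
            if len(lengths) != 1:
                raise ValueError(
                    f"region {name}: pre-aligned sequences differ in length"
                )
            out.append(AlignedRegion(name, category, ids, _strip_allgap_columns(seqs)))
        else:
            if len(set(seqs)) == 1:  # identical: trivial gap-free alignment
                out.append(AlignedRegion(name, category, ids, seqs))
            else:
                out.append(align_region(name, ids, seqs, category))
    return out


@dataclass(frozen=True)
class VariabilityStat:
    """S, I and P for one aligned region, plus the S/P and I/P fractions."""

    name: str
    category: str
    substitutions: int
    indel_events: int
    aligned_length: int

    @property
    def sp(self) -> float:
        return self.substitutions / self.aligned_length

    @property
    def ip(self) -> float:
        return self.indel_events / self.aligned_length


def compute_variability(
    aligned: AlignedRegion, indel_mode: str = "shared"
) -> VariabilityStat:
    """Count substitution columns and indel events in one alignment.

    ``indel_mode="shared"`` counts a maximal run of columns with an
    identical gapped-sequence subset as one event; ``"per-sequence"``
    counts each sequence's own gap runs separately.
    """
    if indel_mode not in ("shared", "per-sequence"):
        raise ValueError(f"unknown indel_mode {indel_mode!r}")
    seqs = aligned.sequences
    P = aligned.aligned_length
    S = 0
    I = 0
    prev_pattern: frozenset[int] = frozenset()
    for col in range(P):
        column = [s[col] for s in seqs]
        bases = {c for c in column if c not in ("-", "N")}
        if len(bases) >= 2:
            S += 1
        pattern = frozenset(i for i, c in enumerate(column) if c == "-")
        if pattern:
            if indel_mode == "shared":
                if pattern != prev_pattern:
                    I += 1
            else:
                started = pattern - prev_pattern
                I += len(started)
        prev_pattern = pattern
    return VariabilityStat(aligned.name, aligned.category, S, I, P)


@dataclass(frozen=True)
class HotspotCriteria:
    """Marker-candidate filter: Sanger-amplifiable size, above-average variability."""

    min_length: int = 500
    max_length: int = 1500

    def __post_init__(self) -> None:
        if self.min_length >= self.max_length:
            raise ValueError("min_length must be < max_length")


def hotspot_filter(
    stats: Sequence[VariabilityStat], criteria: HotspotCriteria | None = None
) -> list[VariabilityStat]:
    """Regions of suitable size whose S/P or I/P strictly exceeds the
    mean of their category; sorted by S/P descending, ties by name."""
    criteria = criteria or HotspotCriteria()
    if not stats:
        return []
    mean_sp: dict[str, float] = {}
    mean_ip: dict[str, float] = {}
    for cat in {s.category for s in stats}:
        group = [s for s in stats if s.category == cat]
        mean_sp[cat] = mean(s.sp for s in group)
        mean_ip[cat] = mean(s.ip for s in group)
    picked = [
        s
        for s in stats
        if criteria.min_length <= s.aligned_length <= criteria.max_length
        and (s.sp > mean_sp[s.category] or s.ip > mean_ip[s.category])
    ]
    return sorted(picked, key=lambda s: (-s.sp, s.name))
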