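"""Perfect microsatellite (cpSSR) detection, classification and census.

The scanner re-implements the classical perfect-SSR semantics used for
plastomes: a locus is a maximal run of a primitive motif of length 1-6
whose whole-copy count reaches a per-motif-length minimum (defaults
10, 6, 5, 5, 5, 5 for mono- through hexanucleotides).  N never
participates in a repeat.  Motifs are reported as-read plus a canonical
strand/rotation-independent class label (A/T, C/G, AT/TA, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

from .coords import CoordinateInterval, revcomp

#: window wrapped past the origin when scanning circular genomes;
#: 60 bp = 6 x the mononucleotide threshold, enough for any
#: threshold-length repeat spanning the junction.
JUNCTION_WINDOW = 60


@dataclass(frozen=True)
class SSRThresholds:
    """Minimum whole-copy counts per motif length, plus compound merge distance."""

    mono: int = 10
    di: int = 6
    tri: int = 5
    tetra: int = 5
    penta: int = 5
    hexa: int = 5
    compound_max_interruption: int = 100

    def __post_init__(self) -> None:
        for val in (self.mono, self.di, self.tri, self.tetra, self.penta, self.hexa):
            if val < 2:
                raise ValueError("minimum repeat counts must be >= 2")

    def min_count(self, motif_length: int) -> int:
        return (self.mono, self.di, self.tri, self.tetra, self.penta, self.hexa)[
            motif_length - 1
        ]


@dataclass(frozen=True)
class SSRLocus:
    """One perfect microsatellite (motif as read on the forward strand)."""

    motif: str
    motif_class: str
    repeat_count: int
    interval: CoordinateInterval
    compartment: str | None = None
    context: str | None = None
    compound_member: bool = False

    def key(self) -> tuple[int, str, int]:
        return (self.interval.start, self.motif, self.repeat_count)


def is_primitive(motif: str) -> bool:
    """True if the motif is not a repetition of a shorter motif."""
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def classify_motif(motif: str) -> str:
    """Canonical class label, invariant under rotation and strand.

    The class is the lexicographically smallest string among all cyclic
    rotations of the motif and of its reverse complement; the label pairs
    it with its reverse complement (or, for self-complementary classes,
    the next-smallest orbit member), ordered alphabetically — e.g. A/T,
    C/G, AT/TA, AC/GT.
    """
    if not motif or len(motif) > 6:
        raise ValueError(f"motif length must be 1-6, got {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    orbit = set()
    for m in (motif, revcomp(motif)):
        for i in range(len(m)):
            orbit.add(m[i:] + m[:i])
    canonical = min(orbit)
    partner = revcomp(canonical)
    if partner == canonical:
        others = sorted(orbit - {canonical})
        partner = others[0] if others else canonical
    a, b = sorted((canonical, partner))
    return f"{a}/{b}"


def _scan_linear(seq: str, thresholds: SSRThresholds) -> list[SSRLocus]:
    n = len(seq)
    loci: list[SSRLocus] = []
    for m in range(1, 7):
        min_count = thresholds.min_count(m)
        i = 0
        limit = n - m
        while i < limit:
            if seq[i] != seq[i + m] or seq[i] == "N":
                i += 1
                continue
            # maximal run of the period-m self-match starting at i
            j = i
            while j < limit and seq[j] == seq[j + m] and seq[j] != "N":
                j += 1
            stretch = (j - i) + m  # length of the periodic stretch at i
            count = stretch // m
            motif = seq[i : i + m]
            if count >= min_count and "N" not in motif and is_primitive(motif):
                interval = CoordinateInterval(i, i + count * m)
                loci.append(
                    SSRLocus(motif, classify_motif(motif), count, interval)
                )
            i = j + 1
    return loci


def scan_ssrs(
    seq: str, thresholds: SSRThresholds | None = None, circular: bool = False
) -> list[SSRLocus]:
    """All maximal perfect SSRs of primitive motifs meeting their thresholds.

    A longer-motif repeat that is merely a run of a shorter primitive
    motif (e.g. poly-A read as AA x n) is suppressed via the primitivity
    requirement.  In circular mode a 60 bp window wrapped past the origin
    is additionally scanned and origin-spanning loci are reported with
    wrap-around intervals; truncated linear fragments of such loci are
    dropped.
    """
    thresholds = thresholds or SSRThresholds()
    seq = seq.upper()
    L = len(seq)
    loci = _scan_linear(seq, thresholds)

    if circular and L > 2 * JUNCTION_WINDOW:
        w = JUNCTION_WINDOW
        window = seq[L - w :] + seq[:w]
        wrapped: list[SSRLocus] = []
        for loc in _scan_linear(window, thresholds):
            gstart = (L - w + loc.interval.start) % L
            gend = (gstart + loc.interval.length()) % L
            if gstart + loc.interval.length() <= L or gend == 0:
                continue  # fully on one side of the origin: already found
            wrapped.append(
                replace(loc, interval=CoordinateInterval(gstart, gend, "+"))
            )
        for wloc in wrapped:
            period = len(wloc.motif)
            span = set(wloc.interval.positions(L))
            loci = [
                l
                for l in loci
                if not (
                    len(l.motif) == period
                    and set(l.interval.positions(L)) <= span
                )
            ]
            loci.append(wloc)
    return sorted(loci, key=lambda l: (l.interval.start, len(l.motif)))


def merge_compound(
    loci: Sequence[SSRLocus], max_interruption: int = 100
) -> tuple[list[SSRLocus], int]:
    """Flag SSRs separated by <= ``max_interruption`` bp as compound members.

    Returns the loci (compound flags set) and the number of compound
    groups (each group of >=2 member loci counted once).
    """
    ordered = sorted(loci, key=lambda l: l.interval.start)
    groups: list[list[int]] = []
    current = [0] if ordered else []
    for idx in range(1, len(ordered)):
        gap = ordered[idx].interval.start - ordered[idx - 1].interval.end
        if gap <= max_interruption:
            current.append(idx)
        else:
            groups.append(current)
            current = [idx]
    if current:
        groups.append(current)
    compound_groups = [g for g in groups if len(g) >= 2]
    flagged = set(i for g in compound_groups for i in g)
    out = [
        replace(loc, compound_member=(i in flagged)) for i, loc in enumerate(ordered)
    ]
    return out, len(compound_groups)


def _pct(count: int, total: int) -> float:
    if total == 0:
        return 0.0
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


_LENGTH_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass
class SSRCensus:
    """Table-3-shaped tallies of an SSR scan."""

    total: int
    by_compartment: dict[str, int]
    by_compartment_pct: dict[str, float]
    by_motif_length: dict[str, int]
    by_motif_class: dict[str, int]
    by_context: dict[str, int]
    compound_count: int
    compound_pct: float

    def as_row(self, identifier: str) -> dict[str, object]:
        row: dict[str, object] = {"sample": identifier, "N": self.total}
        for comp in ("LSC", "SSC", "IRa", "IRb"):
            row[comp] = (
                f"{self.by_compartment.get(comp, 0)} "
                f"({self.by_compartment_pct.get(comp, 0.0):.2f})"
            )
        row["Compound"] = f"{self.compound_count} ({self.compound_pct:.2f})"
        for name in _LENGTH_NAMES.values():
            if self.by_motif_length.get(name):
                row[name] = self.by_motif_length[name]
        for cls, n in sorted(self.by_motif_class.items()):
            row[cls] = f"{n} ({_pct(n, self.total):.2f})"
        return row


def summarize_census(
    loci: Sequence[SSRLocus],
    structure=None,
    regions: Sequence | None = None,
    genome_length: int | None = None,
    max_interruption: int = 100,
) -> tuple[list[SSRLocus], SSRCensus]:
    """Assign compartment/context to each locus and tally the census.

    ``structure`` is a :class:`~plastotype.structure.QuadripartiteStructure`
    (or None); ``regions`` a list of
    :class:`~plastotype.structure.RegionRecord` used for the functional
    context (CDS / intron / IGS by containment).  Compartment of a
    boundary-straddling locus is that of its midpoint.
    """
    annotated: list[SSRLocus] = []
    for loc in loci:
        compartment = None
        if structure is not None and structure.found:
            mid = loc.interval.midpoint(genome_length)
            compartment = structure.compartment_of(mid)
        context = "unassigned"
        if regions:
            containing = [
                reg
                for reg in regions
                if reg.interval.contains_interval(loc.interval)
            ]
            if containing:  # smallest containing region is the most specific
                reg = min(containing, key=lambda r: r.interval.length(genome_length))
                context = f"{reg.category}:{reg.name}"
        annotated.append(replace(loc, compartment=compartment, context=context))

    total = len(annotated)
    by_comp: dict[str, int] = {}
    by_len: dict[str, int] = {}
    by_class: dict[str, int] = {}
    by_ctx: dict[str, int] = {}
    for loc in annotated:
        if loc.compartment:
            by_comp[loc.compartment] = by_comp.get(loc.compartment, 0) + 1
        lname = _LENGTH_NAMES[len(loc.motif)]
        by_len[lname] = by_len.get(lname, 0) + 1
        by_class[loc.motif_class] = by_class.get(loc.motif_class, 0) + 1
        ctx = (loc.context or "unassigned").split(":", 1)[0]
        by_ctx[ctx] = by_ctx.get(ctx, 0) + 1
    flagged, n_groups = merge_compound(annotated, max_interruption)
    census = SSRCensus(
        total=total,
        by_compartment=by_comp,
        by_compartment_pct={k: _pct(v, total) for k, v in by_comp.items()},
        by_motif_length=by_len,
        by_motif_class=by_class,
        by_context=by_ctx,
        compound_count=n_groups,
        compound_pct=_pct(n_groups, total),
    )
    return flagged, census
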