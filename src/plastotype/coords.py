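"""Shared coordinate model and genome record types.

Every interval in this package is 0-based, half-open, on the forward
strand of the record it belongs to.  User-facing tables (TSV/GFF3) are
converted to the 1-based inclusive convention at write time; BED output
stays 0-based half-open.

A plastome is circular, so an interval may span the origin.  This is
encoded as ``start > end`` and denotes ``[start, L) ∪ [0, end)`` where
``L`` is the genome length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_KINDS = ("CDS", "tRNA", "rRNA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N} (case kept)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class CoordinateInterval:
    """A genomic interval, 0-based half-open; ``start > end`` wraps the origin."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValueError(f"negative coordinate in {self}")
        if self.start == self.end:
            raise ValueError(f"zero-length interval {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def spans_origin(self) -> bool:
        return self.start > self.end

    def length(self, genome_length: int | None = None) -> int:
        if not self.spans_origin:
            return self.end - self.start
        if genome_length is None:
            raise ValueError("genome_length required for an origin-spanning interval")
        return genome_length - self.start + self.end

    def positions(self, genome_length: int | None = None) -> Iterator[int]:
        if not self.spans_origin:
            yield from range(self.start, self.end)
        else:
            if genome_length is None:
                raise ValueError("genome_length required for an origin-spanning interval")
            yield from range(self.start, genome_length)
            yield from range(0, self.end)

    def contains(self, pos: int) -> bool:
        if not self.spans_origin:
            return self.start <= pos < self.end
        return pos >= self.start or pos < self.end

    def contains_interval(self, other: "CoordinateInterval") -> bool:
        if other.spans_origin and not self.spans_origin:
            return False
        return self.contains(other.start) and (
            self.contains(other.end - 1) if other.end > 0 else self.contains(0)
        )

    def midpoint(self, genome_length: int | None = None) -> int:
        if not self.spans_origin:
            return (self.start + self.end) // 2
        if genome_length is None:
            raise ValueError("genome_length required for an origin-spanning interval")
        return (self.start + self.length(genome_length) // 2) % genome_length

    def extract(self, seq: str) -> str:
        """Forward-strand bases covered by the interval (no strand flip)."""
        if not self.spans_origin:
            return seq[self.start : self.end]
        return seq[self.start :] + seq[: self.end]

    def to_onebased(self) -> tuple[int, int]:
        """(start, end) in the 1-based inclusive convention of the reports."""
        return self.start + 1, self.end

    def shifted(self, offset: int, genome_length: int | None = None) -> "CoordinateInterval":
        if self.spans_origin:
            raise ValueError("cannot shift an origin-spanning interval")
        return CoordinateInterval(self.start + offset, self.end + offset, self.strand)


@dataclass(frozen=True)
class FeatureAnnotation:
    """One annotated gene feature.

    ``intervals`` are the exons, ordered along the feature's strand
    (ascending genomic coordinates on '+', descending on '-').  A gene
    duplicated in the inverted repeats appears as two features sharing a
    name, each tagged ``IR-duplicate``.
    """

    name: str
    kind: str
    intervals: tuple[CoordinateInterval, ...]
    copy_tag: str = "unique"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("feature with empty gene name")
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r} for {self.name}")
        if not self.intervals:
            raise ValueError(f"feature {self.name} has no intervals")

    @property
    def strand(self) -> str:
        return self.intervals[0].strand

    def span(self) -> CoordinateInterval:
        """Genomic footprint from leftmost start to rightmost end (non-wrapping)."""
        start = min(iv.start for iv in self.intervals)
        end = max(iv.end for iv in self.intervals)
        return CoordinateInterval(start, end, self.strand)

    def genomic_sorted(self) -> tuple[CoordinateInterval, ...]:
        return tuple(sorted(self.intervals, key=lambda iv: iv.start))


@dataclass
class PlastomeRecord:
    """A (usually circular) plastid genome with its feature annotations."""

    identifier: str
    sequence: str
    circular: bool = True
    annotations: list[FeatureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.identifier}: empty sequence")
        self.sequence = self.sequence.upper()
        L = len(self.sequence)
        for feat in self.annotations:
            for iv in feat.intervals:
                if iv.spans_origin:
                    if iv.start >= L or iv.end > L:
                        raise ValueError(
                            f"feature {feat.name}: interval {iv} outside sequence of length {L}"
                        )
                elif iv.end > L:
                    raise ValueError(
                        f"feature {feat.name}: interval {iv} outside sequence of length {L}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, interval: CoordinateInterval) -> str:
        """Strand-aware sequence of an interval (reverse-complemented on '-')."""
        raw = interval.extract(self.sequence)
        return revcomp(raw) if interval.strand == "-" else raw

    def feature_sequence(self, feat: FeatureAnnotation) -> str:
        """Concatenated exon sequence in transcription order."""
        return "".join(self.fetch(iv) for iv in feat.intervals)
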