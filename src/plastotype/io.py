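"""Readers and writers for the formats the pipeline touches.

GenBank flat files and FASTA are read with biopython; the located-feature
writers emit BED (0-based half-open), GFF3 and TSV (both 1-based
inclusive, the convention used throughout plastome literature).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.SeqFeature import SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .coords import CoordinateInterval, FeatureAnnotation, PlastomeRecord, VALID_KINDS

logger = logging.getLogger(__name__)

_NON_ACGTN = re.compile(r"[^ACGTN]")

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "FMET": "fM",
}


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


def _clean_sequence(seq: str, source: str) -> str:
    """Upper-case and map ambiguity codes other than N to N (logged)."""
    seq = seq.upper()
    n_amb = len(_NON_ACGTN.findall(seq))
    if n_amb:
        logger.warning("%s: %d ambiguity bases mapped to N", source, n_amb)
        seq = _NON_ACGTN.sub("N", seq)
    return seq


def normalize_trna_name(name: str, anticodon: str | None = None) -> str:
    """Normalize tRNA gene names to the trnX-NNN form used in region labels."""
    m = re.match(r"^tRNA[-_ ]?([A-Za-z]{3,4})(?:[-_ (]*([ACGTUacgtu]{3}))?", name)
    if m:
        aa = _AA3TO1.get(m.group(1).upper(), m.group(1))
        name = f"trn{aa}"
        if m.group(2):
            anticodon = anticodon or m.group(2)
    if name.lower().startswith("trn") and anticodon and "-" not in name:
        name = f"{name}-{anticodon.upper().replace('U', 'T')}"
    return name


def _feature_name(feat: SeqFeature) -> str | None:
    q = feat.qualifiers
    for key in ("gene", "standard_name", "product"):
        if key in q and q[key]:
            name = str(q[key][0]).strip()
            if feat.type == "tRNA":
                anticodon = None
                if "anticodon" in q and q["anticodon"]:
                    ac = re.search(r"seq\s*:\s*([acgtu]{3})", str(q["anticodon"][0]), re.I)
                    anticodon = ac.group(1) if ac else None
                name = normalize_trna_name(name, anticodon)
            return name
    return None


def read_genbank(path: str | Path) -> PlastomeRecord:
    """Read a single-record GenBank flat file into a :class:`PlastomeRecord`.

    CDS, tRNA and rRNA features are captured with their gene name and
    exon intervals ordered along the strand; all other feature kinds are
    ignored.  Sequences are upper-cased and ambiguity codes mapped to N.
    """
    path = Path(path)
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    try:
        seq = str(rec.seq)
    except Exception as exc:  # UndefinedSequenceError for records without ORIGIN
        raise ParseError(f"{path}: record has no ORIGIN sequence") from exc
    if not seq:
        raise ParseError(f"{path}: record has no ORIGIN sequence")
    seq = _clean_sequence(seq, str(path))
    circular = rec.annotations.get("topology", "circular") == "circular"

    annotations: list[FeatureAnnotation] = []
    for feat in rec.features:
        if feat.type not in VALID_KINDS:
            continue
        name = _feature_name(feat)
        if name is None:
            logger.warning("%s: %s feature without a name skipped", path, feat.type)
            continue
        strand = "-" if feat.location.strand == -1 else "+"
        parts = sorted(feat.location.parts, key=lambda p: int(p.start))
        intervals = []
        for part in parts:
            s, e = int(part.start), int(part.end)
            if s < 0 or e > len(seq):
                raise ParseError(
                    f"{path}: feature {name} interval [{s},{e}) outside sequence"
                )
            intervals.append(CoordinateInterval(s, e, strand))
        if strand == "-":
            intervals.reverse()  # exon order along the minus strand
        annotations.append(FeatureAnnotation(name, feat.type, tuple(intervals)))
    return PlastomeRecord(rec.id or path.stem, seq, circular, annotations)


def read_fasta(path: str | Path, aligned: bool = False) -> list[tuple[str, str]]:
    """Read FASTA into (identifier, sequence) pairs in file order.

    With ``aligned=True`` gap characters are preserved and all sequences
    must have equal length.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not aligned:
            seq = seq.replace("-", "")
        body = seq.replace("-", "")
        cleaned = _clean_sequence(body, f"{path}:{rec.id}")
        if cleaned != body:  # re-insert gaps after cleaning
            out, it = [], iter(cleaned)
            for ch in seq:
                out.append("-" if ch == "-" else next(it))
            seq = "".join(out)
        pairs.append((rec.id, seq))
    if not pairs:
        raise ParseError(f"{path}: empty FASTA")
    if aligned:
        lengths = {len(s) for _, s in pairs}
        if len(lengths) > 1:
            raise ParseError(f"{path}: aligned sequences differ in length {sorted(lengths)}")
    return pairs


def write_fasta(pairs: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in pairs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_features(
    items: Sequence[tuple[str, CoordinateInterval]],
    fmt: str,
    path: str | Path,
    seqid: str = "genome",
    genome_length: int | None = None,
) -> None:
    """Write labelled intervals as BED, GFF3 or TSV.

    BED is 0-based half-open; GFF3 and TSV report 1-based inclusive
    coordinates.  Rows are sorted by start.  An origin-spanning interval
    is written as two BED lines sharing a name suffix.
    """
    fmt = fmt.upper()
    if fmt not in ("BED", "GFF3", "TSV"):
        raise ValueError(f"unknown format {fmt!r}")
    items = sorted(items, key=lambda kv: (kv[1].start, kv[1].end, kv[0]))
    lines: list[str] = []
    if fmt == "BED":
        for label, iv in items:
            if iv.spans_origin:
                if genome_length is None:
                    raise ValueError("genome_length required to write origin-spanning BED")
                lines.append(f"{seqid}\t{iv.start}\t{genome_length}\t{label}|part1\t0\t{iv.strand}")
                lines.append(f"{seqid}\t0\t{iv.end}\t{label}|part2\t0\t{iv.strand}")
            else:
                lines.append(f"{seqid}\t{iv.start}\t{iv.end}\t{label}\t0\t{iv.strand}")
    elif fmt == "GFF3":
        lines.append("##gff-version 3")
        for label, iv in items:
            end = iv.end if not iv.spans_origin else (genome_length or 0) + iv.end
            lines.append(
                f"{seqid}\tplastotype\tregion\t{iv.start + 1}\t{end}\t.\t{iv.strand}\t.\tName={label}"
            )
    else:  # TSV, 1-based inclusive
        lines.append("name\tstart\tend\tstrand")
        for label, iv in items:
            s1, e1 = iv.start + 1, (iv.end if not iv.spans_origin else (genome_length or 0) + iv.end)
            lines.append(f"{label}\t{s1}\t{e1}\t{iv.strand}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_genbank(record: PlastomeRecord, path: str | Path) -> None:
    """Write a PlastomeRecord as a GenBank flat file (used by the simulator)."""
    from Bio.SeqFeature import CompoundLocation, SimpleLocation

    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.identifier,
        name=record.identifier[:16],
        description="synthetic plastome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
        },
    )
    for feat in record.annotations:
        strand = -1 if feat.strand == "-" else 1
        parts = [SimpleLocation(iv.start, iv.end, strand) for iv in feat.genomic_sorted()]
        if strand == -1:
            parts.reverse()
        loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        seqrec.features.append(
            SeqFeature(loc, type=feat.kind, qualifiers={"gene": [feat.name]})
        )
    SeqIO.write([seqrec], str(path), "genbank")
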