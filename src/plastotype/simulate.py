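"""Seeded synthetic plastome sets with planted ground truth.

The generator emulates the study design this toolkit targets: a handful
of near-identical cultivar plastomes in two chemotype groups, each a
circular quadripartite genome (LSC + IRb + SSC + IRa with IRa the exact
reverse complement of IRb), annotated with non-overlapping genes (some
multi-exon, some duplicated into both IRs), carrying planted perfect
SSRs in an otherwise SSR-free background, one group-diagnostic
homopolymer locus in a named intergenic spacer, and optional
within-group background substitutions.  Amplicon reads for the
diagnostic locus are simulated with symmetric ±1-repeat replication
slippage.

Everything is driven by a single integer seed; identical spec + seed
give byte-identical output.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path


from .coords import CoordinateInterval, FeatureAnnotation, PlastomeRecord, revcomp
from .markers import MarkerDefinition, in_silico_pcr
from .ssr import SSRThresholds, scan_ssrs

ALPHABET = "ACGT"

#: default genotype table: repeat count -> (genotype, chemotype), the
#: convention for the patchouli chemotype marker (11 repeats = Genotype A
#: = patchoulol-type; 10 = Genotype B = pogostone-type)
DEFAULT_GENOTYPE_TABLE: dict[int, tuple[str, str]] = {
    11: ("Genotype A", "patchoulol-type"),
    10: ("Genotype B", "pogostone-type"),
}

# gene catalogue: (name, kind, intron count, compartment); placement
# follows list order within each compartment.  ycf3 and trnS-GGA are
# adjacent so the diagnostic spacer between them exists by construction.
_GENE_CATALOGUE: list[tuple[str, str, int, str]] = [
    ("psbA", "CDS", 0, "LSC"),
    ("trnK-UUU", "tRNA", 1, "LSC"),
    ("matK", "CDS", 0, "LSC"),
    ("rps16", "CDS", 0, "LSC"),
    ("atpA", "CDS", 0, "LSC"),
    ("atpF", "CDS", 1, "LSC"),
    ("rpoC1", "CDS", 1, "LSC"),
    ("rpoB", "CDS", 0, "LSC"),
    ("ycf3", "CDS", 2, "LSC"),
    ("trnS-GGA", "tRNA", 0, "LSC"),
    ("psaA", "CDS", 0, "LSC"),
    ("rbcL", "CDS", 0, "LSC"),
    ("petB", "CDS", 1, "LSC"),
    ("rpl16", "CDS", 1, "LSC"),
    ("clpP", "CDS", 0, "LSC"),
    ("ndhF", "CDS", 0, "SSC"),
    ("ccsA", "CDS", 0, "SSC"),
    ("rrn16", "rRNA", 0, "IRb"),
    ("rrn23", "rRNA", 0, "IRb"),
    ("ndhB", "CDS", 1, "IRb"),
]

DIAGNOSTIC_IGS = ("ycf3", "trnS-GGA")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic cultivar set (defaults = study-shaped)."""

    seed: int = 0
    lsc_length: int = 20_000
    irb_length: int = 4_000
    ssc_length: int = 3_000
    n_genes: int = 20
    planted_ssrs: tuple[tuple[str, int, str], ...] = (
        ("A", 10, "LSC"),
        ("T", 12, "LSC"),
        ("AT", 6, "LSC"),
        ("C", 10, "LSC"),
        ("AG", 6, "LSC:intron"),
        ("A", 11, "SSC"),
        ("AAT", 5, "SSC"),
        ("A", 10, "IRb"),
    )
    diagnostic_motif: str = "A"
    diagnostic_alleles: tuple[tuple[str, int], ...] = (
        ("pogostone-type", 10),
        ("patchoulol-type", 11),
    )
    samples: tuple[tuple[str, str], ...] = (
        ("SP1", "pogostone-type"),
        ("GY1", "pogostone-type"),
        ("HN1", "patchoulol-type"),
    )
    n_background_edits: int = 3
    slippage_p: float = 0.2
    reads_per_sample: int = 15

    def __post_init__(self) -> None:
        if min(self.lsc_length, self.irb_length, self.ssc_length) <= 0:
            raise ValueError("compartment lengths must be positive")
        if not (0 <= self.slippage_p < 0.5):
            raise ValueError("slippage probability must be in [0, 0.5)")
        groups = {g for _, g in self.samples}
        if not groups <= set(dict(self.diagnostic_alleles)):
            raise ValueError("every sample group needs a diagnostic allele")


@dataclass
class PlantedTruth:
    """Exact coordinates and payloads of everything the generator planted."""

    spec: SyntheticSpec
    base_sequence: str
    features: list[FeatureAnnotation]
    structure_base: dict[str, tuple[int, int]]
    planted_ssrs_base: list[tuple[int, str, int]]  # (start, motif, count) on base
    diagnostic_base_interval: tuple[int, int]
    diagnostic_motif: str
    diagnostic_igs: str
    group_alleles: dict[str, int]
    sample_groups: dict[str, str]
    sample_sequences: dict[str, str]
    sample_deltas: dict[str, int]  # length change downstream of the locus
    edits: list[tuple[str, int, str, str]]  # (sample, base position, ref, alt)

    def record(self, sample: str) -> PlastomeRecord:
        """PlastomeRecord for one sample, annotations shifted to its coordinates."""
        delta = self.sample_deltas[sample]
        ds = self.diagnostic_base_interval[1]
        feats = []
        for f in self.features:
            ivs = tuple(
                CoordinateInterval(
                    iv.start + (delta if iv.start >= ds else 0),
                    iv.end + (delta if iv.start >= ds else 0),
                    iv.strand,
                )
                for iv in f.intervals
            )
            feats.append(FeatureAnnotation(f.name, f.kind, ivs, f.copy_tag))
        return PlastomeRecord(sample, self.sample_sequences[sample], True, feats)

    def structure_of(self, sample: str) -> dict[str, tuple[int, int]]:
        delta = self.sample_deltas[sample]
        out = {}
        for name, (s, e) in self.structure_base.items():
            ds = self.diagnostic_base_interval[1]
            out[name] = (s + (delta if s >= ds else 0), e + (delta if e >= ds else 0))
        return out

    def expected_ssrs(self, sample: str) -> set[tuple[int, str, int]]:
        """(start, motif, count) of every SSR the scanner should report."""
        delta = self.sample_deltas[sample]
        ds = self.diagnostic_base_interval[0]
        out = set()
        for start, motif, count in self.planted_ssrs_base:
            shift = delta if start >= ds else 0
            out.add((start + shift, motif, count))
        allele = self.group_alleles[self.sample_groups[sample]]
        out.add((ds, self.diagnostic_motif, allele))
        return out

    def diagnostic_interval(self, sample: str) -> tuple[int, int]:
        s = self.diagnostic_base_interval[0]
        allele = self.group_alleles[self.sample_groups[sample]]
        return (s, s + allele * len(self.diagnostic_motif))

    def to_json(self, path: str | Path) -> None:
        doc = {
            "structure_base": self.structure_base,
            "planted_ssrs_base": self.planted_ssrs_base,
            "diagnostic": {
                "interval_base": self.diagnostic_base_interval,
                "motif": self.diagnostic_motif,
                "igs": self.diagnostic_igs,
                "group_alleles": self.group_alleles,
            },
            "samples": {
                s: {"group": g, "delta": self.sample_deltas[s]}
                for s, g in self.sample_groups.items()
            },
            "edits": self.edits,
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def _random_ssr_free(
    rng: random.Random, length: int, thresholds: SSRThresholds, max_rounds: int = 100
) -> list[str]:
    """Random sequence containing no SSR that meets the thresholds.

    Offending runs are resampled in place (rejection), keeping the
    negative space clean so planted loci are the only loci.
    """
    seq = [rng.choice(ALPHABET) for _ in range(length)]
    for _ in range(max_rounds):
        loci = scan_ssrs("".join(seq), thresholds)
        if not loci:
            return seq
        for loc in loci:
            for pos in range(loc.interval.start, loc.interval.end):
                seq[pos] = rng.choice(ALPHABET)
    raise RuntimeError("could not generate SSR-free background")


def _break_run(seq: list[str], pos: int, forbidden: str, rng: random.Random) -> None:
    """Set seq[pos] to a base different from `forbidden` and both neighbours."""
    avoid = {forbidden}
    if pos > 0:
        avoid.add(seq[pos - 1])
    if pos + 1 < len(seq):
        avoid.add(seq[pos + 1])
    choices = [b for b in ALPHABET if b not in avoid] or [
        b for b in ALPHABET if b != forbidden
    ]
    seq[pos] = rng.choice(choices)


def _plant_run(seq: list[str], pos: int, motif: str, count: int, rng: random.Random) -> None:
    run = motif * count
    seq[pos : pos + len(run)] = list(run)
    m = len(motif)
    if pos > 0:
        _break_run(seq, pos - 1, motif[m - 1], rng)
    end = pos + len(run)
    if end < len(seq):
        _break_run(seq, end, motif[0], rng)


def simulate_plastome_set(
    spec: SyntheticSpec | None = None,
    thresholds: SSRThresholds | None = None,
    max_attempts: int = 30,
) -> tuple[list[tuple[PlastomeRecord, str]], PlantedTruth]:
    """Build the labelled genome set and its planted truth.

    Returns ``([(record, group label), ...], truth)``.  The emitted
    genomes are verified: a full SSR scan of every sample must recover
    exactly the planted loci (including IR mirrors and the diagnostic
    run); if a chance background structure slips through, the whole
    build is retried with a derived seed.
    """
    spec = spec or SyntheticSpec()
    thresholds = thresholds or SSRThresholds()
    last_err: Exception | None = None
    for attempt in range(max_attempts):
        rng = random.Random(f"{spec.seed}:{attempt}")
        try:
            return _build_once(spec, thresholds, rng)
        except _RetryBuild as exc:
            last_err = exc
    raise RuntimeError(f"synthetic build failed after {max_attempts} attempts: {last_err}")


class _RetryBuild(Exception):
    pass


def _place_genes(
    spec: SyntheticSpec, rng: random.Random
) -> tuple[list[tuple[str, str, int, str, list[tuple[int, int]]]], dict[str, list]]:
    """Lay genes out per compartment; returns placements and free gaps.

    Placement entry: (name, kind, compartment, strand idx unused, exon
    intervals in compartment-local coordinates).  Gaps: per compartment,
    list of [start, end, tag] with tag "IGS:<up>–<down>" or "intron:<gene>".
    """
    catalogue = list(_GENE_CATALOGUE)
    extra = 0
    while len(catalogue) < spec.n_genes:
        extra += 1
        catalogue.append((f"orf{extra:02d}", "CDS", 0, "LSC"))
    catalogue = catalogue[: spec.n_genes]
    lengths = {"LSC": spec.lsc_length, "SSC": spec.ssc_length, "IRb": spec.irb_length}
    placements = []
    gaps: dict[str, list] = {"LSC": [], "SSC": [], "IRb": []}
    pointers = {c: 150 for c in lengths}
    prev_gene: dict[str, str | None] = {c: None for c in lengths}
    for name, kind, n_introns, comp in catalogue:
        if comp not in lengths:
            continue
        if kind == "tRNA":
            exon_lens = [rng.randrange(70, 90)]
        elif kind == "rRNA":
            exon_lens = [rng.randrange(800, 1200)]
        else:
            exon_lens = [rng.randrange(250, 500, 3) for _ in range(n_introns + 1)]
        intron_lens = [rng.randrange(120, 300) for _ in range(n_introns)]
        exons = []
        q = pointers[comp]
        for i, el in enumerate(exon_lens):
            exons.append((q, q + el))
            q += el
            if i < len(intron_lens):
                gaps[comp].append([q + 2, q + intron_lens[i] - 2, f"intron:{name}"])
                q += intron_lens[i]
        if q > lengths[comp] - 150:
            raise ValueError(
                f"gene layout does not fit in {comp} ({q} > {lengths[comp] - 150}); "
                "increase the compartment length"
            )
        placements.append((name, kind, comp, exons))
        prev_gene[comp] = name
        gap_len = rng.randrange(90, 240)
        gaps[comp].append([q + 2, q + gap_len - 2, f"IGS:{name}"])
        pointers[comp] = q + gap_len
    # tail gaps up to compartment end
    for comp, L in lengths.items():
        if pointers[comp] < L - 100:
            gaps[comp].append([pointers[comp] + 2, L - 100, f"IGS:{prev_gene[comp]}"])
    return placements, gaps


def _build_once(
    spec: SyntheticSpec, thresholds: SSRThresholds, rng: random.Random
) -> tuple[list[tuple[PlastomeRecord, str]], PlantedTruth]:
    lsc = _random_ssr_free(rng, spec.lsc_length, thresholds)
    irb = _random_ssr_free(rng, spec.irb_length, thresholds)
    ssc = _random_ssr_free(rng, spec.ssc_length, thresholds)
    comp_seq = {"LSC": lsc, "SSC": ssc, "IRb": irb}
    comp_offset = {
        "LSC": 0,
        "IRb": spec.lsc_length,
        "SSC": spec.lsc_length + spec.irb_length,
    }
    ira_offset = spec.lsc_length + spec.irb_length + spec.ssc_length
    genome_length = ira_offset + spec.irb_length

    placements, gaps = _place_genes(spec, rng)

    # diagnostic spacer: the gap following ycf3 in the LSC
    diag_gap = None
    for gap in gaps["LSC"]:
        if gap[2] == f"IGS:{DIAGNOSTIC_IGS[0]}":
            diag_gap = gap
            break
    if diag_gap is None:
        raise ValueError("gene catalogue lacks the diagnostic spacer genes")

    alleles = dict(spec.diagnostic_alleles)
    base_group = spec.samples[0][1]
    base_count = alleles[base_group]
    motif = spec.diagnostic_motif
    diag_len = base_count * len(motif)
    max_len = max(alleles.values()) * len(motif)
    if diag_gap[1] - diag_gap[0] < max_len + 8:
        raise ValueError("diagnostic spacer too short for the repeat alleles")
    diag_local = (diag_gap[0] + diag_gap[1] - diag_len) // 2
    _plant_run(lsc, diag_local, motif, base_count, rng)
    diag_start = diag_local  # LSC offset is 0
    used = [(diag_local - 4, diag_local + max_len + 4, "LSC")]

    # planted SSRs
    planted: list[tuple[int, str, int]] = []
    for sm, sc, where in spec.planted_ssrs:
        comp, _, tag = where.partition(":")
        pool = [
            g
            for g in gaps[comp]
            if (tag == "intron") == g[2].startswith("intron")
            and g is not diag_gap
            and g[1] - g[0] >= sc * len(sm) + 10
        ]
        pool = [
            g
            for g in pool
            if not any(
                c == comp and not (g[1] + 4 < a or g[0] - 4 > b) for a, b, c in used
            )
        ]
        if not pool:
            raise ValueError(f"no room to plant SSR {sm}x{sc} in {where}")
        gap = rng.choice(pool)
        local = gap[0] + 3
        _plant_run(comp_seq[comp], local, sm, sc, rng)
        used.append((local - 4, local + sc * len(sm) + 4, comp))
        planted.append((comp_offset[comp] + local, sm, sc))
        gap[0] = local + sc * len(sm) + 6  # rest of gap stays available

    # annotations (base coordinates); IRb genes mirrored into IRa
    features: list[FeatureAnnotation] = []
    for name, kind, comp, exons in placements:
        off = comp_offset[comp]
        tag = "IR-duplicate" if comp == "IRb" else "unique"
        ivs = tuple(CoordinateInterval(off + s, off + e, "+") for s, e in exons)
        features.append(FeatureAnnotation(name, kind, ivs, tag))
        if comp == "IRb":
            mirror = [
                CoordinateInterval(
                    ira_offset + (spec.irb_length - e),
                    ira_offset + (spec.irb_length - s),
                    "-",
                )
                for s, e in exons
            ]
            mirror.sort(key=lambda iv: iv.start, reverse=True)
            features.append(FeatureAnnotation(name, kind, tuple(mirror), "IR-duplicate"))

    # junction bases must not extend the IR pair
    if lsc[0] == revcomp(lsc[-1]):
        _break_run(lsc, 0, revcomp(lsc[-1]), rng)
    if ssc[0] == revcomp(ssc[-1]):
        _break_run(ssc, 0, revcomp(ssc[-1]), rng)

    base = "".join(lsc) + "".join(irb) + "".join(ssc) + revcomp("".join(irb))
    assert len(base) == genome_length

    # IR mirrors of planted IRb SSRs
    mirrors = []
    for start, sm, sc in planted:
        if comp_offset["IRb"] <= start < comp_offset["IRb"] + spec.irb_length:
            local = start - comp_offset["IRb"]
            mstart = ira_offset + spec.irb_length - (local + sc * len(sm))
            mirrors.append((mstart, revcomp(sm), sc))
    planted_all = planted + mirrors

    # background edits: substitutions private to one member of a
    # multi-sample group (within-group polymorphic, hence never diagnostic)
    sample_groups = dict(spec.samples)
    group_members: dict[str, list[str]] = {}
    for s, g in spec.samples:
        group_members.setdefault(g, []).append(s)
    editable = [s for g, mem in group_members.items() if len(mem) >= 2 for s in mem]
    edits: list[tuple[str, int, str, str]] = []
    if editable and spec.n_background_edits:
        forbidden = [(a - 50, b + 50) for a, b, comp in used if comp == "LSC"]
        forbidden.append((diag_start - 60, diag_start + max_len + 60))
        candidates = [
            g for g in gaps["LSC"] if g[1] - g[0] >= 8 and g is not diag_gap
        ]
        tries = 0
        while len(edits) < spec.n_background_edits and tries < 500:
            tries += 1
            gap = rng.choice(candidates)
            pos = rng.randrange(gap[0] + 2, gap[1] - 2)
            if any(a <= pos <= b for a, b in forbidden):
                continue
            if any(abs(pos - e[1]) < 50 for e in edits):
                continue
            ref = base[pos]
            alt = rng.choice([b for b in ALPHABET if b != ref])
            target = editable[len(edits) % len(editable)]
            edits.append((target, pos, ref, alt))
            forbidden.append((pos - 50, pos + 50))

    # per-sample sequences
    diag_end = diag_start + diag_len
    sample_sequences: dict[str, str] = {}
    sample_deltas: dict[str, int] = {}
    for sample, group in spec.samples:
        allele = alleles[group]
        delta = (allele - base_count) * len(motif)
        seq = base[:diag_start] + motif * allele + base[diag_end:]
        for target, pos, ref, alt in sorted(edits, key=lambda e: -e[1]):
            if target != sample:
                continue
            p = pos + (delta if pos >= diag_end else 0)
            assert seq[p] == ref
            seq = seq[:p] + alt + seq[p + 1 :]
        sample_sequences[sample] = seq
        sample_deltas[sample] = delta

    structure_base = {
        "LSC": (0, spec.lsc_length),
        "IRb": (spec.lsc_length, spec.lsc_length + spec.irb_length),
        "SSC": (spec.lsc_length + spec.irb_length, ira_offset),
        "IRa": (ira_offset, genome_length),
    }
    truth = PlantedTruth(
        spec=spec,
        base_sequence=base,
        features=features,
        structure_base=structure_base,
        planted_ssrs_base=sorted(planted_all),
        diagnostic_base_interval=(diag_start, diag_end),
        diagnostic_motif=motif,
        diagnostic_igs=f"{DIAGNOSTIC_IGS[0]}–{DIAGNOSTIC_IGS[1]}",
        group_alleles=alleles,
        sample_groups=sample_groups,
        sample_sequences=sample_sequences,
        sample_deltas=sample_deltas,
        edits=edits,
    )

    # verification: every sample's scan must equal its planted truth
    records = []
    for sample, group in spec.samples:
        rec = truth.record(sample)
        found = {
            (l.interval.start, l.motif, l.repeat_count)
            for l in scan_ssrs(rec.sequence, thresholds, circular=True)
        }
        if found != truth.expected_ssrs(sample):
            raise _RetryBuild(
                f"sample {sample}: scan found {sorted(found ^ truth.expected_ssrs(sample))}"
            )
        records.append((rec, group))
    return records, truth


def simulate_amplicons(
    truth: PlantedTruth,
    sample: str,
    marker: MarkerDefinition,
    n_reads: int | None = None,
    slippage_p: float | None = None,
    seed: int = 0,
    margin: int = 470,
) -> list[tuple[str, str]]:
    """Amplicon reads for one sample with ±1-repeat slippage noise.

    Each read carries the sample's true repeat count shifted by +1 or -1
    with probability p/2 each (otherwise unshifted); about half the
    reads are emitted reverse-complemented.
    """
    if sample not in truth.sample_sequences:
        raise ValueError(f"unknown sample {sample!r}")
    p = truth.spec.slippage_p if slippage_p is None else slippage_p
    n = truth.spec.reads_per_sample if n_reads is None else n_reads
    if not (0 <= p < 0.5):
        raise ValueError("slippage probability must be in [0, 0.5)")
    rng = random.Random(f"{seed}:{sample}")
    seq = truth.sample_sequences[sample]
    ds, de = truth.diagnostic_interval(sample)
    if marker.primers:
        rec = truth.record(sample)
        products = in_silico_pcr(rec, *marker.primers)
        if not products:
            raise ValueError("marker primers produce no amplicon on this sample")
        amp = products[0].sequence
        amp_start = products[0].interval.start
    else:
        amp_start = max(0, ds - margin)
        amp = seq[amp_start : min(len(seq), de + margin)]
    run_start, run_end = ds - amp_start, de - amp_start
    motif = truth.diagnostic_motif
    true_count = (run_end - run_start) // len(motif)
    reads = []
    for i in range(n):
        u = rng.random()
        shift = 1 if u < p / 2 else (-1 if u < p else 0)
        count = max(1, true_count + shift)
        read = amp[:run_start] + motif * count + amp[run_end:]
        if rng.random() < 0.5:
            read = revcomp(read)
        reads.append((f"{sample}/read{i + 1}", read))
    return reads
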