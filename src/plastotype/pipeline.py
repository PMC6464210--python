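"""Pipeline orchestration: structure → regions → variability → SSR →
discovery, with a YAML config, a run manifest and TSV/JSON outputs.

Each stage writes its results to files in the output directory so
stages can be inspected or re-run independently; the manifest records
package version, parameters, seed and input checksums so a run can be
reproduced byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coords import PlastomeRecord
from .io import read_genbank
from .markers import (
    GroupedGenomeSet,
    build_marker_definition,
    discover_diagnostic_loci,
)
from .simulate import DEFAULT_GENOTYPE_TABLE
from .ssr import SSRThresholds, scan_ssrs, summarize_census
from .structure import detect_quadripartite, extract_regions, gene_census
from .variability import (
    HotspotCriteria,
    align_regions,
    compute_variability,
    hotspot_filter,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline parameters; every field has the module default."""

    inputs: list[str] = field(default_factory=list)  # GenBank paths
    groups: dict[str, str] = field(default_factory=dict)  # record id -> group
    output_dir: str = "plastotype_out"
    seed: int = 0
    log_level: str = "INFO"
    min_ir_length: int = 1000
    ssr_mono: int = 10
    ssr_di: int = 6
    ssr_tri: int = 5
    ssr_tetra: int = 5
    ssr_penta: int = 5
    ssr_hexa: int = 5
    compound_max_interruption: int = 100
    hotspot_min_length: int = 500
    hotspot_max_length: int = 1500
    indel_mode: str = "shared"
    flank_length: int = 20
    flank_mismatch_tolerance: int = 2

    def thresholds(self) -> SSRThresholds:
        return SSRThresholds(
            self.ssr_mono, self.ssr_di, self.ssr_tri, self.ssr_tetra,
            self.ssr_penta, self.ssr_hexa, self.compound_max_interruption,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(
    config: PipelineConfig, records: list[PlastomeRecord] | None = None
) -> dict[str, object]:
    """Run every stage and write the report bundle; returns a summary dict.

    ``records`` may be passed directly (e.g. from the simulator);
    otherwise ``config.inputs`` are read as GenBank files.  Discovery
    runs only when group labels cover at least two groups.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    t0 = time.time()
    stage = "setup"
    summary: dict[str, object] = {}
    try:
        if records is None:
            stage = "read"
            records = [read_genbank(p) for p in config.inputs]
        if not records:
            raise ValueError("no input genomes")
        thresholds = config.thresholds()

        stage = "structure"
        structures = {}
        structure_rows = []
        all_regions: dict[str, list] = {}
        for rec in records:
            st = detect_quadripartite(rec, config.min_ir_length)
            structures[rec.identifier] = st
            census = gene_census(rec, st)
            structure_rows.append(
                st.as_row(
                    rec.identifier,
                    {
                        "genes": census.total,
                        "PCGs": census.pcg,
                        "tRNAs": census.trna,
                        "rRNAs": census.rrna,
                    },
                )
            )
            all_regions[rec.identifier] = extract_regions(rec, st)
        _write_tsv(pd.DataFrame(structure_rows), out / "structure.tsv")

        stage = "ssr"
        census_rows = []
        loci_rows = []
        for rec in records:
            loci = scan_ssrs(rec.sequence, thresholds, circular=rec.circular)
            flagged, census = summarize_census(
                loci,
                structures[rec.identifier],
                all_regions[rec.identifier],
                len(rec.sequence),
                thresholds.compound_max_interruption,
            )
            census_rows.append(census.as_row(rec.identifier))
            for loc in flagged:
                s1, e1 = loc.interval.to_onebased()
                loci_rows.append(
                    {
                        "sample": rec.identifier,
                        "start": s1,
                        "end": e1,
                        "motif": loc.motif,
                        "class": loc.motif_class,
                        "repeats": loc.repeat_count,
                        "compartment": loc.compartment or "NA",
                        "context": loc.context or "NA",
                        "compound": loc.compound_member,
                    }
                )
            summary[f"n_ssrs:{rec.identifier}"] = census.total
        _write_tsv(pd.DataFrame(census_rows), out / "ssr_census.tsv")
        _write_tsv(pd.DataFrame(loci_rows), out / "ssr_loci.tsv")

        if len(records) >= 2:
            stage = "variability"
            named: dict[str, list[tuple[str, str]]] = {}
            categories: dict[str, str] = {}
            for rec in records:
                for reg in all_regions[rec.identifier]:
                    named.setdefault(reg.name, []).append((rec.identifier, reg.sequence))
                    categories[reg.name] = (
                        "coding" if reg.category == "PCG" else "noncoding"
                    )
            aligned = align_regions(named, categories, mode="internal")
            stats = [compute_variability(a, config.indel_mode) for a in aligned]
            _write_tsv(
                pd.DataFrame(
                    {
                        "name": s.name,
                        "category": s.category,
                        "S": s.substitutions,
                        "I": s.indel_events,
                        "P": s.aligned_length,
                        "S/P": round(s.sp, 6),
                        "I/P": round(s.ip, 6),
                    }
                    for s in stats
                ),
                out / "variability.tsv",
            )
            stage = "hotspots"
            criteria = HotspotCriteria(config.hotspot_min_length, config.hotspot_max_length)
            hot = hotspot_filter(stats, criteria)
            _write_tsv(
                pd.DataFrame(
                    {
                        "name": s.name,
                        "category": s.category,
                        "P": s.aligned_length,
                        "S/P": round(s.sp, 6),
                        "I/P": round(s.ip, 6),
                    }
                    for s in hot
                ),
                out / "hotspots.tsv",
            )
            summary["n_hotspots"] = len(hot)

        group_labels = {
            rid: g for rid, g in config.groups.items()
        } if config.groups else {}
        if group_labels and len(set(group_labels.values())) >= 2:
            stage = "discovery"
            genomes = GroupedGenomeSet(records, group_labels)
            loci = discover_diagnostic_loci(genomes, records[0].identifier)
            rows = []
            for loc in loci:
                s1, e1 = loc.interval.to_onebased()
                rows.append(
                    {
                        "kind": loc.kind,
                        "reference": loc.reference_id,
                        "start": s1,
                        "end": e1,
                        "context": loc.context,
                        "motif": loc.motif or "NA",
                        "alleles": ";".join(
                            f"{g}={a}" for g, a in sorted(loc.alleles.items())
                        ),
                    }
                )
            _write_tsv(pd.DataFrame(rows), out / "diagnostic_loci.tsv")
            summary["n_diagnostic_loci"] = len(loci)
            ssr_loci = [l for l in loci if l.kind == "SSR-length"]
            if ssr_loci:
                stage = "marker"
                table = {
                    int(a): (f"Genotype-{a}", g)
                    for g, a in sorted(ssr_loci[0].alleles.items())
                }
                if set(int(a) for a in ssr_loci[0].alleles.values()) <= set(
                    DEFAULT_GENOTYPE_TABLE
                ):
                    table = {
                        k: v
                        for k, v in DEFAULT_GENOTYPE_TABLE.items()
                        if k in {int(a) for a in ssr_loci[0].alleles.values()}
                    }
                marker = build_marker_definition(
                    ssr_loci[0],
                    records[0],
                    config.flank_length,
                    genotype_table=table,
                    flank_mismatch_tolerance=config.flank_mismatch_tolerance,
                )
                marker.to_json(out / "marker.json")
                summary["marker"] = marker.name

        stage = "manifest"
        manifest = {
            "plastotype_version": __version__,
            "parameters": dataclasses.asdict(config),
            "seed": config.seed,
            "inputs": {
                p: _sha256(Path(p)) for p in config.inputs if Path(p).exists()
            },
            "n_genomes": len(records),
            "elapsed_s": round(time.time() - t0, 2),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        failed_marker.write_text(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return summary
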