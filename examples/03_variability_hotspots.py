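"""Per-region variability (S/P, I/P) across cultivars and hotspot filtering.

Aligns each homologous region across three simulated cultivar genomes,
computes the substitution and indel fractions of the aligned length,
then filters for marker-sized (500-1,500 bp) regions whose variability
strictly exceeds their category average.
"""

from plastotype.simulate import SyntheticSpec, simulate_plastome_set
from plastotype.structure import detect_quadripartite, extract_regions
from plastotype.variability import align_regions, compute_variability, hotspot_filter

records, truth = simulate_plastome_set(SyntheticSpec(seed=1))

named, categories = {}, {}
for rec, _ in records:
    st = detect_quadripartite(rec)
    for reg in extract_regions(rec, st):
        named.setdefault(reg.name, []).append((rec.identifier, reg.sequence))
        categories[reg.name] = "coding" if reg.category == "PCG" else "noncoding"

stats = [compute_variability(a) for a in align_regions(named, categories)]
variable = [s for s in stats if s.substitutions or s.indel_events]
print(f"{len(stats)} regions profiled; {len(variable)} carry variation:")
for s in variable:
    print(f"  {s.name:<24} {s.category:<9} S={s.substitutions} I={s.indel_events} "
          f"P={s.aligned_length} S/P={s.sp:.4f} I/P={s.ip:.4f}")

hot = hotspot_filter(stats)
print(f"hotspot shortlist (500-1,500 bp, above category mean): {len(hot)}")
for s in hot:
    print(f"  {s.name}: S/P={s.sp:.4f} I/P={s.ip:.4f} P={s.aligned_length}")
# Near-identical cultivars carry almost no variation, so S/P is zero for
# most regions; only the spacer holding the diagnostic repeat and the
# spacers with private substitutions show any signal.
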