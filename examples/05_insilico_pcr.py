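"""In-silico PCR: locate a primer pair on a circular template and
extract the would-be product.

Primer sites are matched within a mismatch budget, except the three
3'-terminal bases which must match exactly (the polymerase-extension
requirement); both strands and origin-spanning products are handled.
"""

import random

from plastotype.coords import PlastomeRecord, revcomp
from plastotype.markers import in_silico_pcr

rng = random.Random(0)
dna = lambda n: "".join(rng.choice("ACGT") for _ in range(n))

fwd, rev = dna(20), dna(20)
insert = dna(927)
template = dna(2000) + fwd + insert + revcomp(rev) + dna(2000)
rec = PlastomeRecord("demo", template, circular=True)

for p in in_silico_pcr(rec, fwd, rev):
    s1 = p.interval.start + 1
    print(f"product: {p.length} bp at {s1} ({p.interval.strand} strand)")
    print(f"  starts with forward primer: {p.sequence.startswith(fwd)}")
    print(f"  ends with revcomp(reverse): {p.sequence.endswith(revcomp(rev))}")
# 20 bp + 927 bp insert + 20 bp = 967 bp, the size class of the
# chemotype-marker amplicon this toolkit was built around.
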