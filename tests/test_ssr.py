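import random
from itertools import product

import pytest
from hypothesis import given, strategies as st

from plastotype.coords import revcomp
from plastotype.ssr import (
    classify_motif,
    is_primitive,
    merge_compound,
    scan_ssrs,
    summarize_census,
)

from conftest import random_dna
from oracles import enumerate_ssrs


def _plant(seq: str, pos: int, motif: str, count: int, guard: bool = True) -> str:
    """Overwrite seq with a motif run; guard bases stop chance extension."""
    run = motif * count
    out = seq[:pos] + run + seq[pos + len(run) :]
    if guard:
        left = next(b for b in "GCAT" if b != motif[-1] and (pos < 1 or b != out[pos - 2]))
        right = next(
            b for b in "GCAT" if b != motif[0] and b != out[min(len(out) - 1, pos + len(run) + 1)]
        )
        if pos >= 1:
            out = out[: pos - 1] + left + out[pos:]
        end = pos + len(run)
        if end < len(out):
            out = out[:end] + right + out[end + 1 :]
    return out


def _clean_background(rng: random.Random, n: int) -> str:
    """Random sequence guaranteed free of threshold-level SSRs."""
    while True:
        seq = random_dna(rng, n)
        if not enumerate_ssrs(seq):
            return seq


class TestScan:
    def test_run_below_threshold_is_ignored(self):
        seq = _clean_background(random.Random(0), 400)
        seq = "G" + "A" * 9 + "G" + seq  # A x9: one short of the mono minimum
        assert all(l.motif != "A" for l in scan_ssrs(seq))

    def test_planted_mononucleotide_run_found_exactly(self):
        rng = random.Random(1)
        seq = _plant(_clean_background(rng, 2000), 500, "A", 10)
        loci = scan_ssrs(seq)
        expected = enumerate_ssrs(seq)
        assert {(l.interval.start, l.motif, l.repeat_count) for l in loci} == expected
        mine = [l for l in loci if l.interval.start == 500]
        assert len(mine) == 1
        l = mine[0]
        assert (l.motif, l.repeat_count, l.motif_class) == ("A", 10, "A/T")
        assert (l.interval.start, l.interval.end) == (500, 510)

    def test_planted_dinucleotide_reported_with_primitive_motif(self):
        rng = random.Random(2)
        seq = _plant(_clean_background(rng, 1000), 300, "AT", 6)
        loci = [l for l in scan_ssrs(seq) if l.interval.start == 300]
        assert len(loci) == 1
        assert (loci[0].motif, loci[0].repeat_count, loci[0].motif_class) == (
            "AT", 6, "AT/TA",
        )
        # no degenerate AA-style or ATAT-style loci anywhere
        assert all(is_primitive(l.motif) for l in scan_ssrs(seq))

    def test_n_never_participates(self):
        seq = "G" + "A" * 5 + "N" + "A" * 5 + "G"
        assert scan_ssrs(seq) == []

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_enumeration_oracle_on_spiked_sequences(self, seed):
        rng = random.Random(seed)
        seq = random_dna(rng, rng.randrange(300, 1500))
        for _ in range(rng.randrange(0, 4)):
            m = rng.randrange(1, 7)
            motif = random_dna(rng, m)
            count = rng.randrange(3, 14)
            pos = rng.randrange(0, len(seq) - m * count)
            seq = _plant(seq, pos, motif, count)
        assert {
            (l.interval.start, l.motif, l.repeat_count) for l in scan_ssrs(seq)
        } == enumerate_ssrs(seq)

    def test_every_locus_is_maximal_and_primitive(self):
        rng = random.Random(99)
        seq = _clean_background(rng, 1200)
        for pos, motif, count in [(100, "T", 11), (400, "CT", 7), (800, "AAG", 6)]:
            seq = _plant(seq, pos, motif, count)
        for l in scan_ssrs(seq):
            m = len(l.motif)
            s, e = l.interval.start, l.interval.end
            assert is_primitive(l.motif)
            assert seq[s:e] == l.motif * l.repeat_count
            if s > 0:  # left extension breaks periodicity
                assert seq[s - 1] != seq[s - 1 + m]
            run_end = s
            while run_end < len(seq) and seq[run_end] == seq[(run_end - s) % m + s]:
                run_end += 1
            assert run_end - s < (l.repeat_count + 1) * m  # no extra whole copy

    def test_reverse_complement_mirrors_locus_set(self):
        rng = random.Random(7)
        seq = _plant(_plant(_clean_background(rng, 900), 200, "A", 10), 600, "AG", 6)
        fwd = scan_ssrs(seq)
        rev = scan_ssrs(revcomp(seq))
        L = len(seq)
        mirrored = {
            (L - l.interval.end, revcomp(l.motif) if len(l.motif) == 1 else None, l.repeat_count, l.motif_class)
            for l in fwd
        }
        got = {
            (l.interval.start, l.motif if len(l.motif) == 1 else None, l.repeat_count, l.motif_class)
            for l in rev
        }
        assert got == mirrored

    def test_circular_scan_joins_run_across_origin(self):
        rng = random.Random(8)
        mid = _clean_background(rng, 500)
        # guard bases so the run is bounded away from the background
        seq = "A" * 6 + "G" + mid + "C" + "A" * 5
        loci = scan_ssrs(seq, circular=True)
        wrapped = [l for l in loci if l.interval.spans_origin]
        assert len(wrapped) == 1
        l = wrapped[0]
        assert (l.motif, l.repeat_count) == ("A", 11)
        assert l.interval.start == len(seq) - 5 and l.interval.end == 6

    def test_circular_scan_replaces_truncated_linear_locus(self):
        rng = random.Random(9)
        mid = _clean_background(rng, 500)
        seq = "A" * 3 + "G" + mid + "C" + "A" * 10
        linear = scan_ssrs(seq, circular=False)
        assert {(l.interval.start, l.repeat_count) for l in linear} == {(len(seq) - 10, 10)}
        circular = scan_ssrs(seq, circular=True)
        assert {(l.interval.start, l.repeat_count) for l in circular} == {(len(seq) - 10, 13)}

    def test_empty_sequence(self):
        assert scan_ssrs("") == []


class TestClassifyMotif:
    @pytest.mark.parametrize(
        "motif,label",
        [("A", "A/T"), ("T", "A/T"), ("G", "C/G"), ("C", "C/G"),
         ("AT", "AT/TA"), ("TA", "AT/TA"), ("AC", "AC/GT"), ("GT", "AC/GT"),
         ("AG", "AG/CT"), ("CT", "AG/CT")],
    )
    def test_known_classes(self, motif, label):
        assert classify_motif(motif) == label

    def test_all_twelve_dinucleotides_fall_into_four_classes(self):
        motifs = [a + b for a, b in product("ACGT", repeat=2) if a != b]
        assert len(motifs) == 12
        # brute-force orbit enumeration: rotations x strands
        orbits = {}
        for m in motifs:
            orbit = frozenset(
                x[i:] + x[:i]
                for x in (m, revcomp(m))
                for i in range(2)
            )
            orbits.setdefault(orbit, set()).add(classify_motif(m))
        assert len(orbits) == 4
        for labels in orbits.values():
            assert len(labels) == 1  # one label per orbit

    @given(st.text(alphabet="ACGT", min_size=1, max_size=6))
    def test_invariant_under_rotation_and_strand(self, motif):
        if not is_primitive(motif):
            with pytest.raises(ValueError):
                classify_motif(motif)
            return
        label = classify_motif(motif)
        for i in range(len(motif)):
            assert classify_motif(motif[i:] + motif[:i]) == label
        assert classify_motif(revcomp(motif)) == label

    def test_non_primitive_motif_rejected(self):
        with pytest.raises(ValueError):
            classify_motif("ATAT")


class TestCompound:
    def _two_runs(self, gap: int):
        rng = random.Random(30)
        seq = _clean_background(rng, 1200)
        seq = _plant(seq, 100, "A", 10)
        seq = _plant(seq, 110 + gap, "T", 10)
        return scan_ssrs(seq)

    def test_gap_within_default_interruption_forms_one_group(self):
        loci, n = merge_compound(self._two_runs(50))
        assert n == 1
        assert all(l.compound_member for l in loci if l.motif in "AT")

    def test_gap_beyond_interruption_boundary_does_not(self):
        _, n = merge_compound(self._two_runs(101))
        assert n == 0

    def test_gap_exactly_at_interruption_boundary_merges(self):
        _, n = merge_compound(self._two_runs(100))
        assert n == 1


class TestCensus:
    def test_all_zero_census_without_loci(self):
        _, census = summarize_census([])
        assert census.total == 0
        assert census.by_compartment == {} and census.compound_count == 0

    def test_census_matches_planted_truth(self, default_sim):
        records, truth = default_sim
        rec, _ = records[0]
        from plastotype.structure import detect_quadripartite, extract_regions

        st = detect_quadripartite(rec)
        regions = extract_regions(rec, st)
        loci = scan_ssrs(rec.sequence, circular=True)
        flagged, census = summarize_census(loci, st, regions, len(rec.sequence))
        expected = truth.expected_ssrs(rec.identifier)
        assert census.total == len(expected)
        # compartment tallies recompute from the planted coordinates
        comp_truth = {}
        for start, motif, count in expected:
            for name, (s, e) in truth.structure_of(rec.identifier).items():
                if s <= start < e:
                    comp_truth[name] = comp_truth.get(name, 0) + 1
        assert census.by_compartment == comp_truth
        # percentages re-derive from counts
        for comp, n in census.by_compartment.items():
            assert census.by_compartment_pct[comp] == pytest.approx(
                round(100 * n / census.total, 2), abs=0.005
            )
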