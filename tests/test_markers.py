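import random

import pytest

from plastotype.coords import PlastomeRecord, revcomp
from plastotype.markers import (
    DiagnosticLocus,
    GroupedGenomeSet,
    MarkerDefinition,
    build_marker_definition,
    call_genotype,
    discover_diagnostic_loci,
    in_silico_pcr,
)
from plastotype.coords import CoordinateInterval
from plastotype.simulate import simulate_amplicons

from conftest import random_dna


class TestDiscovery:
    def test_identical_genomes_yield_no_loci(self):
        seq = random_dna(random.Random(0), 5000)
        recs = [PlastomeRecord("a", seq), PlastomeRecord("b", seq)]
        gs = GroupedGenomeSet(recs, {"a": "g1", "b": "g2"})
        assert discover_diagnostic_loci(gs, "a") == []

    def test_planted_homopolymer_is_the_single_locus(self, default_sim):
        records, truth = default_sim
        gs = GroupedGenomeSet(
            [r for r, _ in records], {r.identifier: g for r, g in records}
        )
        loci = discover_diagnostic_loci(gs, records[0][0].identifier)
        assert len(loci) == 1
        locus = loci[0]
        assert locus.kind == "SSR-length"
        assert locus.motif == truth.diagnostic_motif
        assert (locus.interval.start, locus.interval.end) == truth.diagnostic_base_interval
        assert locus.context == truth.diagnostic_igs
        assert locus.alleles == truth.group_alleles

    def test_within_group_polymorphic_sites_never_reported(self, default_sim):
        """The generator plants background substitutions private to one
        member of the two-sample group; none may surface as diagnostic."""
        records, truth = default_sim
        assert truth.edits, "fixture should carry background edits"
        gs = GroupedGenomeSet(
            [r for r, _ in records], {r.identifier: g for r, g in records}
        )
        loci = discover_diagnostic_loci(gs, records[0][0].identifier)
        edit_positions = {pos for _, pos, _, _ in truth.edits}
        for locus in loci:
            assert not any(
                locus.interval.start - 5 <= p <= locus.interval.end + 5
                for p in edit_positions
            )

    def test_snp_fixed_between_groups_is_reported(self):
        rng = random.Random(1)
        base = random_dna(rng, 4000)
        pos = 2000
        alt = base[:pos] + {"A": "C", "C": "A", "G": "T", "T": "G"}[base[pos]] + base[pos + 1 :]
        recs = [
            PlastomeRecord("a1", base),
            PlastomeRecord("a2", base),
            PlastomeRecord("b1", alt),
        ]
        gs = GroupedGenomeSet(recs, {"a1": "g1", "a2": "g1", "b1": "g2"})
        loci = discover_diagnostic_loci(gs, "a1")
        assert [l.kind for l in loci] == ["SNP"]
        assert loci[0].interval.start == pos


class TestMarkerDefinition:
    def test_flanks_match_known_construction(self, default_sim):
        records, truth = default_sim
        ref = records[0][0]
        ds, de = truth.diagnostic_base_interval
        locus = DiagnosticLocus(
            "SSR-length", ref.identifier, CoordinateInterval(ds, de),
            truth.diagnostic_igs, truth.group_alleles, truth.diagnostic_motif,
        )
        marker = build_marker_definition(locus, ref, flank_length=20)
        assert marker.left_flank == ref.sequence[ds - 20 : ds]
        assert marker.right_flank == ref.sequence[de : de + 20]
        assert marker.motif == truth.diagnostic_motif

    def test_repeat_continuing_flank_bases_are_trimmed(self):
        seq = "G" * 30 + "CA" + "T" * 10 + "AC" + "G" * 30
        # plant an A immediately left of the run start so the flank would
        # end with a base continuing a T-run leftwards? use motif T: left
        # flank ends with 'A' (fine); craft one ending with 'T' instead
        seq = "G" * 28 + "TT" + "T" * 10 + "AC" + "G" * 30
        rec = PlastomeRecord("r", seq)
        locus = DiagnosticLocus(
            "SSR-length", "r", CoordinateInterval(30, 40), "", {"g1": 10, "g2": 11}, "T"
        )
        marker = build_marker_definition(locus, rec, flank_length=10)
        assert not marker.left_flank.endswith("T")
        assert len(marker.left_flank) == 8  # two repeat-continuing bases trimmed

    def test_json_round_trip(self, tmp_path):
        marker = MarkerDefinition(
            "m", "A" * 9 + "CGTCGTCGT", "TGCATGCATGCATGCATG", "A",
            {10: ("Genotype B", "pogostone-type"), 11: ("Genotype A", "patchoulol-type")},
            primers=("TCGCGATCTAGGCATAGCTA", "TTCCAATGCTACGCCTTGAA"),
        )
        path = tmp_path / "marker.json"
        marker.to_json(path)
        back = MarkerDefinition.from_json(path)
        assert back == marker

    def test_flank_beyond_sequence_is_an_error(self):
        rec = PlastomeRecord("r", "ACGT" * 10)
        locus = DiagnosticLocus(
            "SSR-length", "r", CoordinateInterval(2, 12), "", {"g1": 10, "g2": 11}, "A"
        )
        with pytest.raises(ValueError):
            build_marker_definition(locus, rec, flank_length=20)


class TestInSilicoPcr:
    def _template(self, rng, insert=460, circular=False):
        fwd = random_dna(rng, 20)
        rev = random_dna(rng, 20)
        bg = random_dna(rng, 3000)
        tpl = bg[:1000] + fwd + random_dna(rng, insert) + revcomp(rev) + bg[1000:]
        return PlastomeRecord("t", tpl, circular=circular), fwd, rev

    def test_product_length_is_construction_arithmetic(self):
        rec, fwd, rev = self._template(random.Random(2))
        products = in_silico_pcr(rec, fwd, rev)
        assert len(products) == 1
        p = products[0]
        assert p.length == 20 + 460 + 20
        assert p.sequence.startswith(fwd)
        assert p.sequence.endswith(revcomp(rev))

    def test_absent_forward_primer_gives_no_product(self):
        rec, fwd, rev = self._template(random.Random(3))
        absent = "ACGT" * 5
        assert in_silico_pcr(rec, absent, rev) == []

    def test_mismatch_tolerated_except_at_three_prime_end(self):
        rec, fwd, rev = self._template(random.Random(4))
        mutated = ("G" if fwd[5] != "G" else "C").join([fwd[:5], fwd[6:]])
        assert len(in_silico_pcr(rec, mutated, rev, max_mismatches=1)) == 1
        bad_end = fwd[:-1] + ("G" if fwd[-1] != "G" else "C")
        assert in_silico_pcr(rec, bad_end, rev, max_mismatches=1) == []

    def test_flipped_template_reports_forward_orientation(self):
        rec, fwd, rev = self._template(random.Random(5))
        flipped = PlastomeRecord("t", revcomp(rec.sequence), circular=False)
        products = in_silico_pcr(flipped, fwd, rev)
        assert len(products) == 1
        assert products[0].sequence.startswith(fwd)
        assert products[0].length == 500

    def test_product_spanning_the_origin_on_a_circular_template(self):
        rng = random.Random(6)
        fwd, rev = random_dna(rng, 20), random_dna(rng, 20)
        bg = random_dna(rng, 2000)
        # forward site 100 bp before the origin, reverse site 80 bp after
        tpl = revcomp(rev) + bg[:1900] + fwd + bg[1900:1980]
        rec = PlastomeRecord("t", tpl, circular=True)
        products = in_silico_pcr(rec, fwd, rev)
        assert len(products) == 1
        assert products[0].interval.spans_origin
        assert products[0].length == 20 + 80 + 20
        assert products[0].sequence.startswith(fwd)

    def test_short_primers_rejected(self):
        rec, fwd, rev = self._template(random.Random(7))
        with pytest.raises(ValueError):
            in_silico_pcr(rec, "ACGTACGT", rev)


class TestCallGenotype:
    @pytest.fixture()
    def marker(self):
        rng = random.Random(8)
        left = random_dna(rng, 20).replace("A", "G")
        right = random_dna(rng, 20).replace("A", "C")
        return MarkerDefinition(
            "m", left, right, "A",
            {10: ("Genotype B", "pogostone-type"), 11: ("Genotype A", "patchoulol-type")},
        ), rng

    def _read(self, marker, rng, count):
        return random_dna(rng, 50) + marker.left_flank + "A" * count + marker.right_flank + random_dna(rng, 50)

    def test_noise_free_eleven_repeat_read_calls_genotype_a(self, marker):
        marker, rng = marker
        call = call_genotype([("r1", self._read(marker, rng, 11))], marker, "s")
        assert call.consensus == 11
        assert call.genotype == "Genotype A"
        assert call.chemotype == "patchoulol-type"

    def test_out_of_table_count_is_unknown(self, marker):
        marker, rng = marker
        call = call_genotype([("r1", self._read(marker, rng, 12))], marker, "s")
        assert call.consensus == 12
        assert call.genotype == "unknown" and call.chemotype == "unknown"

    def test_strand_symmetry(self, marker):
        marker, rng = marker
        reads = [(f"r{i}", self._read(marker, rng, 10)) for i in range(5)]
        fwd_call = call_genotype(reads, marker, "s")
        rc_call = call_genotype([(i, revcomp(r)) for i, r in reads], marker, "s")
        assert fwd_call.consensus == rc_call.consensus
        assert fwd_call.genotype == rc_call.genotype
        assert fwd_call.chemotype == rc_call.chemotype

    def test_tie_between_modes_is_undetermined(self, marker):
        marker, rng = marker
        reads = [("r1", self._read(marker, rng, 10)), ("r2", self._read(marker, rng, 11))]
        call = call_genotype(reads, marker, "s")
        assert call.consensus is None
        assert "tie" in call.reason

    def test_flank_not_found_is_a_no_call_with_reason(self, marker):
        marker, rng = marker
        call = call_genotype([("r1", random_dna(rng, 200))], marker, "s")
        assert call.consensus is None and call.evidence == 0
        assert call.reason

    def test_interrupted_run_excludes_the_read(self, marker):
        marker, rng = marker
        good = self._read(marker, rng, 10)
        interrupted = (
            random_dna(rng, 30) + marker.left_flank + "AAAAA" + "G" + "AAAA"
            + marker.right_flank + random_dna(rng, 30)
        )
        call = call_genotype([("ok", good), ("bad", interrupted)], marker, "s")
        assert call.evidence == 1 and call.consensus == 10

    def test_slippage_reads_recover_modal_count(self, default_sim):
        records, truth = default_sim
        ref = records[0][0]
        ds, de = truth.diagnostic_base_interval
        locus = DiagnosticLocus(
            "SSR-length", ref.identifier, CoordinateInterval(ds, de),
            truth.diagnostic_igs, truth.group_alleles, truth.diagnostic_motif,
        )
        marker = build_marker_definition(
            locus, ref,
            genotype_table={10: ("Genotype B", "pogostone-type"),
                            11: ("Genotype A", "patchoulol-type")},
        )
        sample = ref.identifier  # true count 10
        reads = simulate_amplicons(truth, sample, marker, n_reads=15, slippage_p=0.2, seed=5)
        call = call_genotype(reads, marker, sample)
        # independent oracle: orient each read by exact flank search and
        # count the run with a regex
        import re
        from collections import Counter

        oracle_counts = []
        for _, read in reads:
            oriented = read if marker.left_flank in read else revcomp(read)
            m = re.search(re.escape(marker.left_flank) + "(A+)", oriented)
            oracle_counts.append(len(m.group(1)))
        assert sorted(call.per_read_counts) == sorted(oracle_counts)
        assert call.consensus == Counter(oracle_counts).most_common(1)[0][0] == 10
        assert call.genotype == "Genotype B"
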