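"""Junction parsing, screening, reconstruction and target ranking."""

import logging

import pytest

from svmrd.io import write_sv_vcf
from svmrd.simulate import implant_svs, random_junction_specs
from svmrd.sv_targets import (
    DOWNSTREAM,
    UPSTREAM,
    Breakend,
    GenomeSequence,
    JunctionSpec,
    KmerIndex,
    PrevalenceUnavailableError,
    Region,
    RegionList,
    SvCandidate,
    estimate_prevalence,
    parse_sv_calls,
    reconstruct_junction,
    repeat_screen,
    revcomp,
    select_targets,
)

TOY = GenomeSequence({"chr1": "AAAACCCCGGGGTTTT"})


def _del_spec(insert=""):
    # deletion removing 1-based positions 5..12 of the 16 bp toy contig
    return JunctionSpec(
        id="del1",
        end_a=Breakend("chr1", 4, UPSTREAM, "+"),
        end_b=Breakend("chr1", 13, DOWNSTREAM, "+"),
        insert_seq=insert,
    )


class TestReconstructJunction:
    def test_simple_deletion_flanks(self):
        j = reconstruct_junction(TOY, _del_spec(), flank_len=4)
        assert j.sequence == "AAAATTTT"
        assert j.junction_offset == 4

    def test_non_templated_insert(self):
        j = reconstruct_junction(TOY, _del_spec("GA"), flank_len=4)
        assert j.sequence == "AAAAGATTTT"
        assert j.junction_offset == 4
        assert j.insert_len == 2

    def test_inversion_junction_b_flank_is_reverse_complement(self):
        # 20 bp toy contig; inversion-type junction joining the plus-strand
        # flank ending at 6 to the minus-strand (upstream) flank ending at 15
        contig = "ACGTACGGTTCAGGCTTACG"
        genome = GenomeSequence({"c": contig})
        spec = JunctionSpec(
            id="inv1",
            end_a=Breakend("c", 6, UPSTREAM, "+"),
            end_b=Breakend("c", 15, UPSTREAM, "-"),
            sv_class="inversion-junction",
        )
        j = reconstruct_junction(genome, spec, flank_len=5)
        # manual oracle: A = bases 2..6, B = revcomp(bases 11..15)
        assert j.sequence[:5] == contig[1:6]
        assert j.sequence[5:] == revcomp(contig[10:15])

    def test_flank_truncated_at_contig_edge_warns(self, caplog):
        with caplog.at_level(logging.WARNING):
            j = reconstruct_junction(TOY, _del_spec(), flank_len=10)
        assert j.sequence == "AAAATTTT"  # 4 left, 4 right available
        assert any("truncated" in r.message for r in caplog.records)

    def test_zero_flank_len_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_junction(TOY, _del_spec(), flank_len=0)

    def test_novelty_and_round_trip_on_simulated_svs(self, unique_genome, rng):
        """Reconstruction equals the simulator's read-through exactly, and
        the junction sequence is absent from the reference (both strands)
        for non-adjacent breakpoints."""
        specs = random_junction_specs(unique_genome, rng, n=12)
        for sv in implant_svs(unique_genome, specs):
            j = reconstruct_junction(unique_genome, sv.spec, flank_len=120)
            assert j.sequence == sv.read_through(120).sequence
            for contig in unique_genome.contigs.values():
                assert j.sequence not in contig
                assert revcomp(j.sequence) not in contig


class TestPrevalence:
    @pytest.mark.parametrize(
        "support,ref,expected",
        [(10, 10, 1.0), (5, 15, 0.5), (0, 20, 0.0), (30, 10, 1.0)],
    )
    def test_heterozygous_cell_fraction(self, support, ref, expected):
        cand = SvCandidate(_del_spec(), support_reads=support, ref_reads=ref)
        assert estimate_prevalence(cand) == pytest.approx(expected)

    def test_homozygous_override_halves_the_estimate(self):
        cand = SvCandidate(_del_spec(), support_reads=10, ref_reads=10)
        assert estimate_prevalence(cand, copies_per_genome=2) == pytest.approx(0.5)

    def test_no_reads_is_an_error(self):
        cand = SvCandidate(_del_spec(), support_reads=0, ref_reads=0)
        with pytest.raises(PrevalenceUnavailableError):
            estimate_prevalence(cand)


class TestRepeatScreen:
    def test_homopolymer_run_fails(self):
        contig = "A" * 10 + "GTCGATCGCATGCGTACGAT" + "C" * 30
        genome = GenomeSequence({"c": contig})
        spec = JunctionSpec(
            id="j", end_a=Breakend("c", 20, UPSTREAM, "+"),
            end_b=Breakend("c", 40, DOWNSTREAM, "+"),
        )
        res = repeat_screen(genome, spec, flank_len=20, k=15, max_homopolymer=8)
        assert not res.passed
        assert any("homopolymer-run" in r for r in res.reasons)

    def test_unique_genome_flanks_pass(self, unique_genome, rng):
        specs = random_junction_specs(unique_genome, rng, n=6)
        index = KmerIndex(unique_genome, 15)
        for spec in specs:
            res = repeat_screen(unique_genome, spec, kmer_index=index)
            assert res.passed, res.reasons

    def test_kmer_census_matches_brute_force(self, unique_genome):
        index = KmerIndex(unique_genome, 15)
        joined = list(unique_genome.contigs.values())
        for contig in joined:
            for i in (0, 137, 9000):
                kmer = contig[i : i + 15]
                brute = sum(
                    c[j : j + 15] in (kmer, revcomp(kmer))
                    for c in joined
                    for j in range(len(c) - 14)
                )
                assert index.hits(kmer) == brute == 1

    def test_triplicated_segment_fails_uniqueness(self, rng):
        segment = "".join(rng.choice(list("ACGT")) for _ in range(400))
        tail = "".join(rng.choice(list("ACGT")) for _ in range(800))
        genome = GenomeSequence({"c": segment * 3 + tail})
        spec = JunctionSpec(
            id="j",
            end_a=Breakend("c", 200, UPSTREAM, "+"),
            end_b=Breakend("c", 1500, DOWNSTREAM, "+"),
        )
        res = repeat_screen(genome, spec, flank_len=60, k=15, max_kmer_hits=2)
        assert not res.passed
        assert any("repetitive-kmer" in r for r in res.reasons)
        # brute-force confirmation: a flank 15-mer occurs 3x in the genome
        flank = genome["c"][185:200]
        count = sum(
            genome["c"][j : j + 15] == flank for j in range(len(genome["c"]) - 14)
        )
        assert count == 3

    def test_ambiguous_base_fails(self):
        genome = GenomeSequence({"c": "ACGT" * 20 + "N" + "TTGCAGTCAC" * 10})
        spec = JunctionSpec(
            id="j",
            end_a=Breakend("c", 85, UPSTREAM, "+"),
            end_b=Breakend("c", 120, DOWNSTREAM, "+"),
        )
        res = repeat_screen(genome, spec, flank_len=20, k=15)
        assert not res.passed
        assert any("ambiguous-base" in r for r in res.reasons)

    def test_flank_shorter_than_k_rejected(self):
        with pytest.raises(ValueError):
            repeat_screen(TOY, _del_spec(), flank_len=4, k=15)


class TestSelectTargets:
    def _candidates(self, genome, rng, n=5):
        specs = random_junction_specs(genome, rng, n=n)
        return [
            SvCandidate(s, support_reads=20 + i, ref_reads=10)
            for i, s in enumerate(specs)
        ]

    def test_recurrent_region_candidates_rank_first(self, unique_genome, rng):
        cands = self._candidates(unique_genome, rng)
        hot = cands[3].junction.end_a
        regions = RegionList(
            [Region(hot.contig, hot.pos - 5, hot.pos + 5, "HOT1")]
        )
        ranked = select_targets(cands, unique_genome, regions, max_targets=5)
        assert ranked[0].id == cands[3].junction.id

    def test_low_prevalence_excluded(self, unique_genome, rng):
        cands = self._candidates(unique_genome, rng)
        cands[0].support_reads, cands[0].ref_reads = 3, 17  # VAF .15 -> 30%
        ranked = select_targets(cands, unique_genome, min_prevalence=0.5)
        assert cands[0].junction.id not in {j.id for j in ranked}

    def test_at_most_max_targets_returned(self, unique_genome, rng):
        cands = self._candidates(unique_genome, rng, n=6)
        ranked = select_targets(cands, unique_genome, max_targets=3)
        assert len(ranked) == 3

    def test_output_is_deterministic_subset(self, unique_genome, rng):
        cands = self._candidates(unique_genome, rng)
        a = select_targets(cands, unique_genome)
        b = select_targets(cands, unique_genome)
        assert [j.id for j in a] == [j.id for j in b]
        assert {j.id for j in a} <= {c.junction.id for c in cands}

    def test_empty_candidate_list(self, unique_genome):
        assert select_targets([], unique_genome) == []


class TestParseSvCalls:
    def test_symbolic_del_coordinates(self, tmp_path, unique_genome):
        spec = JunctionSpec(
            id="d",
            end_a=Breakend("chr1", 4000, UPSTREAM, "+"),
            end_b=Breakend("chr1", 9000, DOWNSTREAM, "+"),
        )
        path = tmp_path / "del.vcf"
        write_sv_vcf(unique_genome, [(spec, 15, 5)], path)
        cands = parse_sv_calls(path, unique_genome)
        assert len(cands) == 1
        j = cands[0].junction
        assert (j.end_a.pos, j.end_a.side) == (4000, UPSTREAM)
        assert (j.end_b.pos, j.end_b.side) == (9000, DOWNSTREAM)
        assert j.sv_class == "deletion"
        assert cands[0].support_reads == 15
        assert cands[0].ref_reads == 5

    def test_reciprocal_translocation_yields_two_candidates(
        self, tmp_path, unique_genome
    ):
        der1 = JunctionSpec(
            id="t1",
            end_a=Breakend("chr1", 5000, UPSTREAM, "+"),
            end_b=Breakend("chr2", 7000, DOWNSTREAM, "+"),
            insert_seq="ACGTACGT",  # 8 bp non-templated insertion
            sv_class="reciprocal-translocation-derivative",
        )
        der2 = JunctionSpec(
            id="t2",
            end_a=Breakend("chr2", 6999, UPSTREAM, "+"),
            end_b=Breakend("chr1", 5001, DOWNSTREAM, "+"),
            sv_class="reciprocal-translocation-derivative",
        )
        path = tmp_path / "tra.vcf"
        write_sv_vcf(unique_genome, [(der1, 20, 8), (der2, 18, 9)], path)
        cands = parse_sv_calls(path, unique_genome)
        # four BND records, one per mate; each mate pair collapses to one
        assert len(cands) == 2
        by_insert = {c.junction.insert_seq for c in cands}
        assert by_insert == {"ACGTACGT", ""}
        assert all(
            c.junction.sv_class == "reciprocal-translocation-derivative"
            for c in cands
        )

    def test_bnd_round_trips_through_vcf(self, tmp_path, unique_genome, rng):
        specs = random_junction_specs(unique_genome, rng, n=6)
        path = tmp_path / "svs.vcf"
        write_sv_vcf(unique_genome, [(s, 10, 10) for s in specs], path)
        cands = parse_sv_calls(path, unique_genome)
        parsed = {
            (c.junction.end_a, c.junction.end_b, c.junction.insert_seq)
            for c in cands
        }
        truth = {(s.end_a, s.end_b, s.insert_seq) for s in specs}
        assert parsed == truth

    def test_empty_vcf_body(self, tmp_path, unique_genome):
        path = tmp_path / "empty.vcf"
        write_sv_vcf(unique_genome, [], path)
        assert parse_sv_calls(path, unique_genome) == []

    def test_malformed_bracket_collected_not_fatal(self, tmp_path, unique_genome, caplog):
        path = tmp_path / "bad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=20000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\tbad1\tA\tA[chr1:x[\t.\t.\t.\n"
            f"chr1\t4000\tok1\t{unique_genome['chr1'][3999]}\t"
            f"{unique_genome['chr1'][3999]}[chr1:9000[\t.\t.\t.\n"
        )
        with caplog.at_level(logging.WARNING):
            cands = parse_sv_calls(path, unique_genome)
        assert [c.junction.id for c in cands] == ["ok1"]
        assert any("malformed" in r.message for r in caplog.records)

    def test_unknown_contig_skipped_with_warning(self, tmp_path, unique_genome, caplog):
        path = tmp_path / "offgenome.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr9,length=20000>\n"
            "##INFO=<ID=SVTYPE,Number=1,Type=String,Description=\"t\">\n"
            "##INFO=<ID=END,Number=1,Type=Integer,Description=\"e\">\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr9\t100\tx\tA\t<DEL>\t.\t.\tSVTYPE=DEL;END=500\n"
        )
        with caplog.at_level(logging.WARNING):
            assert parse_sv_calls(path, unique_genome) == []
        assert any("absent from genome" in r.message for r in caplog.records)
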