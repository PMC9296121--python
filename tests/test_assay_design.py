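"""Primer/probe layout, melting temperatures and in-silico PCR."""

import pytest
from Bio.SeqUtils import MeltingTemp as mt
from hypothesis import given, settings, strategies as st

from svmrd.assay_design import (
    AssayDesignError,
    DesignConstraints,
    design_assay,
    in_silico_pcr,
    melting_temperature,
    specificity_check,
    validate_design,
)
from svmrd.simulate import implant_svs, random_junction_specs
from svmrd.sv_targets import JunctionSequence, revcomp

DNA = st.text(alphabet="ACGT", min_size=8, max_size=35)


class TestMeltingTemperature:
    def test_gc_rich_melts_higher_than_at_rich(self):
        assert melting_temperature("GCGCGCGCGC") > melting_temperature("AAAAAAAAAA")

    @given(DNA)
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_duplex_symmetry(self, seq):
        assert melting_temperature(seq) == pytest.approx(
            melting_temperature(revcomp(seq)), abs=1e-9
        )

    @given(DNA)
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_matches_independent_nearest_neighbor_oracle(self, seq):
        """Cross-check against Biopython's SantaLucia-1998 implementation
        with identical salt and strand-concentration settings."""
        oracle = mt.Tm_NN(
            seq, nn_table=mt.DNA_NN3, dnac1=250, dnac2=0, Na=50, Mg=3.8, saltcorr=5
        )
        assert melting_temperature(seq) == pytest.approx(oracle, abs=0.5)

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTNACGTACG")

    def test_short_oligo_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTA")


@pytest.fixture(scope="module")
def panel():
    from svmrd import SimConfig
    from svmrd.simulate import simulate_junction_panel

    return simulate_junction_panel(SimConfig(seed=11), n=12)


class TestDesignAssay:
    def test_design_satisfies_all_constraints(self, panel):
        c = DesignConstraints()
        designed = 0
        for junction in panel:
            try:
                design = design_assay(junction, c)
            except AssayDesignError:
                continue
            designed += 1
            assert design.amplicon_len < 100
            assert validate_design(design, junction, c) == []
        assert designed >= 8  # most random junctions are designable

    def test_probe_spans_junction(self, panel):
        for junction in panel:
            try:
                design = design_assay(junction)
            except AssayDesignError:
                continue
            (probe,) = design.probes
            assert probe.start + 4 <= junction.junction_offset <= probe.end - 4

    def test_double_probe_layout(self, unique_genome, rng):
        specs = random_junction_specs(
            unique_genome, rng, n=3, insert_range=(10, 12)
        )
        c = DesignConstraints(double_probe=True)
        designed = 0
        for sv in implant_svs(unique_genome, specs):
            junction = sv.read_through(150)
            try:
                design = design_assay(junction, c)
            except AssayDesignError:
                continue
            designed += 1
            p1, p2 = design.probes
            assert p1.end <= p2.start  # non-overlapping
            assert {p1.strand, p2.strand} == {"+", "-"}
            assert validate_design(design, junction, c) == []
        assert designed >= 1

    def test_homopolymer_flank_fails_with_reason(self):
        junction = JunctionSequence(
            junction_id="hp",
            sequence="ATCGGCTAGCATGCATCAGCATGCATGGATCCATGCATCAGCTACGTAGCATGCATCGAT"
            + "A" * 140,
            junction_offset=60,
            flank_len=60,
        )
        with pytest.raises(AssayDesignError) as err:
            design_assay(junction)
        assert "reverse primer" in str(err.value) or "probe" in str(err.value)

    def test_determinism(self, panel):
        junction = panel[0]
        assert design_assay(junction) == design_assay(junction)


def brute_force_pcr(templates, fwd, rev, max_len):
    """Naive all-pairs amplicon scan (independent oracle)."""
    hits = set()
    for name, seq in templates.items():
        n = len(seq)
        for primer_a, primer_b, strand in ((fwd, rev, "+"), (rev, fwd, "-")):
            a_sites = [
                i for i in range(n) if seq[i : i + len(primer_a)] == primer_a
            ]
            b_rc = revcomp(primer_b)
            b_sites = [i for i in range(n) if seq[i : i + len(b_rc)] == b_rc]
            for i in a_sites:
                for j in b_sites:
                    end = j + len(b_rc)
                    if (
                        i <= j
                        and i + len(primer_a) <= end
                        and end - i <= max_len
                    ):
                        hits.add((name, i, end, strand))
    return hits


class TestInSilicoPcr:
    def test_primers_from_junction_amplify_it_once(self, panel):
        junction = panel[1]
        design = design_assay(junction)
        hits = in_silico_pcr(
            {"j": junction.sequence},
            design.forward_primer.seq,
            design.reverse_primer.seq,
        )
        assert len(hits) == 1
        assert hits[0].product_len == design.amplicon_len

    def test_planted_duplicate_site_yields_two_hits(self, rng):
        fwd, rev = "ACGTGCATCGATGCATCG", "TGCATGCAGGCTAGCTAA"
        filler = "".join(rng.choice(list("ACGT")) for _ in range(600))
        cassette = fwd + "TTTTTCCCCC" + revcomp(rev)
        template = filler[:200] + cassette + filler[200:400] + cassette + filler[400:]
        hits = in_silico_pcr({"t": template}, fwd, rev, max_product_len=200)
        assert len(hits) == 2
        assert {(h.template, h.start, h.end, h.strand) for h in hits} == (
            brute_force_pcr({"t": template}, fwd, rev, 200)
        )

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_equals_brute_force_on_random_templates(self, seed):
        import numpy as np

        r = np.random.default_rng(seed)
        template = "".join(r.choice(list("ACGT"), size=300))
        fwd = template[10:18]  # short primers: multiple chance matches
        rev = revcomp(template[60:68])
        got = {
            (h.template, h.start, h.end, h.strand)
            for h in in_silico_pcr({"t": template}, fwd, rev, max_product_len=150)
        }
        assert got == brute_force_pcr({"t": template}, fwd, rev, 150)

    def test_empty_primer_rejected(self):
        with pytest.raises(ValueError):
            in_silico_pcr({"t": "ACGT"}, "", "ACGT")


class TestSpecificityCheck:
    def test_novel_junction_passes(self, unique_genome, rng):
        specs = random_junction_specs(unique_genome, rng, n=4)
        checked = 0
        for sv in implant_svs(unique_genome, specs):
            junction = sv.read_through(150)
            try:
                design = design_assay(junction)
            except AssayDesignError:
                continue
            checked += 1
            report = specificity_check(design, junction, unique_genome)
            assert report.passed, report.reasons
        assert checked >= 2

    def test_amplicon_not_spanning_junction_fails(self, unique_genome, rng):
        """Primers copied from within the A-flank alone amplify a purely
        reference-derived product: the check must fail."""
        specs = random_junction_specs(unique_genome, rng, n=1)
        sv = implant_svs(unique_genome, specs)[0]
        junction = sv.read_through(150)
        design = design_assay(junction)
        # shift the whole design into the A-flank by faking the layout
        a_only = JunctionSequence(
            junction_id=junction.junction_id,
            sequence=junction.sequence,
            junction_offset=len(junction.sequence) - 10,
            flank_len=junction.flank_len,
            insert_len=0,
        )
        report = specificity_check(design, a_only, unique_genome)
        assert not report.passed
        assert any("junction point" in r for r in report.reasons)

    def test_planted_off_target_is_reported(self, unique_genome, rng):
        specs = random_junction_specs(unique_genome, rng, n=1)
        sv = implant_svs(unique_genome, specs)[0]
        junction = sv.read_through(150)
        design = design_assay(junction)
        # plant a convergent copy of the primer sites into a decoy genome
        from svmrd.sv_targets import GenomeSequence

        decoy_insert = (
            design.forward_primer.seq + "T" * 30 + revcomp(design.reverse_primer.seq)
        )
        contig = unique_genome["chr1"]
        decoy = GenomeSequence(
            {"chr1": contig[:5000] + decoy_insert + contig[5000:]}
        )
        report = specificity_check(design, junction, decoy)
        assert not report.passed
        assert len(report.genome_hits) == 1
        # brute-force confirmation of the planted hit
        brute = brute_force_pcr(
            decoy.contigs, design.forward_primer.seq, design.reverse_primer.seq, 1000
        )
        assert {
            (h.template, h.start, h.end, h.strand) for h in report.genome_hits
        } == brute
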