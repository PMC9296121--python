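"""Forward simulation of every input the toolkit consumes.

The simulator generates synthetic reference genomes, implants structural
variants to obtain derivative haplotypes with known junction read-throughs,
and draws droplet counts from the Poisson/binomial partition model that the
quantification module inverts: a well with expected copy load c has each of
its n droplets positive independently with p = 1 - exp(-c/n).

These are ground-truth generators for testing and calibration; they model
droplet partitioning and dilution arithmetic, not sequencing reads, PCR
kinetics or cfDNA fragment-size biology.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .ddpcr_quant import (
    DIPLOID_GENOME_MASS_PG,
    SampleSpec,
    WellCounts,
    merge_wells,
    quantify_sample,
)
from .sensitivity import DilutionPoint
from .sv_targets import (
    DOWNSTREAM,
    UPSTREAM,
    Breakend,
    GenomeSequence,
    JunctionSequence,
    JunctionSpec,
    revcomp,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")

#: p above this in any channel flags the reaction as oversaturated.
SATURATION_P = 0.999


@dataclass(frozen=True)
class SimConfig:
    """Study-condition constants for all simulations.

    Defaults mirror the wet-lab setup being emulated: ~20,000 accepted
    droplets of 0.85 nl, a 6.6 pg diploid genome, and triplicate wells per
    liquid-biopsy sample.  The seed fixes every downstream draw.
    """

    seed: int = 0
    n_droplets_per_well: int = 20_000
    droplet_volume_nl: float = 0.85
    diploid_genome_mass_pg: float = DIPLOID_GENOME_MASS_PG
    wells_per_sample: int = 3

    def __post_init__(self) -> None:
        if (
            self.n_droplets_per_well <= 0
            or self.droplet_volume_nl <= 0
            or self.diploid_genome_mass_pg <= 0
            or self.wells_per_sample <= 0
        ):
            raise ValueError("all SimConfig parameters must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class SimulatedSv:
    """Ground truth for one implanted junction: the spec, the rearranged
    haplotype carrying it, and where the junction sits on that haplotype."""

    spec: JunctionSpec
    haplotype: str
    junction_pos: int  # 0-based: first base after the A segment
    prevalence: float = 1.0

    def read_through(self, flank_len: int) -> JunctionSequence:
        """Junction sequence as written into the haplotype (the round-trip
        oracle for reconstruction)."""
        ins = len(self.spec.insert_seq)
        start = max(0, self.junction_pos - flank_len)
        end = min(len(self.haplotype), self.junction_pos + ins + flank_len)
        return JunctionSequence(
            junction_id=self.spec.id,
            sequence=self.haplotype[start:end],
            junction_offset=self.junction_pos - start,
            flank_len=flank_len,
            insert_len=ins,
        )


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def _canonical_kmer_duplicates(contigs: dict[str, str], k: int) -> dict[str, int]:
    counts: Counter[str] = Counter()
    for seq in contigs.values():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            counts[min(kmer, revcomp(kmer))] += 1
    return {kmer: n for kmer, n in counts.items() if n > 1}


def _enforce_unique_kmers(
    contigs: dict[str, str], k: int, rng: np.random.Generator, max_rounds: int = 60
) -> dict[str, str]:
    """Remutate single bases until no canonical k-mer occurs twice.

    At the ~100 kb scale a random genome is expected to contain a few
    duplicated 15-mers, so duplicates are repaired locally rather than by
    regenerating the genome.
    """
    for _ in range(max_rounds):
        positions: dict[str, list[tuple[str, int]]] = {}
        for name, seq in contigs.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                positions.setdefault(min(kmer, revcomp(kmer)), []).append((name, i))
        dups = {c: ps for c, ps in positions.items() if len(ps) > 1}
        if not dups:
            return contigs
        arrs = {name: bytearray(seq, "ascii") for name, seq in contigs.items()}
        for canon in sorted(dups):
            for name, i in dups[canon][1:]:  # keep the first occurrence
                j = i + k // 2
                old = chr(arrs[name][j])
                arrs[name][j] = ord(rng.choice([b for b in "ACGT" if b != old]))
        contigs = {name: arr.decode() for name, arr in arrs.items()}
    raise RuntimeError(f"could not make {k}-mers unique in {max_rounds} rounds")


def make_genome(
    config: SimConfig,
    n_contigs: int = 2,
    contig_len: int = 50_000,
    repeat_fraction: float = 0.0,
    unique_kmer_k: int = 15,
) -> GenomeSequence:
    """Seeded random genome, optionally laced with repeat tracts.

    With ``repeat_fraction`` 0 the genome is post-processed so that no
    ``unique_kmer_k``-mer occurs twice on either strand (every junction
    flank then passes the uniqueness screen).  With a positive fraction,
    homopolymer and short tandem-repeat tracts are embedded to cover
    roughly that fraction of each contig, to exercise the repeat screen.
    """
    if contig_len < 1000:
        raise ValueError("contig_len must be >= 1 kb")
    if not 0 <= repeat_fraction < 1:
        raise ValueError("repeat_fraction must be in [0, 1)")
    rng = config.rng()
    contigs = {
        f"chr{i + 1}": _random_seq(rng, contig_len) for i in range(n_contigs)
    }
    if repeat_fraction == 0.0:
        contigs = _enforce_unique_kmers(contigs, unique_kmer_k, rng)
    else:
        for name in contigs:
            seq = bytearray(contigs[name], "ascii")
            covered = 0
            want = int(repeat_fraction * len(seq))
            guard = True  # first tract is always a long homopolymer
            while covered < want:
                tract_len = int(rng.integers(20, 60))
                start = int(rng.integers(0, len(seq) - tract_len))
                if guard or rng.random() < 0.5:
                    base = rng.choice(BASES).decode()
                    tract = base * tract_len
                    guard = False
                else:
                    unit = _random_seq(rng, int(rng.integers(2, 7)))
                    tract = (unit * tract_len)[:tract_len]
                seq[start : start + tract_len] = tract.encode()
                covered += tract_len
            contigs[name] = seq.decode()
    return GenomeSequence(contigs=contigs)


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------


def _left_segment(genome: GenomeSequence, be: Breakend) -> str:
    seq = genome[be.contig]
    if be.side == UPSTREAM and be.strand == "+":
        return seq[: be.pos]
    return revcomp(seq[be.pos - 1 :])  # downstream/-


def _right_segment(genome: GenomeSequence, be: Breakend) -> str:
    seq = genome[be.contig]
    if be.side == DOWNSTREAM and be.strand == "+":
        return seq[be.pos - 1 :]
    return revcomp(seq[: be.pos])  # upstream/-


def implant_svs(
    genome: GenomeSequence, specs: list[JunctionSpec], prevalence: float = 1.0
) -> list[SimulatedSv]:
    """Realize each junction spec as a rearranged haplotype.

    Each spec yields one derivative haplotype (a reciprocal translocation
    is represented by its two derivative junction specs, hence two
    haplotypes).  The junction read-through appears exactly once on its
    haplotype by construction.
    """
    if len({s.id for s in specs}) != len(specs):
        raise ValueError("junction spec ids must be unique")
    out = []
    for spec in specs:
        left = _left_segment(genome, spec.end_a)
        right = _right_segment(genome, spec.end_b)
        out.append(
            SimulatedSv(
                spec=spec,
                haplotype=left + spec.insert_seq + right,
                junction_pos=len(left),
                prevalence=prevalence,
            )
        )
    return out


def random_junction_specs(
    genome: GenomeSequence,
    rng: np.random.Generator,
    n: int,
    insert_range: tuple[int, int] = (0, 12),
    margin: int = 500,
    min_span: int = 2000,
) -> list[JunctionSpec]:
    """Draw ``n`` junction specs (deletions, translocation derivatives and
    inversion junctions in rotation) with random non-templated inserts."""
    names = sorted(genome.contigs)
    specs: list[JunctionSpec] = []
    classes = ["deletion", "reciprocal-translocation-derivative", "inversion-junction"]
    for i in range(n):
        cls = classes[i % len(classes)]
        insert = _random_seq(rng, int(rng.integers(insert_range[0], insert_range[1] + 1)))
        if cls == "reciprocal-translocation-derivative" and len(names) > 1:
            c1, c2 = rng.choice(names, size=2, replace=False)
            p1 = int(rng.integers(margin, genome.contig_length(c1) - margin))
            p2 = int(rng.integers(margin, genome.contig_length(c2) - margin))
            end_a = Breakend(c1, p1, UPSTREAM, "+")
            end_b = Breakend(c2, p2, DOWNSTREAM, "+")
        else:
            c = str(rng.choice(names))
            length = genome.contig_length(c)
            p1 = int(rng.integers(margin, length - margin - min_span))
            p2 = int(rng.integers(p1 + min_span, length - margin))
            if cls == "inversion-junction":
                end_a = Breakend(c, p1, UPSTREAM, "+")
                end_b = Breakend(c, p2, UPSTREAM, "-")
            else:
                cls = "deletion"
                end_a = Breakend(c, p1, UPSTREAM, "+")
                end_b = Breakend(c, p2, DOWNSTREAM, "+")
        specs.append(
            JunctionSpec(
                id=f"sv{i + 1:03d}",
                end_a=end_a,
                end_b=end_b,
                insert_seq=insert,
                sv_class=cls,
            )
        )
    return specs


def simulate_junction_panel(
    config: SimConfig,
    n: int = 15,
    contig_len: int = 60_000,
    flank_len: int = 150,
    insert_range: tuple[int, int] = (0, 12),
) -> list[JunctionSequence]:
    """A seeded panel of junction read-through sequences, extracted from the
    implanted haplotypes (simulator-native, independent of the
    reconstruction code path)."""
    genome = make_genome(config, n_contigs=2, contig_len=contig_len)
    rng = np.random.default_rng(config.seed + 1)
    specs = random_junction_specs(genome, rng, n, insert_range=insert_range)
    return [sv.read_through(flank_len) for sv in implant_svs(genome, specs)]


# ---------------------------------------------------------------------------
# Droplet counts
# ---------------------------------------------------------------------------


def simulate_well(
    target_copies: float,
    ref_copies: float,
    config: SimConfig,
    rng: np.random.Generator,
    well_id: str = "w1",
) -> WellCounts:
    """Draw one well's channel-positive counts from the partition model:
    p = 1 - exp(-copies / n_droplets), n_pos ~ Binomial(n_droplets, p)."""
    if target_copies < 0 or ref_copies < 0:
        raise ValueError("expected copies must be >= 0")
    n = config.n_droplets_per_well
    p_t = -np.expm1(-target_copies / n)
    p_r = -np.expm1(-ref_copies / n)
    return WellCounts(
        well_id=well_id,
        n_total=n,
        n_target_pos=int(rng.binomial(n, p_t)),
        n_ref_pos=int(rng.binomial(n, p_r)),
    )


@dataclass(frozen=True)
class MrdSample:
    """Simulated replicate wells for one sample plus the truth behind
    them."""

    wells: tuple[WellCounts, ...]
    expected_target_copies: float  # totals across wells
    expected_ref_copies: float
    saturated: bool


def simulate_mrd_sample(
    true_ratio: float,
    spec: SampleSpec,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_wells: int | None = None,
    cfdna_ref_cn_per_ml: float | None = None,
) -> MrdSample:
    """Simulate replicate wells for a sample with leukemic fraction
    ``true_ratio``.

    For gDNA the genome load comes from ``spec.dna_mass_ng``; for cfDNA it
    comes from ``cfdna_ref_cn_per_ml`` times the biopsy volume.  Target
    copies are ``genomes * true_ratio * copies_per_genome`` summed over the
    multiplexed targets.  Loads driving the per-droplet positive
    probability above ``SATURATION_P`` set the ``saturated`` flag (the
    downstream estimator then raises its oversaturation error).
    """
    if not 0 <= true_ratio <= 1:
        raise ValueError("true_ratio must be in [0, 1]")
    rng = config.rng() if rng is None else rng
    n_wells = config.wells_per_sample if n_wells is None else n_wells
    if spec.is_cfdna:
        if cfdna_ref_cn_per_ml is None:
            raise ValueError("cfDNA simulation requires cfdna_ref_cn_per_ml")
        ref_total = cfdna_ref_cn_per_ml * spec.liquid_volume_ml
        genomes = ref_total / spec.reference_ploidy
    else:
        genomes = (
            spec.dna_mass_ng * 1000.0 * spec.dilution / config.diploid_genome_mass_pg
        )
        ref_total = genomes * spec.reference_ploidy
    target_total = (
        genomes
        * true_ratio
        * spec.target_copies_per_genome
        * spec.n_targets_multiplexed
    )
    per_well_t = target_total / n_wells
    per_well_r = ref_total / n_wells
    n = config.n_droplets_per_well
    saturated = bool(
        max(-np.expm1(-per_well_t / n), -np.expm1(-per_well_r / n)) > SATURATION_P
    )
    wells = tuple(
        simulate_well(per_well_t, per_well_r, config, rng, well_id=f"w{i + 1}")
        for i in range(n_wells)
    )
    return MrdSample(
        wells=wells,
        expected_target_copies=target_total,
        expected_ref_copies=ref_total,
        saturated=saturated,
    )


def simulate_dilution_series(
    config: SimConfig,
    dilutions: tuple[float, ...] = tuple(10.0**-e for e in range(1, 7)),
    total_mass_ng: float = 500.0,
    n_wells: int = 5,
    diagnostic_ratio: float = 1.0,
    rng: np.random.Generator | None = None,
) -> list[DilutionPoint]:
    """Simulate an assay-performance dilution series.

    Positive-control gDNA is serially diluted in negative-control gDNA at
    constant total mass (default 500 ng split across 5 wells).  The
    reference gene therefore stays at full load while target copies scale
    with the dilution times the diagnostic ratio.
    """
    rng = config.rng() if rng is None else rng
    genomes_total = total_mass_ng * 1000.0 / config.diploid_genome_mass_pg
    ref_per_well = 2.0 * genomes_total / n_wells
    points = []
    for d in sorted(dilutions, reverse=True):
        target_total = genomes_total * d * diagnostic_ratio
        wells = [
            simulate_well(
                target_total / n_wells, ref_per_well, config, rng, well_id=f"w{i + 1}"
            )
            for i in range(n_wells)
        ]
        merged = merge_wells(wells)
        quant = quantify_sample(
            wells,
            SampleSpec(
                sample_id=f"dil_{d:g}",
                compartment="BM-gDNA",
                dna_mass_ng=total_mass_ng,
            ),
        )
        points.append(
            DilutionPoint(
                dilution=d,
                counts=merged,
                ratio_percent=quant.ratio_percent,
                expected_copies=target_total,
            )
        )
    return points
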