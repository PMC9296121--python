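"""Selection of leukemia-specific SV junction targets from WGS SV calls.

A structural rearrangement joins two genomic segments and creates a novel
read-through sequence at the junction that exists only in the malignant
clone.  This module parses SV calls (VCF breakends and symbolic alleles),
estimates what fraction of cells carry each junction, screens the flanking
sequence for repeats that would defeat PCR, reconstructs the junction
sequence, and ranks candidates so that at most a handful of high-prevalence,
recurrently-involved, PCR-amenable junctions are carried forward as
patient-specific markers.

Coordinate conventions
----------------------
Breakend positions are 1-based base coordinates (the last retained base for
an ``upstream`` breakend, the first retained base for a ``downstream`` one).
Region lists (BED-derived) and all coordinates on junction sequences are
0-based half-open.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field

import pysam

logger = logging.getLogger(__name__)

UPSTREAM = "upstream"
DOWNSTREAM = "downstream"

SV_CLASSES = (
    "deletion",
    "reciprocal-translocation-derivative",
    "inversion-junction",
    "unbalanced-rearrangement",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Genes recurrently rearranged in ALL, shipped as a replaceable default
#: recurrent-aberration region list (GRCh37/hg19 coordinates, 0-based
#: half-open).  Users monitoring real patients should supply their own BED.
DEFAULT_RECURRENT_GENES_HG19 = (
    ("1", 47681961, 47698007, "TAL1"),
    ("1", 47715810, 47779819, "STIL"),
    ("5", 170736287, 170739138, "TLX3"),
    ("7", 50344378, 50472798, "IKZF1"),
    ("7", 92234235, 92465941, "CDK6"),
    ("9", 21967751, 21995300, "CDKN2A"),
    ("9", 22002902, 22009280, "CDKN2B"),
    ("9", 36833272, 37034103, "PAX5"),
    ("12", 6775642, 6798541, "ZNF384"),
    ("12", 25358180, 25403854, "KRAS"),
    ("19", 1609289, 1652328, "TCF3"),
)


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSequence:
    """A reference genome held in memory as uppercase contig strings."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("genome must contain at least one contig")
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            if set(seq) - set("ACGTN"):
                raise ValueError(
                    f"contig {name!r} contains characters outside A/C/G/T/N"
                )

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def contig_length(self, name: str) -> int:
        return len(self.contigs[name])


@dataclass(frozen=True)
class Breakend:
    """One side of a rearrangement junction.

    ``side`` names the flank retained on the derivative chromosome relative
    to ``pos`` (1-based).  ``strand`` '-' means the retained flank is
    reverse-complemented when read through the junction.
    """

    contig: str
    pos: int
    side: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"breakend pos must be >= 1, got {self.pos}")
        if self.side not in (UPSTREAM, DOWNSTREAM):
            raise ValueError(f"side must be upstream/downstream, got {self.side!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/-, got {self.strand!r}")


def _is_left_end(be: Breakend) -> bool:
    """True if this breakend's retained flank reads with the break at its
    right edge (i.e. it can form the A side of a junction)."""
    return (be.side, be.strand) in ((UPSTREAM, "+"), (DOWNSTREAM, "-"))


def _is_right_end(be: Breakend) -> bool:
    return (be.side, be.strand) in ((DOWNSTREAM, "+"), (UPSTREAM, "-"))


@dataclass(frozen=True)
class JunctionSpec:
    """A breakpoint pair, orientations and non-templated insert defining one
    leukemia-specific junction."""

    id: str
    end_a: Breakend
    end_b: Breakend
    insert_seq: str = ""
    sv_class: str = "deletion"

    def __post_init__(self) -> None:
        if set(self.insert_seq) - set("ACGT"):
            raise ValueError("insert_seq must be over A/C/G/T")
        if self.sv_class not in SV_CLASSES:
            raise ValueError(f"unknown sv_class {self.sv_class!r}")
        if not _is_left_end(self.end_a):
            raise ValueError(
                "end_a must read with the break at its right edge "
                "(upstream/+ or downstream/-)"
            )
        if not _is_right_end(self.end_b):
            raise ValueError(
                "end_b must read with the break at its left edge "
                "(downstream/+ or upstream/-)"
            )


@dataclass
class SvCandidate:
    """A junction plus the read evidence supporting it."""

    junction: JunctionSpec
    support_reads: int = 0
    ref_reads: int = 0
    caller_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.support_reads < 0 or self.ref_reads < 0:
            raise ValueError("read counts must be non-negative")


@dataclass(frozen=True)
class Region:
    contig: str
    start: int  # 0-based half-open
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region start must be < end ({self.start}, {self.end})")


@dataclass
class RegionList:
    """Recurrent-aberration regions (e.g. genes recurrently rearranged in
    ALL), sorted per contig."""

    entries: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = sorted(
            self.entries, key=lambda r: (r.contig, r.start, r.end)
        )

    @classmethod
    def default_recurrent_all(cls) -> "RegionList":
        return cls([Region(*e) for e in DEFAULT_RECURRENT_GENES_HG19])

    def contains_point(self, contig: str, pos_1based: int) -> bool:
        p = pos_1based - 1
        return any(
            r.contig == contig and r.start <= p < r.end for r in self.entries
        )

    def overlapping_labels(self, spec: JunctionSpec) -> list[str]:
        labels = []
        for be in (spec.end_a, spec.end_b):
            for r in self.entries:
                if r.contig == be.contig and r.start <= be.pos - 1 < r.end:
                    labels.append(r.label)
        return labels

    def overlaps_junction(self, spec: JunctionSpec) -> bool:
        return any(
            self.contains_point(be.contig, be.pos)
            for be in (spec.end_a, spec.end_b)
        )


@dataclass(frozen=True)
class JunctionSequence:
    """The reconstructed read-through sequence for one junction.

    ``junction_offset`` is the 0-based index of the first base after the
    A-flank (start of the insert, or of the B-flank when the insert is
    empty).  ``insert_len`` is the length of the non-templated insert, so the
    B-flank starts at ``junction_offset + insert_len``.
    """

    junction_id: str
    sequence: str
    junction_offset: int
    flank_len: int
    insert_len: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.junction_offset < len(self.sequence)):
            raise ValueError("junction_offset must be interior to the sequence")


# ---------------------------------------------------------------------------
# Junction reconstruction
# ---------------------------------------------------------------------------


def _a_flank(genome: GenomeSequence, be: Breakend, flank_len: int) -> str:
    """Flank of end_a, oriented so the breakend base is the last base."""
    seq = genome[be.contig]
    if be.side == UPSTREAM and be.strand == "+":
        start = be.pos - flank_len
        if start < 0:
            logger.warning(
                "A-flank of %s:%d truncated at contig start", be.contig, be.pos
            )
            start = 0
        return seq[start : be.pos]
    # downstream/-: retained right flank, reverse-complemented
    end = be.pos - 1 + flank_len
    if end > len(seq):
        logger.warning("A-flank of %s:%d truncated at contig end", be.contig, be.pos)
        end = len(seq)
    return revcomp(seq[be.pos - 1 : end])


def _b_flank(genome: GenomeSequence, be: Breakend, flank_len: int) -> str:
    """Flank of end_b, oriented so the breakend base is the first base."""
    seq = genome[be.contig]
    if be.side == DOWNSTREAM and be.strand == "+":
        end = be.pos - 1 + flank_len
        if end > len(seq):
            logger.warning(
                "B-flank of %s:%d truncated at contig end", be.contig, be.pos
            )
            end = len(seq)
        return seq[be.pos - 1 : end]
    # upstream/-: retained left flank, reverse-complemented
    start = be.pos - flank_len
    if start < 0:
        logger.warning("B-flank of %s:%d truncated at contig start", be.contig, be.pos)
        start = 0
    return revcomp(seq[start : be.pos])


def _check_breakend(genome: GenomeSequence, be: Breakend) -> None:
    if be.contig not in genome:
        raise KeyError(f"contig {be.contig!r} not in genome")
    if be.pos > genome.contig_length(be.contig):
        raise ValueError(
            f"breakend {be.contig}:{be.pos} beyond contig end "
            f"({genome.contig_length(be.contig)})"
        )


def reconstruct_junction(
    genome: GenomeSequence, spec: JunctionSpec, flank_len: int
) -> JunctionSequence:
    """Build the junction read-through: A-flank + insert + B-flank.

    Each flank is the ``flank_len`` bases retained on the stated side of its
    breakend, reverse-complemented when the breakend strand is '-'.  Flanks
    reaching past a contig end are truncated with a warning.
    """
    if flank_len <= 0:
        raise ValueError("flank_len must be positive")
    _check_breakend(genome, spec.end_a)
    _check_breakend(genome, spec.end_b)
    a = _a_flank(genome, spec.end_a, flank_len)
    b = _b_flank(genome, spec.end_b, flank_len)
    return JunctionSequence(
        junction_id=spec.id,
        sequence=a + spec.insert_seq + b,
        junction_offset=len(a),
        flank_len=flank_len,
        insert_len=len(spec.insert_seq),
    )


# ---------------------------------------------------------------------------
# Prevalence
# ---------------------------------------------------------------------------


class PrevalenceUnavailableError(ValueError):
    """Raised when no reads inform the cell-fraction estimate."""


def estimate_prevalence(cand: SvCandidate, copies_per_genome: int = 1) -> float:
    """Cell fraction carrying the junction under the heterozygous-autosomal
    assumption (one junction copy per leukemic genome by default).

    VAF = support / (support + ref); cell fraction = 2 * VAF /
    copies_per_genome, capped at 1.
    """
    total = cand.support_reads + cand.ref_reads
    if total == 0:
        raise PrevalenceUnavailableError(
            f"no reads for junction {cand.junction.id}; prevalence unavailable"
        )
    vaf = cand.support_reads / total
    return min(1.0, 2.0 * vaf / copies_per_genome)


# ---------------------------------------------------------------------------
# Repeat / uniqueness screen
# ---------------------------------------------------------------------------


class KmerIndex:
    """Forward-strand k-mer counts of a genome; both-strand hit counts are
    answered by adding the reverse-complement count."""

    def __init__(self, genome: GenomeSequence, k: int):
        self.k = k
        counts: Counter[str] = Counter()
        for seq in genome.contigs.values():
            for i in range(len(seq) - k + 1):
                counts[seq[i : i + k]] += 1
        self._counts = counts

    def hits(self, kmer: str) -> int:
        rc = revcomp(kmer)
        n = self._counts.get(kmer, 0)
        if rc != kmer:
            n += self._counts.get(rc, 0)
        return n


def _longest_homopolymer(seq: str) -> int:
    best = run = 0
    prev = ""
    for c in seq:
        run = run + 1 if c == prev else 1
        prev = c
        best = max(best, run)
    return best


@dataclass(frozen=True)
class ScreenResult:
    passed: bool
    reasons: tuple[str, ...] = ()


def repeat_screen(
    genome: GenomeSequence,
    spec: JunctionSpec,
    flank_len: int = 60,
    k: int = 15,
    max_homopolymer: int = 8,
    max_kmer_hits: int = 1,
    kmer_index: KmerIndex | None = None,
) -> ScreenResult:
    """Screen junction flanks for repetitive context unsuitable for PCR.

    Fails if either flank contains a homopolymer run longer than
    ``max_homopolymer``, contains ambiguous bases, or contains any k-mer that
    occurs more than ``max_kmer_hits`` times in the genome (both strands).
    This is an explicit, automated proxy for the by-eye screening of
    "highly repetitive regions" that disqualifies junction candidates.
    """
    if flank_len < k:
        raise ValueError(f"flank_len ({flank_len}) must be >= k ({k})")
    _check_breakend(genome, spec.end_a)
    _check_breakend(genome, spec.end_b)
    if kmer_index is None:
        kmer_index = KmerIndex(genome, k)
    elif kmer_index.k != k:
        raise ValueError("kmer_index was built with a different k")

    reasons: list[str] = []
    flanks = {
        "A": _a_flank(genome, spec.end_a, flank_len),
        "B": _b_flank(genome, spec.end_b, flank_len),
    }
    for name, flank in flanks.items():
        if "N" in flank:
            reasons.append(f"ambiguous-base: {name}-flank contains N")
            continue
        run = _longest_homopolymer(flank)
        if run > max_homopolymer:
            reasons.append(
                f"homopolymer-run: {name}-flank has a {run} bp run "
                f"(max {max_homopolymer})"
            )
        worst = 0
        for i in range(len(flank) - k + 1):
            worst = max(worst, kmer_index.hits(flank[i : i + k]))
        if worst > max_kmer_hits:
            reasons.append(
                f"repetitive-kmer: {name}-flank has a {k}-mer with {worst} "
                f"genome hits (max {max_kmer_hits})"
            )
    return ScreenResult(passed=not reasons, reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# Target selection
# ---------------------------------------------------------------------------


def select_targets(
    cands: list[SvCandidate],
    genome: GenomeSequence,
    regions: RegionList | None = None,
    min_prevalence: float = 0.5,
    max_targets: int = 3,
    flank_len: int = 60,
    k: int = 15,
    max_homopolymer: int = 8,
    max_kmer_hits: int = 1,
) -> list[JunctionSpec]:
    """Filter and rank junction candidates into a patient target panel.

    Candidates failing the repeat screen or with an estimated cell fraction
    below ``min_prevalence`` are dropped.  Survivors are ranked with
    junctions in recurrent-aberration regions first, then by prevalence,
    read support and id; at most ``max_targets`` are returned (default 3:
    up to three targets per patient).
    """
    if max_targets < 1:
        raise ValueError("max_targets must be >= 1")
    if regions is None:
        regions = RegionList()
    if not cands:
        logger.info("no SV candidates supplied; returning empty target list")
        return []

    index = KmerIndex(genome, k)
    ranked: list[tuple[tuple, JunctionSpec]] = []
    for cand in cands:
        try:
            prevalence = estimate_prevalence(cand)
        except PrevalenceUnavailableError:
            logger.warning(
                "junction %s has no informative reads; excluded", cand.junction.id
            )
            continue
        if prevalence < min_prevalence:
            continue
        screen = repeat_screen(
            genome,
            cand.junction,
            flank_len=flank_len,
            k=k,
            max_homopolymer=max_homopolymer,
            max_kmer_hits=max_kmer_hits,
            kmer_index=index,
        )
        if not screen.passed:
            logger.info(
                "junction %s failed repeat screen: %s",
                cand.junction.id,
                "; ".join(screen.reasons),
            )
            continue
        in_recurrent = regions.overlaps_junction(cand.junction)
        key = (
            0 if in_recurrent else 1,
            -prevalence,
            -cand.support_reads,
            cand.junction.id,
        )
        ranked.append((key, cand.junction))
    ranked.sort(key=lambda kv: kv[0])
    return [junction for _, junction in ranked[:max_targets]]


# ---------------------------------------------------------------------------
# VCF parsing
# ---------------------------------------------------------------------------

_BND_RE = re.compile(
    r"^(?P<head>[ACGTNacgtn]*)(?P<br1>[\[\]])(?P<mate>[^\[\]:]+):(?P<pos>\d+)"
    r"(?P<br2>[\[\]])(?P<tail>[ACGTNacgtn]*)$"
)


def _decode_bnd(
    contig: str, pos: int, ref: str, alt: str
) -> tuple[Breakend, Breakend, str]:
    """Decode VCF 4.2 breakend bracket notation into an oriented junction.

    Returns (end_a, end_b, insert_seq) normalized so end_a reads with the
    break at its right edge and end_b at its left edge.
    """
    m = _BND_RE.match(alt)
    if not m or m.group("br1") != m.group("br2"):
        raise ValueError(f"malformed breakend ALT {alt!r}")
    head, tail = m.group("head").upper(), m.group("tail").upper()
    bracket = m.group("br1")
    mate_contig, mate_pos = m.group("mate"), int(m.group("pos"))
    if bool(head) == bool(tail):
        raise ValueError(f"breakend ALT {alt!r} must have bases on exactly one side")

    if head:
        if not head.startswith(ref.upper()):
            raise ValueError(f"breakend ALT {alt!r} does not begin with REF {ref!r}")
        insert = head[len(ref) :]
        end_a = Breakend(contig, pos, UPSTREAM, "+")
        if bracket == "[":  # t[p[ : joined to the piece right of p
            end_b = Breakend(mate_contig, mate_pos, DOWNSTREAM, "+")
        else:  # t]p] : joined to the reverse complement of the piece left of p
            end_b = Breakend(mate_contig, mate_pos, UPSTREAM, "-")
    else:
        if not tail.endswith(ref.upper()):
            raise ValueError(f"breakend ALT {alt!r} does not end with REF {ref!r}")
        insert = tail[: len(tail) - len(ref)]
        end_b = Breakend(contig, pos, DOWNSTREAM, "+")
        if bracket == "]":  # ]p]t : the piece left of p precedes t
            end_a = Breakend(mate_contig, mate_pos, UPSTREAM, "+")
        else:  # [p[t : reverse complement of the piece right of p precedes t
            end_a = Breakend(mate_contig, mate_pos, DOWNSTREAM, "-")
    return end_a, end_b, insert


def _classify_junction(end_a: Breakend, end_b: Breakend) -> str:
    if end_a.contig != end_b.contig:
        return "reciprocal-translocation-derivative"
    if end_a.strand == "-" or end_b.strand == "-":
        return "inversion-junction"
    if (
        end_a.side == UPSTREAM
        and end_b.side == DOWNSTREAM
        and end_b.pos > end_a.pos
    ):
        return "deletion"
    return "unbalanced-rearrangement"


def _info_count(rec, keys: tuple[str, ...]) -> int:
    total = 0
    for key in keys:
        try:
            val = rec.info.get(key)
        except ValueError:  # key not declared in the VCF header
            continue
        if val is None:
            continue
        if isinstance(val, (tuple, list)):
            total += sum(int(v) for v in val)
        else:
            total += int(val)
    return total


def parse_sv_calls(
    vcf_path,
    genome: GenomeSequence,
    support_keys: tuple[str, ...] = ("SR", "PE"),
    ref_keys: tuple[str, ...] = ("RR",),
    caller_key: str = "CALLER",
) -> list[SvCandidate]:
    """Parse SV calls from a VCF into junction candidates.

    Breakend (BND) records are decoded from bracket notation, with each mate
    pair contributing a single candidate (the first-seen, i.e.
    lowest-coordinate mate in a sorted VCF, is canonical).  Symbolic
    ``<DEL>``/``<INV>`` records with END are converted to their junction(s):
    a deletion anchored at POS with END e joins the upstream flank at POS to
    the downstream flank at e+1; an inversion yields two junctions, one per
    inverted boundary.  Records on contigs absent from the genome are
    skipped with a warning, and malformed records are collected as warnings
    rather than aborting the parse.
    """
    candidates: list[SvCandidate] = []
    seen: set[frozenset] = set()
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            if rec.chrom not in genome:
                logger.warning(
                    "record %s on contig %s absent from genome; skipped",
                    rec.id or f"{rec.chrom}:{rec.pos}",
                    rec.chrom,
                )
                continue
            if not rec.alts:
                continue
            alt = rec.alts[0]
            rec_id = rec.id or f"{rec.chrom}:{rec.pos}"
            support = _info_count(rec, support_keys)
            ref_reads = _info_count(rec, ref_keys)
            try:
                caller = rec.info.get(caller_key)
            except ValueError:
                caller = None
            callers = (
                [caller] if isinstance(caller, str) else list(caller or [])
            )

            junctions: list[tuple[str, Breakend, Breakend, str]] = []
            try:
                if alt == "<DEL>":
                    s, e = rec.start + 1, rec.stop  # POS anchor, 1-based END
                    junctions.append(
                        (
                            rec_id,
                            Breakend(rec.chrom, s, UPSTREAM, "+"),
                            Breakend(rec.chrom, e + 1, DOWNSTREAM, "+"),
                            "",
                        )
                    )
                elif alt == "<INV>":
                    p, e = rec.start + 1, rec.stop
                    junctions.append(
                        (
                            f"{rec_id}_j1",
                            Breakend(rec.chrom, p, UPSTREAM, "+"),
                            Breakend(rec.chrom, e, UPSTREAM, "-"),
                            "",
                        )
                    )
                    junctions.append(
                        (
                            f"{rec_id}_j2",
                            Breakend(rec.chrom, p + 1, DOWNSTREAM, "-"),
                            Breakend(rec.chrom, e + 1, DOWNSTREAM, "+"),
                            "",
                        )
                    )
                elif alt.startswith("<"):
                    logger.warning(
                        "record %s: unsupported symbolic ALT %s; skipped",
                        rec_id,
                        alt,
                    )
                    continue
                else:
                    end_a, end_b, insert = _decode_bnd(
                        rec.chrom, rec.pos, rec.ref, alt
                    )
                    junctions.append((rec_id, end_a, end_b, insert))
            except ValueError as exc:
                logger.warning("record %s: %s; skipped", rec_id, exc)
                continue

            for jid, end_a, end_b, insert in junctions:
                if end_b.contig not in genome:
                    logger.warning(
                        "record %s: mate contig %s absent from genome; skipped",
                        jid,
                        end_b.contig,
                    )
                    continue
                key = frozenset(
                    {
                        (end_a.contig, end_a.pos, end_a.side),
                        (end_b.contig, end_b.pos, end_b.side),
                    }
                )
                if key in seen:
                    continue
                seen.add(key)
                spec = JunctionSpec(
                    id=jid,
                    end_a=end_a,
                    end_b=end_b,
                    insert_seq=insert,
                    sv_class=_classify_junction(end_a, end_b),
                )
                candidates.append(
                    SvCandidate(
                        junction=spec,
                        support_reads=support,
                        ref_reads=ref_reads,
                        caller_names=callers,
                    )
                )
    return candidates
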