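"""Breakpoint-spanning ddPCR assay design and in-silico PCR specificity.

Assays place a forward/reverse primer pair around an SV junction with a
hydrolysis probe laid over the junction itself, so that a positive droplet
requires the leukemia-specific read-through sequence.  Amplicons are kept
under 100 bp — short amplicons suit fragmented cfDNA templates and droplet
PCR chemistry.  Specificity is verified by exact-match in-silico PCR: the
primer pair must amplify the junction exactly once and the reference genome
not at all.

The melting-temperature model is the SantaLucia (1998) unified
nearest-neighbor parameter set with an entropy salt correction; divalent
cations are folded into the monovalent concentration via the von Ahsen
square-root equivalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .sv_targets import GenomeSequence, JunctionSequence, revcomp

# SantaLucia 1998 unified nearest-neighbor parameters,
# (delta-H kcal/mol, delta-S cal/mol/K) keyed by the top-strand dinucleotide.
_NN = {
    "AA": (-7.9, -22.2),
    "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
    "CC": (-8.0, -19.9),
}
_INIT_GC = (0.1, -2.8)
_INIT_AT = (2.3, 4.1)
_SYM = (0.0, -1.4)
_R = 1.98720425864083  # cal/mol/K


def melting_temperature(
    oligo: str,
    mono_mM: float = 50.0,
    mg_mM: float = 3.8,
    oligo_nM: float = 250.0,
) -> float:
    """Nearest-neighbor duplex melting temperature in degrees Celsius.

    Raises ValueError for sequences shorter than 8 nt or containing bases
    outside A/C/G/T (a primer cannot be designed over an ambiguous base).
    """
    seq = oligo.upper()
    if len(seq) < 8:
        raise ValueError("Tm model requires length >= 8")
    if set(seq) - set("ACGT"):
        raise ValueError(f"oligo contains non-ACGT characters: {oligo!r}")

    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = _INIT_GC if terminal in "GC" else _INIT_AT
        dh += h
        ds += s

    selfcomp = seq == revcomp(seq)
    if selfcomp:
        ds += _SYM[1]
        k = oligo_nM * 1e-9
    else:
        k = oligo_nM * 1e-9  # excess-free single strand (dnac2 = 0)

    mon_eq = (mono_mM + 120.0 * math.sqrt(max(mg_mM, 0.0))) * 1e-3
    ds += 0.368 * (len(seq) - 1) * math.log(mon_eq)
    return 1000.0 * dh / (ds + _R * math.log(k)) - 273.15


def gc_fraction(seq: str) -> float:
    return sum(1 for c in seq if c in "GC") / len(seq)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignConstraints:
    """Layout and thermodynamic constraints for a junction assay.

    Tm windows default to conventional ddPCR settings: primers 58-62 degC
    with the probe window 3-10 degC above the primer-window midpoint.
    """

    max_amplicon_len: int = 99
    primer_len: tuple[int, int] = (18, 27)
    probe_len: tuple[int, int] = (18, 30)
    primer_tm: tuple[float, float] = (58.0, 62.0)
    probe_tm: tuple[float, float] | None = None
    gc_range: tuple[float, float] = (0.35, 0.65)
    min_probe_overhang: int = 4
    double_probe: bool = False
    mono_mM: float = 50.0
    mg_mM: float = 3.8
    oligo_nM: float = 250.0
    w_tm: float = 1.0
    w_gc: float = 10.0
    w_len: float = 0.05

    def __post_init__(self) -> None:
        if not self.max_amplicon_len < 100:
            raise ValueError("max_amplicon_len must be < 100 bp")
        for lo, hi in (self.primer_len, self.probe_len):
            if lo > hi or lo < 8:
                raise ValueError("length ranges must be non-empty and >= 8")
        if self.min_probe_overhang < 1:
            raise ValueError("min_probe_overhang must be >= 1")
        if self.probe_tm is None:
            mid = 0.5 * (self.primer_tm[0] + self.primer_tm[1])
            object.__setattr__(self, "probe_tm", (mid + 3.0, mid + 10.0))

    def tm(self, seq: str) -> float:
        return melting_temperature(
            seq, mono_mM=self.mono_mM, mg_mM=self.mg_mM, oligo_nM=self.oligo_nM
        )


@dataclass(frozen=True)
class Oligo:
    """A primer or probe placed on the junction sequence (0-based
    half-open coordinates; sequence is the synthesized oligo, i.e. the
    reverse complement of the template slice for '-' strand oligos)."""

    seq: str
    start: int
    end: int
    strand: str
    tm: float
    role: str


@dataclass(frozen=True)
class AssayDesign:
    junction_id: str
    forward_primer: Oligo
    reverse_primer: Oligo
    probes: tuple[Oligo, ...]
    amplicon_start: int
    amplicon_end: int
    penalty: float

    @property
    def amplicon_len(self) -> int:
        return self.amplicon_end - self.amplicon_start


@dataclass(frozen=True)
class AmpliconHit:
    template: str
    start: int
    end: int
    strand: str  # strand carrying the forward-primer match

    @property
    def product_len(self) -> int:
        return self.end - self.start


class AssayDesignError(ValueError):
    """Design failure; ``reasons`` lists the constraints that eliminated
    every candidate layout."""

    def __init__(self, junction_id: str, reasons: list[str]):
        self.junction_id = junction_id
        self.reasons = tuple(reasons)
        super().__init__(
            f"no valid assay for {junction_id}: " + "; ".join(reasons)
        )


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Scored:
    oligo: Oligo
    penalty: float


def _score(c: DesignConstraints, tm: float, gc: float, window) -> float:
    mid_tm = 0.5 * (window[0] + window[1])
    mid_gc = 0.5 * (c.gc_range[0] + c.gc_range[1])
    return c.w_tm * abs(tm - mid_tm) + c.w_gc * abs(gc - mid_gc)


def _enumerate(
    seq: str,
    c: DesignConstraints,
    len_range: tuple[int, int],
    window,
    region: tuple[int, int],
    strand: str,
    role: str,
    reject: dict[str, int],
) -> list[_Scored]:
    lo, hi = region
    out = []
    for L in range(len_range[0], len_range[1] + 1):
        for s in range(max(0, lo), min(len(seq), hi) - L + 1):
            sub = seq[s : s + L]
            if "N" in sub:
                reject["ambiguous-base"] += 1
                continue
            gc = gc_fraction(sub)
            if not (c.gc_range[0] <= gc <= c.gc_range[1]):
                reject["gc-content"] += 1
                continue
            oligo_seq = sub if strand == "+" else revcomp(sub)
            tm = c.tm(oligo_seq)
            if not (window[0] <= tm <= window[1]):
                reject["tm-window"] += 1
                continue
            out.append(
                _Scored(
                    Oligo(oligo_seq, s, s + L, strand, round(tm, 2), role),
                    _score(c, tm, gc, window),
                )
            )
    out.sort(key=lambda sc: (sc.penalty, sc.oligo.end - sc.oligo.start, sc.oligo.seq))
    return out


def _probe_units(
    junction: JunctionSequence, c: DesignConstraints, reject: dict[str, int]
) -> list[tuple[tuple[Oligo, ...], float, int, int]]:
    """Probe layouts: (probes, penalty, span_start, span_end).

    A probe "contains" a junction boundary when it extends at least
    ``min_probe_overhang`` bases on each side of it.  Single-probe mode uses
    the A-flank boundary; double-probe mode puts one probe over each
    boundary of the non-templated insert (plus then minus strand),
    non-overlapping — which requires an insert of at least twice the
    overhang.
    """
    seq = junction.sequence
    o = c.min_probe_overhang
    left = junction.junction_offset
    right = junction.junction_offset + junction.insert_len

    def over(boundary: int, strand: str, role: str) -> list[_Scored]:
        cands = []
        for L in range(c.probe_len[0], c.probe_len[1] + 1):
            for s in range(max(0, boundary + o - L), boundary - o + 1):
                if s + L > len(seq):
                    continue
                sub = seq[s : s + L]
                if "N" in sub:
                    reject["ambiguous-base"] += 1
                    continue
                gc = gc_fraction(sub)
                if not (c.gc_range[0] <= gc <= c.gc_range[1]):
                    reject["gc-content"] += 1
                    continue
                oligo_seq = sub if strand == "+" else revcomp(sub)
                tm = c.tm(oligo_seq)
                if not (c.probe_tm[0] <= tm <= c.probe_tm[1]):
                    reject["tm-window"] += 1
                    continue
                cands.append(
                    _Scored(
                        Oligo(oligo_seq, s, s + L, strand, round(tm, 2), role),
                        _score(c, tm, gc, c.probe_tm),
                    )
                )
        cands.sort(
            key=lambda sc: (sc.penalty, sc.oligo.end - sc.oligo.start, sc.oligo.seq)
        )
        return cands

    if not c.double_probe:
        return [
            ((sc.oligo,), sc.penalty, sc.oligo.start, sc.oligo.end)
            for sc in over(left, "+", "probe")
        ]

    if junction.insert_len < 2 * o:
        reject["double-probe-insert-too-short"] += 1
        return []
    plus = over(left, "+", "probe-plus")[:50]
    minus = over(right, "-", "probe-minus")[:50]
    units = []
    for p in plus:
        for q in minus:
            if p.oligo.end <= q.oligo.start:  # non-overlapping
                units.append(
                    (
                        (p.oligo, q.oligo),
                        p.penalty + q.penalty,
                        p.oligo.start,
                        q.oligo.end,
                    )
                )
    units.sort(key=lambda u: (u[1], u[3] - u[2], tuple(o.seq for o in u[0])))
    return units


# ---------------------------------------------------------------------------
# Design search
# ---------------------------------------------------------------------------


def design_assay(
    junction: JunctionSequence, constraints: DesignConstraints | None = None
) -> AssayDesign:
    """Exhaustively search primer/probe placements on a junction sequence.

    The lowest-penalty layout wins (penalty = Tm deviation from the window
    midpoint + GC deviation + amplicon-length term); ties break toward the
    shorter amplicon, then lexicographically smallest oligo sequences, so
    identical inputs always give byte-identical designs.  Raises
    :class:`AssayDesignError` naming the eliminating constraints when no
    layout survives.
    """
    c = constraints or DesignConstraints()
    seq = junction.sequence
    left = junction.junction_offset
    right = left + junction.insert_len
    if len(seq) < c.max_amplicon_len:
        raise AssayDesignError(
            junction.junction_id,
            [
                f"junction sequence ({len(seq)} bp) shorter than "
                f"max_amplicon_len ({c.max_amplicon_len} bp)"
            ],
        )

    reject: dict[str, int] = {
        "ambiguous-base": 0,
        "gc-content": 0,
        "tm-window": 0,
        "double-probe-insert-too-short": 0,
    }
    forwards = _enumerate(
        seq,
        c,
        c.primer_len,
        c.primer_tm,
        (right - c.max_amplicon_len, left),
        "+",
        "forward",
        reject,
    )
    reverses = _enumerate(
        seq,
        c,
        c.primer_len,
        c.primer_tm,
        (right, left + c.max_amplicon_len),
        "-",
        "reverse",
        reject,
    )
    probes = _probe_units(junction, c, reject)

    def _fail(missing: str) -> AssayDesignError:
        reasons = [f"no candidate {missing}"]
        reasons += [
            f"{n} placements rejected by {why}"
            for why, n in reject.items()
            if n
        ]
        return AssayDesignError(junction.junction_id, reasons)

    if not forwards:
        raise _fail("forward primer satisfied the primer constraints")
    if not reverses:
        raise _fail("reverse primer satisfied the primer constraints")
    if not probes:
        raise _fail("probe satisfied the probe constraints")

    best_key = None
    best: AssayDesign | None = None
    for f in forwards:
        for r in reverses:
            if r.oligo.start < f.oligo.end:
                continue
            amplen = r.oligo.end - f.oligo.start
            if amplen > c.max_amplicon_len:
                continue
            pair_pen = f.penalty + r.penalty + c.w_len * amplen
            if best_key is not None and (pair_pen, amplen) >= best_key[:2]:
                # even the best probe (penalty >= 0) cannot beat current best
                if pair_pen > best_key[0]:
                    continue
            for unit, upen, ustart, uend in probes:
                if ustart >= f.oligo.end and uend <= r.oligo.start:
                    key = (
                        pair_pen + upen,
                        amplen,
                        f.oligo.seq,
                        r.oligo.seq,
                        tuple(p.seq for p in unit),
                    )
                    if best_key is None or key < best_key:
                        best_key = key
                        best = AssayDesign(
                            junction_id=junction.junction_id,
                            forward_primer=f.oligo,
                            reverse_primer=r.oligo,
                            probes=unit,
                            amplicon_start=f.oligo.start,
                            amplicon_end=r.oligo.end,
                            penalty=round(key[0], 4),
                        )
                    break  # probes sorted by penalty: first fit is best
    if best is None:
        raise _fail(
            "primer/probe layout produced an amplicon spanning the junction "
            f"within {c.max_amplicon_len} bp"
        )
    return best


def validate_design(
    design: AssayDesign,
    junction: JunctionSequence,
    constraints: DesignConstraints | None = None,
) -> list[str]:
    """Independent post-hoc check of every layout constraint; returns the
    list of violations (empty when the design is valid)."""
    c = constraints or DesignConstraints()
    seq = junction.sequence
    left = junction.junction_offset
    right = left + junction.insert_len
    o = c.min_probe_overhang
    v: list[str] = []

    f, r = design.forward_primer, design.reverse_primer
    if seq[f.start : f.end] != f.seq:
        v.append("forward primer sequence does not match template")
    if revcomp(seq[r.start : r.end]) != r.seq:
        v.append("reverse primer sequence does not match template")
    if not f.end <= r.start:
        v.append("forward primer not upstream of reverse primer")
    if design.amplicon_len >= 100 or design.amplicon_len > c.max_amplicon_len:
        v.append(f"amplicon length {design.amplicon_len} exceeds limit")
    if not (design.amplicon_start <= left and right <= design.amplicon_end):
        v.append("amplicon does not span the junction")
    for L, role in ((f.seq, "forward"), (r.seq, "reverse")):
        if not (c.primer_len[0] <= len(L) <= c.primer_len[1]):
            v.append(f"{role} primer length out of range")
        if not (c.primer_tm[0] <= c.tm(L) <= c.primer_tm[1]):
            v.append(f"{role} primer Tm out of window")
        if not (c.gc_range[0] <= gc_fraction(L) <= c.gc_range[1]):
            v.append(f"{role} primer GC out of range")
    boundaries = [left] if not c.double_probe else [left, right]
    for i, p in enumerate(design.probes):
        tmpl = seq[p.start : p.end]
        if (tmpl if p.strand == "+" else revcomp(tmpl)) != p.seq:
            v.append(f"probe {i} sequence does not match template")
        if not (c.probe_len[0] <= len(p.seq) <= c.probe_len[1]):
            v.append(f"probe {i} length out of range")
        if not (c.probe_tm[0] <= c.tm(p.seq) <= c.probe_tm[1]):
            v.append(f"probe {i} Tm out of window")
        if not any(
            p.start + o <= b and b <= p.end - o for b in boundaries
        ):
            v.append(f"probe {i} does not contain a junction boundary with overhang")
        if not (f.end <= p.start and p.end <= r.start):
            v.append(f"probe {i} overlaps a primer")
    if c.double_probe:
        if len(design.probes) != 2:
            v.append("double-probe design must have exactly 2 probes")
        else:
            p1, p2 = design.probes
            if not (p1.end <= p2.start or p2.end <= p1.start):
                v.append("double probes overlap")
            if p1.strand == p2.strand:
                v.append("double probes on the same strand")
    elif len(design.probes) != 1:
        v.append("single-probe design must have exactly 1 probe")
    return v


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------


def _find_all(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def in_silico_pcr(
    templates: dict[str, str],
    forward: str,
    reverse: str,
    max_product_len: int = 2000,
) -> list[AmpliconHit]:
    """Exact-match virtual PCR over a set of named templates.

    Reports every convergent primer pair — a forward-primer match on one
    strand with a reverse-primer match downstream on the opposite strand —
    whose product is at most ``max_product_len``.  No mismatches are
    tolerated.  Results are deterministic, sorted by (template, start, end).
    """
    if not forward or not reverse:
        raise ValueError("primers must be non-empty")
    fwd, rev = forward.upper(), reverse.upper()
    rc_fwd, rc_rev = revcomp(fwd), revcomp(rev)
    hits: set[AmpliconHit] = set()
    for name, raw in templates.items():
        seq = raw.upper()
        # forward on '+', reverse annealing downstream on '-'
        f_hits = _find_all(seq, fwd)
        r_hits = _find_all(seq, rc_rev)
        for i in f_hits:
            for j in r_hits:
                end = j + len(rev)
                if i <= j and i + len(fwd) <= end and end - i <= max_product_len:
                    hits.add(AmpliconHit(name, i, end, "+"))
        # forward on '-', reverse annealing downstream on '+'
        f_hits = _find_all(seq, rc_fwd)
        r_hits = _find_all(seq, rev)
        for i in r_hits:
            for j in f_hits:
                end = j + len(fwd)
                if i <= j and i + len(rev) <= end and end - i <= max_product_len:
                    hits.add(AmpliconHit(name, i, end, "-"))
    return sorted(hits, key=lambda h: (h.template, h.start, h.end, h.strand))


@dataclass(frozen=True)
class SpecificityReport:
    passed: bool
    junction_hits: tuple[AmpliconHit, ...]
    genome_hits: tuple[AmpliconHit, ...]
    reasons: tuple[str, ...] = ()


def specificity_check(
    design: AssayDesign,
    junction: JunctionSequence,
    genome: GenomeSequence,
    max_product_len: int = 1000,
) -> SpecificityReport:
    """Pass iff the primer pair amplifies the junction template exactly once
    (with the product containing the junction point) and the reference
    genome not at all.

    ``max_product_len`` bounds what counts as an amplifiable off-target
    product: an assay cycled for sub-100 bp amplicons cannot amplify
    kilobase products, so reference products longer than this (e.g. the
    reference allele spanning a large deletion) are not treated as
    off-targets.
    """
    fwd, rev = design.forward_primer.seq, design.reverse_primer.seq
    j_hits = in_silico_pcr(
        {junction.junction_id: junction.sequence}, fwd, rev, max_product_len
    )
    g_hits = in_silico_pcr(genome.contigs, fwd, rev, max_product_len)
    reasons = []
    if len(j_hits) != 1:
        reasons.append(f"{len(j_hits)} amplicons on the junction template (need 1)")
    else:
        h = j_hits[0]
        left = junction.junction_offset
        right = left + junction.insert_len
        if not (h.start <= left and right <= h.end):
            reasons.append("junction amplicon does not contain the junction point")
    if g_hits:
        reasons.append(f"{len(g_hits)} off-target amplicons in the reference genome")
    return SpecificityReport(
        passed=not reasons,
        junction_hits=tuple(j_hits),
        genome_hits=tuple(g_hits),
        reasons=tuple(reasons),
    )
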