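"""Droplet-count statistics and MRD quantities for ddPCR.

A droplet digital PCR partitions a reaction into ~20,000 droplets; the
number of template copies is inferred from the fraction of positive
droplets by inverting the Poisson zero-class: lambda = -ln(1 - p).  This
module merges replicate wells by summing droplets, classifies positivity
(three or more target-positive droplets; one or two are a "trace"),
converts copies to CN/ml for liquid biopsies, and computes the
target:reference ratio corrected for the number of multiplexed targets and
reference-gene ploidy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

logger = logging.getLogger(__name__)

#: Mass of one diploid human genome in picograms (3.3 pg per haploid copy).
DIPLOID_GENOME_MASS_PG = 6.6

#: Accepted droplets below this per well suggest a failed droplet generation.
MIN_ACCEPTED_DROPLETS = 10_000

BM_GDNA = "BM-gDNA"
PLASMA_CFDNA = "plasma-cfDNA"
CSF_CFDNA = "CSF-cfDNA"
COMPARTMENTS = (BM_GDNA, PLASMA_CFDNA, CSF_CFDNA)

POSITIVE = "positive"
TRACE = "trace"
NOT_DETECTED = "not_detected"


class SaturationError(ValueError):
    """Every droplet positive: the copy estimate diverges.  Titrate the
    input (smaller liquid-biopsy volume or eluate input) and re-run."""


@dataclass(frozen=True)
class WellCounts:
    """Accepted-droplet and channel-positive counts for one well (or a
    merged set of wells).  Channel-positive counts include double
    positives."""

    well_id: str
    n_total: int
    n_target_pos: int
    n_ref_pos: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        for n, name in (
            (self.n_target_pos, "n_target_pos"),
            (self.n_ref_pos, "n_ref_pos"),
        ):
            if not 0 <= n <= self.n_total:
                raise ValueError(f"{name} must be in [0, n_total]")
        if self.n_total < MIN_ACCEPTED_DROPLETS:
            logger.warning(
                "well %s has only %d accepted droplets (< %d)",
                self.well_id,
                self.n_total,
                MIN_ACCEPTED_DROPLETS,
            )


@dataclass(frozen=True)
class SampleSpec:
    """Metadata needed to turn merged copies into MRD quantities."""

    sample_id: str
    compartment: str
    n_targets_multiplexed: int = 1
    liquid_volume_ml: float | None = None
    dna_mass_ng: float | None = None
    dilution: float = 1.0
    reference_ploidy: float = 2.0
    target_copies_per_genome: float = 1.0

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"compartment must be one of {COMPARTMENTS}, got "
                f"{self.compartment!r}"
            )
        if self.n_targets_multiplexed < 1:
            raise ValueError("n_targets_multiplexed must be >= 1")
        if not 0 < self.dilution <= 1:
            raise ValueError("dilution must be in (0, 1]")
        if self.is_cfdna:
            if not self.liquid_volume_ml or self.liquid_volume_ml <= 0:
                raise ValueError("cfDNA samples require a positive liquid volume")
        else:
            if not self.dna_mass_ng or self.dna_mass_ng <= 0:
                raise ValueError("gDNA samples require a positive DNA mass")

    @property
    def is_cfdna(self) -> bool:
        return self.compartment in (PLASMA_CFDNA, CSF_CFDNA)


@dataclass(frozen=True)
class QuantResult:
    sample_id: str
    target_copies: float
    ref_copies: float
    positivity: str
    ratio_percent: float | None
    trace_flag: bool
    target_cn_per_ml: float | None = None
    ref_cn_per_ml: float | None = None


# ---------------------------------------------------------------------------
# Partition statistics
# ---------------------------------------------------------------------------


def poisson_copies(n_pos: int, n_total: int) -> float:
    """Copies in the merged partition set from positive/total droplets.

    lambda = -ln(1 - n_pos/n_total) copies per droplet; returns
    lambda * n_total.  Raises :class:`SaturationError` when every droplet is
    positive (oversaturated input).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_pos <= n_total:
        raise ValueError("n_pos must be in [0, n_total]")
    if n_pos == n_total:
        raise SaturationError(
            "all droplets positive; input oversaturated — titrate input "
            "volume and re-run"
        )
    return -math.log1p(-n_pos / n_total) * n_total


def merge_wells(wells: Iterable[WellCounts]) -> WellCounts:
    """Sum replicate wells component-wise ("the sum of all signals" across
    replicates); downstream estimates use the merged counts."""
    wells = list(wells)
    if not wells:
        raise ValueError("merge_wells requires at least one well")
    if len(wells) == 1:
        return wells[0]
    return WellCounts(
        well_id="+".join(w.well_id for w in wells),
        n_total=sum(w.n_total for w in wells),
        n_target_pos=sum(w.n_target_pos for w in wells),
        n_ref_pos=sum(w.n_ref_pos for w in wells),
    )


def classify_positivity(merged: WellCounts) -> str:
    """Three or more target-positive droplets -> positive; one or two ->
    trace; none -> not detected."""
    if merged.n_target_pos >= 3:
        return POSITIVE
    if merged.n_target_pos >= 1:
        return TRACE
    return NOT_DETECTED


# ---------------------------------------------------------------------------
# MRD quantities
# ---------------------------------------------------------------------------


def cn_per_ml(copies: float, spec: SampleSpec) -> float:
    """Copies per ml of the original liquid biopsy: merged copies divided
    by the initial plasma/CSF volume (no eluate-fraction correction)."""
    if not spec.is_cfdna:
        raise ValueError("CN/ml is defined for cfDNA compartments only")
    if not spec.liquid_volume_ml or spec.liquid_volume_ml <= 0:
        raise ValueError("liquid_volume_ml must be positive")
    return copies / spec.liquid_volume_ml


def mrd_ratio(target_cn: float, ref_cn: float, spec: SampleSpec) -> float:
    """Target:reference ratio in percent, corrected for the number of
    multiplexed targets and reference ploidy.

    ratio% = 100 * (target / (n_targets * copies_per_genome))
                 / (ref / reference_ploidy)

    Units cancel, so per-reaction copies and CN/ml are equally valid inputs.
    """
    if target_cn < 0:
        raise ValueError("target_cn must be >= 0")
    if ref_cn <= 0:
        raise ValueError(
            "reference channel has no copies; sample is unquantifiable"
        )
    target_per_genome = target_cn / (
        spec.n_targets_multiplexed * spec.target_copies_per_genome
    )
    genomes = ref_cn / spec.reference_ploidy
    return 100.0 * target_per_genome / genomes


class TheoreticalCn(NamedTuple):
    target_copies: float
    ref_copies: float
    genomes: float


def theoretical_cn(
    dna_mass_ng: float,
    dilution: float,
    spec: SampleSpec,
    diploid_genome_mass_pg: float = DIPLOID_GENOME_MASS_PG,
) -> TheoreticalCn:
    """Expected copies at 100% PCR efficiency and no pipetting loss.

    genomes = mass * dilution / diploid genome mass; target copies scale
    with copies-per-genome, reference copies with reference ploidy.
    """
    if dna_mass_ng < 0:
        raise ValueError("dna_mass_ng must be >= 0")
    if not 0 < dilution <= 1:
        raise ValueError("dilution must be in (0, 1]")
    genomes = dna_mass_ng * 1000.0 * dilution / diploid_genome_mass_pg
    return TheoreticalCn(
        target_copies=genomes * spec.target_copies_per_genome,
        ref_copies=dna_mass_ng * 1000.0 / diploid_genome_mass_pg
        * spec.reference_ploidy,
        genomes=genomes,
    )


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def fold_range(values: Iterable[float]) -> float:
    """max/min fold difference across positive measurements, to 2
    significant figures."""
    vals = list(values)
    if len(vals) < 2:
        raise ValueError("fold_range requires at least two values")
    if any(v <= 0 for v in vals):
        raise ValueError("fold_range requires positive values")
    return _round_sig(max(vals) / min(vals), 2)


# ---------------------------------------------------------------------------
# Sample-level quantification
# ---------------------------------------------------------------------------


def quantify_sample(wells: Iterable[WellCounts], spec: SampleSpec) -> QuantResult:
    """Merge replicate wells and derive the full MRD quantity set.

    Trace samples (1-2 droplets) are still quantified, with ``trace_flag``
    set; not-detected samples report zero target copies and a 0% ratio.
    A saturated target or reference channel raises
    :class:`SaturationError`.
    """
    merged = merge_wells(wells)
    positivity = classify_positivity(merged)
    target_copies = poisson_copies(merged.n_target_pos, merged.n_total)
    ref_copies = poisson_copies(merged.n_ref_pos, merged.n_total)
    if positivity == NOT_DETECTED:
        target_copies = 0.0

    target_ml = ref_ml = None
    if spec.is_cfdna:
        target_ml = cn_per_ml(target_copies, spec)
        ref_ml = cn_per_ml(ref_copies, spec)

    ratio = mrd_ratio(target_copies, ref_copies, spec) if ref_copies > 0 else None
    return QuantResult(
        sample_id=spec.sample_id,
        target_copies=target_copies,
        ref_copies=ref_copies,
        positivity=positivity,
        ratio_percent=ratio,
        trace_flag=positivity == TRACE,
        target_cn_per_ml=target_ml,
        ref_cn_per_ml=ref_ml,
    )
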