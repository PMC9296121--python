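"""Limit of detection / limit of quantifiability from serial dilutions.

Assay performance is characterised on 10-fold serial dilutions of positive
control (diagnostic) DNA in negative control (healthy donor) DNA, from
10^-1 down to 10^-6.  The measured target:reference ratio is regressed on
the dilution in log10-log10 space; the assay is quantifiable down to the
deepest dilution at which the restricted fit is still linear with unit
slope and the point itself is positive and accurate, and detectable down to
the deepest dilution with at least one target-positive droplet (trace
counts as detection).  A fitted series can also be extrapolated to
dilution 1 to stand in for a missing diagnostic sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy import stats

from .ddpcr_quant import POSITIVE, WellCounts, classify_positivity

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DilutionPoint:
    """One decade of the dilution series: merged replicate counts, the
    measured ratio (percent) and the theoretically expected copies."""

    dilution: float
    counts: WellCounts
    ratio_percent: float | None
    expected_copies: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.dilution <= 1:
            raise ValueError("dilution must be in (0, 1]")

    @property
    def positivity(self) -> str:
        return classify_positivity(self.counts)


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float  # log10(ratio %) at dilution 1
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class SensitivityResult:
    lod_dilution: float | None
    loq_dilution: float | None
    fit: LinearFit | None
    detection_classes: tuple[tuple[float, str], ...]


def _sorted_desc(points: list[DilutionPoint]) -> list[DilutionPoint]:
    if len({p.dilution for p in points}) != len(points):
        raise ValueError("dilution points must have distinct dilutions")
    return sorted(points, key=lambda p: -p.dilution)


def fit_linearity(points: list[DilutionPoint]) -> LinearFit | None:
    """Least-squares regression of log10(measured ratio) on log10(dilution)
    over target-positive points only; ``None`` (linearity undefined) when
    fewer than three points are positive."""
    pos = [
        p
        for p in _sorted_desc(points)
        if p.positivity == POSITIVE and p.ratio_percent and p.ratio_percent > 0
    ]
    if len(pos) < 3:
        return None
    x = [math.log10(p.dilution) for p in pos]
    y = [math.log10(p.ratio_percent) for p in pos]
    res = stats.linregress(x, y)
    return LinearFit(
        slope=res.slope,
        intercept=res.intercept,
        r_squared=res.rvalue**2,
        n_points=len(pos),
    )


def determine_loq(
    points: list[DilutionPoint],
    slope_tolerance: float = 0.15,
    r2_min: float = 0.98,
    accuracy_tolerance_log10: float = 0.5,
) -> float | None:
    """Deepest (smallest) dilution down to which the assay is quantifiable.

    LoQ is the smallest dilution d such that the fit restricted to
    dilutions >= d has |slope - 1| <= slope_tolerance and r^2 >= r2_min,
    and the point at d is itself positive with the measured ratio within
    ``accuracy_tolerance_log10`` of the fit's prediction.  ``None`` when no
    dilution qualifies.
    """
    pts = _sorted_desc(points)
    for idx in range(len(pts) - 1, -1, -1):  # deepest candidate first
        cand = pts[idx]
        if cand.positivity != POSITIVE or not cand.ratio_percent:
            continue
        fit = fit_linearity(pts[: idx + 1])
        if fit is None:
            continue
        if abs(fit.slope - 1.0) > slope_tolerance or fit.r_squared < r2_min:
            continue
        predicted = fit.intercept + fit.slope * math.log10(cand.dilution)
        if abs(math.log10(cand.ratio_percent) - predicted) > accuracy_tolerance_log10:
            continue
        return cand.dilution
    return None


def determine_lod(points: list[DilutionPoint]) -> float | None:
    """Deepest dilution with uninterrupted detection.

    Walks the series from the least dilute point down; any dilution with at
    least one target-positive droplet (trace counts) extends the LoD.  A
    detected point below an undetected one marks the series non-monotone;
    the LoD stops at the gap.
    """
    lod = None
    gap = False
    for p in _sorted_desc(points):
        if p.counts.n_target_pos >= 1:
            if gap:
                logger.warning(
                    "detection at dilution %g below an undetected dilution; "
                    "series non-monotone, LoD kept at the gap",
                    p.dilution,
                )
                break
            lod = p.dilution
        else:
            gap = True
    return lod


def analyze_series(
    points: list[DilutionPoint],
    slope_tolerance: float = 0.15,
    r2_min: float = 0.98,
    accuracy_tolerance_log10: float = 0.5,
) -> SensitivityResult:
    """Full assay-performance summary for one dilution series."""
    pts = _sorted_desc(points)
    return SensitivityResult(
        lod_dilution=determine_lod(pts),
        loq_dilution=determine_loq(
            pts,
            slope_tolerance=slope_tolerance,
            r2_min=r2_min,
            accuracy_tolerance_log10=accuracy_tolerance_log10,
        ),
        fit=fit_linearity(pts),
        detection_classes=tuple((p.dilution, p.positivity) for p in pts),
    )


def extrapolate_theoretical_ratio(fit: LinearFit | None, at_dilution: float) -> float:
    """Ratio (percent) predicted by the dilution-series fit at
    ``at_dilution`` — extrapolated to 1.0 this stands in for a diagnostic
    sample that was never analysed."""
    if fit is None:
        raise ValueError("linearity fit undefined; cannot extrapolate")
    if not 0 < at_dilution <= 1:
        raise ValueError("at_dilution must be in (0, 1]")
    return 10.0 ** (fit.intercept + fit.slope * math.log10(at_dilution))


def format_dilution(dilution: float | None) -> str:
    """Decade string ("10^-4") for report tables; "-" when undefined."""
    if dilution is None:
        return "-"
    exp = math.log10(dilution)
    if abs(exp - round(exp)) < 1e-9:
        return f"10^{round(exp):d}" if round(exp) != 0 else "1"
    return f"{dilution:g}"
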