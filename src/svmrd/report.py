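"""Longitudinal MRD report assembly.

Renders per-patient MRD trajectories the way clinical summary tables print
them: percentages to two decimals (four below 0.01%), trace amounts in
parentheses, "ND" for not detected, plus log10 changes in reference-gene
CN/ml between the first and each later timepoint as a summary of cfDNA
kinetics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import pandas as pd

from .ddpcr_quant import NOT_DETECTED, TRACE, QuantResult


def format_ratio(ratio_percent: float | None, positivity: str) -> str:
    """Table rendering of a ratio: "ND" when not detected, parentheses for
    trace amounts, 2 decimals at >= 0.01%, 4 decimals below."""
    if positivity == NOT_DETECTED or ratio_percent is None:
        return "ND"
    text = f"{ratio_percent:.2f}" if ratio_percent >= 0.01 else f"{ratio_percent:.4f}"
    return f"({text})" if positivity == TRACE else text


def format_ratio_whole_percent(ratio_percent: float | None) -> str:
    """Whole-percent rendering used in compact CSF summaries."""
    if ratio_percent is None:
        return "ND"
    return f"{round(ratio_percent):d}"


@dataclass(frozen=True)
class TimepointEntry:
    patient_id: str
    sample_id: str
    timepoint_day: int
    compartment: str
    ratio_percent: float | None
    positivity: str
    ref_cn_per_ml: float | None

    @property
    def rendered_ratio(self) -> str:
        return format_ratio(self.ratio_percent, self.positivity)


@dataclass
class LongitudinalReport:
    """Per-patient ordered timepoints with per-compartment ratios and
    reference-gene cfDNA kinetics."""

    patients: dict[str, list[TimepointEntry]] = field(default_factory=dict)

    def log10_change(
        self, patient_id: str, compartment: str, to_day: int
    ) -> float | None:
        """log10 drop in reference CN/ml from the first timepoint of this
        compartment to ``to_day`` (one decimal); ``None`` when either end
        is missing."""
        series = [
            e
            for e in self.patients.get(patient_id, [])
            if e.compartment == compartment and e.ref_cn_per_ml
        ]
        if not series:
            return None
        first = series[0]
        later = [e for e in series if e.timepoint_day == to_day]
        if not later or first.timepoint_day == to_day:
            return None
        return round(math.log10(first.ref_cn_per_ml / later[0].ref_cn_per_ml), 1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid in sorted(self.patients):
            for e in self.patients[pid]:
                rows.append(
                    {
                        "patient_id": pid,
                        "timepoint_day": e.timepoint_day,
                        "compartment": e.compartment,
                        "sample_id": e.sample_id,
                        "ratio": e.rendered_ratio,
                        "positivity": e.positivity,
                        "ref_cn_per_ml": ""
                        if e.ref_cn_per_ml is None
                        else f"{e.ref_cn_per_ml:.4g}",
                    }
                )
        return pd.DataFrame(rows)

    def write(self, tsv_path, json_path=None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            payload = {
                pid: [
                    {
                        "day": e.timepoint_day,
                        "compartment": e.compartment,
                        "sample_id": e.sample_id,
                        "ratio": e.rendered_ratio,
                        "positivity": e.positivity,
                    }
                    for e in entries
                ]
                for pid, entries in sorted(self.patients.items())
            }
            with open(json_path, "w") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)
                fh.write("\n")


def build_report(
    results: dict[str, QuantResult], sample_info: dict[str, dict]
) -> LongitudinalReport:
    """Assemble the longitudinal report from per-sample quantifications.

    ``sample_info`` maps sample_id to {patient_id, timepoint_day} (the
    metadata CSV's extra columns).  Within each patient, timepoints must
    arrive strictly increasing per compartment; samples without a
    quantified reference channel are omitted with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    report = LongitudinalReport()
    last_day: dict[tuple[str, str], int] = {}
    for sample_id, info in sample_info.items():
        if sample_id not in results:
            continue
        q = results[sample_id]
        if q.ref_copies <= 0:
            logger.warning(
                "sample %s has no reference-channel signal; omitted", sample_id
            )
            continue
        pid = info["patient_id"]
        day = int(info["timepoint_day"])
        compartment = info.get("compartment", "unknown")
        key = (pid, compartment)
        if key in last_day and day <= last_day[key]:
            raise ValueError(
                f"timepoints for patient {pid} ({compartment}) are not "
                f"strictly increasing at day {day}"
            )
        last_day[key] = day
        report.patients.setdefault(pid, []).append(
            TimepointEntry(
                patient_id=pid,
                sample_id=sample_id,
                timepoint_day=day,
                compartment=compartment,
                ratio_percent=q.ratio_percent,
                positivity=q.positivity,
                ref_cn_per_ml=q.ref_cn_per_ml,
            )
        )
    return report
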