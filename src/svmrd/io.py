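"""Readers and writers for the toolkit's file surface.

Formats: FASTA (reference genomes, junction sequences), VCF 4.2 (SV
calls), BED (recurrent-aberration regions, 0-based half-open), and
documented CSV dialects for droplet counts, sample metadata and dilution
series.  CSV files may carry ``#`` comment headers (the simulator records
its seed there); all writers produce deterministic, byte-stable output.
"""

from __future__ import annotations

import csv
import json

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assay_design import AssayDesign
from .ddpcr_quant import QuantResult, SampleSpec, WellCounts
from .sensitivity import SensitivityResult, format_dilution
from .sv_targets import (
    GenomeSequence,
    JunctionSequence,
    JunctionSpec,
    Region,
    RegionList,
    revcomp,
)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_genome_fasta(path) -> GenomeSequence:
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    return GenomeSequence(contigs=contigs)


def write_genome_fasta(genome: GenomeSequence, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_junction_fasta(junctions: list[JunctionSequence], path) -> None:
    """One record per junction; the description encodes the junction
    layout so the file round-trips."""
    records = [
        SeqRecord(
            Seq(j.sequence),
            id=j.junction_id,
            description=(
                f"junction_offset={j.junction_offset} "
                f"flank_len={j.flank_len} insert_len={j.insert_len}"
            ),
        )
        for j in junctions
    ]
    SeqIO.write(records, str(path), "fasta")


def read_junction_fasta(path) -> list[JunctionSequence]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            kv.split("=") for kv in rec.description.split() if "=" in kv
        )
        out.append(
            JunctionSequence(
                junction_id=rec.id,
                sequence=str(rec.seq).upper(),
                junction_offset=int(fields["junction_offset"]),
                flank_len=int(fields["flank_len"]),
                insert_len=int(fields.get("insert_len", 0)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path) -> RegionList:
    df = pd.read_csv(
        str(path),
        sep="\t",
        comment="#",
        header=None,
        names=["contig", "start", "end", "label"],
        usecols=[0, 1, 2, 3],
        dtype={0: str},
    )
    entries = [
        Region(str(r.contig), int(r.start), int(r.end), str(r.label))
        for r in df.itertuples()
    ]
    return RegionList(entries=entries)


def write_bed(regions: RegionList, path) -> None:
    with open(path, "w") as fh:
        for r in regions.entries:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.label}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_sv_vcf(
    genome: GenomeSequence,
    specs: list[tuple[JunctionSpec, int, int]],
    path,
    seed: int | None = None,
) -> None:
    """Write junction specs as VCF records: plain +/+ intra-contig
    deletions without inserts become symbolic ``<DEL>``; everything else is
    written as a breakend mate pair.  ``specs`` items are (junction,
    support_reads, ref_reads)."""
    header = pysam.VariantHeader()
    header.add_line('##source=svmrd-simulate' + (f"_seed{seed}" if seed is not None else ""))
    for name, seq in genome.contigs.items():
        header.contigs.add(name, length=len(seq))
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    header.add_line('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">')
    header.add_line('##INFO=<ID=SR,Number=1,Type=Integer,Description="Split reads supporting the junction">')
    header.add_line('##INFO=<ID=PE,Number=1,Type=Integer,Description="Discordant pairs supporting the junction">')
    header.add_line('##INFO=<ID=RR,Number=1,Type=Integer,Description="Reference-spanning reads">')
    header.add_line('##INFO=<ID=CALLER,Number=1,Type=String,Description="Calling tool">')

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for spec, support, ref_reads in specs:
            a, b = spec.end_a, spec.end_b
            common = dict(SR=support, PE=0, RR=ref_reads, CALLER="svmrd-sim")
            if (
                spec.sv_class == "deletion"
                and not spec.insert_seq
                and a.contig == b.contig
            ):
                rec = vcf.new_record(
                    contig=a.contig,
                    start=a.pos - 1,  # POS anchor = last retained base
                    stop=b.pos - 1,  # END = last deleted base (1-based)
                    alleles=(genome[a.contig][a.pos - 1], "<DEL>"),
                    id=spec.id,
                )
                rec.info["SVTYPE"] = "DEL"
                for k, v in common.items():
                    rec.info[k] = v
                vcf.write(rec)
            else:
                ref_a = genome[a.contig][a.pos - 1]
                ref_b = genome[b.contig][b.pos - 1]
                if a.strand == "+" and b.strand == "+":
                    alt_a = f"{ref_a}{spec.insert_seq}[{b.contig}:{b.pos}["
                    alt_b = f"]{a.contig}:{a.pos}]{spec.insert_seq}{ref_b}"
                elif b.strand == "-":  # end_b is upstream/-
                    alt_a = f"{ref_a}{spec.insert_seq}]{b.contig}:{b.pos}]"
                    alt_b = f"{ref_b}{revcomp(spec.insert_seq)}]{a.contig}:{a.pos}]"
                else:  # end_a is downstream/-
                    alt_a = f"[{b.contig}:{b.pos}[{revcomp(spec.insert_seq)}{ref_a}"
                    alt_b = f"[{a.contig}:{a.pos}[{spec.insert_seq}{ref_b}"
                for rec_id, mate_id, contig, pos, ref, alt in (
                    (f"{spec.id}_1", f"{spec.id}_2", a.contig, a.pos, ref_a, alt_a),
                    (f"{spec.id}_2", f"{spec.id}_1", b.contig, b.pos, ref_b, alt_b),
                ):
                    rec = vcf.new_record(
                        contig=contig,
                        start=pos - 1,
                        alleles=(ref, alt),
                        id=rec_id,
                    )
                    rec.stop = pos  # BND records span a single base
                    rec.info["SVTYPE"] = "BND"
                    rec.info["MATEID"] = mate_id
                    for k, v in common.items():
                        rec.info[k] = v
                    vcf.write(rec)


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

COUNTS_COLUMNS = ["sample_id", "well_id", "n_total", "n_target_pos", "n_ref_pos"]
META_COLUMNS = [
    "sample_id",
    "patient_id",
    "compartment",
    "n_targets",
    "volume_ml",
    "mass_ng",
    "dilution",
    "timepoint_day",
]
SERIES_COLUMNS = [
    "assay_id",
    "dilution",
    "well_id",
    "n_total",
    "n_target_pos",
    "n_ref_pos",
]


def write_counts_csv(
    rows: dict[str, list[WellCounts]], path, seed: int | None = None
) -> None:
    with open(path, "w", newline="") as fh:
        if seed is not None:
            fh.write(f"# svmrd simulated counts, seed={seed}\n")
        w = csv.writer(fh)
        w.writerow(COUNTS_COLUMNS)
        for sample_id in sorted(rows):
            for well in rows[sample_id]:
                w.writerow(
                    [sample_id, well.well_id, well.n_total, well.n_target_pos, well.n_ref_pos]
                )


def read_counts_csv(path) -> dict[str, list[WellCounts]]:
    df = pd.read_csv(str(path), comment="#")
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts CSV missing columns: {sorted(missing)}")
    out: dict[str, list[WellCounts]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.sample_id), []).append(
            WellCounts(
                well_id=str(r.well_id),
                n_total=int(r.n_total),
                n_target_pos=int(r.n_target_pos),
                n_ref_pos=int(r.n_ref_pos),
            )
        )
    return out


def write_metadata_csv(rows: list[dict], path, seed: int | None = None) -> None:
    with open(path, "w", newline="") as fh:
        if seed is not None:
            fh.write(f"# svmrd simulated metadata, seed={seed}\n")
        w = csv.DictWriter(fh, fieldnames=META_COLUMNS)
        w.writeheader()
        for row in rows:
            w.writerow({k: row.get(k, "") for k in META_COLUMNS})


def read_metadata_csv(path) -> tuple[dict[str, SampleSpec], dict[str, dict]]:
    """Returns (sample_id -> SampleSpec, sample_id -> extra fields
    {patient_id, timepoint_day})."""
    df = pd.read_csv(str(path), comment="#")
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    specs: dict[str, SampleSpec] = {}
    extra: dict[str, dict] = {}
    for r in df.itertuples():
        sid = str(r.sample_id)
        specs[sid] = SampleSpec(
            sample_id=sid,
            compartment=str(r.compartment),
            n_targets_multiplexed=int(r.n_targets),
            liquid_volume_ml=None if pd.isna(r.volume_ml) else float(r.volume_ml),
            dna_mass_ng=None if pd.isna(r.mass_ng) else float(r.mass_ng),
            dilution=1.0 if pd.isna(r.dilution) else float(r.dilution),
        )
        extra[sid] = {
            "patient_id": str(r.patient_id),
            "timepoint_day": int(r.timepoint_day),
            "compartment": str(r.compartment),
        }
    return specs, extra


def write_series_csv(
    series: dict[str, list[tuple[float, list[WellCounts]]]],
    path,
    seed: int | None = None,
) -> None:
    """``series`` maps assay_id -> [(dilution, replicate wells), ...]."""
    with open(path, "w", newline="") as fh:
        if seed is not None:
            fh.write(f"# svmrd simulated dilution series, seed={seed}\n")
        w = csv.writer(fh)
        w.writerow(SERIES_COLUMNS)
        for assay_id in sorted(series):
            for dilution, wells in series[assay_id]:
                for well in wells:
                    w.writerow(
                        [
                            assay_id,
                            f"{dilution:g}",
                            well.well_id,
                            well.n_total,
                            well.n_target_pos,
                            well.n_ref_pos,
                        ]
                    )


def read_series_csv(path) -> dict[str, list[tuple[float, list[WellCounts]]]]:
    df = pd.read_csv(str(path), comment="#")
    missing = set(SERIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"series CSV missing columns: {sorted(missing)}")
    out: dict[str, list[tuple[float, list[WellCounts]]]] = {}
    for (assay_id, dilution), group in df.groupby(["assay_id", "dilution"]):
        wells = [
            WellCounts(
                well_id=str(r.well_id),
                n_total=int(r.n_total),
                n_target_pos=int(r.n_target_pos),
                n_ref_pos=int(r.n_ref_pos),
            )
            for r in group.itertuples()
        ]
        out.setdefault(str(assay_id), []).append((float(dilution), wells))
    for assay_id in out:
        out[assay_id].sort(key=lambda t: -t[0])
    return out


# ---------------------------------------------------------------------------
# Result sheets
# ---------------------------------------------------------------------------


def write_assay_sheet(designs: list[AssayDesign], tsv_path, json_path=None) -> None:
    rows = []
    for d in designs:
        oligos = [
            ("forward", d.forward_primer),
            ("reverse", d.reverse_primer),
        ] + [(p.role, p) for p in d.probes]
        for role, o in oligos:
            rows.append(
                {
                    "junction_id": d.junction_id,
                    "role": role,
                    "sequence": o.seq,
                    "start": o.start,
                    "end": o.end,
                    "strand": o.strand,
                    "tm_c": f"{o.tm:.2f}",
                    "amplicon_len": d.amplicon_len,
                }
            )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(rows, fh, indent=1, sort_keys=True)
            fh.write("\n")


def write_quant_results(
    results: list[QuantResult], tsv_path, json_path=None
) -> None:
    rows = [
        {
            "sample_id": q.sample_id,
            "target_copies": f"{q.target_copies:.3f}",
            "ref_copies": f"{q.ref_copies:.3f}",
            "positivity": q.positivity,
            "ratio_percent": "" if q.ratio_percent is None else f"{q.ratio_percent:.6g}",
            "trace": int(q.trace_flag),
            "target_cn_per_ml": ""
            if q.target_cn_per_ml is None
            else f"{q.target_cn_per_ml:.4g}",
            "ref_cn_per_ml": ""
            if q.ref_cn_per_ml is None
            else f"{q.ref_cn_per_ml:.4g}",
        }
        for q in sorted(results, key=lambda q: q.sample_id)
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(rows, fh, indent=1, sort_keys=True)
            fh.write("\n")


def write_sensitivity_tsv(
    results: dict[str, SensitivityResult], path
) -> None:
    rows = []
    for assay_id in sorted(results):
        r = results[assay_id]
        rows.append(
            {
                "assay_id": assay_id,
                "lod": format_dilution(r.lod_dilution),
                "loq": format_dilution(r.loq_dilution),
                "slope": "" if r.fit is None else f"{r.fit.slope:.4f}",
                "intercept": "" if r.fit is None else f"{r.fit.intercept:.4f}",
                "r_squared": "" if r.fit is None else f"{r.fit.r_squared:.5f}",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
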