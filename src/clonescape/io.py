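"""Readers and writers for the cohort file formats.

The canonical mutation format is a headered TSV (one row per variant per
sample); VCF 4.x is accepted as an input dialect and mapped onto it, with
multiallelic sites decomposed into one record per ALT allele. Segment,
expression, TCR and cohort tables are headered TSVs. All writers round-trip
through the corresponding reader.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

import pandas as pd
import pysam

from .types import (
    CNSegment,
    ExpressionMatrix,
    FormatError,
    MutationRecord,
    PatientMeta,
    SampleMeta,
    ValidationError,
    mutations_to_frame,
    segments_to_frame,
    validate_tcr_table,
)

MUTATION_REQUIRED = [
    "chrom", "pos", "ref", "alt", "sample_id",
    "ref_count", "alt_count", "normal_ref_count", "normal_alt_count",
]
MUTATION_OPTIONAL = {
    "gene": "", "effect": "other", "is_driver": 0,
    "is_neoantigenic": 0, "filter_flag": "PASS",
}

SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "cn_total", "cn_major", "cn_minor"]


def normalise_chrom(chrom: str, style: str = "keep") -> str:
    """Normalise chromosome naming: ``keep``, ``strip`` ("chr1"→"1") or
    ``add`` ("1"→"chr1"). One style is applied consistently per run."""
    if style == "keep":
        return chrom
    if style == "strip":
        return chrom[3:] if chrom.lower().startswith("chr") else chrom
    if style == "add":
        return chrom if chrom.lower().startswith("chr") else f"chr{chrom}"
    raise ValueError(f"unknown chromosome style {style!r}")


def _records_from_frame(df: pd.DataFrame, chrom_style: str) -> list[MutationRecord]:
    records = []
    for row in df.itertuples(index=False):
        gene = getattr(row, "gene", "")
        if isinstance(gene, float) and pd.isna(gene):
            gene = ""
        records.append(
            MutationRecord(
                chrom=normalise_chrom(str(row.chrom), chrom_style),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                sample_id=str(row.sample_id),
                ref_count=int(row.ref_count),
                alt_count=int(row.alt_count),
                normal_ref_count=int(row.normal_ref_count),
                normal_alt_count=int(row.normal_alt_count),
                gene=str(gene) or None,
                effect=str(getattr(row, "effect", "other")),
                is_driver=bool(int(getattr(row, "is_driver", 0))),
                is_neoantigenic=bool(int(getattr(row, "is_neoantigenic", 0))),
                filter_flag=str(getattr(row, "filter_flag", "PASS")),
            )
        )
    return records


def read_mutations(path: str, format: str = "tsv", chrom_style: str = "keep",
                   sample_id: Optional[str] = None) -> list[MutationRecord]:
    """Read somatic mutations from a headered TSV or a VCF.

    For VCF input, ``sample_id`` names the tumour sample column; the matched
    normal is taken from a ``NORMAL`` column when present, else counts of 0/0
    are assumed. Multiallelic rows are decomposed per ALT allele.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = [c for c in MUTATION_REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(
                f"mutation TSV {path} missing required column(s): {missing}"
            )
        for col, default in MUTATION_OPTIONAL.items():
            if col not in df.columns:
                df[col] = default
        return _records_from_frame(df, chrom_style)
    if format == "vcf":
        return _read_vcf(path, chrom_style, sample_id)
    raise ValueError(f"unknown mutation format {format!r}")


def _read_vcf(path: str, chrom_style: str, sample_id: Optional[str]) -> list[MutationRecord]:
    records = []
    with pysam.VariantFile(path) as vf:
        vcf_samples = list(vf.header.samples)
        tumour = sample_id or (vcf_samples[0] if vcf_samples else None)
        if tumour is None:
            raise FormatError(f"VCF {path} has no sample columns")
        normal = "NORMAL" if "NORMAL" in vcf_samples and tumour != "NORMAL" else None
        for rec in vf:
            for i, alt in enumerate(rec.alts or ()):
                t_ref, t_alt = _allele_depths(rec, tumour, i)
                if normal is not None:
                    n_ref, n_alt = _allele_depths(rec, normal, i)
                else:
                    n_ref, n_alt = 0, 0
                try:
                    gene = rec.info.get("GENE", None)
                except (KeyError, ValueError):
                    gene = None
                if isinstance(gene, tuple):
                    gene = gene[0]
                try:
                    effect = rec.info.get("EFFECT", "other")
                except (KeyError, ValueError):
                    effect = "other"
                if isinstance(effect, tuple):
                    effect = effect[0]
                records.append(
                    MutationRecord(
                        chrom=normalise_chrom(rec.chrom, chrom_style),
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        sample_id=tumour,
                        ref_count=t_ref,
                        alt_count=t_alt,
                        normal_ref_count=n_ref,
                        normal_alt_count=n_alt,
                        gene=str(gene) if gene else None,
                        effect=str(effect),
                        filter_flag=";".join(rec.filter.keys()) or "PASS",
                    )
                )
    return records


def _allele_depths(rec, sample: str, alt_index: int) -> tuple[int, int]:
    fmt = rec.samples[sample]
    ad = fmt.get("AD")
    if ad is None:
        raise FormatError(
            f"VCF record {rec.chrom}:{rec.pos} lacks the AD format field "
            f"for sample {sample}"
        )
    ref_count = int(ad[0]) if ad[0] is not None else 0
    alt_count = int(ad[alt_index + 1]) if ad[alt_index + 1] is not None else 0
    return ref_count, alt_count


def write_mutations(records: list[MutationRecord], path: str) -> None:
    mutations_to_frame(records).to_csv(path, sep="\t", index=False)


def filter_candidate_mutations(records: list[MutationRecord],
                               min_tumour_depth: int = 5,
                               min_normal_depth: int = 5,
                               min_alt: int = 3,
                               max_normal_alt: int = 0) -> list[MutationRecord]:
    """Apply the candidate-mutation filter.

    Keeps records that are caller-PASS, have coverage of at least 5 reads in
    both tumour and matched normal, at least 3 variant reads in the tumour,
    and zero variant reads in the normal. Order-preserving and idempotent.
    """
    kept = []
    for r in records:
        if r.filter_flag != "PASS":
            continue
        if r.ref_count + r.alt_count < min_tumour_depth:
            continue
        if r.normal_ref_count + r.normal_alt_count < min_normal_depth:
            continue
        if r.alt_count < min_alt:
            continue
        if r.normal_alt_count > max_normal_alt:
            continue
        kept.append(r)
    return kept


def read_segments(path: str, chrom_style: str = "keep") -> list[CNSegment]:
    """Read allele-specific copy-number segments from a headered TSV.

    Column aliases follow Sequenza output: ``chromosome/start.pos/end.pos/
    CNt/A/B`` are accepted alongside the canonical names.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "chromosome": str})
    aliases = {
        "chromosome": "chrom", "start.pos": "start", "end.pos": "end",
        "CNt": "cn_total", "A": "cn_major", "B": "cn_minor",
    }
    df = df.rename(columns=aliases)
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"segment TSV {path} missing required column(s): {missing}")
    segments = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            segments.append(
                CNSegment(
                    sample_id=str(row.sample_id),
                    chrom=normalise_chrom(str(row.chrom), chrom_style),
                    start=int(row.start),
                    end=int(row.end),
                    cn_total=int(row.cn_total),
                    cn_major=int(row.cn_major),
                    cn_minor=int(row.cn_minor),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"segment row {i + 1}: {exc}") from exc
    return segments


def write_segments(segments: list[CNSegment], path: str) -> None:
    segments_to_frame(segments).to_csv(path, sep="\t", index=False)


def read_expression(path: str) -> ExpressionMatrix:
    """Read a gene-by-sample expression TSV (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    unit = "CPM"
    if df.index.name and df.index.name.upper() in ("CPM", "TPM"):
        unit = df.index.name.upper()
    df.index.name = "gene"
    return ExpressionMatrix(values=df.astype(float), unit=unit)


def write_expression(expr: ExpressionMatrix, path: str) -> None:
    out = expr.values.copy()
    out.index.name = expr.unit
    out.to_csv(path, sep="\t")


def read_tcr(path: str) -> pd.DataFrame:
    """Read a TCR clone-count table (sample_id, chain, clone_id, count)."""
    df = pd.read_csv(path, sep="\t", dtype={"clone_id": str})
    return validate_tcr_table(df)


def write_tcr(df: pd.DataFrame, path: str) -> None:
    validate_tcr_table(df).to_csv(path, sep="\t", index=False)


def read_cohort(path: str) -> tuple[list[PatientMeta], list[SampleMeta]]:
    """Read cohort metadata: one row per sample with patient-level fields
    (response_group, becker_grade) repeated per sample."""
    df = pd.read_csv(path, sep="\t")
    required = ["patient_id", "sample_id", "response_group", "timepoint",
                "region_id", "purity", "ploidy"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"cohort TSV {path} missing required column(s): {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id(s) in cohort table: {dupes}")
    patients: dict[str, PatientMeta] = {}
    samples: list[SampleMeta] = []
    for row in df.itertuples(index=False):
        pid = str(row.patient_id)
        grade = getattr(row, "becker_grade", None)
        if grade is None or (isinstance(grade, float) and pd.isna(grade)) or grade == "":
            grade = None
        else:
            grade = int(grade)
        meta = PatientMeta(patient_id=pid, response_group=str(row.response_group),
                           becker_grade=grade)
        if pid in patients:
            if patients[pid] != meta:
                raise ValidationError(
                    f"inconsistent patient-level metadata for {pid}"
                )
        else:
            patients[pid] = meta
        samples.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                patient_id=pid,
                timepoint=str(row.timepoint),
                region_id=str(row.region_id),
                purity=float(row.purity),
                ploidy=float(row.ploidy),
            )
        )
    return list(patients.values()), samples


def write_cohort(patients: list[PatientMeta], samples: list[SampleMeta], path: str) -> None:
    pmap = {p.patient_id: p for p in patients}
    rows = []
    for s in samples:
        p = pmap[s.patient_id]
        rows.append({
            "patient_id": s.patient_id,
            "sample_id": s.sample_id,
            "response_group": p.response_group,
            "timepoint": s.timepoint,
            "region_id": s.region_id,
            "purity": s.purity,
            "ploidy": s.ploidy,
            "becker_grade": "" if p.becker_grade is None else p.becker_grade,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def check_sample_ids(data_sample_ids: Iterable[str], samples: list[SampleMeta]) -> None:
    """Fail when a data file references a sample absent from the cohort table."""
    known = {s.sample_id for s in samples}
    unknown = sorted(set(data_sample_ids) - known)
    if unknown:
        raise ValidationError(f"unknown sample_id(s) not in cohort table: {unknown}")
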