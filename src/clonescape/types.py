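"""Domain types shared across the pipeline.

All genomic coordinates are 1-based and inclusive throughout the package;
no operation silently converts between coordinate conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

RESPONSE_GROUPS = ("RE", "NR")
TIMEPOINTS = ("A", "B", "C")
EFFECTS = ("synonymous", "nonsynonymous", "frameshift", "stopgain", "stoploss", "other")

#: substitution classes after pyrimidine-strand collapsing
SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


class ValidationError(ValueError):
    """Raised when an input table violates a domain invariant."""


class FormatError(ValueError):
    """Raised when an input file does not parse in the declared dialect."""


@dataclass(frozen=True)
class PatientMeta:
    """Per-patient clinical metadata.

    ``response_group`` is RE (responder) or NR (non-responder) by PET
    SUVmax criteria after one chemotherapy cycle; ``becker_grade`` is the
    histopathological tumour-regression grade (1 best to 3 worst), missing
    when no resection specimen was graded.
    """

    patient_id: str
    response_group: str
    becker_grade: Optional[int] = None

    def __post_init__(self) -> None:
        if self.response_group not in RESPONSE_GROUPS:
            raise ValidationError(
                f"response_group must be one of {RESPONSE_GROUPS}, "
                f"got {self.response_group!r} for patient {self.patient_id}"
            )
        if self.becker_grade is not None and self.becker_grade not in (1, 2, 3):
            raise ValidationError(
                f"becker_grade must be 1, 2 or 3; got {self.becker_grade!r}"
            )


@dataclass(frozen=True)
class SampleMeta:
    """One tumour sample: patient, timepoint (A pre-treatment, B
    post-first-cycle, C resection), multi-region id, and the Sequenza-style
    purity (rho) and ploidy (psi) estimates."""

    sample_id: str
    patient_id: str
    timepoint: str
    region_id: str = "R1"
    purity: float = 1.0
    ploidy: float = 2.0

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r} "
                f"for sample {self.sample_id}"
            )
        if not (0.0 < self.purity <= 1.0):
            raise ValidationError(
                f"purity must be in (0, 1], got {self.purity} for {self.sample_id}"
            )
        if not (1.0 <= self.ploidy <= 5.0):
            raise ValidationError(
                f"ploidy must be in [1, 5], got {self.ploidy} for {self.sample_id}"
            )


@dataclass(frozen=True)
class MutationRecord:
    """One somatic SNV/indel observed in one sample, with tumour and
    matched-normal read counts and functional annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    ref_count: int
    alt_count: int
    normal_ref_count: int = 0
    normal_alt_count: int = 0
    gene: Optional[str] = None
    effect: str = "other"
    is_driver: bool = False
    is_neoantigenic: bool = False
    filter_flag: str = "PASS"

    def __post_init__(self) -> None:
        for name in ("ref_count", "alt_count", "normal_ref_count", "normal_alt_count"):
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"{name} must be non-negative, got {getattr(self, name)} "
                    f"at {self.chrom}:{self.pos} in {self.sample_id}"
                )
        if self.pos < 1:
            raise ValidationError(f"pos must be 1-based positive, got {self.pos}")
        if self.effect not in EFFECTS:
            raise ValidationError(
                f"effect must be one of {EFFECTS}, got {self.effect!r}"
            )

    @property
    def key(self) -> str:
        """Variant identity independent of the sample it was seen in."""
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)

    @property
    def vaf(self) -> float:
        depth = self.ref_count + self.alt_count
        return self.alt_count / depth if depth else 0.0


@dataclass(frozen=True)
class CNSegment:
    """Allele-specific copy-number interval (Sequenza-style): total copy
    number CNt with major (A) and minor (B) allele counts."""

    sample_id: str
    chrom: str
    start: int
    end: int
    cn_total: int
    cn_major: int
    cn_minor: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"segment start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.cn_major + self.cn_minor != self.cn_total:
            raise ValidationError(
                f"cn_major + cn_minor must equal cn_total; got "
                f"{self.cn_major}+{self.cn_minor} != {self.cn_total} "
                f"({self.sample_id} {self.chrom}:{self.start}-{self.end})"
            )
        if not (self.cn_major >= self.cn_minor >= 0):
            raise ValidationError(
                f"need cn_major >= cn_minor >= 0, got "
                f"{self.cn_major}/{self.cn_minor}"
            )

    @property
    def length(self) -> int:
        """Interval length in bp (1-based inclusive)."""
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression matrix in CPM or TPM units."""

    values: pd.DataFrame  # genes x samples
    unit: str = "CPM"

    def __post_init__(self) -> None:
        if self.unit not in ("CPM", "TPM"):
            raise ValidationError(f"unit must be CPM or TPM, got {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene symbols in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


TCR_COLUMNS = ["sample_id", "chain", "clone_id", "count"]


def validate_tcr_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a TCR clone-count table (one row per sample/chain/clone)."""
    missing = [c for c in TCR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"TCR table missing required column(s): {missing}")
    bad_chain = set(df["chain"]) - {"alpha", "beta"}
    if bad_chain:
        raise ValidationError(f"TCR chain must be alpha/beta, got {sorted(bad_chain)}")
    if (df["count"] < 1).any():
        raise ValidationError("TCR clone counts must be >= 1")
    if df.duplicated(subset=["sample_id", "chain", "clone_id"]).any():
        raise ValidationError("duplicate (sample_id, chain, clone_id) rows in TCR table")
    return df.reset_index(drop=True)


def segments_non_overlapping(segments: list[CNSegment]) -> bool:
    """Check the per-sample non-overlap invariant for a segment list."""
    by_key: dict[tuple[str, str], list[CNSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    for segs in by_key.values():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                return False
    return True


def mutations_to_frame(records: list[MutationRecord]) -> pd.DataFrame:
    """Tabular view of a mutation list (canonical TSV column order)."""
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "sample_id": r.sample_id,
                "ref_count": r.ref_count,
                "alt_count": r.alt_count,
                "normal_ref_count": r.normal_ref_count,
                "normal_alt_count": r.normal_alt_count,
                "gene": r.gene if r.gene is not None else "",
                "effect": r.effect,
                "is_driver": int(r.is_driver),
                "is_neoantigenic": int(r.is_neoantigenic),
                "filter_flag": r.filter_flag,
            }
            for r in records
        ],
        columns=[
            "chrom", "pos", "ref", "alt", "sample_id",
            "ref_count", "alt_count", "normal_ref_count", "normal_alt_count",
            "gene", "effect", "is_driver", "is_neoantigenic", "filter_flag",
        ],
    )


def segments_to_frame(segments: list[CNSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "cn_total": s.cn_total,
                "cn_major": s.cn_major,
                "cn_minor": s.cn_minor,
            }
            for s in segments
        ],
        columns=["sample_id", "chrom", "start", "end", "cn_total", "cn_major", "cn_minor"],
    )
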