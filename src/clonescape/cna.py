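"""Copy-number categories, altered-exome fractions, CNA clonality classes,
inter-timepoint turnover and fragment-size statistics.

Allele-specific states (CNt, minor) are mapped onto six categories —
loss, cnLOH, high LOH, diploid, gain, amplification — with configurable
boundaries. Cross-sample comparisons first harmonise segments of one
patient to the union of breakpoints, so every derived quantity is
length-weighted over identical intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import CNSegment

CN_CATEGORIES = ("loss", "cnLOH", "highLOH", "diploid", "gain", "amplification")
CNA_CLONALITY_CLASSES = ("clonal", "subclonal", "private", "subclonal_or_private")


@dataclass(frozen=True)
class CNThresholds:
    """Category boundaries for classify_segment.

    Defaults: loss CNt<=1; cnLOH = 2 copies with minor 0; high LOH = >=3
    copies with minor 0; diploid = heterozygous 2 copies; amplification
    CNt>=5; gain otherwise.
    """

    loss_max_total: int = 1
    amplification_min_total: int = 5


def classify_segment(cn_total: int, cn_minor: int,
                     thresholds: CNThresholds = CNThresholds()) -> str:
    """Map an allele-specific copy-number state to its category."""
    if cn_total < 0 or cn_minor < 0 or cn_minor > cn_total:
        raise ValueError(f"invalid CN state ({cn_total}, {cn_minor})")
    if cn_total <= thresholds.loss_max_total:
        return "loss"
    if cn_total == 2 and cn_minor == 0:
        return "cnLOH"
    if cn_total >= thresholds.amplification_min_total:
        return "amplification"
    if cn_minor == 0:
        return "highLOH"
    if cn_total == 2 and cn_minor == 1:
        return "diploid"
    return "gain"


#: coarsening used for figure-style summaries (amplification / LOH / loss)
COARSE_MAP = {
    "loss": "loss",
    "cnLOH": "LOH",
    "highLOH": "LOH",
    "diploid": "diploid",
    "gain": "gain",
    "amplification": "amplification",
}


def altered_fraction(segments: Sequence[CNSegment], mode: str = "absolute",
                     ploidy: Optional[float] = None,
                     thresholds: CNThresholds = CNThresholds()) -> float:
    """Length-weighted fraction of covered genome that is not diploid.

    ``mode="absolute"`` counts everything not classified diploid (2,1);
    ``mode="ploidy_relative"`` counts CNt != round(ploidy) instead.
    """
    total = sum(s.length for s in segments)
    if total == 0:
        raise ValueError("zero covered length: no segments provided")
    if mode == "absolute":
        altered = sum(
            s.length for s in segments
            if classify_segment(s.cn_total, s.cn_minor, thresholds) != "diploid"
        )
    elif mode == "ploidy_relative":
        if ploidy is None:
            raise ValueError("ploidy_relative mode requires a ploidy value")
        baseline = int(round(ploidy))
        altered = sum(s.length for s in segments if s.cn_total != baseline)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return altered / total


# ---------------------------------------------------------------------------
# breakpoint harmonisation


def harmonise_breakpoints(segment_lists: Sequence[Sequence[CNSegment]]) -> pd.DataFrame:
    """Split each sample's segments at the union of all breakpoints.

    Returns one row per (chrom, start, end) interval covered by every input
    list, with per-sample (cn_total, cn_minor) columns. Total covered
    length is conserved on the shared support.
    """
    if not segment_lists:
        raise ValueError("no segment lists to harmonise")
    chroms = sorted({s.chrom for segs in segment_lists for s in segs})
    rows = []
    for chrom in chroms:
        cuts: set[int] = set()
        for segs in segment_lists:
            for s in segs:
                if s.chrom == chrom:
                    cuts.add(s.start)
                    cuts.add(s.end + 1)
        edges = sorted(cuts)
        for lo, hi in zip(edges, edges[1:]):
            states = []
            for segs in segment_lists:
                state = None
                for s in segs:
                    if s.chrom == chrom and s.start <= lo and hi - 1 <= s.end:
                        state = (s.cn_total, s.cn_minor)
                        break
                states.append(state)
            if all(st is not None for st in states):
                row = {"chrom": chrom, "start": lo, "end": hi - 1, "length": hi - lo}
                for i, st in enumerate(states):
                    row[f"cn_total_{i}"] = st[0]
                    row[f"cn_minor_{i}"] = st[1]
                rows.append(row)
    return pd.DataFrame(rows)


def cna_clonality(segments_by_sample: dict[str, Sequence[CNSegment]],
                  thresholds: CNThresholds = CNThresholds()) -> pd.DataFrame:
    """Classify each harmonised non-diploid segment as clonal / subclonal /
    private across the samples of one patient.

    A non-diploid category is clonal when the identical category holds in
    all samples, subclonal when present in more than 1/3 of samples but not
    all, and private when present in at most 1/3. Two-sample patients
    cannot distinguish subclonal from private and use the combined class.
    """
    sample_ids = sorted(segments_by_sample)
    if len(sample_ids) < 2:
        raise ValueError("CNA clonality needs >= 2 samples")
    grid = harmonise_breakpoints([segments_by_sample[s] for s in sample_ids])
    n = len(sample_ids)
    two_sample = n == 2
    rows = []
    for row in grid.itertuples(index=False):
        cats = [
            classify_segment(getattr(row, f"cn_total_{i}"), getattr(row, f"cn_minor_{i}"),
                             thresholds)
            for i in range(n)
        ]
        for cat in sorted(set(cats)):
            if cat == "diploid":
                continue
            count = cats.count(cat)
            if count == n:
                cls = "clonal"
            elif two_sample:
                cls = "subclonal_or_private"
            elif count > n / 3:
                cls = "subclonal"
            else:
                cls = "private"
            rows.append({
                "chrom": row.chrom, "start": row.start, "end": row.end,
                "length": row.length, "category": cat,
                "n_samples_with_category": count, "n_samples": n,
                "clonality": cls,
            })
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "length", "category",
        "n_samples_with_category", "n_samples", "clonality",
    ])


def turnover_fraction(segments_a: Sequence[CNSegment], segments_b: Sequence[CNSegment],
                      mode: str = "allele_specific") -> float:
    """Length-weighted fraction of the shared covered exome whose copy-number
    state differs between two samples (e.g. timepoints A and B).

    ``allele_specific`` compares (CNt, minor) pairs; ``total`` compares CNt
    only. Symmetric in its arguments; exactly 0 on identical profiles.
    """
    if mode not in ("allele_specific", "total"):
        raise ValueError(f"unknown mode {mode!r}")
    grid = harmonise_breakpoints([segments_a, segments_b])
    if grid.empty:
        raise ValueError("no shared covered exome between the two profiles")
    if mode == "allele_specific":
        changed = (grid["cn_total_0"] != grid["cn_total_1"]) | (
            grid["cn_minor_0"] != grid["cn_minor_1"])
    else:
        changed = grid["cn_total_0"] != grid["cn_total_1"]
    return float(grid.loc[changed, "length"].sum() / grid["length"].sum())


def fragment_size_stats(clonality_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-clonality-class CNA fragment-length summaries and pairwise
    two-sided rank-sum tests.

    Input is the cna_clonality output. Classes with fewer than 2 segments
    are summarised but excluded from testing.
    """
    summaries = []
    lengths_by_class: dict[str, np.ndarray] = {}
    for cls, sub in clonality_table.groupby("clonality"):
        lengths = sub["length"].to_numpy(dtype=float)
        lengths_by_class[cls] = lengths
        summaries.append({
            "clonality": cls,
            "n_segments": len(lengths),
            "median_length": float(np.median(lengths)),
            "q25_length": float(np.quantile(lengths, 0.25)),
            "q75_length": float(np.quantile(lengths, 0.75)),
        })
    tests = []
    testable = sorted(c for c, v in lengths_by_class.items() if len(v) >= 2)
    for i, a in enumerate(testable):
        for b in testable[i + 1:]:
            xa, xb = lengths_by_class[a], lengths_by_class[b]
            if np.unique(np.concatenate([xa, xb])).size == 1:
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.ranksums(xa, xb)
            tests.append({"class_a": a, "class_b": b,
                          "statistic": float(stat), "p_value": float(p)})
    return (
        pd.DataFrame(summaries, columns=["clonality", "n_segments", "median_length",
                                         "q25_length", "q75_length"]),
        pd.DataFrame(tests, columns=["class_a", "class_b", "statistic", "p_value"]),
    )


def category_fractions(segments: Sequence[CNSegment],
                       thresholds: CNThresholds = CNThresholds()) -> pd.Series:
    """Length fraction of the covered genome in each CN category."""
    total = sum(s.length for s in segments)
    if total == 0:
        raise ValueError("zero covered length")
    frac = pd.Series(0.0, index=list(CN_CATEGORIES))
    for s in segments:
        frac[classify_segment(s.cn_total, s.cn_minor, thresholds)] += s.length / total
    return frac
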