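"""Neoantigen bookkeeping and the composite immune-escape caller.

Neoantigenic SNVs (neoSNVs) are consumed as precomputed flags. Their
distribution across copy-number categories is summarised by a per-sample
enrichment ratio: each neoSNV is weighted per-copy (2/CNt, i.e. relative
to a diploid locus), weights are renormalised to sum to 1 within the
sample, and the ratio for category c is the summed weight in c divided by
the genome length fraction of c. Under per-copy uniform placement every
category's ratio is 1 in expectation, which anchors the diploid category
at ~1.

Immune escape combines four mechanisms: somatic HLA mutation, B2M
mutation, HLA loss of heterozygosity (confirmed against allelic-imbalance
and copy-number thresholds), and PD-L1 overexpression relative to the
treatment-naive baseline. The first three constitute genetic escape; a
patient is escaped when at least one sample is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cna import CN_CATEGORIES, CNThresholds, category_fractions, classify_segment
from .types import CNSegment, ExpressionMatrix, MutationRecord

B2M_EFFECTS = {"nonsynonymous", "frameshift", "stopgain", "stoploss"}


def neoantigen_burden(ccf_frame: pd.DataFrame, neo_keys: set[str]) -> pd.DataFrame:
    """Per-sample neoSNV counts, neo/total ratio, and the clonality split.

    ``ccf_frame`` is the clonality output (columns mutation_key, sample_id,
    clonality); ``neo_keys`` is the set of neoantigenic mutation keys.
    """
    rows = []
    for sample_id, sub in ccf_frame.groupby("sample_id"):
        is_neo = sub["mutation_key"].isin(neo_keys)
        n_total = len(sub)
        n_neo = int(is_neo.sum())
        n_neo_clonal = int((is_neo & (sub["clonality"] == "clonal")).sum())
        n_neo_subclonal = int((is_neo & (sub["clonality"] == "subclonal")).sum())
        rows.append({
            "sample_id": sample_id,
            "n_total": n_total,
            "n_neo": n_neo,
            "neo_ratio": n_neo / n_total if n_total else 0.0,
            "n_neo_clonal": n_neo_clonal,
            "n_neo_subclonal": n_neo_subclonal,
        })
    return pd.DataFrame(rows, columns=[
        "sample_id", "n_total", "n_neo", "neo_ratio", "n_neo_clonal", "n_neo_subclonal",
    ])


@dataclass
class CNEnrichment:
    """Per-category copy-number-normalised neoSNV enrichment for one sample."""

    sample_id: str
    ratios: pd.Series           # index = CN_CATEGORIES; NaN where undefined
    weight_fractions: pd.Series
    length_fractions: pd.Series


def cn_enrichment(sample_id: str, neo_mutations: Sequence[MutationRecord],
                  segments: Sequence[CNSegment],
                  thresholds: CNThresholds = CNThresholds(),
                  weighting: str = "per_copy") -> CNEnrichment:
    """Copy-number-normalised neoSNV enrichment per CN category.

    Each neoSNV is weighted 2/CNt (``weighting="per_copy"``) or 1
    (``weighting="count"``); CNt=0 sites are excluded. Weights are
    renormalised to sum to 1 over the sample, and ratio_c = (weight in c)
    / (length fraction of c). A category covering zero genome has an
    undefined (NaN) ratio.
    """
    if weighting not in ("per_copy", "count"):
        raise ValueError(f"unknown weighting {weighting!r}")
    length_frac = category_fractions(segments, thresholds)
    weights = pd.Series(0.0, index=list(CN_CATEGORIES))
    for rec in neo_mutations:
        seg = next((s for s in segments if s.contains(rec.chrom, rec.pos)), None)
        if seg is None or seg.cn_total == 0:
            continue
        cat = classify_segment(seg.cn_total, seg.cn_minor, thresholds)
        weights[cat] += 2.0 / seg.cn_total if weighting == "per_copy" else 1.0
    total = weights.sum()
    if total > 0:
        weights = weights / total
    ratios = pd.Series(np.nan, index=list(CN_CATEGORIES))
    nonzero = length_frac > 0
    ratios[nonzero] = weights[nonzero] / length_frac[nonzero]
    return CNEnrichment(sample_id=sample_id, ratios=ratios,
                        weight_fractions=weights, length_fractions=length_frac)


def neoantigen_expression(expr: ExpressionMatrix,
                          neo_genes_by_sample: dict[str, set[str]]) -> pd.Series:
    """Mean expression (CPM) per sample over that sample's neoantigen-bearing
    genes; missing value (NaN) when the sample has no such gene in the
    matrix. Genes absent from the matrix are skipped."""
    out = {}
    for sample_id, genes in neo_genes_by_sample.items():
        if sample_id not in expr.values.columns:
            continue
        present = [g for g in sorted(genes) if g in expr.values.index]
        out[sample_id] = (
            float(expr.values.loc[present, sample_id].mean()) if present else np.nan
        )
    return pd.Series(out, dtype=float).sort_index()


def median_split(scores: pd.Series) -> pd.Series:
    """Split samples at the median score: strictly above -> "high",
    at or below -> "low"."""
    med = scores.median()
    return pd.Series(np.where(scores > med, "high", "low"), index=scores.index)


# ---------------------------------------------------------------------------
# escape mechanisms


@dataclass(frozen=True)
class HLALohCall:
    """Inputs and verdict for HLA loss-of-heterozygosity at one allele."""

    sample_id: str
    allele: str
    candidate: bool              # minor allele CN 0 at the HLA locus
    ai_p_value: float            # allelic-imbalance test
    lost_cn: float
    lost_cn_ci_upper: float
    kept_cn: float
    mismatched_sites: int
    confirmed: bool = False


def call_hla_loh(calls: Sequence[HLALohCall], ai_alpha: float = 0.01,
                 lost_cn_max: float = 0.5, ci_upper_max: float = 0.7,
                 kept_cn_min: float = 0.75, min_mismatches: int = 10) -> list[HLALohCall]:
    """Confirm candidate HLA-LOH calls.

    Confirmed iff the allele is a candidate (minor CN 0), the allelic-
    imbalance p-value is below 0.01, the lost-allele copy number is below
    0.5 with its confidence interval strictly below 0.7, the kept-allele
    copy number is above 0.75, and more than 10 mismatched sites
    distinguish the alleles. All inequalities are strict.
    """
    out = []
    for c in calls:
        confirmed = (
            c.candidate
            and c.ai_p_value < ai_alpha
            and c.lost_cn < lost_cn_max
            and c.lost_cn_ci_upper < ci_upper_max
            and c.kept_cn > kept_cn_min
            and c.mismatched_sites > min_mismatches
        )
        out.append(HLALohCall(
            sample_id=c.sample_id, allele=c.allele, candidate=c.candidate,
            ai_p_value=c.ai_p_value, lost_cn=c.lost_cn,
            lost_cn_ci_upper=c.lost_cn_ci_upper, kept_cn=c.kept_cn,
            mismatched_sites=c.mismatched_sites, confirmed=confirmed,
        ))
    return out


def call_pdl1_over(expr: ExpressionMatrix, naive_samples: Sequence[str],
                   sd_multiplier: float = 1.0, gene: str = "CD274") -> tuple[pd.Series, dict]:
    """Flag PD-L1 overexpression: expression >= treatment-naive baseline
    mean + ``sd_multiplier`` population standard deviations.

    The Methods-style threshold uses 1 SD (default); ``sd_multiplier=2``
    reproduces the stricter figure-legend variant.
    """
    naive = [s for s in naive_samples if s in expr.values.columns]
    if len(naive) < 2:
        raise ValueError(
            f"need >= 2 treatment-naive samples to set the PD-L1 baseline, got {len(naive)}"
        )
    if gene not in expr.values.index:
        raise ValueError(f"gene {gene!r} not in expression matrix")
    values = expr.values.loc[gene]
    baseline = float(values[naive].mean())
    sd = float(values[naive].std(ddof=0))
    threshold = baseline + sd_multiplier * sd
    flags = values >= threshold
    stats_out = {"baseline_mean": baseline, "baseline_sd": sd,
                 "threshold": threshold, "n_naive": len(naive)}
    return flags.astype(bool), stats_out


def call_b2m(mutations_by_sample: dict[str, Sequence[MutationRecord]]) -> pd.Series:
    """Per-sample flag: any exonic B2M mutation with a protein-altering
    effect (nonsynonymous, frameshift, stop-gain, stop-loss)."""
    out = {}
    for sample_id, recs in mutations_by_sample.items():
        out[sample_id] = any(
            r.gene == "B2M" and r.effect in B2M_EFFECTS for r in recs
        )
    return pd.Series(out, dtype=bool).sort_index()


def call_hla_mutation(mutations_by_sample: dict[str, Sequence[MutationRecord]],
                      hla_genes: Sequence[str] = ("HLA-A", "HLA-B", "HLA-C")) -> pd.Series:
    """Per-sample flag: any protein-altering somatic mutation in a class-I
    HLA gene."""
    genes = set(hla_genes)
    out = {}
    for sample_id, recs in mutations_by_sample.items():
        out[sample_id] = any(
            r.gene in genes and r.effect in B2M_EFFECTS for r in recs
        )
    return pd.Series(out, dtype=bool).sort_index()


# ---------------------------------------------------------------------------
# combination


def combine_escape(flags: pd.DataFrame, sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Combine per-sample mechanism flags into escape-status rows.

    ``flags`` has boolean columns hla_mutation, b2m_mutation, hla_loh,
    pdl1_over indexed by sample_id; ``sample_meta`` carries patient_id,
    timepoint, response_group (and optionally becker_grade) per sample_id.
    genetic_escape = hla_mutation | b2m_mutation | hla_loh;
    any_escape = genetic_escape | pdl1_over; a patient is escaped when any
    sample is; an escape is "early" when first observed at timepoint A and
    "late" when first at B or C.
    """
    required = ["hla_mutation", "b2m_mutation", "hla_loh", "pdl1_over"]
    missing = [c for c in required if c not in flags.columns]
    if missing:
        raise ValueError(f"flags table missing column(s): {missing}")
    merged = flags.join(sample_meta.set_index("sample_id")
                        if "sample_id" in sample_meta.columns else sample_meta)
    merged = merged.copy()
    merged["genetic_escape"] = (
        merged["hla_mutation"] | merged["b2m_mutation"] | merged["hla_loh"]
    )
    merged["any_escape"] = merged["genetic_escape"] | merged["pdl1_over"]
    patient_escape = merged.groupby("patient_id")["any_escape"].any()
    merged["patient_escape"] = merged["patient_id"].map(patient_escape)

    # escape timing per patient: early if first escaped sample is at A
    timing = {}
    for pid, sub in merged.groupby("patient_id"):
        escaped = sub[sub["any_escape"]]
        if escaped.empty:
            timing[pid] = "none"
        else:
            timing[pid] = "early" if (escaped["timepoint"] == "A").any() else "late"
    merged["escape_timing"] = merged["patient_id"].map(timing)
    merged.index.name = "sample_id"
    return merged.reset_index()


def escape_association_tests(status: pd.DataFrame, level: str = "patient") -> pd.DataFrame:
    """Chi-square tests of escape against response group and Becker grade.

    At ``level="patient"`` (default) each patient contributes once with its
    patient_escape flag; at ``level="sample"`` each sample contributes its
    any_escape flag. The chi-square is computed without continuity
    correction; when any expected cell count falls below 5 a Fisher exact
    test (2xk via freeman-halton not attempted; 2x2 only) replaces it and
    is named in the output. Degenerate tables are reported not-applicable.
    """
    if level == "patient":
        units = status.drop_duplicates("patient_id")
        escape_col = "patient_escape"
    elif level == "sample":
        units = status
        escape_col = "any_escape"
    else:
        raise ValueError(f"unknown level {level!r}")

    rows = []
    for grouping in ("response_group", "becker_grade"):
        if grouping not in units.columns:
            continue
        sub = units.dropna(subset=[grouping])
        table = pd.crosstab(sub[escape_col], sub[grouping])
        if table.shape[0] < 2 or table.shape[1] < 2:
            rows.append({"grouping": grouping, "test": "not_applicable",
                         "statistic": np.nan, "p_value": np.nan})
            continue
        chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
        test = "chi_square"
        if (expected < 5).any() and table.shape == (2, 2):
            _, p = stats.fisher_exact(table)
            chi2 = np.nan
            test = "fisher_exact"
        rows.append({"grouping": grouping, "test": test,
                     "statistic": float(chi2) if not np.isnan(chi2) else np.nan,
                     "p_value": float(p)})
    return pd.DataFrame(rows, columns=["grouping", "test", "statistic", "p_value"])
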