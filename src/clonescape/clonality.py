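"""Cancer cell fraction (CCF) normalisation and clonal/subclonal calling.

The VAF of a somatic mutation is corrected for tumour purity, local total
copy number and mutation multiplicity:

    ccf = vaf * (purity * CNt + (1 - purity) * 2) / (purity * m)

with the multiplicity m estimated by rounding the copy-number-scaled VAF
and clamping it into [1, cn_major]. Per sample, mutations are then split
into a clonal peak (CCF concentrated near 1) and a monotonically
decreasing subclonal tail by a two-component EM mixture (Beta-shaped peak,
truncated power-law tail), with a plain CCF-threshold fallback for sparse
or non-converging inputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .types import CNSegment, MutationRecord

log = logging.getLogger(__name__)

CCF_CAP = 1.5  # super-clonal CCFs above this are labelled clonal outright


@dataclass(frozen=True)
class CCFRecord:
    """A mutation's purity/CN-normalised cancer cell fraction in one sample."""

    mutation_key: str
    sample_id: str
    vaf: float
    multiplicity: int
    ccf: float
    cn_total: int
    cn_major: int
    clonality: str = "unclassified"  # clonal | subclonal | unclassified
    no_segment: bool = False


def compute_ccf(record: MutationRecord, seg: Optional[CNSegment], purity: float) -> CCFRecord:
    """Normalise one mutation's VAF to a CCF.

    ``seg`` is the covering copy-number segment; when ``None`` the site is
    assigned a diploid-heterozygous state (CNt=2, minor=1) and flagged.
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if seg is not None and not seg.contains(record.chrom, record.pos):
        raise ValueError(
            f"mutation {record.key} not inside segment "
            f"{seg.chrom}:{seg.start}-{seg.end}"
        )
    if seg is None:
        cn_total, cn_major, flagged = 2, 1, True
    else:
        cn_total, cn_major, flagged = seg.cn_total, seg.cn_major, False
    vaf = record.vaf
    scale = purity * cn_total + (1.0 - purity) * 2.0
    m = int(np.clip(round(vaf * scale / purity), 1, max(cn_major, 1)))
    ccf = vaf * scale / (purity * m)
    return CCFRecord(
        mutation_key=record.key,
        sample_id=record.sample_id,
        vaf=vaf,
        multiplicity=m,
        ccf=ccf,
        cn_total=cn_total,
        cn_major=cn_major,
        no_segment=flagged,
    )


def ccf_for_sample(records: Sequence[MutationRecord], segments: Sequence[CNSegment],
                   purity: float) -> list[CCFRecord]:
    """Map each mutation to its covering segment and compute CCFs."""
    by_chrom: dict[str, list[CNSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for segs in by_chrom.values():
        segs.sort(key=lambda s: s.start)
    out = []
    for rec in records:
        seg = None
        for cand in by_chrom.get(rec.chrom, ()):
            if cand.start <= rec.pos <= cand.end:
                seg = cand
                break
        out.append(compute_ccf(rec, seg, purity))
    return out


# ---------------------------------------------------------------------------
# peak + tail mixture


@dataclass
class ClonalityFit:
    """Summary of one sample's peak/tail mixture fit."""

    sample_id: str
    method: str              # "em" or "threshold"
    converged: bool
    n_iter: int
    weight_peak: float
    peak_mean: float
    tail_exponent: float
    loglik: float
    threshold: float = 0.75


def _beta_logpdf(y: np.ndarray, a: float, b: float) -> np.ndarray:
    return (a - 1) * np.log(y) + (b - 1) * np.log1p(-y) - special.betaln(a, b)


def _tail_logpdf(y: np.ndarray, alpha: float, lo: float, hi: float) -> np.ndarray:
    # truncated power law ~ y^-alpha on [lo, hi]
    if abs(alpha - 1.0) < 1e-9:
        log_z = np.log(np.log(hi / lo))
    else:
        log_z = np.log(abs(hi ** (1 - alpha) - lo ** (1 - alpha))) - np.log(abs(1 - alpha))
    return -alpha * np.log(y) - log_z


def _weighted_beta_mom(y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    wsum = w.sum()
    mu = float((w * y).sum() / wsum)
    var = float((w * (y - mu) ** 2).sum() / wsum)
    mu = min(max(mu, 1e-3), 1 - 1e-3)
    var = max(var, 1e-6)
    common = mu * (1 - mu) / var - 1
    common = max(common, 1e-2)
    return max(mu * common, 1e-2), max((1 - mu) * common, 1e-2)


def _fit_tail_exponent(y: np.ndarray, w: np.ndarray, lo: float, hi: float) -> float:
    def nll(alpha: float) -> float:
        return float(-(w * _tail_logpdf(y, alpha, lo, hi)).sum())

    res = optimize.minimize_scalar(nll, bounds=(0.5, 10.0), method="bounded")
    return float(res.x)


def classify_clonality(ccfs: Sequence[CCFRecord], threshold: float = 0.75,
                       max_iter: int = 200, tol: float = 1e-6,
                       min_mutations: int = 20) -> tuple[list[CCFRecord], ClonalityFit]:
    """Label each mutation clonal (peak) or subclonal (tail) for one sample.

    Fits the two-component mixture by EM on CCFs capped at ``CCF_CAP``;
    mutations above the cap are labelled clonal outright. With fewer than
    ``min_mutations`` mutations, or on non-convergence, labels fall back to
    ``ccf >= threshold``.
    """
    if not ccfs:
        return [], ClonalityFit("", "threshold", False, 0, np.nan, np.nan, np.nan,
                                np.nan, threshold)
    sample_id = ccfs[0].sample_id
    values = np.array([r.ccf for r in ccfs])
    fit_mask = values <= CCF_CAP
    x = np.clip(values[fit_mask], 1e-4, CCF_CAP)

    def _threshold_labels(method: str, converged: bool, n_iter: int) -> tuple[list[CCFRecord], ClonalityFit]:
        labelled = [
            _with_label(r, "clonal" if r.ccf >= threshold else "subclonal")
            for r in ccfs
        ]
        fit = ClonalityFit(sample_id, method, converged, n_iter,
                           np.nan, np.nan, np.nan, np.nan, threshold)
        return labelled, fit

    if fit_mask.sum() < min_mutations:
        return _threshold_labels("threshold", False, 0)

    y = x / CCF_CAP  # map to (0, 1] for the Beta peak
    lo = max(float(y.min()) * 0.5, 1e-4)
    hi = 1.0

    # initialisation: peak mean 0.95 (CCF scale), tail exponent 2, equal weights
    mu0 = 0.95 / CCF_CAP
    kappa0 = 30.0
    a, b = mu0 * kappa0, (1 - mu0) * kappa0
    alpha = 2.0
    w_peak = 0.5
    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        with np.errstate(over="ignore", invalid="ignore"):
            lp_peak = np.log(w_peak) + _beta_logpdf(np.clip(y, 1e-9, 1 - 1e-9), a, b)
            lp_tail = np.log1p(-w_peak) + _tail_logpdf(np.clip(y, lo, hi), alpha, lo, hi)
        m = np.maximum(lp_peak, lp_tail)
        ll = float(np.sum(m + np.log(np.exp(lp_peak - m) + np.exp(lp_tail - m))))
        resp = 1.0 / (1.0 + np.exp(np.clip(lp_tail - lp_peak, -700, 700)))
        w_peak = float(np.clip(resp.mean(), 1e-3, 1 - 1e-3))
        if resp.sum() > 1e-9:
            a, b = _weighted_beta_mom(np.clip(y, 1e-9, 1 - 1e-9), resp)
        if (1 - resp).sum() > 1e-9:
            alpha = _fit_tail_exponent(np.clip(y, lo, hi), 1 - resp, lo, hi)
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll

    if not converged:
        log.warning("clonality EM did not converge for %s after %d iterations; "
                    "falling back to CCF threshold %.2f", sample_id, max_iter, threshold)
        return _threshold_labels("threshold", False, n_iter)

    peak_mean_ccf = float(a / (a + b) * CCF_CAP)
    if peak_mean_ccf < threshold:
        # degenerate fit: the "peak" sits in subclonal territory, so there is
        # no clonal peak to separate — label by the CCF threshold instead
        log.warning("clonality EM peak mean %.2f below %.2f for %s; "
                    "no clonal peak, using threshold labels",
                    peak_mean_ccf, threshold, sample_id)
        return _threshold_labels("threshold", True, n_iter)

    # final responsibilities on the capped values; label by maximum responsibility
    lp_peak = np.log(w_peak) + _beta_logpdf(np.clip(y, 1e-9, 1 - 1e-9), a, b)
    lp_tail = np.log1p(-w_peak) + _tail_logpdf(np.clip(y, lo, hi), alpha, lo, hi)
    is_peak = lp_peak >= lp_tail

    labelled: list[CCFRecord] = []
    j = 0
    for r, in_fit in zip(ccfs, fit_mask):
        if not in_fit:
            labelled.append(_with_label(r, "clonal"))
        else:
            labelled.append(_with_label(r, "clonal" if is_peak[j] else "subclonal"))
            j += 1
    peak_mean = float(a / (a + b) * CCF_CAP)
    fit = ClonalityFit(sample_id, "em", True, n_iter, w_peak, peak_mean,
                       float(alpha), float(prev_ll), threshold)
    return labelled, fit


def _with_label(r: CCFRecord, label: str) -> CCFRecord:
    return CCFRecord(
        mutation_key=r.mutation_key, sample_id=r.sample_id, vaf=r.vaf,
        multiplicity=r.multiplicity, ccf=r.ccf, cn_total=r.cn_total,
        cn_major=r.cn_major, clonality=label, no_segment=r.no_segment,
    )


def burden_summary(ccfs_by_sample: dict[str, Sequence[CCFRecord]],
                   territory_mb: float = 30.0) -> pd.DataFrame:
    """Per-sample total/clonal/subclonal mutation counts and per-Mb rates."""
    rows = []
    for sample_id in sorted(ccfs_by_sample):
        recs = ccfs_by_sample[sample_id]
        clonal = sum(1 for r in recs if r.clonality == "clonal")
        subclonal = sum(1 for r in recs if r.clonality == "subclonal")
        total = len(recs)
        if clonal + subclonal != total:
            raise ValueError(
                f"sample {sample_id}: {total - clonal - subclonal} unclassified "
                "mutations in burden summary"
            )
        rows.append({
            "sample_id": sample_id,
            "n_total": total,
            "n_clonal": clonal,
            "n_subclonal": subclonal,
            "rate_total_per_mb": total / territory_mb,
            "rate_clonal_per_mb": clonal / territory_mb,
            "rate_subclonal_per_mb": subclonal / territory_mb,
        })
    return pd.DataFrame(rows, columns=[
        "sample_id", "n_total", "n_clonal", "n_subclonal",
        "rate_total_per_mb", "rate_clonal_per_mb", "rate_subclonal_per_mb",
    ])


def ccf_records_frame(records: Sequence[CCFRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mutation_key": r.mutation_key,
                "sample_id": r.sample_id,
                "vaf": r.vaf,
                "multiplicity": r.multiplicity,
                "ccf": r.ccf,
                "cn_total": r.cn_total,
                "cn_major": r.cn_major,
                "clonality": r.clonality,
                "no_segment": int(r.no_segment),
            }
            for r in records
        ],
        columns=["mutation_key", "sample_id", "vaf", "multiplicity", "ccf",
                 "cn_total", "cn_major", "clonality", "no_segment"],
    )
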