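"""Treatment-epoch assignment, substitution spectra and signature refitting.

SNVs are stratified by the treatment epoch in which they first appear:
mutations already present at the pre-treatment biopsy (timepoint A) are
treatment-naive in both response groups; mutations first detected at
timepoint B arose under chemotherapy (CTx) in both groups; mutations first
detected at the resection (timepoint C) arose under CTx in responders and
under radiochemotherapy (RCTx) in non-responders, whose neoadjuvant course
adds radiation before surgery. First detection wins: a mutation new at B
and still present at C belongs to the CTx epoch only.

Spectra are six-class substitution proportions after pyrimidine-strand
collapsing, with optional 96-bin trinucleotide catalogs when context is
available. Signature exposures are refit against a supplied signature
matrix by non-negative least squares, followed by a prevalence filter that
drops low-weight signatures and refits on the retained set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .types import SPECTRUM_CLASSES, MutationRecord

EPOCHS = ("naive", "CTx", "RCTx")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: purine-reference substitutions and their pyrimidine-strand equivalents
_COLLAPSE = {}
for _ref in "CT":
    for _alt in "ACGT":
        if _alt != _ref:
            _COLLAPSE[f"{_ref}>{_alt}"] = f"{_ref}>{_alt}"
for _ref in "AG":
    for _alt in "ACGT":
        if _alt != _ref:
            _COLLAPSE[f"{_ref}>{_alt}"] = f"{_COMPLEMENT[_ref]}>{_COMPLEMENT[_alt]}"


@dataclass(frozen=True)
class EpochAssignment:
    mutation_key: str
    patient_id: str
    epoch: str  # naive | CTx | RCTx


def assign_epochs(presence_by_timepoint: dict[str, set[str]], response_group: str,
                  patient_id: str = "") -> list[EpochAssignment]:
    """Assign each SNV of one patient to a treatment epoch.

    ``presence_by_timepoint`` maps timepoint (A/B/C) to the set of mutation
    keys detected in any sample of that timepoint. Present at A -> naive;
    first detected at B -> CTx; first detected at C -> CTx for responders
    and RCTx for non-responders.
    """
    if response_group not in ("RE", "NR"):
        raise ValueError(f"response_group must be RE or NR, got {response_group!r}")
    at_a = presence_by_timepoint.get("A", set())
    at_b = presence_by_timepoint.get("B", set())
    at_c = presence_by_timepoint.get("C", set())
    out = []
    for key in sorted(at_a):
        out.append(EpochAssignment(key, patient_id, "naive"))
    for key in sorted(at_b - at_a):
        out.append(EpochAssignment(key, patient_id, "CTx"))
    late = "CTx" if response_group == "RE" else "RCTx"
    for key in sorted(at_c - at_a - at_b):
        out.append(EpochAssignment(key, patient_id, late))
    return out


def collapse_substitution(ref: str, alt: str) -> str:
    """Pyrimidine-strand collapse of an SNV (e.g. G>T is counted as C>A)."""
    sub = f"{ref.upper()}>{alt.upper()}"
    if sub not in _COLLAPSE:
        raise ValueError(f"not a single-nucleotide substitution: {sub}")
    return _COLLAPSE[sub]


def collapse_context(context: str, ref: str, alt: str) -> tuple[str, str]:
    """Collapse a trinucleotide context to the pyrimidine strand, returning
    (context, substitution)."""
    sub = collapse_substitution(ref, alt)
    if ref.upper() in "CT":
        return context.upper(), sub
    rc = "".join(_COMPLEMENT[b] for b in reversed(context.upper()))
    return rc, sub


TRINUC_BINS: list[str] = [
    f"{five}[{sub}]{three}"
    for sub in SPECTRUM_CLASSES
    for five in "ACGT"
    for three in "ACGT"
]


@dataclass
class SpectrumProfile:
    """Six-class substitution proportions, optionally with 96-bin counts."""

    proportions: pd.Series          # index = SPECTRUM_CLASSES, sums to 1
    counts: pd.Series               # six-class raw counts
    trinucleotide_counts: Optional[pd.Series] = None  # index = TRINUC_BINS

    def __post_init__(self) -> None:
        if self.counts.sum() > 0 and abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError("spectrum proportions must sum to 1")


def spectrum(mutations: Sequence[MutationRecord],
             contexts: Optional[dict[str, str]] = None) -> SpectrumProfile:
    """Six-class substitution spectrum of a set of SNVs.

    ``contexts`` optionally maps mutation key -> trinucleotide context on
    the reference strand (ref base in the middle); when given, 96-bin
    counts are produced as well.
    """
    counts = pd.Series(0, index=list(SPECTRUM_CLASSES), dtype=int)
    tri = pd.Series(0, index=TRINUC_BINS, dtype=int) if contexts is not None else None
    for rec in mutations:
        if not rec.is_snv:
            continue
        sub = collapse_substitution(rec.ref, rec.alt)
        counts[sub] += 1
        if contexts is not None and rec.key in contexts:
            ctx, sub2 = collapse_context(contexts[rec.key], rec.ref, rec.alt)
            tri[f"{ctx[0]}[{sub2}]{ctx[2]}"] += 1
    total = counts.sum()
    props = counts / total if total > 0 else counts.astype(float)
    return SpectrumProfile(proportions=props, counts=counts, trinucleotide_counts=tri)


def compare_spectra(per_sample_a: pd.DataFrame, per_sample_b: pd.DataFrame) -> pd.DataFrame:
    """Per-class two-sided Wilcoxon rank-sum tests between two groups of
    per-sample spectrum proportions (rows = samples, columns = classes),
    with Benjamini-Hochberg adjustment alongside the raw p-values."""
    if len(per_sample_a) < 2 or len(per_sample_b) < 2:
        raise ValueError("need >= 2 samples per group to compare spectra")
    rows = []
    for cls in SPECTRUM_CLASSES:
        a = per_sample_a[cls].to_numpy()
        b = per_sample_b[cls].to_numpy()
        if np.allclose(a[:, None], b[None, :]) and len(a) == len(b):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"class": cls, "statistic": float(stat), "p_value": float(p)})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# signature refitting


@dataclass
class SignatureExposure:
    """Per-group signature weights (non-negative, summing to 1)."""

    exposures: pd.DataFrame  # rows = group keys, columns = signature ids
    retained: list[str]

    def __post_init__(self) -> None:
        arr = self.exposures.to_numpy()
        if (arr < -1e-12).any():
            raise ValueError("exposures must be non-negative")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("exposures must sum to 1 per group")


def _nnls_exposures(catalogs: pd.DataFrame, signatures: pd.DataFrame) -> pd.DataFrame:
    sig = signatures.to_numpy(dtype=float)
    sig = sig / sig.sum(axis=0, keepdims=True)
    rows = {}
    for group in catalogs.columns:
        y = catalogs[group].to_numpy(dtype=float)
        w, _ = optimize.nnls(sig, y)
        total = w.sum()
        if total <= 0:
            raise ValueError(f"NNLS produced an all-zero fit for group {group!r}")
        rows[group] = w / total
    return pd.DataFrame(rows, index=list(signatures.columns)).T


def refit_signatures(catalogs: pd.DataFrame, signatures: pd.DataFrame,
                     min_weight: float = 0.05, mode: str = "any_cell") -> SignatureExposure:
    """Refit signature exposures by NNLS, with a prevalence filter.

    ``catalogs`` is a 96-bin x groups count table (one column per
    response-group x timepoint cell); ``signatures`` is a 96-bin x k
    probability matrix. After an initial fit, the filter removes signatures
    of low weight and the retained set is refit and renormalised.

    ``mode="any_cell"`` drops a signature whose weight falls below
    ``min_weight`` in at least one group cell (the strict reading of the
    prevalence rule); ``mode="all_cells"`` drops it only when it is below
    the cutoff in every cell.
    """
    if mode not in ("any_cell", "all_cells"):
        raise ValueError(f"unknown filter mode {mode!r}")
    if catalogs.shape[0] != signatures.shape[0]:
        raise ValueError("catalog and signature matrices must share the 96-bin index")
    first = _nnls_exposures(catalogs, signatures)
    if mode == "any_cell":
        keep = [s for s in first.columns if (first[s] >= min_weight).all()]
    else:
        keep = [s for s in first.columns if (first[s] >= min_weight).any()]
    if not keep:
        raise ValueError(
            f"prevalence filter at {min_weight:.0%} removed every signature"
        )
    refit = _nnls_exposures(catalogs, signatures[keep])
    return SignatureExposure(exposures=refit, retained=keep)
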