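"""TCR repertoire normalisation and longitudinal clone-expansion tracking.

Clone counts are normalised within each sample and chain to TCRs/million.
A clone has expanded between two timepoints when its per-million abundance
grew by at least a fold threshold (4x and 8x by default); clones absent at
the earlier timepoint are assigned a half-count floor so de-novo clones
are counted without letting singletons dominate, and a minimum later-
timepoint count suppresses sampling artefacts. Alpha and beta chains are
analysed separately throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import validate_tcr_table


def normalise(tcr: pd.DataFrame) -> pd.DataFrame:
    """Add a ``per_million`` column: count / (sample+chain total) * 1e6.

    The per-million values of one sample+chain sum exactly to 1e6.
    """
    df = validate_tcr_table(tcr).copy()
    totals = df.groupby(["sample_id", "chain"])["count"].transform("sum")
    if (totals <= 0).any():
        raise ValueError("sample with zero total TCR count")
    df["per_million"] = df["count"] / totals * 1e6
    return df


def size_distribution(norm: pd.DataFrame, sample_id: Optional[str] = None,
                      chain: Optional[str] = None) -> pd.DataFrame:
    """Proportion of clones found at each raw abundance (rank/abundance
    profile); proportions sum to 1 over abundance bins."""
    df = norm
    if sample_id is not None:
        df = df[df["sample_id"] == sample_id]
    if chain is not None:
        df = df[df["chain"] == chain]
    counts = df.groupby("count").size()
    out = pd.DataFrame({
        "abundance": counts.index.to_numpy(),
        "n_clones": counts.to_numpy(),
    })
    out["proportion"] = out["n_clones"] / out["n_clones"].sum()
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class ExpansionEvent:
    patient_id: str
    chain: str
    clone_id: str
    from_tp: str
    to_tp: str
    per_million_from: float
    per_million_to: float
    fold: float
    de_novo: bool                 # absent at the earlier timepoint
    thresholds_passed: frozenset  # subset of the fold thresholds


def detect_expansions(norm: pd.DataFrame, patient_id: str,
                      sample_from: str, sample_to: str,
                      tp_from: str, tp_to: str,
                      folds: Sequence[float] = (4.0, 8.0),
                      floor_count: float = 0.5,
                      min_later_count: int = 2) -> list[ExpansionEvent]:
    """Detect clones expanded by at least each fold threshold between two
    timepoints of one patient.

    fold = per_million_to / max(per_million_from, floor), where the floor
    is ``floor_count`` converted to per-million of the earlier sample's
    chain total. Clones absent at the earlier timepoint use the floor and
    are marked de novo. Events require a raw later-timepoint count of at
    least ``min_later_count``; thresholds are evaluated with >=.
    """
    events: list[ExpansionEvent] = []
    for chain in ("alpha", "beta"):
        before = norm[(norm["sample_id"] == sample_from) & (norm["chain"] == chain)]
        after = norm[(norm["sample_id"] == sample_to) & (norm["chain"] == chain)]
        if before.empty or after.empty:
            continue
        total_before = before["count"].sum()
        floor_pm = floor_count / total_before * 1e6
        pm_before = dict(zip(before["clone_id"], before["per_million"]))
        for row in after.itertuples(index=False):
            if row.count < min_later_count:
                continue
            pm_from = pm_before.get(row.clone_id, 0.0)
            de_novo = row.clone_id not in pm_before
            denom = max(pm_from, floor_pm)
            fold = row.per_million / denom
            passed = frozenset(f for f in folds if fold >= f)
            if passed:
                events.append(ExpansionEvent(
                    patient_id=patient_id, chain=chain, clone_id=row.clone_id,
                    from_tp=tp_from, to_tp=tp_to,
                    per_million_from=pm_from, per_million_to=row.per_million,
                    fold=fold, de_novo=de_novo, thresholds_passed=passed,
                ))
    return events


def track_expansions(norm: pd.DataFrame, patient_id: str,
                     samples_by_tp: dict[str, str],
                     anchor: tuple[str, str] = ("A", "C"),
                     folds: Sequence[float] = (4.0, 8.0),
                     floor_count: float = 0.5,
                     min_later_count: int = 2) -> pd.DataFrame:
    """Track anchored expanded clones across all timepoints (fishplot input).

    Clones expanded between the anchor timepoints (default A->C) are
    followed: one row per (chain, clone, timepoint) with its per-million
    abundance, plus the summed proportion per timepoint.
    """
    tps = sorted(samples_by_tp)
    missing = [t for t in anchor if t not in samples_by_tp]
    if missing:
        import warnings
        warnings.warn(
            f"patient {patient_id}: timepoint(s) {missing} missing; "
            "expansion tracking restricted to available pairs"
        )
        return pd.DataFrame(columns=["chain", "clone_id", "timepoint",
                                     "per_million", "fold_anchor"])
    events = detect_expansions(
        norm, patient_id, samples_by_tp[anchor[0]], samples_by_tp[anchor[1]],
        anchor[0], anchor[1], folds=folds, floor_count=floor_count,
        min_later_count=min_later_count,
    )
    rows = []
    for ev in events:
        for tp in tps:
            sid = samples_by_tp[tp]
            sub = norm[(norm["sample_id"] == sid) & (norm["chain"] == ev.chain)
                       & (norm["clone_id"] == ev.clone_id)]
            pm = float(sub["per_million"].iloc[0]) if not sub.empty else 0.0
            rows.append({
                "chain": ev.chain, "clone_id": ev.clone_id, "timepoint": tp,
                "per_million": pm, "fold_anchor": ev.fold,
            })
    return pd.DataFrame(rows, columns=["chain", "clone_id", "timepoint",
                                       "per_million", "fold_anchor"])


def expansion_counts(events_by_patient: dict[str, Sequence[ExpansionEvent]],
                     folds: Sequence[float] = (4.0, 8.0)) -> pd.DataFrame:
    """Per-patient number of expansion events per (timepoint pair, chain,
    fold threshold)."""
    rows = []
    for patient_id in sorted(events_by_patient):
        events = events_by_patient[patient_id]
        pairs = sorted({(e.from_tp, e.to_tp) for e in events})
        for from_tp, to_tp in pairs or [("A", "B")]:
            for chain in ("alpha", "beta"):
                for fold in folds:
                    n = sum(
                        1 for e in events
                        if e.from_tp == from_tp and e.to_tp == to_tp
                        and e.chain == chain and fold in e.thresholds_passed
                    )
                    rows.append({
                        "patient_id": patient_id, "from_tp": from_tp,
                        "to_tp": to_tp, "chain": chain,
                        "fold_threshold": fold, "n_expanded": n,
                    })
    return pd.DataFrame(rows, columns=["patient_id", "from_tp", "to_tp",
                                       "chain", "fold_threshold", "n_expanded"])


def compare_expansion_counts(counts: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Two-sided Mann-Whitney U tests of per-patient expansion counts
    between two groups (response group or Becker grade).

    ``groups`` maps patient_id -> group label (exactly two labels enter the
    test; groups with < 2 patients are skipped with a warning).
    """
    import warnings
    rows = []
    labels = sorted(groups.dropna().unique())
    for (from_tp, to_tp, chain, fold), sub in counts.groupby(
            ["from_tp", "to_tp", "chain", "fold_threshold"]):
        per_patient = sub.set_index("patient_id")["n_expanded"]
        samples = {
            lab: per_patient[groups[groups == lab].index.intersection(per_patient.index)]
            for lab in labels
        }
        usable = [lab for lab in labels if len(samples[lab]) >= 2]
        if len(usable) != 2:
            warnings.warn(
                f"degenerate group sizes for {from_tp}->{to_tp} {chain} "
                f">={fold}; test skipped"
            )
            continue
        a, b = samples[usable[0]].to_numpy(), samples[usable[1]].to_numpy()
        if np.unique(np.concatenate([a, b])).size == 1:
            stat, p = len(a) * len(b) / 2, 1.0
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({
            "from_tp": from_tp, "to_tp": to_tp, "chain": chain,
            "fold_threshold": fold, "group_a": usable[0], "group_b": usable[1],
            "median_a": float(np.median(a)), "median_b": float(np.median(b)),
            "statistic": float(stat), "p_value": float(p),
        })
    return pd.DataFrame(rows, columns=["from_tp", "to_tp", "chain", "fold_threshold",
                                       "group_a", "group_b", "median_a", "median_b",
                                       "statistic", "p_value"])


def events_frame(events: Sequence[ExpansionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": e.patient_id, "chain": e.chain, "clone_id": e.clone_id,
                "from_tp": e.from_tp, "to_tp": e.to_tp,
                "per_million_from": e.per_million_from,
                "per_million_to": e.per_million_to,
                "fold": e.fold, "de_novo": int(e.de_novo),
                "thresholds_passed": "|".join(str(int(f)) for f in sorted(e.thresholds_passed)),
            }
            for e in events
        ],
        columns=["patient_id", "chain", "clone_id", "from_tp", "to_tp",
                 "per_million_from", "per_million_to", "fold", "de_novo",
                 "thresholds_passed"],
    )
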