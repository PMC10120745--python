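"""Synthetic longitudinal cohort generator with known ground truth.

Emulates a neoadjuvant-treatment oesophageal-adenocarcinoma cohort: per
patient, a clone tree rooted at the germline with treatment-perturbed
clone fractions across timepoints A (pre-treatment), B (post-first-cycle)
and C (resection); allele-specific copy-number profiles with
inter-timepoint turnover; read counts drawn binomially at the configured
sequencing depth from the purity/copy-number VAF model; neoantigen and
driver flags; immune-escape mechanism truth (HLA/B2M mutations, HLA-LOH
call inputs, PD-L1 overexpression); and power-law TCR repertoires with
expansions injected at an exact per-million fold.

The genome is an abstraction — pseudo-chromosomes of unit-length exonic
blocks — since every downstream statistic is length- and count-based.
All randomness flows from a single seeded generator, so a fixed seed
reproduces the cohort byte-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    CNSegment,
    ExpressionMatrix,
    MutationRecord,
    PatientMeta,
    SampleMeta,
)

# (CNt, minor) states the CN simulator draws from, with baseline probabilities
CN_STATES: list[tuple[int, int]] = [(2, 1), (1, 0), (2, 0), (3, 0), (3, 1), (4, 1), (5, 2)]
CN_STATE_PROBS: list[float] = [0.50, 0.10, 0.10, 0.06, 0.12, 0.07, 0.05]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

# six-class substitution probabilities per treatment epoch: the naive
# spectrum is ageing-like (C>T rich); chemotherapy enriches C>A
# (platinum-style); radiochemotherapy is modelled C>T/indel-like.
EPOCH_SPECTRA = {
    "naive": (0.08, 0.08, 0.45, 0.09, 0.20, 0.10),
    "CTx": (0.35, 0.08, 0.25, 0.09, 0.15, 0.08),
    "RCTx": (0.12, 0.10, 0.40, 0.12, 0.16, 0.10),
}

EFFECT_CHOICES = ("nonsynonymous", "synonymous", "stopgain", "frameshift", "other")
EFFECT_PROBS = (0.70, 0.18, 0.05, 0.04, 0.03)

DRIVER_GENES = [f"DRV{i:02d}" for i in range(1, 21)]


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the study design: mean sequencing depth 300x, three
    timepoints, purity in a realistic surgical-specimen range, a handful of
    clones per tumour, and stronger clonal perturbation under treatment in
    responders than in non-responders.
    """

    n_patients: int = 6
    timepoints: tuple[str, ...] = ("A", "B", "C")
    regions_per_timepoint: int = 1
    mean_depth: float = 300.0
    purity_range: tuple[float, float] = (0.4, 0.9)
    clone_count_range: tuple[int, int] = (3, 6)
    mutations_per_clone: float = 40.0
    clone_dropout: float = 0.25
    perturbation_sd: dict = field(default_factory=lambda: {"RE": 1.0, "NR": 0.4})
    n_new_clones_b: int = 1
    n_new_clones_c: int = 1
    neoantigen_prob: float = 0.15
    driver_prob: float = 0.03
    n_chromosomes: int = 4
    segments_per_chromosome: int = 10
    segment_length: int = 1_000_000
    cn_turnover_prob: float = 0.10
    b2m_mutation_prob: float = 0.10
    hla_mutation_prob: float = 0.10
    hla_loh_prob: dict = field(default_factory=lambda: {"RE": 0.15, "NR": 0.35})
    pdl1_over_prob: dict = field(default_factory=lambda: {"RE": 0.10, "NR": 0.30})
    tcr_n_clones: int = 3000
    tcr_total: int = 30_000
    tcr_power_exponent: float = 2.0
    tcr_n_expansions: int = 5
    tcr_expansion_fold: float = 8.0
    tcr_background_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.clone_dropout, self.neoantigen_prob, self.driver_prob,
                  self.cn_turnover_prob, self.b2m_mutation_prob, self.hla_mutation_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.tcr_power_exponent <= 1.0:
            raise ValueError("tcr_power_exponent must exceed 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class CloneTree:
    """Ground-truth clone tree: parent pointers (root = 'germline'),
    per-clone mutation counts, and per-sample clone fractions (masses).

    A clone's cancer cell fraction in a sample is the summed mass of its
    subtree; descendant CCF never exceeds ancestor CCF by construction.
    """

    parents: dict[str, str]
    mutations_per_clone: dict[str, int]
    clone_fractions: dict[str, dict[str, float]] = field(default_factory=dict)

    def children(self, clone: str) -> list[str]:
        return sorted(c for c, p in self.parents.items() if p == clone)

    def subtree(self, clone: str) -> list[str]:
        out = [clone]
        for c in self.children(clone):
            out.extend(self.subtree(c))
        return out

    def ccf(self, clone: str, sample_id: str) -> float:
        masses = self.clone_fractions[sample_id]
        return sum(masses.get(c, 0.0) for c in self.subtree(clone))


def expected_vaf(ccf: float, purity: float, cn_total: int, multiplicity: int) -> float:
    """Expected variant allele frequency of a mutation with the given CCF,
    multiplicity and local total copy number in a tumour of the given purity."""
    return purity * multiplicity * ccf / (purity * cn_total + (1.0 - purity) * 2.0)


# ---------------------------------------------------------------------------
# copy-number profiles


def make_genome(cfg: SimConfig) -> list[tuple[str, int, int]]:
    """Pseudo-genome: (chrom, start, end) exonic blocks, 1-based inclusive."""
    blocks = []
    for ci in range(1, cfg.n_chromosomes + 1):
        for si in range(cfg.segments_per_chromosome):
            start = si * cfg.segment_length + 1
            blocks.append((f"chr{ci}", start, start + cfg.segment_length - 1))
    return blocks


def simulate_cn_profiles(cfg: SimConfig, n_segments: int, rng: np.random.Generator,
                         timepoints: Optional[Sequence[str]] = None
                         ) -> dict[str, list[tuple[int, int]]]:
    """Per-timepoint allele-specific CN states over ``n_segments`` segments.

    The first timepoint's profile is drawn from the baseline state mix;
    each later timepoint toggles every segment independently with the
    configured turnover probability to a different random state, so the
    expected fraction of genome length changing state equals that
    probability.
    """
    tps = list(timepoints or cfg.timepoints)
    states = [CN_STATES[i] for i in
              rng.choice(len(CN_STATES), size=n_segments, p=CN_STATE_PROBS)]
    profiles = {tps[0]: states}
    prev = states
    for tp in tps[1:]:
        nxt = []
        for st in prev:
            if rng.random() < cfg.cn_turnover_prob:
                choices = [s for s in CN_STATES if s != st]
                nxt.append(choices[rng.integers(len(choices))])
            else:
                nxt.append(st)
        profiles[tp] = nxt
        prev = nxt
    return profiles


# ---------------------------------------------------------------------------
# TCR repertoires


def _power_law_probs(n_clones: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n_clones + 1, dtype=float)
    p = ranks ** (-exponent)
    return p / p.sum()


def simulate_tcr(cfg: SimConfig, patient_id: str, timepoints: Sequence[str],
                 rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Power-law TCR repertoires per timepoint with injected expansions.

    Baseline clone counts are a multinomial draw from a rank-frequency
    power law. Background clones persist across timepoints (optionally
    perturbed by ``tcr_background_noise``); the injected clones' counts at
    the final timepoint are constructed so their per-million fold relative
    to the first timepoint is at least the configured fold exactly, with a
    half-way abundance at the middle timepoint. Returns (tcr table, truth
    table of injected expansions).
    """
    rows = []
    truth_rows = []
    tps = list(timepoints)
    for chain in ("alpha", "beta"):
        probs = _power_law_probs(cfg.tcr_n_clones, cfg.tcr_power_exponent)
        base = rng.multinomial(cfg.tcr_total, probs)
        clone_ids = np.array(
            [f"{patient_id}_{chain}_{i:05d}" for i in range(cfg.tcr_n_clones)]
        )
        # injected expansions: mid-abundance clones with enough baseline support
        eligible = np.where((base >= 5) & (base <= max(10, cfg.tcr_total // 1000)))[0]
        n_inj = min(cfg.tcr_n_expansions, len(eligible))
        injected = rng.choice(eligible, size=n_inj, replace=False) if n_inj else np.array([], dtype=int)

        counts_by_tp = {tps[0]: base.copy()}
        if len(tps) > 1:
            final = _with_injected_fold(base, injected, cfg.tcr_expansion_fold, rng, cfg)
            counts_by_tp[tps[-1]] = final
            for tp in tps[1:-1]:
                mid = _background(base, rng, cfg)
                # injected clones ramp up half-way (geometric mean of the fold)
                for idx in injected:
                    mid[idx] = max(
                        base[idx], int(round(math.sqrt(base[idx] * final[idx])))
                    )
                counts_by_tp[tp] = mid
        for tp in tps:
            counts = counts_by_tp[tp]
            nz = counts > 0
            for cid, cnt in zip(clone_ids[nz], counts[nz]):
                rows.append({
                    "sample_id": f"{patient_id}_{tp}",
                    "chain": chain, "clone_id": cid, "count": int(cnt),
                })
        t0, t1 = counts_by_tp[tps[0]], counts_by_tp[tps[-1]]
        for idx in injected:
            truth_rows.append({
                "patient_id": patient_id, "chain": chain,
                "clone_id": clone_ids[idx],
                "from_tp": tps[0], "to_tp": tps[-1],
                "count_from": int(t0[idx]), "count_to": int(t1[idx]),
                "fold_target": cfg.tcr_expansion_fold,
            })
    tcr = pd.DataFrame(rows, columns=["sample_id", "chain", "clone_id", "count"])
    truth = pd.DataFrame(truth_rows, columns=[
        "patient_id", "chain", "clone_id", "from_tp", "to_tp",
        "count_from", "count_to", "fold_target",
    ])
    return tcr, truth


def _background(base: np.ndarray, rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    if cfg.tcr_background_noise <= 0:
        return base.copy()
    noisy = base * np.exp(rng.normal(0.0, cfg.tcr_background_noise, size=base.size))
    return np.maximum(np.rint(noisy), 0).astype(int)


def _with_injected_fold(base: np.ndarray, injected: np.ndarray, fold: float,
                        rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Final-timepoint counts achieving per-million fold >= ``fold`` for the
    injected clones against the baseline repertoire."""
    final = _background(base, rng, cfg)
    if injected.size == 0:
        return final
    t0 = base.sum()
    for _ in range(100):
        t1 = final.sum()
        ok = True
        for idx in injected:
            target_pm = fold * base[idx] / t0  # required proportion
            if final[idx] / final.sum() < target_pm:
                final[idx] = int(math.ceil(target_pm * final.sum())) + 1
                ok = False
        if ok:
            break
    return final


# ---------------------------------------------------------------------------
# per-patient simulation


@dataclass
class PatientSim:
    """Ground truth and observed tables for one simulated patient."""

    patient: PatientMeta
    samples: list[SampleMeta]
    clone_tree: CloneTree
    mutations: list[MutationRecord]
    segments: list[CNSegment]
    contexts: dict[str, str]
    truth_mutations: pd.DataFrame     # mutation_key, clone, epoch, gene, flags
    truth_cn: pd.DataFrame            # per-timepoint-transition turnover fractions
    truth_escape: pd.DataFrame        # per-sample mechanism flags
    hla_loh_inputs: pd.DataFrame      # per-sample per-allele LOHHLA-style inputs
    pdl1_over_truth: dict[str, bool]
    tcr: pd.DataFrame
    truth_tcr: pd.DataFrame
    truth_presence: pd.DataFrame = field(default_factory=pd.DataFrame)


def _build_clone_tree(cfg: SimConfig, rng: np.random.Generator) -> tuple[CloneTree, dict[str, str]]:
    """Random clone tree plus the epoch of origin of each clone."""
    k = int(rng.integers(cfg.clone_count_range[0], cfg.clone_count_range[1] + 1))
    parents: dict[str, str] = {"clone1": "germline"}
    for i in range(2, k + 1):
        parent = ["germline"] + [f"clone{j}" for j in range(1, i)]
        # attach below an existing clone (never germline) so clone1 is truncal
        parents[f"clone{i}"] = parent[int(rng.integers(1, len(parent)))]
    origin = {c: "A" for c in parents}
    new_b = [f"clone{k + 1 + i}" for i in range(cfg.n_new_clones_b)]
    new_c = [f"clone{k + 1 + cfg.n_new_clones_b + i}" for i in range(cfg.n_new_clones_c)]
    hosts = [f"clone{j}" for j in range(1, k + 1)]
    for c in new_b:
        parents[c] = hosts[int(rng.integers(len(hosts)))]
        origin[c] = "B"
    for c in new_c:
        parents[c] = hosts[int(rng.integers(len(hosts)))]
        origin[c] = "C"
    muts = {
        c: max(1, int(rng.poisson(cfg.mutations_per_clone))) for c in parents
    }
    return CloneTree(parents=parents, mutations_per_clone=muts), origin


def _clone_masses(tree: CloneTree, origin: dict[str, str], timepoint: str,
                  base_masses: Optional[dict[str, float]], cfg: SimConfig,
                  response_group: str, rng: np.random.Generator) -> dict[str, float]:
    """Clone masses for one sample: Dirichlet at A, log-normal perturbation
    of the patient's A masses at B/C, with subtree-closed dropout of
    non-truncal clones and timepoint-gated new clones."""
    tp_order = {"A": 0, "B": 1, "C": 2}
    active = [c for c in tree.parents if tp_order[origin[c]] <= tp_order[timepoint]]
    # subtree-closed dropout of non-truncal clones
    present = set(active)
    for c in sorted(active):
        if c != "clone1" and origin[c] == "A" and rng.random() < cfg.clone_dropout:
            present -= set(tree.subtree(c))
    present.add("clone1")
    present = sorted(present & set(active))
    if base_masses is None or timepoint == "A":
        raw = rng.dirichlet(np.ones(len(present)))
        masses = dict(zip(present, raw))
    else:
        sd = cfg.perturbation_sd[response_group]
        masses = {}
        for c in present:
            if c in base_masses:
                base = base_masses[c]
            elif origin[c] != "A":
                base = 0.02  # treatment-emergent clones start small
            else:
                continue  # absent from the baseline sampling: stays absent
            masses[c] = base * float(np.exp(rng.normal(0.0, sd)))
        total = sum(masses.values())
        masses = {c: m / total for c, m in masses.items()}
    return masses


def simulate_patient(cfg: SimConfig, response_group: str, patient_id: str,
                     rng: np.random.Generator) -> PatientSim:
    """Simulate one patient end to end (truth plus observed tables)."""
    tree, origin = _build_clone_tree(cfg, rng)
    genome = make_genome(cfg)
    n_segments = len(genome)
    profiles = simulate_cn_profiles(cfg, n_segments, rng)

    purity_by_tp = {
        tp: float(rng.uniform(*cfg.purity_range)) for tp in cfg.timepoints
    }
    becker = int(rng.integers(1, 4)) if response_group == "NR" else int(rng.integers(1, 3))
    patient = PatientMeta(patient_id=patient_id, response_group=response_group,
                          becker_grade=becker)

    # mutation catalogue: position weighted per genome copy (timepoint-A CN)
    a_profile = profiles[cfg.timepoints[0]]
    seg_weights = np.array(
        [(genome[i][2] - genome[i][1] + 1) * a_profile[i][0] for i in range(n_segments)],
        dtype=float,
    )
    seg_weights /= seg_weights.sum()

    mut_catalog = []   # (key, clone, chrom, pos, ref, alt, effect, gene, flags, context)
    used_positions: set[tuple[str, int]] = set()
    for clone in sorted(tree.parents):
        epoch = _epoch_of(origin[clone], response_group)
        for _ in range(tree.mutations_per_clone[clone]):
            si = int(rng.choice(n_segments, p=seg_weights))
            chrom, lo, hi = genome[si]
            pos = int(rng.integers(lo, hi + 1))
            while (chrom, pos) in used_positions:
                pos = int(rng.integers(lo, hi + 1))
            used_positions.add((chrom, pos))
            effect = EFFECT_CHOICES[int(rng.choice(len(EFFECT_CHOICES), p=EFFECT_PROBS))]
            ref, alt, context = _draw_substitution(epoch, effect, rng)
            gene = f"GENE{rng.integers(1, 400):04d}"
            is_driver = bool(rng.random() < cfg.driver_prob)
            if is_driver:
                gene = DRIVER_GENES[int(rng.integers(len(DRIVER_GENES)))]
            is_neo = bool(
                effect == "nonsynonymous" and len(ref) == 1 == len(alt)
                and rng.random() < cfg.neoantigen_prob
            )
            key = f"{chrom}:{pos}:{ref}>{alt}"
            mult_u = float(rng.random())
            mut_catalog.append({
                "mutation_key": key, "clone": clone, "epoch": epoch,
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "segment_index": si, "effect": effect, "gene": gene,
                "is_driver": is_driver, "is_neoantigenic": is_neo,
                "context": context, "mult_u": mult_u,
            })

    samples: list[SampleMeta] = []
    segments: list[CNSegment] = []
    mutations: list[MutationRecord] = []
    base_masses: Optional[dict[str, float]] = None
    truth_presence_rows = []
    for tp in cfg.timepoints:
        for region in range(1, cfg.regions_per_timepoint + 1):
            sample_id = (f"{patient_id}_{tp}" if cfg.regions_per_timepoint == 1
                         else f"{patient_id}_{tp}_R{region}")
            purity = purity_by_tp[tp]
            masses = _clone_masses(tree, origin, tp, base_masses, cfg,
                                   response_group, rng)
            if tp == cfg.timepoints[0] and region == 1:
                base_masses = masses
            tree.clone_fractions[sample_id] = masses
            profile = profiles[tp]
            ploidy = float(
                sum((genome[i][2] - genome[i][1] + 1) * profile[i][0]
                    for i in range(n_segments))
                / sum(genome[i][2] - genome[i][1] + 1 for i in range(n_segments))
            )
            samples.append(SampleMeta(
                sample_id=sample_id, patient_id=patient_id, timepoint=tp,
                region_id=f"R{region}", purity=purity,
                ploidy=float(np.clip(ploidy, 1.0, 5.0)),
            ))
            for i, (chrom, lo, hi) in enumerate(genome):
                cnt, minor = profile[i]
                segments.append(CNSegment(
                    sample_id=sample_id, chrom=chrom, start=lo, end=hi,
                    cn_total=cnt, cn_major=cnt - minor, cn_minor=minor,
                ))
            for m in mut_catalog:
                ccf = tree.ccf(m["clone"], sample_id) if m["clone"] in _present(masses, tree) else 0.0
                cnt, minor = profile[m["segment_index"]]
                cn_major = cnt - minor
                if ccf <= 0 or cnt == 0:
                    continue
                mult = 1 + int(m["mult_u"] * max(cn_major, 1))
                mult = min(mult, max(cn_major, 1))
                vaf = expected_vaf(ccf, purity, cnt, mult)
                depth = int(rng.poisson(cfg.mean_depth))
                alt_count = int(rng.binomial(depth, min(vaf, 1.0))) if depth else 0
                if alt_count < 3:
                    continue  # below detection
                normal_depth = max(5, int(rng.poisson(cfg.mean_depth / 2)))
                mutations.append(MutationRecord(
                    chrom=m["chrom"], pos=m["pos"], ref=m["ref"], alt=m["alt"],
                    sample_id=sample_id,
                    ref_count=depth - alt_count, alt_count=alt_count,
                    normal_ref_count=normal_depth, normal_alt_count=0,
                    gene=m["gene"], effect=m["effect"],
                    is_driver=m["is_driver"], is_neoantigenic=m["is_neoantigenic"],
                    filter_flag="PASS",
                ))
                truth_presence_rows.append({
                    "mutation_key": m["mutation_key"], "sample_id": sample_id,
                    "clone": m["clone"], "ccf": ccf, "multiplicity": mult,
                    "expected_vaf": vaf,
                })

    truth_mutations = pd.DataFrame(mut_catalog)[[
        "mutation_key", "clone", "epoch", "chrom", "pos", "ref", "alt",
        "effect", "gene", "is_driver", "is_neoantigenic", "context",
    ]]
    truth_presence = pd.DataFrame(truth_presence_rows, columns=[
        "mutation_key", "sample_id", "clone", "ccf", "multiplicity", "expected_vaf",
    ])

    # realised CN turnover truth per timepoint transition
    lengths = np.array([hi - lo + 1 for _, lo, hi in genome], dtype=float)
    turnover_rows = []
    for a, b in zip(cfg.timepoints, cfg.timepoints[1:]):
        changed = np.array(
            [profiles[a][i] != profiles[b][i] for i in range(n_segments)]
        )
        turnover_rows.append({
            "patient_id": patient_id, "from_tp": a, "to_tp": b,
            "turnover_fraction": float(lengths[changed].sum() / lengths.sum()),
        })
    truth_cn = pd.DataFrame(turnover_rows,
                            columns=["patient_id", "from_tp", "to_tp", "turnover_fraction"])

    mutations, escape_rows, loh_rows, pdl1_truth = _escape_truth(
        cfg, patient_id, response_group, samples, mutations, rng
    )
    truth_escape = pd.DataFrame(escape_rows, columns=[
        "sample_id", "hla_mutation", "b2m_mutation", "hla_loh", "pdl1_over",
    ])
    hla_loh_inputs = pd.DataFrame(loh_rows, columns=[
        "sample_id", "allele", "candidate", "ai_p_value", "lost_cn",
        "lost_cn_ci_upper", "kept_cn", "mismatched_sites", "truth_loh",
    ])

    tcr, truth_tcr = simulate_tcr(cfg, patient_id, cfg.timepoints, rng)

    return PatientSim(
        patient=patient, samples=samples, clone_tree=tree,
        mutations=mutations, segments=segments,
        contexts={m["mutation_key"]: m["context"] for m in mut_catalog},
        truth_mutations=truth_mutations, truth_cn=truth_cn,
        truth_escape=truth_escape, hla_loh_inputs=hla_loh_inputs,
        pdl1_over_truth=pdl1_truth, tcr=tcr, truth_tcr=truth_tcr,
        truth_presence=truth_presence,
    )


def _present(masses: dict[str, float], tree: CloneTree) -> set[str]:
    return {c for c, m in masses.items() if m > 0}


def _epoch_of(origin_tp: str, response_group: str) -> str:
    if origin_tp == "A":
        return "naive"
    if origin_tp == "B":
        return "CTx"
    return "CTx" if response_group == "RE" else "RCTx"


_PYRIMIDINE_PARTNER = {"C": "G", "T": "A"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _draw_substitution(epoch: str, effect: str, rng: np.random.Generator
                       ) -> tuple[str, str, str]:
    """Draw (ref, alt, trinucleotide context). Half the SNVs are emitted on
    the purine strand to exercise pyrimidine collapsing; frameshifts become
    single-base insertions."""
    sub = SUBSTITUTIONS[int(rng.choice(len(SUBSTITUTIONS), p=EPOCH_SPECTRA[epoch]))]
    ref, alt = sub[0], sub[2]
    bases = "ACGT"
    context = bases[rng.integers(4)] + ref + bases[rng.integers(4)]
    if effect == "frameshift":
        ins = bases[rng.integers(4)]
        return ref, ref + ins, context
    if rng.random() < 0.5:  # purine strand
        rc = "".join(_COMP[b] for b in reversed(context))
        return _COMP[ref], _COMP[alt], rc
    return ref, alt, context


def _escape_truth(cfg: SimConfig, patient_id: str, response_group: str,
                  samples: list[SampleMeta], mutations: list[MutationRecord],
                  rng: np.random.Generator):
    """Inject escape mechanisms and emit per-sample truth flags and
    LOHHLA-style call inputs."""
    escape_rows = []
    loh_rows = []
    pdl1_truth = {}
    extra: list[MutationRecord] = []
    loh_p = cfg.hla_loh_prob[response_group]
    pdl1_p = cfg.pdl1_over_prob[response_group]
    for s in samples:
        b2m = bool(rng.random() < cfg.b2m_mutation_prob)
        hla_mut = bool(rng.random() < cfg.hla_mutation_prob)
        hla_loh = bool(rng.random() < loh_p)
        pdl1 = bool(s.timepoint != "A" and rng.random() < pdl1_p)
        if b2m:
            extra.append(MutationRecord(
                chrom="chr15", pos=int(rng.integers(44_711_487, 44_718_877)),
                ref="C", alt="CT", sample_id=s.sample_id,
                ref_count=150, alt_count=60, normal_ref_count=100, normal_alt_count=0,
                gene="B2M", effect="frameshift", filter_flag="PASS",
            ))
        if hla_mut:
            extra.append(MutationRecord(
                chrom="chr6", pos=int(rng.integers(29_941_260, 29_945_884)),
                ref="G", alt="A", sample_id=s.sample_id,
                ref_count=150, alt_count=55, normal_ref_count=100, normal_alt_count=0,
                gene="HLA-A", effect="nonsynonymous", filter_flag="PASS",
            ))
        for allele in ("HLA-A*lost", "HLA-B*lost"):
            if hla_loh and allele == "HLA-A*lost":
                loh_rows.append({
                    "sample_id": s.sample_id, "allele": allele, "candidate": True,
                    "ai_p_value": float(rng.uniform(1e-5, 0.005)),
                    "lost_cn": float(rng.uniform(0.05, 0.4)),
                    "lost_cn_ci_upper": float(rng.uniform(0.45, 0.65)),
                    "kept_cn": float(rng.uniform(0.9, 1.8)),
                    "mismatched_sites": int(rng.integers(12, 40)),
                    "truth_loh": True,
                })
            else:
                # benign: either not a candidate or failing a threshold
                loh_rows.append({
                    "sample_id": s.sample_id, "allele": allele,
                    "candidate": bool(rng.random() < 0.3),
                    "ai_p_value": float(rng.uniform(0.05, 0.9)),
                    "lost_cn": float(rng.uniform(0.7, 1.2)),
                    "lost_cn_ci_upper": float(rng.uniform(0.9, 1.5)),
                    "kept_cn": float(rng.uniform(0.8, 1.4)),
                    "mismatched_sites": int(rng.integers(5, 30)),
                    "truth_loh": False,
                })
        pdl1_truth[s.sample_id] = pdl1
        escape_rows.append({
            "sample_id": s.sample_id, "hla_mutation": hla_mut,
            "b2m_mutation": b2m, "hla_loh": hla_loh, "pdl1_over": pdl1,
        })
    return mutations + extra, escape_rows, loh_rows, pdl1_truth


# ---------------------------------------------------------------------------
# cohort level


@dataclass
class CohortSim:
    config: SimConfig
    patients: list[PatientSim]
    expression: ExpressionMatrix
    pdl1_stats: dict


def simulate_cohort(cfg: SimConfig) -> CohortSim:
    """Simulate the full cohort from one seeded generator.

    Patients alternate RE/NR. The expression matrix is built cohort-wide so
    PD-L1 overexpression truth is injected relative to the realised
    treatment-naive baseline (flagged samples are placed above the 1-SD
    threshold, unflagged samples below it).
    """
    rng = np.random.default_rng(cfg.seed)
    patients = []
    for i in range(cfg.n_patients):
        group = "RE" if i % 2 == 0 else "NR"
        pid = f"{group}{i + 1:02d}"
        patients.append(simulate_patient(cfg, group, pid, rng))
    expression, pdl1_stats = _build_expression(cfg, patients, rng)
    return CohortSim(config=cfg, patients=patients, expression=expression,
                     pdl1_stats=pdl1_stats)


def _build_expression(cfg: SimConfig, patients: list[PatientSim],
                      rng: np.random.Generator) -> tuple[ExpressionMatrix, dict]:
    genes = sorted(
        {m.gene for p in patients for m in p.mutations if m.gene}
        | {f"GENE{i:04d}" for i in range(1, 60)}
        | {"CD274", "B2M"}
    )
    all_samples = [s.sample_id for p in patients for s in p.samples]
    base = rng.lognormal(mean=2.5, sigma=1.0, size=len(genes))
    values = np.empty((len(genes), len(all_samples)))
    for j in range(len(all_samples)):
        values[:, j] = base * rng.lognormal(mean=0.0, sigma=0.3, size=len(genes))
    df = pd.DataFrame(values, index=genes, columns=all_samples)

    naive = [s.sample_id for p in patients for s in p.samples if s.timepoint == "A"]
    pdl1_base = 20.0 + rng.normal(0.0, 2.0, size=len(naive))
    df.loc["CD274", naive] = np.clip(pdl1_base, 5.0, None)
    baseline = float(df.loc["CD274", naive].mean())
    sd = float(df.loc["CD274", naive].std(ddof=0))
    threshold = baseline + sd
    for p in patients:
        for s in p.samples:
            if s.timepoint == "A":
                continue
            if p.pdl1_over_truth[s.sample_id]:
                df.loc["CD274", s.sample_id] = threshold + float(rng.uniform(1.0, 10.0))
            else:
                df.loc["CD274", s.sample_id] = max(
                    0.5, threshold - float(rng.uniform(1.0, 10.0))
                )
    stats = {"baseline_mean": baseline, "baseline_sd": sd, "threshold": threshold}
    return ExpressionMatrix(values=df, unit="CPM"), stats


def write_cohort(sim: CohortSim, outdir) -> None:
    """Write observed tables and truth_* files as headered TSVs."""
    import os
    from . import io as cio
    from .types import mutations_to_frame, segments_to_frame

    os.makedirs(outdir, exist_ok=True)
    j = lambda name: os.path.join(outdir, name)
    cio.write_cohort([p.patient for p in sim.patients],
                     [s for p in sim.patients for s in p.samples], j("cohort.tsv"))
    mutations_to_frame([m for p in sim.patients for m in p.mutations]).to_csv(
        j("mutations.tsv"), sep="\t", index=False)
    segments_to_frame([s for p in sim.patients for s in p.segments]).to_csv(
        j("segments.tsv"), sep="\t", index=False)
    cio.write_expression(sim.expression, j("expression.tsv"))
    pd.concat([p.tcr for p in sim.patients], ignore_index=True).to_csv(
        j("tcr.tsv"), sep="\t", index=False)
    pd.concat([p.hla_loh_inputs for p in sim.patients], ignore_index=True).to_csv(
        j("hla_loh_inputs.tsv"), sep="\t", index=False)
    contexts = pd.DataFrame(
        [{"mutation_key": k, "context": v}
         for p in sim.patients for k, v in sorted(p.contexts.items())]
    ).drop_duplicates("mutation_key")
    contexts.to_csv(j("contexts.tsv"), sep="\t", index=False)
    # truth files
    pd.concat([p.truth_mutations.assign(patient_id=p.patient.patient_id)
               for p in sim.patients], ignore_index=True).to_csv(
        j("truth_mutations.tsv"), sep="\t", index=False)
    pd.concat([p.truth_presence for p in sim.patients],
              ignore_index=True).to_csv(j("truth_presence.tsv"), sep="\t", index=False)
    pd.concat([p.truth_cn for p in sim.patients], ignore_index=True).to_csv(
        j("truth_cn.tsv"), sep="\t", index=False)
    pd.concat([p.truth_escape for p in sim.patients], ignore_index=True).to_csv(
        j("truth_escape.tsv"), sep="\t", index=False)
    pd.concat([p.truth_tcr for p in sim.patients], ignore_index=True).to_csv(
        j("truth_tcr.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# synthetic signature matrix (for refitting tests and the bundled default)


def make_signature_matrix(n_signatures: int = 4, seed: int = 7,
                          concentration: float = 0.1) -> pd.DataFrame:
    """A 96-bin synthetic signature matrix (columns sum to 1) with sparse,
    distinct support per signature; labelled synthetic, not COSMIC."""
    from .epochs import TRINUC_BINS

    rng = np.random.default_rng(seed)
    cols = {}
    for k in range(n_signatures):
        w = rng.dirichlet(np.full(96, concentration))
        cols[f"SYN{k + 1}"] = w
    return pd.DataFrame(cols, index=TRINUC_BINS)
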