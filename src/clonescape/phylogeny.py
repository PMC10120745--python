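"""Maximum-parsimony phylogenies over multi-region / multi-timepoint samples.

Samples are taxa; non-tail somatic mutations are binary characters (1 =
detected in the sample). An all-zero germline outgroup roots every tree,
so somatic states are derived. Tree search is a parsimony ratchet:
hill-climbing with nearest-neighbour-interchange and subtree-pruning-
regrafting moves, alternating between a randomly upweighted and the
original character matrix. Ancestral states are resolved acctran-style
(changes pushed toward the root), which yields per-branch mutation gains,
clade lengths, driver/neoantigen annotations, a homoplasy index and
character-bootstrap supports.

Trees are represented as nested tuples of sample indices; a leaf is an
``int`` and an internal node a 2-tuple of subtrees. The implicit germline
leaf attaches above the top-level node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import MutationRecord

TreeT = Union[int, tuple]

# Fitch state sets encoded as bitmasks: 1 = {0}, 2 = {1}, 3 = {0,1}
_STATE0 = np.uint8(1)
_STATE1 = np.uint8(2)


@dataclass
class PresenceMatrix:
    """Binary samples x mutations matrix feeding the parsimony search."""

    samples: list[str]
    mutation_keys: list[str]
    matrix: np.ndarray  # shape (n_samples, n_characters), dtype uint8

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.shape != (len(self.samples), len(self.mutation_keys)):
            raise ValueError("presence matrix shape mismatch")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("presence matrix must be binary")

    @property
    def n_characters(self) -> int:
        return self.matrix.shape[1]


def build_presence_matrix(mutations_by_sample: dict[str, Sequence[MutationRecord]],
                          clonality_by_sample: Optional[dict[str, dict[str, str]]] = None,
                          tail_policy: str = "exclude") -> PresenceMatrix:
    """Build the binary presence matrix for one patient.

    ``clonality_by_sample`` maps sample -> mutation key -> label. With the
    default tail-excluded policy only mutations labelled clonal (peak) in at
    least one sample become characters; a character is then 1 in every
    sample where the mutation was detected at all. ``tail_policy="include"``
    keeps every detected mutation as a character.
    """
    if tail_policy not in ("exclude", "include"):
        raise ValueError(f"unknown tail_policy {tail_policy!r}")
    samples = sorted(mutations_by_sample)
    if len(samples) < 3:
        raise ValueError(
            f"need >= 3 samples to build a phylogeny, got {len(samples)}"
        )
    detected: dict[str, set[str]] = {}
    for sid, recs in mutations_by_sample.items():
        for r in recs:
            detected.setdefault(r.key, set()).add(sid)

    if tail_policy == "exclude":
        if clonality_by_sample is None:
            raise ValueError("tail_policy='exclude' requires clonality labels")
        keep = {
            key for key, sids in detected.items()
            if any(clonality_by_sample.get(s, {}).get(key) == "clonal" for s in sids)
        }
    else:
        keep = set(detected)

    keys = sorted(k for k in keep if detected[k])  # drop constant-zero characters
    if len(keys) < 2:
        raise ValueError(
            f"fewer than 2 variable characters after tail filtering "
            f"({len(keys)}); refusing to build a tree"
        )
    mat = np.zeros((len(samples), len(keys)), dtype=np.uint8)
    for j, key in enumerate(keys):
        for sid in detected[key]:
            mat[samples.index(sid), j] = 1
    return PresenceMatrix(samples=samples, mutation_keys=keys, matrix=mat)


# ---------------------------------------------------------------------------
# Fitch small parsimony


def _leaf_sets(matrix: np.ndarray) -> np.ndarray:
    """Per-leaf Fitch state sets: bitmask 2 where state 1, else 1."""
    return np.where(matrix == 1, _STATE1, _STATE0)


def _fitch(tree: TreeT, leaf_sets: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, float]:
    if isinstance(tree, int):
        return leaf_sets[tree], 0.0
    sl, cl = _fitch(tree[0], leaf_sets, weights)
    sr, cr = _fitch(tree[1], leaf_sets, weights)
    inter = sl & sr
    union_mask = inter == 0
    out = np.where(union_mask, sl | sr, inter)
    return out, cl + cr + float(weights[union_mask].sum())


def parsimony_score(tree: TreeT, pm: PresenceMatrix,
                    weights: Optional[np.ndarray] = None) -> float:
    """Weighted Fitch parsimony count with the germline fixed to 0 at the root.

    With unit weights the result is the integer parsimony score.
    """
    if weights is None:
        weights = np.ones(pm.n_characters)
    leaf_sets = _leaf_sets(pm.matrix)
    root_set, changes = _fitch(tree, leaf_sets, weights)
    # join with the all-zero germline leaf above the root
    germline_conflict = (root_set & _STATE0) == 0
    return changes + float(weights[germline_conflict].sum())


def homoplasy_index(tree: TreeT, pm: PresenceMatrix) -> float:
    """HI = 1 - (minimum possible changes / observed score); 0 for a
    perfect phylogeny. Minimum = number of variable binary characters."""
    score = parsimony_score(tree, pm)
    min_changes = pm.n_characters
    return 1.0 - min_changes / score if score > 0 else 0.0


# ---------------------------------------------------------------------------
# tree manipulation


def tree_leaves(tree: TreeT) -> list[int]:
    if isinstance(tree, int):
        return [tree]
    return tree_leaves(tree[0]) + tree_leaves(tree[1])


def canonical(tree: TreeT) -> TreeT:
    """Canonical child order: subtree with the smallest leaf index first."""
    if isinstance(tree, int):
        return tree
    a, b = canonical(tree[0]), canonical(tree[1])
    if min(tree_leaves(a)) > min(tree_leaves(b)):
        a, b = b, a
    return (a, b)


def tree_newick(tree: TreeT, names: Sequence[str]) -> str:
    """Newick under the canonical leaf order (used for tie-breaking)."""
    def _fmt(t: TreeT) -> str:
        if isinstance(t, int):
            return names[t]
        return f"({_fmt(t[0])},{_fmt(t[1])})"
    return _fmt(canonical(tree)) + ";"


def _prunings(tree: TreeT) -> Iterator[tuple[TreeT, TreeT]]:
    """All (pruned subtree, remainder) decompositions of a tree."""
    if isinstance(tree, int):
        return
    left, right = tree
    yield left, right
    yield right, left
    for sub, rem in _prunings(left):
        yield sub, (rem, right)
    for sub, rem in _prunings(right):
        yield sub, (left, rem)


def _insertions(tree: TreeT, sub: TreeT) -> Iterator[TreeT]:
    """All trees with ``sub`` regrafted onto each edge of ``tree`` (the
    top-level yield attaches on the germline edge)."""
    yield (tree, sub)
    if isinstance(tree, tuple):
        for t in _insertions(tree[0], sub):
            yield (t, tree[1])
        for t in _insertions(tree[1], sub):
            yield (tree[0], t)


def spr_neighbors(tree: TreeT) -> list[TreeT]:
    """Subtree-prune-regraft neighbourhood (includes all NNI moves)."""
    seen: set[TreeT] = set()
    out: list[TreeT] = []
    for sub, rem in _prunings(tree):
        for t in _insertions(rem, sub):
            c = canonical(t)
            if c not in seen:
                seen.add(c)
                out.append(c)
    return out


def nni_neighbors(tree: TreeT) -> list[TreeT]:
    """Nearest-neighbour-interchange neighbourhood (rooted form: swap a
    child of an internal node with its uncle)."""
    results: set[TreeT] = set()

    def _walk(t: TreeT) -> Iterator[TreeT]:
        if isinstance(t, int):
            return
        left, right = t
        for side, (inner, other) in enumerate(((left, right), (right, left))):
            if isinstance(inner, tuple):
                a, b = inner
                yield ((a, other), b)
                yield ((b, other), a)
        for alt in _walk(left):
            yield (alt, right)
        for alt in _walk(right):
            yield (left, alt)

    for t in _walk(tree):
        results.add(canonical(t))
    results.discard(canonical(tree))
    return sorted(results, key=lambda t: repr(t))


# ---------------------------------------------------------------------------
# search


def _starting_tree(pm: PresenceMatrix) -> TreeT:
    """Average-linkage joining tree on Hamming distances between samples."""
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    n = len(pm.samples)
    if n == 1:
        return 0
    dist = pdist(pm.matrix.astype(float), metric="hamming")
    link = hierarchy.linkage(dist, method="average")
    nodes: dict[int, TreeT] = {i: i for i in range(n)}
    for i, (a, b, _, _) in enumerate(link):
        nodes[n + i] = (nodes[int(a)], nodes[int(b)])
    return canonical(nodes[n + len(link) - 1])


def _hill_climb(tree: TreeT, pm: PresenceMatrix, weights: np.ndarray,
                plateau_budget: int = 64) -> tuple[TreeT, float]:
    """Steepest-descent search over the SPR neighbourhood (which contains
    all NNI rearrangements) with bounded plateau drift: when no move
    improves the score, up to ``plateau_budget`` equal-score trees are
    explored breadth-first before giving up, since parsimony landscapes
    are rich in plateaus. Deterministic; ties resolve to the
    lexicographically smallest canonical newick."""
    names = pm.samples
    current = canonical(tree)
    best_score = parsimony_score(current, pm, weights)
    frontier = [current]
    visited = {current}
    while True:
        improving: list[tuple[float, TreeT]] = []
        plateau: list[TreeT] = []
        for t in frontier:
            for cand in spr_neighbors(t):
                s = parsimony_score(cand, pm, weights)
                if s < best_score - 1e-12:
                    improving.append((s, cand))
                elif (abs(s - best_score) <= 1e-12 and cand not in visited
                      and len(visited) < plateau_budget):
                    visited.add(cand)
                    plateau.append(cand)
        if improving:
            s, cand = min(improving,
                          key=lambda x: (x[0], tree_newick(x[1], names)))
            best_score = s
            frontier = [cand]
            visited = {cand}
        elif plateau:
            frontier = plateau
        else:
            best = min(visited, key=lambda t: tree_newick(t, names))
            return best, best_score


@dataclass
class PhyloTree:
    """Result of a parsimony search for one patient."""

    samples: list[str]
    tree: TreeT
    score: int
    homoplasy: float
    mutation_keys: list[str]
    branch_changes: dict[frozenset, dict[str, list[str]]] = field(default_factory=dict)
    bootstrap_support: dict[frozenset, float] = field(default_factory=dict)
    branch_drivers: dict[frozenset, list[str]] = field(default_factory=dict)
    branch_neoantigen_counts: dict[frozenset, int] = field(default_factory=dict)

    def clades(self) -> list[frozenset]:
        """Leaf sets below each internal node (including the full ingroup)."""
        out: list[frozenset] = []

        def _walk(t: TreeT) -> frozenset:
            if isinstance(t, int):
                return frozenset([self.samples[t]])
            s = _walk(t[0]) | _walk(t[1])
            out.append(s)
            return s

        top = _walk(self.tree)
        if top not in out:
            out.append(top)
        return out


def ratchet_search(pm: PresenceMatrix, min_iter: int = 10, max_iter: int = 1000,
                   patience: int = 10, seed: int = 0,
                   reweight_fraction: float = 0.25) -> PhyloTree:
    """Parsimony-ratchet search.

    Each iteration doubles the weight of a random ~25% of characters,
    hill-climbs on the weighted matrix, re-optimises on the original
    weights, and accepts improvements. Runs at least ``min_iter``
    iterations; stops after ``patience`` iterations without improvement or
    at ``max_iter``. Deterministic under a fixed seed; among equally
    parsimonious trees the lexicographically smallest canonical newick wins.
    """
    rng = np.random.default_rng(seed)
    ones = np.ones(pm.n_characters)
    best, best_score = _hill_climb(_starting_tree(pm), pm, ones)
    best_newick = tree_newick(best, pm.samples)
    stale = 0
    for iteration in range(1, max_iter + 1):
        n_up = max(1, int(round(reweight_fraction * pm.n_characters)))
        idx = rng.choice(pm.n_characters, size=n_up, replace=False)
        weights = ones.copy()
        weights[idx] = 2.0
        # random SPR kick before the weighted climb, for search diversity
        kicks = spr_neighbors(best)
        start = kicks[int(rng.integers(len(kicks)))] if kicks else best
        perturbed, _ = _hill_climb(start, pm, weights)
        cand, cand_score = _hill_climb(perturbed, pm, ones)
        improved = False
        if cand_score < best_score - 1e-12:
            improved = True
        elif abs(cand_score - best_score) <= 1e-12:
            nwk = tree_newick(cand, pm.samples)
            if nwk < best_newick:
                best, best_newick = cand, nwk
        if improved:
            best, best_score = cand, cand_score
            best_newick = tree_newick(best, pm.samples)
            stale = 0
        else:
            stale += 1
        if iteration >= min_iter and stale >= patience:
            break
    score = int(round(best_score))
    result = PhyloTree(
        samples=list(pm.samples), tree=best, score=score,
        homoplasy=homoplasy_index(best, pm),
        mutation_keys=list(pm.mutation_keys),
    )
    result.branch_changes = acctran_assign(best, pm)
    return result


# ---------------------------------------------------------------------------
# acctran ancestral states


def acctran_assign(tree: TreeT, pm: PresenceMatrix) -> dict[frozenset, dict[str, list[str]]]:
    """Accelerated-transformation assignment of character changes to branches.

    Fitch up-pass state sets are resolved root-to-tip: a node takes its
    parent's state whenever that state is in its first-pass set, otherwise
    its own unique state (placing the change on the edge, as rootward as
    the reconstruction allows). The germline root is fixed to state 0.
    Branches are keyed by the sample set of the child clade; the branch from
    the germline root is keyed by the full ingroup. Values are
    ``{"gained": [...], "lost": [...]}`` mutation-key lists.
    """
    leaf_sets = _leaf_sets(pm.matrix)
    up: dict[int, np.ndarray] = {}
    children: dict[int, tuple[int, int]] = {}
    clade_of: dict[int, frozenset] = {}
    counter = [len(pm.samples)]

    def _up(t: TreeT) -> int:
        if isinstance(t, int):
            up[t] = leaf_sets[t]
            clade_of[t] = frozenset([pm.samples[t]])
            return t
        lid, rid = _up(t[0]), _up(t[1])
        nid = counter[0]
        counter[0] += 1
        inter = up[lid] & up[rid]
        up[nid] = np.where(inter == 0, up[lid] | up[rid], inter)
        children[nid] = (lid, rid)
        clade_of[nid] = clade_of[lid] | clade_of[rid]
        return nid

    root = _up(tree)
    n_chars = pm.n_characters
    final: dict[int, np.ndarray] = {}

    # germline ancestor is state 0; root takes 0 where possible, else 1
    root_set = up[root]
    final[root] = np.where((root_set & _STATE0) != 0, 0, 1).astype(np.int8)

    order = [root]
    stack = [root]
    while stack:
        nid = stack.pop()
        for cid in children.get(nid, ()):
            parent_state = final[nid]
            child_set = up[cid]
            parent_mask = np.where(parent_state == 0, _STATE0, _STATE1)
            has_parent = (child_set & parent_mask) != 0
            own = np.where((child_set & _STATE1) != 0, 1, 0).astype(np.int8)
            final[cid] = np.where(has_parent, parent_state, own)
            stack.append(cid)
            order.append(cid)

    branches: dict[frozenset, dict[str, list[str]]] = {}
    # branch from germline to root
    keys = pm.mutation_keys
    branches[clade_of[root]] = {
        "gained": [keys[j] for j in range(n_chars) if final[root][j] == 1],
        "lost": [],
    }
    for nid in order:
        for cid in children.get(nid, ()):
            gained = [keys[j] for j in range(n_chars)
                      if final[nid][j] == 0 and final[cid][j] == 1]
            lost = [keys[j] for j in range(n_chars)
                    if final[nid][j] == 1 and final[cid][j] == 0]
            branches[clade_of[cid]] = {"gained": gained, "lost": lost}
    return branches


def branch_change_counts(branches: dict[frozenset, dict[str, list[str]]]) -> dict[frozenset, int]:
    return {clade: len(d["gained"]) + len(d["lost"]) for clade, d in branches.items()}


def annotate_clades(result: PhyloTree,
                    mutation_annotations: dict[str, MutationRecord]) -> PhyloTree:
    """Attach driver-gene lists and neoantigenic-SNV counts to branches,
    based on the mutations gained on each branch."""
    result.branch_drivers = {}
    result.branch_neoantigen_counts = {}
    for clade, changes in result.branch_changes.items():
        drivers = []
        neo = 0
        for key in changes["gained"]:
            rec = mutation_annotations.get(key)
            if rec is None:
                continue
            if rec.is_driver and rec.gene:
                drivers.append(rec.gene)
            if rec.is_neoantigenic and rec.is_snv:
                neo += 1
        result.branch_drivers[clade] = sorted(set(drivers))
        result.branch_neoantigen_counts[clade] = neo
    return result


def bootstrap(result: PhyloTree, pm: PresenceMatrix, n_reps: int = 100,
              seed: int = 0, search_kwargs: Optional[dict] = None) -> PhyloTree:
    """Character bootstrap: resample columns with replacement, re-run the
    ratchet, and report per-clade support as the replicate frequency."""
    rng = np.random.default_rng(seed)
    kwargs = {"min_iter": 5, "max_iter": 50, "patience": 5}
    if search_kwargs:
        kwargs.update(search_kwargs)
    clades = [c for c in result.clades() if len(c) > 1]
    hits = {c: 0 for c in clades}
    for rep in range(n_reps):
        idx = rng.integers(0, pm.n_characters, size=pm.n_characters)
        sub = PresenceMatrix(
            samples=pm.samples,
            mutation_keys=[f"c{j}" for j in range(pm.n_characters)],
            matrix=pm.matrix[:, idx],
        )
        rep_tree = ratchet_search(sub, seed=int(rng.integers(0, 2**31 - 1)), **kwargs)
        rep_clades = set(rep_tree.clades())
        for c in clades:
            if c in rep_clades:
                hits[c] += 1
    result.bootstrap_support = {c: hits[c] / n_reps for c in clades}
    return result


# ---------------------------------------------------------------------------
# output


def to_newick(result: PhyloTree, with_annotations: bool = True) -> str:
    """Newick with branch lengths = change counts; internal-node labels carry
    bootstrap support and branch comments carry driver genes."""
    counts = branch_change_counts(result.branch_changes)

    def _clade(t: TreeT) -> frozenset:
        return frozenset(result.samples[i] for i in tree_leaves(t))

    def _fmt(t: TreeT) -> str:
        clade = _clade(t)
        length = counts.get(clade, 0)
        comment = ""
        if with_annotations:
            drivers = result.branch_drivers.get(clade, [])
            neo = result.branch_neoantigen_counts.get(clade)
            bits = []
            if drivers:
                bits.append("drivers=" + "|".join(drivers))
            if neo:
                bits.append(f"neoSNVs={neo}")
            if bits:
                comment = "[&" + ",".join(bits) + "]"
        if isinstance(t, int):
            return f"{result.samples[t]}:{length}{comment}"
        inner = ",".join(_fmt(c) for c in canonical(t))
        support = result.bootstrap_support.get(clade)
        label = f"{support * 100:.0f}" if support is not None else ""
        return f"({inner}){label}:{length}{comment}"

    return f"({_fmt(canonical(result.tree))},germline:0);"


def clade_mutations_frame(result: PhyloTree) -> pd.DataFrame:
    """Tabular per-branch mutation assignment (clade, direction, key)."""
    rows = []
    for clade in sorted(result.branch_changes, key=lambda c: (len(c), sorted(c))):
        changes = result.branch_changes[clade]
        for direction in ("gained", "lost"):
            for key in changes[direction]:
                rows.append({
                    "clade": "|".join(sorted(clade)),
                    "direction": direction,
                    "mutation_key": key,
                })
    return pd.DataFrame(rows, columns=["clade", "direction", "mutation_key"])
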