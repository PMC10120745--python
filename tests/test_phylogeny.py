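"""Parsimony: Fitch counting vs brute force, ratchet vs exhaustive
enumeration, acctran placement, clade annotation and bootstrap."""

import numpy as np
import pytest

from clonescape.phylogeny import (
    PresenceMatrix,
    acctran_assign,
    annotate_clades,
    bootstrap,
    branch_change_counts,
    build_presence_matrix,
    homoplasy_index,
    parsimony_score,
    ratchet_search,
    to_newick,
    tree_newick,
)
from clonescape.types import MutationRecord
from conftest import all_rooted_trees, sankoff_min_changes


def _pm(matrix, samples=None):
    matrix = np.asarray(matrix, dtype=np.uint8)
    samples = samples or [f"S{i}" for i in range(matrix.shape[0])]
    return PresenceMatrix(samples, [f"m{j}" for j in range(matrix.shape[1])], matrix)


def perfect_matrix():
    """4 samples, compatible characters only: 12 truncal, 12 per internal
    clade ({S0,S1} and {S0,S1,S2}), 3 private per sample."""
    cols = ([[1, 1, 1, 1]] * 12 + [[1, 1, 0, 0]] * 12 + [[1, 1, 1, 0]] * 12 +
            [[1, 0, 0, 0]] * 3 + [[0, 1, 0, 0]] * 3 +
            [[0, 0, 1, 0]] * 3 + [[0, 0, 0, 1]] * 3)
    return _pm(np.array(cols).T)


class TestPresenceMatrix:
    def test_construction_pattern(self):
        def mut(pos, sid):
            return MutationRecord(chrom="chr1", pos=pos, ref="C", alt="A",
                                  sample_id=sid, ref_count=90, alt_count=10)

        shared = list(range(100, 105))
        by_sample = {
            f"S{i}": [mut(p, f"S{i}") for p in shared] + [mut(200 + i, f"S{i}")]
            for i in range(3)
        }
        labels = {s: {m.key: "clonal" for m in recs} for s, recs in by_sample.items()}
        pm = build_presence_matrix(by_sample, labels)
        assert pm.n_characters == 8
        assert pm.matrix.sum() == 5 * 3 + 3  # truncal in all, privates once

    def test_all_tail_refused(self):
        def mut(pos, sid):
            return MutationRecord(chrom="chr1", pos=pos, ref="C", alt="A",
                                  sample_id=sid, ref_count=90, alt_count=10)

        by_sample = {f"S{i}": [mut(100 + i, f"S{i}")] for i in range(3)}
        labels = {s: {m.key: "subclonal" for m in recs} for s, recs in by_sample.items()}
        with pytest.raises(ValueError, match="variable characters"):
            build_presence_matrix(by_sample, labels)

    def test_two_samples_refused(self):
        with pytest.raises(ValueError, match=">= 3 samples"):
            build_presence_matrix({"S0": [], "S1": []}, {}, tail_policy="include")


class TestParsimonyScore:
    def test_perfect_phylogeny_score_is_character_count(self):
        pm = perfect_matrix()
        tree = (((0, 1), 2), 3)
        assert parsimony_score(tree, pm) == pm.n_characters

    def test_ubiquitous_character_costs_one(self):
        pm = _pm([[1], [1], [1], [1]])
        assert parsimony_score(((0, 1), (2, 3)), pm) == 1

    def test_matches_brute_force_sankoff(self):
        """Random 5x10 matrices: Fitch count equals exhaustive minimum over
        internal state assignments on the same tree."""
        rng = np.random.default_rng(7)
        for trial in range(25):
            mat = rng.integers(0, 2, size=(5, 10)).astype(np.uint8)
            mat[:, mat.sum(0) == 0] = 0
            keep = mat.sum(0) > 0
            if keep.sum() < 2:
                continue
            pm = _pm(mat[:, keep])
            trees = all_rooted_trees(5)
            tree = trees[int(rng.integers(len(trees)))]
            assert parsimony_score(tree, pm) == sankoff_min_changes(tree, pm.matrix)


class TestRatchet:
    def test_oracle_equivalence_small(self):
        """Ratchet score equals the exhaustive minimum on random matrices
        (the full 200-matrix sweep runs in the acceptance suite)."""
        rng = np.random.default_rng(1)
        for trial in range(20):
            n = int(rng.integers(4, 7))
            mat = rng.integers(0, 2, size=(n, int(rng.integers(4, 16)))).astype(np.uint8)
            mat = mat[:, mat.sum(0) > 0]
            if mat.shape[1] < 2:
                continue
            pm = _pm(mat)
            oracle = min(parsimony_score(t, pm) for t in all_rooted_trees(n))
            assert ratchet_search(pm, seed=trial).score == int(oracle)

    def test_perfect_phylogeny_recovers_truth(self):
        pm = perfect_matrix()
        res = ratchet_search(pm, seed=0)
        assert res.score == pm.n_characters
        assert homoplasy_index(res.tree, pm) == 0.0
        assert frozenset({"S0", "S1"}) in res.clades()

    def test_fixed_seed_deterministic(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(0, 2, size=(5, 12)).astype(np.uint8)
        mat = mat[:, mat.sum(0) > 0]
        pm = _pm(mat)
        t1 = ratchet_search(pm, seed=42)
        t2 = ratchet_search(pm, seed=42)
        assert tree_newick(t1.tree, pm.samples) == tree_newick(t2.tree, pm.samples)
        assert t1.score == t2.score

    def test_pruning_leaf_never_increases_score(self):
        rng = np.random.default_rng(4)
        mat = rng.integers(0, 2, size=(5, 10)).astype(np.uint8)
        mat = mat[:, mat.sum(0) > 0]
        pm = _pm(mat)
        full = ratchet_search(pm, seed=0).score
        sub = mat[:4, :]
        sub = sub[:, sub.sum(0) > 0]
        if sub.shape[1] >= 2:
            pruned = ratchet_search(_pm(sub), seed=0).score
            assert pruned <= full


class TestIndependentReference:
    def test_matches_phangorn_ratchet_score(self, tmp_path):
        """Cross-check against an independent parsimony-ratchet
        implementation (phangorn's pratchet/fitch via Rscript) on a random
        binary matrix with the germline outgroup as an explicit taxon."""
        import subprocess

        rng = np.random.default_rng(0)
        mat = rng.integers(0, 2, size=(5, 10)).astype(np.uint8)
        mat = mat[:, mat.sum(0) > 0]
        n, k = mat.shape
        phy = tmp_path / "m.phy"
        lines = [f" {n + 1} {k}", "germline  " + "0" * k]
        lines += [f"S{i}  " + "".join(map(str, mat[i])) for i in range(n)]
        phy.write_text("\n".join(lines) + "\n")
        rscript = (
            'suppressMessages(library(phangorn));'
            f'd <- read.phyDat("{phy}", format="phylip", type="USER",'
            ' levels=c("0","1"));'
            'tree <- pratchet(d, trace=0, minit=10, maxit=100, k=10);'
            'cat(fitch(tree, d))'
        )
        proc = subprocess.run(["Rscript", "-e", rscript],
                              capture_output=True, text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr
        reference = int(proc.stdout.strip().split()[-1])
        ours = ratchet_search(_pm(mat), seed=0).score
        assert ours == reference


class TestAcctran:
    def test_truncal_assigned_to_germline_branch(self):
        pm = perfect_matrix()
        branches = acctran_assign((((0, 1), 2), 3), pm)
        root_clade = frozenset(pm.samples)
        assert set(branches[root_clade]["gained"]) == {f"m{j}" for j in range(12)}

    def test_changes_sum_to_score(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            mat = rng.integers(0, 2, size=(5, 8)).astype(np.uint8)
            mat = mat[:, mat.sum(0) > 0]
            if mat.shape[1] < 2:
                continue
            pm = _pm(mat)
            res = ratchet_search(pm, seed=trial)
            total = sum(branch_change_counts(res.branch_changes).values())
            assert total == res.score

    def test_four_taxon_homoplasy_hand_case(self):
        """Character in two non-sister leaves: the unique minimum
        reconstruction places independent gains on both terminal branches."""
        pm = _pm([[1], [0], [1], [0]], samples=["A", "B", "C", "D"])
        tree = ((0, 1), (2, 3))
        assert parsimony_score(tree, pm) == 2
        branches = acctran_assign(tree, pm)
        assert branches[frozenset({"A"})]["gained"] == ["m0"]
        assert branches[frozenset({"C"})]["gained"] == ["m0"]
        assert branches[frozenset({"A", "B"})]["gained"] == []
        assert branches[frozenset({"C", "D"})]["gained"] == []


class TestAnnotation:
    def _records(self, driver=False, neo=False):
        return {
            f"m{j}": MutationRecord(
                chrom="chr1", pos=100 + j, ref="C", alt="A", sample_id="S0",
                ref_count=90, alt_count=10, gene=f"G{j}",
                is_driver=driver, is_neoantigenic=neo)
            for j in range(48)
        }

    def test_no_drivers_empty_labels(self):
        pm = perfect_matrix()
        res = ratchet_search(pm, seed=0)
        res = annotate_clades(res, self._records(driver=False))
        assert all(not v for v in res.branch_drivers.values())

    def test_neoantigen_counts_conserve(self):
        pm = perfect_matrix()
        res = ratchet_search(pm, seed=0)
        res = annotate_clades(res, self._records(neo=True))
        assert sum(res.branch_neoantigen_counts.values()) == pm.n_characters

    def test_newick_contains_supports_and_lengths(self):
        pm = perfect_matrix()
        res = ratchet_search(pm, seed=0)
        res = annotate_clades(res, self._records())
        res = bootstrap(res, pm, n_reps=10, seed=0)
        nwk = to_newick(res)
        assert nwk.endswith("germline:0);")
        assert ":12" in nwk  # truncal branch length


class TestBootstrapAndHI:
    def test_perfect_phylogeny_full_support(self):
        pm = perfect_matrix()
        res = ratchet_search(pm, seed=0)
        res = bootstrap(res, pm, n_reps=30, seed=1)
        assert all(v == 1.0 for v in res.bootstrap_support.values())

    def test_homoplasy_hand_value(self):
        """One character needing 2 changes among 9 needing 1: HI = 1 - 10/11."""
        base = np.array([[1, 1, 1, 1]] * 3 + [[1, 1, 0, 0]] * 2 +
                        [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]]).T
        conflict = np.array([[1, 0, 1, 0]]).T
        pm = _pm(np.hstack([base, conflict]))
        tree = (((0, 1), 2), 3)
        assert parsimony_score(tree, pm) == 11
        assert homoplasy_index(tree, pm) == pytest.approx(1 - 10 / 11)

    def test_hi_bounds(self):
        rng = np.random.default_rng(6)
        for trial in range(10):
            mat = rng.integers(0, 2, size=(5, 8)).astype(np.uint8)
            mat = mat[:, mat.sum(0) > 0]
            if mat.shape[1] < 2:
                continue
            pm = _pm(mat)
            res = ratchet_search(pm, seed=trial)
            hi = homoplasy_index(res.tree, pm)
            assert 0.0 <= hi < 1.0
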