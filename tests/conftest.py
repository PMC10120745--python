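import numpy as np
import pytest

from clonescape.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-patient cohort simulated once per session."""
    return simulate_cohort(SimConfig(seed=11, n_patients=4))


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    """The small cohort written to disk in the canonical directory layout."""
    from clonescape.simulate import write_cohort

    outdir = tmp_path_factory.mktemp("cohort")
    write_cohort(small_cohort, outdir)
    return outdir


# ---------------------------------------------------------------------------
# phylogeny oracles (independent of the search code)


def all_rooted_trees(n_leaves: int):
    """Exhaustive enumeration of rooted binary trees over leaves 0..n-1
    (stepwise leaf addition; (2n-3)!! trees)."""
    trees = [0]
    for leaf in range(1, n_leaves):
        new = []
        for t in trees:
            new.extend(_insert_everywhere(t, leaf))
        trees = new
    return trees


def _insert_everywhere(t, leaf):
    out = [(t, leaf)]
    if isinstance(t, tuple):
        out += [(x, t[1]) for x in _insert_everywhere(t[0], leaf)]
        out += [(t[0], x) for x in _insert_everywhere(t[1], leaf)]
    return out


def sankoff_min_changes(tree, matrix) -> int:
    """Brute-force small parsimony: enumerate every internal 0/1 state
    assignment per character and count the minimum number of edge changes,
    with a germline state-0 node above the root."""
    internal = []

    def _collect(t):
        if isinstance(t, tuple):
            internal.append(t)
            _collect(t[0])
            _collect(t[1])

    _collect(tree)
    n_char = matrix.shape[1]
    total = 0
    for j in range(n_char):
        best = None
        for bits in range(2 ** max(len(internal), 1)):
            states = {id(t): (bits >> i) & 1 for i, t in enumerate(internal)}

            def _state(t):
                return matrix[t, j] if isinstance(t, int) else states[id(t)]

            changes = 0
            stack = [tree]
            while stack:
                t = stack.pop()
                if isinstance(t, tuple):
                    for c in t:
                        changes += _state(c) != _state(t)
                        stack.append(c)
            changes += _state(tree) != 0  # germline edge
            if best is None or changes < best:
                best = changes
        total += best
    return total
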