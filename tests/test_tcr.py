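"""TCR normalisation, size distributions, expansion detection/tracking and
group comparisons."""

import numpy as np
import pandas as pd
import pytest

from clonescape.tcr import (
    compare_expansion_counts,
    detect_expansions,
    events_frame,
    expansion_counts,
    normalise,
    size_distribution,
    track_expansions,
)


def table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "chain", "clone_id", "count"])


class TestNormalise:
    def test_single_clone_full_million(self):
        out = normalise(table([("S1", "alpha", "c1", 5)]))
        assert out["per_million"].iloc[0] == 1e6

    def test_proportions(self):
        out = normalise(table([("S1", "alpha", "c1", 1),
                               ("S1", "alpha", "c2", 1),
                               ("S1", "alpha", "c3", 2)]))
        assert sorted(out["per_million"]) == [250_000, 250_000, 500_000]

    def test_scale_invariance(self):
        t1 = table([("S1", "alpha", "c1", 3), ("S1", "alpha", "c2", 7)])
        t2 = t1.assign(count=t1["count"] * 10)
        pd.testing.assert_series_equal(normalise(t1)["per_million"],
                                       normalise(t2)["per_million"])

    def test_sums_to_million_per_sample_chain(self):
        rng = np.random.default_rng(0)
        rows = [("S1", ch, f"c{i}", int(rng.integers(1, 100)))
                for ch in ("alpha", "beta") for i in range(50)]
        out = normalise(table(rows))
        sums = out.groupby(["sample_id", "chain"])["per_million"].sum()
        assert np.allclose(sums, 1e6)


class TestSizeDistribution:
    def test_all_singletons_one_bin(self):
        out = size_distribution(normalise(table(
            [("S1", "alpha", f"c{i}", 1) for i in range(5)])))
        assert len(out) == 1 and out.iloc[0].proportion == 1.0

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(1)
        rows = [("S1", "alpha", f"c{i}", int(rng.integers(1, 50)))
                for i in range(200)]
        out = size_distribution(normalise(table(rows)))
        assert out["proportion"].sum() == pytest.approx(1.0)


def two_tp(counts_a, counts_b):
    rows = [("A1", "alpha", cid, c) for cid, c in counts_a.items()]
    rows += [("B1", "alpha", cid, c) for cid, c in counts_b.items()]
    return normalise(table(rows))


class TestDetectExpansions:
    def test_fold_five_passes_four_only(self):
        norm = two_tp({"c1": 10, "bg": 90}, {"c1": 50, "bg": 50})
        events = detect_expansions(norm, "P1", "A1", "B1", "A", "B")
        ev = {e.clone_id: e for e in events}
        assert ev["c1"].fold == pytest.approx(5.0)
        assert ev["c1"].thresholds_passed == frozenset({4.0})

    def test_fold_eight_boundary_inclusive(self):
        norm = two_tp({"c1": 10, "bg": 90}, {"c1": 80, "bg": 20})
        events = detect_expansions(norm, "P1", "A1", "B1", "A", "B")
        ev = {e.clone_id: e for e in events}
        assert ev["c1"].thresholds_passed == frozenset({4.0, 8.0})

    def test_eight_set_subset_of_four_set(self):
        rng = np.random.default_rng(2)
        ca = {f"c{i}": int(rng.integers(1, 50)) for i in range(100)}
        cb = {f"c{i}": int(rng.integers(1, 200)) for i in range(100)}
        events = detect_expansions(two_tp(ca, cb), "P1", "A1", "B1", "A", "B")
        set8 = {e.clone_id for e in events if 8.0 in e.thresholds_passed}
        set4 = {e.clone_id for e in events if 4.0 in e.thresholds_passed}
        assert set8 <= set4

    def test_de_novo_clone_uses_floor(self):
        norm = two_tp({"bg": 100}, {"new": 10, "bg": 90})
        events = detect_expansions(norm, "P1", "A1", "B1", "A", "B")
        ev = {e.clone_id: e for e in events}
        assert ev["new"].de_novo
        # floor = 0.5/100 * 1e6 = 5000 pm; new clone at 1e5 pm -> fold 20
        assert ev["new"].fold == pytest.approx(20.0)

    def test_min_later_count_suppresses_singletons(self):
        norm = two_tp({"bg": 100}, {"new": 1, "bg": 99})
        events = detect_expansions(norm, "P1", "A1", "B1", "A", "B")
        assert all(e.clone_id != "new" for e in events)


class TestTrackExpansions:
    def _norm3(self):
        rows = [("A1", "alpha", "c1", 10), ("A1", "alpha", "bg", 990),
                ("B1", "alpha", "c1", 20), ("B1", "alpha", "bg", 980),
                ("C1", "alpha", "c1", 80), ("C1", "alpha", "bg", 920)]
        return normalise(table(rows))

    def test_anchored_trajectory(self):
        out = track_expansions(self._norm3(), "P1",
                               {"A": "A1", "B": "B1", "C": "C1"})
        c1 = out[out["clone_id"] == "c1"].set_index("timepoint")
        assert c1.loc["A", "per_million"] == pytest.approx(10_000)
        assert c1.loc["B", "per_million"] == pytest.approx(20_000)
        assert c1.loc["C", "per_million"] == pytest.approx(80_000)
        assert (c1["fold_anchor"] >= 8.0).all()

    def test_no_expansions_empty(self):
        rows = [(f"{tp}1", "alpha", "c1", 100) for tp in "ABC"]
        out = track_expansions(normalise(table(rows)), "P1",
                               {"A": "A1", "B": "B1", "C": "C1"})
        assert out.empty

    def test_missing_timepoint_warns_and_restricts(self):
        rows = [("A1", "alpha", "c1", 10), ("C1", "alpha", "c1", 80)]
        with pytest.warns(UserWarning, match="missing"):
            out = track_expansions(normalise(table(rows)), "P1",
                                   {"A": "A1", "C": "C1"}, anchor=("A", "B"))
        assert out.empty

    def test_summed_proportion_bounded(self):
        out = track_expansions(self._norm3(), "P1",
                               {"A": "A1", "B": "B1", "C": "C1"})
        sums = out.groupby("timepoint")["per_million"].sum()
        assert (sums <= 1e6 + 1e-6).all() and (sums >= 0).all()


class TestCompareCounts:
    def _counts(self, by_patient):
        rows = []
        for pid, n in by_patient.items():
            rows.append({"patient_id": pid, "from_tp": "A", "to_tp": "C",
                         "chain": "alpha", "fold_threshold": 4.0, "n_expanded": n})
        return pd.DataFrame(rows)

    def test_identical_groups_p_one(self):
        counts = self._counts({"P1": 5, "P2": 5, "P3": 5, "P4": 5})
        groups = pd.Series({"P1": "RE", "P2": "RE", "P3": "NR", "P4": "NR"})
        out = compare_expansion_counts(counts, groups)
        assert out.iloc[0].p_value == pytest.approx(1.0)

    def test_separated_small_groups_u_closed_form(self):
        """{10,12,11} vs {0,1,0}: complete separation gives U = 0 (or n1*n2)
        by the closed form U = R1 - n1(n1+1)/2; a two-sided exact test on
        3 vs 3 bottoms out at p = 0.1, so only ordering is asserted here."""
        counts = self._counts({"P1": 10, "P2": 12, "P3": 11,
                               "P4": 0, "P5": 1, "P6": 0})
        groups = pd.Series({"P1": "RE", "P2": "RE", "P3": "RE",
                            "P4": "NR", "P5": "NR", "P6": "NR"})
        out = compare_expansion_counts(counts, groups)
        row = out.iloc[0]
        medians = {row.group_a: row.median_a, row.group_b: row.median_b}
        assert medians["RE"] > medians["NR"]
        assert row.statistic in (0.0, 9.0)  # complete separation
        assert row.p_value <= 0.1

    def test_separated_groups_significant(self):
        counts = self._counts({f"P{i}": 10 + i for i in range(5)}
                              | {f"Q{i}": i % 2 for i in range(5)})
        groups = pd.Series({f"P{i}": "RE" for i in range(5)}
                           | {f"Q{i}": "NR" for i in range(5)})
        out = compare_expansion_counts(counts, groups)
        assert out.iloc[0].p_value < 0.05

    def test_rank_invariance_under_doubling(self):
        counts = self._counts({"P1": 3, "P2": 9, "P3": 1, "P4": 6})
        groups = pd.Series({"P1": "RE", "P2": "RE", "P3": "NR", "P4": "NR"})
        u1 = compare_expansion_counts(counts, groups).iloc[0].statistic
        doubled = counts.assign(n_expanded=counts["n_expanded"] * 2)
        u2 = compare_expansion_counts(doubled, groups).iloc[0].statistic
        assert u1 == u2

    def test_degenerate_group_skipped_with_warning(self):
        counts = self._counts({"P1": 5, "P2": 6, "P3": 7})
        groups = pd.Series({"P1": "RE", "P2": "RE", "P3": "NR"})
        with pytest.warns(UserWarning, match="degenerate"):
            out = compare_expansion_counts(counts, groups)
        assert out.empty

    def test_null_p_values_near_uniform(self):
        """Label permutation: the Mann-Whitney p-values are approximately
        uniform under the null (calibration of the comparison)."""
        rng = np.random.default_rng(3)
        base = {f"P{i}": int(rng.integers(0, 20)) for i in range(12)}
        counts = self._counts(base)
        pvals = []
        pids = list(base)
        for _ in range(300):
            rng.shuffle(pids)
            groups = pd.Series({p: ("RE" if i < 6 else "NR")
                                for i, p in enumerate(pids)})
            pvals.append(compare_expansion_counts(counts, groups).iloc[0].p_value)
        pvals = np.asarray(pvals)
        assert (pvals < 0.05).mean() <= 0.1
        assert pvals.mean() > 0.3


class TestEventsFrame:
    def test_round_trip_columns(self):
        norm = two_tp({"c1": 10, "bg": 90}, {"c1": 80, "bg": 20})
        events = detect_expansions(norm, "P1", "A1", "B1", "A", "B")
        frame = events_frame(events)
        assert list(frame.columns)[:3] == ["patient_id", "chain", "clone_id"]
        assert frame.iloc[0].thresholds_passed == "4|8"

    def test_expansion_counts_shape(self):
        norm = two_tp({"c1": 10, "bg": 90}, {"c1": 80, "bg": 20})
        events = detect_expansions(norm, "P1", "A1", "B1", "A", "B")
        counts = expansion_counts({"P1": events})
        assert set(counts["fold_threshold"]) == {4.0, 8.0}
        n8 = counts[(counts["chain"] == "alpha") &
                    (counts["fold_threshold"] == 8.0)]["n_expanded"].iloc[0]
        assert n8 == 1
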