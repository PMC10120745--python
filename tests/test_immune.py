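"""Neoantigen burden, CN enrichment, escape mechanism callers and the
composite escape combination."""

import numpy as np
import pandas as pd
import pytest

from clonescape.immune import (
    HLALohCall,
    call_b2m,
    call_hla_loh,
    call_pdl1_over,
    cn_enrichment,
    combine_escape,
    escape_association_tests,
    median_split,
    neoantigen_burden,
    neoantigen_expression,
)
from clonescape.types import CNSegment, ExpressionMatrix, MutationRecord


def seg(sample, start, end, cnt, minor):
    return CNSegment(sample, "chr1", start, end, cnt, cnt - minor, minor)


def snv(pos, sample="S1", gene="G1", effect="nonsynonymous", neo=True):
    return MutationRecord(chrom="chr1", pos=pos, ref="C", alt="A",
                          sample_id=sample, ref_count=90, alt_count=10,
                          gene=gene, effect=effect, is_neoantigenic=neo)


class TestNeoantigenBurden:
    def _frame(self, n_total, neo_keys, n_clonal):
        rows = []
        for i in range(n_total):
            rows.append({"mutation_key": f"m{i}", "sample_id": "S1",
                         "clonality": "clonal" if i < n_clonal else "subclonal"})
        return pd.DataFrame(rows)

    def test_zero_neo_ratio_zero(self):
        out = neoantigen_burden(self._frame(10, set(), 5), set())
        assert out.iloc[0].neo_ratio == 0.0

    def test_all_neo_ratio_one(self):
        frame = self._frame(10, None, 5)
        out = neoantigen_burden(frame, set(frame["mutation_key"]))
        assert out.iloc[0].neo_ratio == 1.0
        assert out.iloc[0].n_neo_clonal + out.iloc[0].n_neo_subclonal == 10

    def test_bernoulli_rate_recovered(self):
        rng = np.random.default_rng(0)
        n, p = 1000, 0.15
        frame = self._frame(n, None, 500)
        neo = {f"m{i}" for i in range(n) if rng.random() < p}
        out = neoantigen_burden(frame, neo)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(out.iloc[0].neo_ratio - p) < 3 * se


class TestCNEnrichment:
    def test_all_diploid_ratio_exactly_one(self):
        segs = [seg("S1", 1, 1000, 2, 1)]
        muts = [snv(p) for p in (10, 20, 30)]
        enr = cn_enrichment("S1", muts, segs)
        assert enr.ratios["diploid"] == 1.0

    def test_all_in_small_gain_ratio_ten(self):
        segs = [seg("S1", 1, 100, 3, 1), seg("S1", 101, 1000, 2, 1)]
        muts = [snv(p) for p in (10, 50, 90)]
        enr = cn_enrichment("S1", muts, segs)
        assert enr.ratios["gain"] == pytest.approx(10.0)
        assert enr.ratios["diploid"] == 0.0

    def test_weight_conservation_identity(self):
        rng = np.random.default_rng(1)
        states = [(2, 1), (1, 0), (3, 0), (3, 1), (5, 2)]
        segs = [seg("S1", 1 + i * 100, (i + 1) * 100, *states[rng.integers(5)])
                for i in range(30)]
        muts = [snv(int(rng.integers(1, 3000))) for _ in range(200)]
        enr = cn_enrichment("S1", muts, segs)
        identity = float((enr.ratios.fillna(0) * enr.length_fractions).sum())
        assert identity == pytest.approx(1.0, abs=1e-9)
        assert enr.weight_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_length_category_is_nan(self):
        segs = [seg("S1", 1, 1000, 2, 1)]
        enr = cn_enrichment("S1", [snv(10)], segs)
        assert np.isnan(enr.ratios["amplification"])

    def test_per_copy_uniform_placement_anchors_all_ratios_at_one(self):
        """NeoSNVs placed uniformly per genome copy: every category's
        enrichment ratio converges to 1 under the 2/CNt weighting."""
        rng = np.random.default_rng(2)
        states = [(2, 1), (1, 0), (2, 0), (3, 0), (3, 1), (5, 2)]
        segs = [seg("S1", 1 + i * 1000, (i + 1) * 1000, *states[i % 6])
                for i in range(30)]
        w = np.array([s.length * s.cn_total for s in segs], float)
        w /= w.sum()
        idx = rng.choice(len(segs), size=10_000, p=w)
        muts = [snv(int(rng.integers(segs[i].start, segs[i].end + 1)))
                for i in idx]
        enr = cn_enrichment("S1", muts, segs)
        assert abs(enr.ratios["diploid"] - 1.0) < 0.1
        for cat in ("loss", "gain", "amplification"):
            assert abs(enr.ratios[cat] - 1.0) < 0.15


class TestExpressionProxy:
    def _expr(self, data):
        return ExpressionMatrix(values=pd.DataFrame(data))

    def test_single_gene(self):
        expr = self._expr({"S1": pd.Series({"G1": 10.0})})
        out = neoantigen_expression(expr, {"S1": {"G1"}})
        assert out["S1"] == 10.0

    def test_mean_of_two(self):
        expr = self._expr({"S1": pd.Series({"G1": 10.0, "G2": 30.0})})
        out = neoantigen_expression(expr, {"S1": {"G1", "G2"}})
        assert out["S1"] == 20.0

    def test_empty_gene_set_missing_not_zero(self):
        expr = self._expr({"S1": pd.Series({"G1": 10.0})})
        out = neoantigen_expression(expr, {"S1": set()})
        assert np.isnan(out["S1"])

    def test_median_split_even_sizes(self):
        scores = pd.Series({"S1": 1.0, "S2": 2.0, "S3": 3.0, "S4": 4.0})
        groups = median_split(scores)
        assert (groups == "high").sum() == 2 and (groups == "low").sum() == 2
        assert groups["S4"] == "high" and groups["S1"] == "low"


def loh(candidate=True, p=0.005, lost=0.3, ci=0.6, kept=1.2, mm=15):
    return HLALohCall(sample_id="S1", allele="A*01", candidate=candidate,
                      ai_p_value=p, lost_cn=lost, lost_cn_ci_upper=ci,
                      kept_cn=kept, mismatched_sites=mm)


class TestHLALoh:
    def test_reference_confirmed(self):
        assert call_hla_loh([loh()])[0].confirmed

    @pytest.mark.parametrize("kw", [
        dict(candidate=False),
        dict(p=0.01),        # boundary: must be strictly below 0.01
        dict(lost=0.5),      # boundary: strictly below 0.5
        dict(ci=0.7),        # boundary: strictly below 0.7
        dict(kept=0.75),     # boundary: strictly above 0.75
        dict(mm=10),         # boundary: strictly above 10
    ])
    def test_each_threshold_is_strict(self, kw):
        assert not call_hla_loh([loh(**kw)])[0].confirmed

    def test_monotone_in_each_criterion(self):
        """Worsening one criterion never flips a negative call positive."""
        base = loh(mm=10)  # negative
        assert not call_hla_loh([base])[0].confirmed
        worse = loh(mm=10, lost=0.9, p=0.5)
        assert not call_hla_loh([worse])[0].confirmed


class TestPDL1:
    def _expr(self, values_by_sample):
        df = pd.DataFrame({s: pd.Series({"CD274": v})
                           for s, v in values_by_sample.items()})
        return ExpressionMatrix(values=df)

    def test_zero_sd_boundary_flagged(self):
        expr = self._expr({"N1": 10.0, "N2": 10.0, "N3": 10.0, "T1": 10.0})
        flags, stats = call_pdl1_over(expr, ["N1", "N2", "N3"])
        assert stats["threshold"] == 10.0
        assert bool(flags["T1"])

    def test_hand_arithmetic_one_sd(self):
        expr = self._expr({"N1": 8.0, "N2": 12.0, "T1": 11.9, "T2": 12.0})
        flags, stats = call_pdl1_over(expr, ["N1", "N2"])
        assert stats["baseline_mean"] == 10.0 and stats["baseline_sd"] == 2.0
        assert not bool(flags["T1"]) and bool(flags["T2"])

    def test_two_sd_variant(self):
        expr = self._expr({"N1": 8.0, "N2": 12.0, "T1": 13.9, "T2": 14.0})
        flags, _ = call_pdl1_over(expr, ["N1", "N2"], sd_multiplier=2.0)
        assert not bool(flags["T1"]) and bool(flags["T2"])

    def test_single_naive_sample_rejected(self):
        expr = self._expr({"N1": 8.0, "T1": 14.0})
        with pytest.raises(ValueError):
            call_pdl1_over(expr, ["N1"])


class TestB2M:
    def test_effect_classes(self):
        by_sample = {
            "S1": [snv(1, "S1", gene="B2M", effect="synonymous", neo=False)],
            "S2": [snv(2, "S2", gene="B2M", effect="frameshift", neo=False)],
            "S3": [snv(3, "S3", gene="TP53", effect="stopgain", neo=False)],
            "S4": [],
        }
        out = call_b2m(by_sample)
        assert not out["S1"] and out["S2"] and not out["S3"] and not out["S4"]


class TestCombineEscape:
    def _fixture(self):
        """10 samples over 5 patients with hand-assigned mechanism flags."""
        flags = pd.DataFrame(
            {
                "hla_mutation": [1, 0, 0, 0, 0, 0, 0, 0, 0, 0],
                "b2m_mutation": [0, 0, 1, 0, 0, 0, 0, 0, 0, 0],
                "hla_loh":      [0, 0, 0, 0, 1, 1, 0, 0, 0, 0],
                "pdl1_over":    [0, 1, 0, 0, 0, 0, 0, 1, 0, 0],
            },
            index=[f"S{i}" for i in range(10)],
        ).astype(bool)
        meta = pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(10)],
            "patient_id": ["P1", "P1", "P2", "P2", "P3", "P3", "P4", "P4", "P5", "P5"],
            "timepoint": ["A", "B"] * 5,
            "response_group": ["NR", "NR", "NR", "NR", "RE", "RE", "RE", "RE", "RE", "RE"],
            "becker_grade": [3, 3, 2, 2, 1, 1, 1, 1, 2, 2],
        })
        return flags, meta

    def test_boolean_algebra_matches_hand_computation(self):
        flags, meta = self._fixture()
        out = combine_escape(flags, meta).set_index("sample_id")
        assert out.loc["S0", "genetic_escape"] and out.loc["S0", "any_escape"]
        assert not out.loc["S1", "genetic_escape"] and out.loc["S1", "any_escape"]
        assert not out.loc["S6", "any_escape"] and out.loc["S7", "any_escape"]
        assert out.loc["S3", "patient_escape"]  # P2 escaped via S2
        assert not out.loc["S8", "any_escape"] and not out.loc["S8", "patient_escape"]
        # timing: P1 escaped at A -> early; P4 first escaped at B -> late
        assert out.loc["S0", "escape_timing"] == "early"
        assert out.loc["S6", "escape_timing"] == "late"
        assert out.loc["S8", "escape_timing"] == "none"

    def test_genetic_escape_ignores_pdl1(self):
        flags, meta = self._fixture()
        out1 = combine_escape(flags, meta)
        flags2 = flags.copy()
        flags2["pdl1_over"] = False
        out2 = combine_escape(flags2, meta)
        assert (out1["genetic_escape"] == out2["genetic_escape"]).all()

    def test_all_false_degenerate_tests(self):
        flags, meta = self._fixture()
        for c in flags.columns:
            flags[c] = False
        out = combine_escape(flags, meta)
        tests = escape_association_tests(out)
        assert (tests["test"] == "not_applicable").all()

    def test_chi_square_closed_form(self):
        """2x2 table (8,2;3,7): chi2 = N(ad-bc)^2 / (r1 r2 c1 c2)."""
        from scipy.stats import chi2_contingency

        table = np.array([[8, 2], [3, 7]])
        n = table.sum()
        a, b, c, d = table.ravel()
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        stat, _, _, _ = chi2_contingency(table, correction=False)
        assert stat == pytest.approx(expected)

    def test_association_test_runs_on_mixed_cohort(self):
        flags, meta = self._fixture()
        out = combine_escape(flags, meta)
        tests = escape_association_tests(out, level="patient")
        resp = tests[tests["grouping"] == "response_group"].iloc[0]
        assert resp["test"] in ("chi_square", "fisher_exact")
        assert 0.0 <= resp["p_value"] <= 1.0
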