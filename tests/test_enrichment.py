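"""Hypergeometric/chi-squared tests, p-value adjustment, enrichment reports."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import helpers
from mycoenrich.annotation_io import AnnotationRecord
from mycoenrich.enrichment import (
    adjust_pvalues,
    chisquared_pvalue,
    enrich,
    hypergeometric_pvalue,
    read_report_tsv,
    reduce_go_redundancy,
    write_report_tsv,
    EnrichmentReport,
    EnrichmentResult,
)
from mycoenrich.models import create_kog_model


def kog(protein, letter):
    return AnnotationRecord(protein_id=protein, category_id=letter,
                            category_label=letter, category_group="Metabolism",
                            source="kog")


def letter_model(assignments: dict[str, list[str]]):
    """letter -> proteins"""
    records = [kog(p, letter) for letter, ps in assignments.items() for p in ps]
    return create_kog_model(records)[0]


class TestHypergeometric:
    def test_k_zero_is_exactly_one(self):
        assert hypergeometric_pvalue(0, 5, 3, 10) == 1.0

    def test_category_is_whole_background(self):
        assert hypergeometric_pvalue(2, 10, 4, 10) == 1.0

    def test_two_of_two_in_two_draws_from_four(self):
        # one of the C(4,2)=6 equally likely draws contains both members
        assert hypergeometric_pvalue(2, 2, 2, 4) == pytest.approx(1 / 6, abs=1e-12)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_pvalue(3, 2, 3, 10)  # k > K
        with pytest.raises(ValueError):
            hypergeometric_pvalue(1, 2, 3, 2)  # n > N
        with pytest.raises(ValueError):
            hypergeometric_pvalue(-1, 2, 3, 10)

    def test_non_increasing_in_k(self):
        K, n, N = 6, 8, 20
        ps = [hypergeometric_pvalue(k, K, n, N) for k in range(0, min(K, n) + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_matches_enumeration_on_small_grid(self):
        for N in range(0, 9):
            for n in range(0, N + 1):
                for K in range(0, N + 1):
                    for k in range(0, min(K, n) + 1):
                        expected = helpers.hypergeom_tail_by_enumeration(k, K, n, N)
                        assert hypergeometric_pvalue(k, K, n, N) == pytest.approx(
                            expected, abs=1e-12), (k, K, n, N)


class TestChiSquared:
    def test_independence_gives_p_one(self):
        assert chisquared_pvalue(5, 10, 10, 20) == pytest.approx(1.0)

    def test_degenerate_table_gives_p_one(self):
        assert chisquared_pvalue(4, 4, 4, 4) == 1.0

    def test_classical_statistic_without_correction(self):
        k, K, n, N = 8, 10, 10, 40
        a, b, c, d = k, n - k, K - k, (N - K) - (n - k)
        chi2 = N * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        expected = float(stats.chi2.sf(chi2, df=1))
        assert chisquared_pvalue(k, K, n, N, correction=False) == pytest.approx(expected)

    def test_enriched_table_is_significant(self):
        assert chisquared_pvalue(20, 30, 25, 300) < 1e-6


class TestAdjustment:
    def test_none_is_identity(self):
        ps = [0.5, 0.01, 1.0]
        assert adjust_pvalues(ps, "none") == ps

    def test_bh_stepup_worked_example(self):
        assert adjust_pvalues([0.01, 0.02, 0.03], "BH") == pytest.approx([0.03, 0.03, 0.03])

    def test_bonferroni_clamped(self):
        assert adjust_pvalues([0.02, 0.5], "bonferroni") == pytest.approx([0.04, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([1.5], "BH")
        with pytest.raises(ValueError):
            adjust_pvalues([float("nan")], "BH")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], "fishing")

    @pytest.mark.parametrize("method,oracle", [
        ("BH", helpers.bh_oracle),
        ("bonferroni", helpers.bonferroni_oracle),
        ("holm", helpers.holm_oracle),
    ])
    def test_matches_direct_definition_on_random_vectors(self, method, oracle):
        rng = np.random.default_rng(5)
        for _ in range(200):
            ps = rng.random(int(rng.integers(1, 40))).tolist()
            assert adjust_pvalues(ps, method) == pytest.approx(oracle(ps), abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=30))
    def test_bh_bounded_and_dominates_raw(self, ps):
        qs = adjust_pvalues(ps, "BH")
        assert all(0 <= q <= 1 for q in qs)
        assert all(q >= p - 1e-12 for p, q in zip(ps, qs))

    def test_single_test_bh_equals_bonferroni(self):
        assert adjust_pvalues([0.037], "BH") == adjust_pvalues([0.037], "bonferroni")


class TestEnrich:
    def test_saturated_query(self):
        model = letter_model({"E": ["p1", "p2"], "G": ["p2", "p3"]})
        report = enrich(model, {"p1", "p2", "p3"})
        for r in report.results:
            assert r.k == r.K and r.n == r.N
            assert r.ratio == pytest.approx(1.0)
            assert r.p_value == 1.0

    def test_single_category_closed_form(self):
        # query = exactly the 3 members of one category in a background of 30
        assignments = {"E": [f"e{i}" for i in range(3)]}
        assignments.update({letter: [f"{letter}{i}" for i in range(3)]
                            for letter in "ABCDFGHIJ"})
        model = letter_model(assignments)
        assert model.background_size == 30
        report = enrich(model, set(assignments["E"]))
        row = next(r for r in report.results if r.category_id == "E")
        assert row.p_value == pytest.approx(1 / math.comb(30, 3), rel=1e-12)

    def test_unknown_ids_bookkeeping(self):
        model = letter_model({"E": ["p1", "p2"]})
        report = enrich(model, ["p1", "ghost1", "ghost2"])
        assert (report.n_input, report.n_mapped) == (3, 1)
        assert sorted(report.dropped_ids) == ["ghost1", "ghost2"]
        assert report.n_input == report.n_mapped + len(report.dropped_ids)

    def test_empty_mapped_query_warns_not_raises(self):
        model = letter_model({"E": ["p1"]})
        report = enrich(model, ["ghost"])
        assert report.results == [] and report.dropped_ids == ["ghost"]

    def test_k_zero_categories_still_count_toward_m(self):
        # two categories, query hits only one; with m=2 the BH-adjusted p
        # of the hit category is doubled relative to a single test
        model = letter_model({"E": ["e1", "e2"], "G": [f"g{i}" for i in range(8)]})
        report = enrich(model, {"e1", "e2"})
        assert len(report.results) == 1  # k=0 rows skipped
        row = report.results[0]
        assert row.p_adjusted == pytest.approx(min(1.0, 2 * row.p_value))

    def test_sorted_by_adjusted_then_id(self):
        model = letter_model({"E": ["p1", "p2"], "G": ["p1", "p2"], "C": ["p3", "p4"]})
        report = enrich(model, {"p1", "p2"})
        keys = [(r.p_adjusted, r.category_id) for r in report.results]
        assert keys == sorted(keys)

    def test_chisquared_alternative_runs(self):
        model = letter_model({"E": [f"e{i}" for i in range(10)],
                              "G": [f"g{i}" for i in range(10)]})
        report = enrich(model, {f"e{i}" for i in range(5)}, test="chisquared")
        assert report.results[0].category_id == "E"
        assert 0 <= report.results[0].p_value <= 1


class TestRedundancyReduction:
    def _report(self, rows):
        results = [
            EnrichmentResult(category_id=t, label=t, group="biological_process",
                             k=2, K=4, n=10, N=100, ratio=5.0, p_value=p, p_adjusted=q)
            for t, p, q in rows
        ]
        results.sort(key=lambda r: (r.p_adjusted, r.category_id))
        return EnrichmentReport(results=results, n_input=10, n_mapped=10, dropped_ids=[])

    def test_sibling_pair_keeps_most_significant(self):
        dag = helpers.make_dag([("t1", "parent", "is_a"), ("t2", "parent", "is_a")])
        report = self._report([("t1", 0.001, 0.002), ("t2", 0.005, 0.01)])
        reduced = reduce_go_redundancy(report, dag, depth_limit=1)
        assert [r.category_id for r in reduced.results] == ["t1"]
        # adjusted p-values are not recomputed
        assert reduced.results[0].p_adjusted == 0.002

    def test_depth_zero_preserves_all_significant(self):
        dag = helpers.make_dag([("t1", "parent", "is_a"), ("t2", "parent", "is_a")])
        report = self._report([("t1", 0.001, 0.002), ("t2", 0.005, 0.01), ("parent", 0.2, 0.4)])
        reduced = reduce_go_redundancy(report, dag, depth_limit=0)
        assert {r.category_id for r in reduced.results} == {"t1", "t2"}

    def test_three_terms_two_components(self):
        dag = helpers.make_dag([
            ("t1", "p12", "is_a"), ("t2", "p12", "is_a"), ("t3", "p3", "is_a"),
            ("p12", "root", "is_a"), ("p3", "root", "is_a"),
        ])
        report = self._report([("t1", 0.001, 0.002), ("t2", 0.002, 0.004),
                               ("t3", 0.003, 0.006)])
        reduced = reduce_go_redundancy(report, dag, depth_limit=1)
        assert {r.category_id for r in reduced.results} == {"t1", "t3"}

    def test_insignificant_rows_dropped(self):
        dag = helpers.make_dag([("t1", "parent", "is_a"), ("t2", "parent", "is_a")])
        report = self._report([("t1", 0.5, 0.9), ("t2", 0.6, 0.95)])
        reduced = reduce_go_redundancy(report, dag, depth_limit=1, alpha=0.05)
        assert reduced.results == []


class TestReportSerialization:
    def test_tsv_roundtrip(self, tmp_path):
        model = letter_model({"E": ["p1", "p2", "p3"], "G": ["p4", "p5"]})
        report = enrich(model, ["p1", "p2", "ghost"])
        path = tmp_path / "res.tsv"
        write_report_tsv(report, path)
        loaded = read_report_tsv(path)
        assert loaded.n_input == report.n_input
        assert loaded.n_mapped == report.n_mapped
        assert loaded.dropped_ids == report.dropped_ids
        assert [(r.category_id, r.k, r.K) for r in loaded.results] == \
               [(r.category_id, r.k, r.K) for r in report.results]
        assert loaded.results[0].p_value == pytest.approx(report.results[0].p_value, rel=1e-9)
        assert loaded.results[0].query_hits == report.results[0].query_hits
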