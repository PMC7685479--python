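"""20/20 rule, length comparisons, chi-square, over-representation."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from driverscan.characterization import (chi_square_2x2, classify_20_20,
                                         compare_lengths, enrich_gene_sets,
                                         oncogene_tsg_rates)
from driverscan.io_formats import TRUNCATING_CLASSES, GeneCatalog, VariantRecord
from driverscan.synthetic_data import simulate_maf_for_2020


def rec(cls, pos=None, gene="G", start=None):
    return VariantRecord(gene, f"s{np.random.default_rng().integers(1e9)}",
                         cls, protein_position=pos, start=start)


class TestClassify2020:
    def test_recurrent_missense_flags_oncogene(self):
        records = [rec("Missense_Mutation", 175) for _ in range(5)] + \
                  [rec("In_Frame_Del", i + 1) for i in range(5)]
        r = classify_20_20(records)
        assert r.recurrent_missense_fraction == 0.5
        assert r.oncogene_flag and not r.tsg_flag
        assert r.combined_label == "oncogene"

    def test_truncating_flags_tsg_without_recurrence(self):
        records = [rec("Nonsense_Mutation", i + 1) for i in range(3)] + \
                  [rec("Missense_Mutation", 100 + i) for i in range(7)]
        r = classify_20_20(records)
        assert r.truncating_fraction == pytest.approx(0.3)
        assert r.tsg_flag and not r.oncogene_flag  # 7 distinct positions: no recurrence
        assert r.combined_label == "tsg"

    def test_tsg_priority_when_both_fire(self):
        records = [rec("Missense_Mutation", 7) for _ in range(3)] + \
                  [rec("Nonsense_Mutation", i + 100) for i in range(3)] + \
                  [rec("In_Frame_Ins", i + 200) for i in range(4)]
        r = classify_20_20(records)
        assert r.oncogene_flag and r.tsg_flag
        assert r.combined_label == "tsg"

    def test_min_mutations_gates_label_not_flags(self):
        records = [rec("Nonsense_Mutation", i) for i in range(3)]
        r = classify_20_20(records, min_mutations=5)
        assert r.tsg_flag and not r.classified
        assert r.combined_label == "unclassified"

    def test_genomic_start_fallback(self):
        records = [rec("Missense_Mutation", None, start=500) for _ in range(3)] + \
                  [rec("Missense_Mutation", None, start=900 + i) for i in range(7)]
        r = classify_20_20(records)
        assert r.recurrent_missense_fraction == pytest.approx(0.3)

    def test_fractions_match_brute_force_recount(self):
        records = simulate_maf_for_2020(200, missense_fraction=0.55,
                                        truncating_fraction=0.25,
                                        hotspot_concentration=0.4, seed=9,
                                        gene="X")
        r = classify_20_20(records)
        hist = Counter(x.protein_position for x in records
                       if x.classification == "Missense_Mutation")
        recurrent = sum(n for n in hist.values() if n >= 2)
        truncating = sum(1 for x in records if x.classification in TRUNCATING_CLASSES)
        assert r.recurrent_missense_fraction == pytest.approx(recurrent / 200)
        assert r.truncating_fraction == pytest.approx(truncating / 200)

    def test_order_and_duplication_invariance(self):
        records = simulate_maf_for_2020(40, 0.5, 0.3, 0.5, seed=3)
        rng = np.random.default_rng(0)
        shuffled = list(records)
        rng.shuffle(shuffled)
        a, b = classify_20_20(records), classify_20_20(shuffled)
        assert (a.recurrent_missense_fraction, a.truncating_fraction) == \
               (b.recurrent_missense_fraction, b.truncating_fraction)
        doubled = classify_20_20(records + records)
        assert doubled.n_mutations == 2 * a.n_mutations
        assert doubled.truncating_fraction == pytest.approx(a.truncating_fraction)
        # the recurrent-missense fraction is duplication-invariant only when
        # no position is a singleton (duplication creates recurrence there)
        hot_only = simulate_maf_for_2020(20, 1.0, 0.0, 1.0, seed=5)
        one, two = classify_20_20(hot_only), classify_20_20(hot_only + hot_only)
        assert two.recurrent_missense_fraction == pytest.approx(
            one.recurrent_missense_fraction)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            classify_20_20([])


def make_catalog(lengths):
    rows = [{"gene": g, "known_cancer_gene": False,
             "gene_length": L, "protein_length": L / 3} for g, L in lengths.items()]
    return GeneCatalog(pd.DataFrame(rows).set_index("gene"))


class TestCompareLengths:
    def test_identical_groups_give_d_zero(self):
        cat = make_catalog({f"G{i}": 1000 + i for i in range(10)})
        table = compare_lengths({"a": cat.table.index, "b": cat.table.index}, cat)
        gl = table[table.length_type == "gene_length"].iloc[0]
        assert gl.ks_statistic == 0.0 and gl.ks_p == 1.0

    def test_disjoint_supports_give_d_one(self):
        lengths = {f"A{i}": 1 + i for i in range(100)}
        lengths.update({f"B{i}": 1001 + i for i in range(100)})
        cat = make_catalog(lengths)
        table = compare_lengths({"a": [f"A{i}" for i in range(100)],
                                 "b": [f"B{i}" for i in range(100)]}, cat)
        assert (table.ks_statistic == 1.0).all()

    def test_matches_brute_force_ecdf(self):
        rng = np.random.default_rng(4)
        la = {f"A{i}": float(v) for i, v in enumerate(rng.lognormal(9, 1, 50))}
        lb = {f"B{i}": float(v) for i, v in enumerate(rng.lognormal(9.5, 1, 50))}
        cat = make_catalog({**la, **lb})
        table = compare_lengths({"a": la.keys(), "b": lb.keys()}, cat)
        xa, xb = np.array(list(la.values())), np.array(list(lb.values()))
        # O(n^2) empirical-CDF scan
        d_brute = max(abs(np.mean(xa <= t) - np.mean(xb <= t))
                      for t in np.concatenate([xa, xb]))
        row = table[table.length_type == "gene_length"].iloc[0]
        assert row.ks_statistic == pytest.approx(d_brute, abs=1e-12)

    def test_small_group_skipped(self):
        cat = make_catalog({"A": 100, "B": 200, "C": 300})
        table = compare_lengths({"a": ["A"], "b": ["B", "C"]}, cat)
        assert table.empty


class TestChiSquare:
    def test_uniform_table_is_null(self):
        stat, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_perfect_diagonal(self):
        stat, p = chi_square_2x2([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)  # equals n for a perfect diagonal
        assert p < 1e-9

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            t = rng.integers(1, 50, size=(2, 2)).astype(float)
            stat, p = chi_square_2x2(t)
            row, col, n = t.sum(1), t.sum(0), t.sum()
            expected = np.outer(row, col) / n
            assert stat == pytest.approx(((t - expected) ** 2 / expected).sum())
            assert p == pytest.approx(sps.chi2.sf(stat, 1))

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestEnrichment:
    def test_query_equals_universe(self):
        rows = enrich_gene_sets({"A", "B"}, {"A", "B"}, {"S": {"A", "B"}})
        assert rows[0].overlap == 2 and rows[0].p_value == pytest.approx(1.0)

    def test_hypergeometric_tail_by_pmf_summation(self):
        universe = {f"G{i}" for i in range(100)}
        member = {f"G{i}" for i in range(10)}
        query = {f"G{i}" for i in range(5)} | {f"G{i}" for i in range(50, 65)}
        rows = enrich_gene_sets(query, universe, {"S": member})
        assert rows[0].overlap == 5
        expected = sum(sps.hypergeom.pmf(k, 100, 10, 20) for k in range(5, 11))
        assert rows[0].p_value == pytest.approx(expected, rel=1e-9)

    def test_min_overlap_excludes_empty_sets(self):
        rows = enrich_gene_sets({"A"}, {"A", "B", "C"}, {"S": {"B", "C"}},
                                min_overlap=1)
        assert rows == []

    def test_bh_monotone_and_fisher_equivalent(self):
        rng = np.random.default_rng(6)
        universe = [f"G{i}" for i in range(60)]
        sets = {f"S{j}": set(rng.choice(universe, size=rng.integers(5, 20),
                                        replace=False)) for j in range(12)}
        query = set(rng.choice(universe, size=15, replace=False))
        rows = enrich_gene_sets(query, universe, sets, min_overlap=0)
        ps = [r.p_value for r in rows]
        adj = [r.adjusted_p for r in rows]
        assert all(a >= p for p, a in zip(ps, adj))
        assert adj == sorted(adj)  # rows sorted by p; BH preserves the order
        for r in rows:
            table = [[r.overlap, r.query_size - r.overlap],
                     [r.set_size - r.overlap,
                      r.universe_size - r.set_size - r.query_size + r.overlap]]
            _, fisher_p = sps.fisher_exact(table, alternative="greater")
            assert r.p_value == pytest.approx(fisher_p, abs=1e-9)


def test_enrichment_matches_gseapy_reference():
    """Agreement with gseapy's offline enrichr-style test (reference
    implementation) on p-values and BH adjustment."""
    import gseapy

    rng = np.random.default_rng(13)
    universe = [f"G{i}" for i in range(120)]
    sets = {f"S{j}": list(rng.choice(universe, size=int(rng.integers(8, 30)),
                                     replace=False)) for j in range(6)}
    query = list(rng.choice(universe, size=25, replace=False))
    mine = {r.set_name: r for r in enrich_gene_sets(query, universe, sets)}
    ref = gseapy.enrich(gene_list=query, gene_sets=sets, background=universe,
                        outdir=None).results.set_index("Term")
    assert set(mine) == set(ref.index)
    for name, row in mine.items():
        assert row.p_value == pytest.approx(ref.loc[name, "P-value"], rel=1e-9)
        assert row.adjusted_p == pytest.approx(ref.loc[name, "Adjusted P-value"], rel=1e-9)


class TestRates:
    def test_rates_and_pairwise_tests(self):
        results = {}
        for i in range(10):
            n = 3 if i < 4 else 0
            records = [rec("Missense_Mutation", 7, gene=f"D{i}") for _ in range(n)] + \
                      [rec("In_Frame_Del", 100 + j, gene=f"D{i}") for j in range(10 - n)]
            results[f"D{i}"] = classify_20_20(records)
        groups = {"driver_like": [f"D{i}" for i in range(10)],
                  "same": [f"D{i}" for i in range(10)]}
        rates, tests = oncogene_tsg_rates(groups, results)
        assert rates.set_index("group").loc["driver_like", "oncogene_rate"] == 0.4
        onc = tests[(tests.flag == "oncogene")].iloc[0]
        assert onc.p == pytest.approx(1.0)  # identical groups

    def test_hotspot_drivers_exceed_passengers(self):
        results = {}
        for i in range(20):
            hot = 0.9 if i < 10 else 0.0
            recs20 = simulate_maf_for_2020(30, missense_fraction=0.8,
                                           truncating_fraction=0.1,
                                           hotspot_concentration=hot,
                                           seed=100 + i, gene=f"G{i}")
            results[f"G{i}"] = classify_20_20(recs20)
        groups = {"driver_like": [f"G{i}" for i in range(10)],
                  "passenger_like": [f"G{i}" for i in range(10, 20)]}
        rates, _ = oncogene_tsg_rates(groups, results)
        r = rates.set_index("group")
        assert r.loc["driver_like", "oncogene_rate"] > r.loc["passenger_like", "oncogene_rate"]
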