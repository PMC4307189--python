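import numpy as np
import pandas as pd
import pytest

from xtalknet.crosstalk import (
    PathwayCollection,
    enumerate_crosstalk_pairs,
    filter_resistant_pairs,
    intersect_crosstalks,
    odds_ratio,
    read_gmt,
    read_pathway_dir,
    summarize_crosstalks,
)


class TestOddsRatio:
    def test_reported_values_to_two_decimals(self):
        assert round(odds_ratio(0.5, 0.03), 2) == 16.67
        assert round(odds_ratio(0.5, 0.04), 2) == 12.5

    def test_identity_for_equal_probabilities(self):
        for p in (0.1, 0.5, 1.0):
            assert odds_ratio(p, p) == 1.0

    def test_zero_parental_gives_infinity(self):
        assert odds_ratio(0.3, 0.0) == float("inf")

    def test_zero_over_zero_is_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert odds_ratio(0.0, 0.0) == 0.0
        assert "0/0" in caplog.text

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio(1.2, 0.5)
        with pytest.raises(ValueError):
            odds_ratio(0.5, -0.1)

    def test_scale_consistency(self):
        for c in (0.2, 0.5, 1.9):
            assert odds_ratio(c * 0.4, c * 0.05) == pytest.approx(odds_ratio(0.4, 0.05))


def prob_matrices(gene_ids, entries):
    g = len(gene_ids)
    pr_r, pr_p = np.zeros((g, g)), np.zeros((g, g))
    for (i, j), (a, b) in entries.items():
        pr_r[i, j] = pr_r[j, i] = a
        pr_p[i, j] = pr_p[j, i] = b
    return pr_r, pr_p


class TestFilterResistantPairs:
    def test_reported_pairs_pass_default_thresholds(self):
        genes = ["AKT2", "MAML2", "TP53"]
        pr_r, pr_p = prob_matrices(genes, {(0, 1): (0.5, 0.03), (0, 2): (0.5, 0.04)})
        kept = filter_resistant_pairs(pr_r, pr_p, genes)
        assert frozenset(("AKT2", "MAML2")) in kept
        assert frozenset(("AKT2", "TP53")) in kept
        assert kept[frozenset(("AKT2", "MAML2"))][2] == pytest.approx(16.67, abs=0.005)

    def test_high_odds_but_low_probability_rejected(self):
        genes = ["A", "B"]
        pr_r, pr_p = prob_matrices(genes, {(0, 1): (0.4, 0.01)})  # odds 40
        assert filter_resistant_pairs(pr_r, pr_p, genes) == {}

    def test_thresholds_inclusive(self):
        genes = ["A", "B"]
        pr_r, pr_p = prob_matrices(genes, {(0, 1): (0.5, 0.05)})  # odds exactly 10
        assert len(filter_resistant_pairs(pr_r, pr_p, genes)) == 1

    def test_matches_double_loop_oracle(self, rng):
        g = 15
        genes = [f"G{k}" for k in range(g)]
        pr_r = np.round(rng.random((g, g)), 2)
        pr_r = np.triu(pr_r, 1) + np.triu(pr_r, 1).T
        pr_p = np.round(rng.random((g, g)) * 0.2, 2)
        pr_p = np.triu(pr_p, 1) + np.triu(pr_p, 1).T
        kept = filter_resistant_pairs(pr_r, pr_p, genes, odds_min=5.0, pr_min=0.4)
        expected = set()
        for i in range(g):
            for j in range(i + 1, g):
                odds = np.inf if pr_p[i, j] == 0 else pr_r[i, j] / pr_p[i, j]
                if pr_r[i, j] >= 0.4 and odds >= 5.0:
                    expected.add(frozenset((genes[i], genes[j])))
        assert set(kept) == expected

    def test_monotone_in_both_thresholds(self, rng):
        g = 10
        genes = [f"G{k}" for k in range(g)]
        pr_r = np.triu(rng.random((g, g)), 1)
        pr_r += pr_r.T
        pr_p = np.triu(rng.random((g, g)) * 0.3, 1)
        pr_p += pr_p.T
        prev = None
        for odds_min, pr_min in [(2, 0.2), (5, 0.4), (10, 0.6)]:
            kept = set(filter_resistant_pairs(pr_r, pr_p, genes, odds_min, pr_min))
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestEnumerate:
    def test_same_pathway_pairs_excluded(self):
        pw = PathwayCollection(
            "toy", {"EGFR": {"A", "B"}, "Notch": {"B", "C"}}, "EGFR"
        )
        assert enumerate_crosstalk_pairs(pw, {"A", "B", "C"}) == {("A", "C", "Notch")}

    def test_same_pair_counts_once_per_pathway(self):
        pw = PathwayCollection(
            "toy", {"EGFR": {"A"}, "Q1": {"X"}, "Q2": {"X"}}, "EGFR"
        )
        triples = enumerate_crosstalk_pairs(pw, {"A", "X"})
        assert triples == {("A", "X", "Q1"), ("A", "X", "Q2")}

    def test_disjoint_singletons(self):
        pw = PathwayCollection("toy", {"EGFR": {"A"}, "Q": {"X"}}, "EGFR")
        assert enumerate_crosstalk_pairs(pw, {"A", "X"}) == {("A", "X", "Q")}

    def test_universe_restricts_both_sides(self):
        pw = PathwayCollection("toy", {"EGFR": {"A", "B"}, "Q": {"X", "Y"}}, "EGFR")
        assert enumerate_crosstalk_pairs(pw, {"A", "X"}) == {("A", "X", "Q")}

    def test_empty_poi_in_universe_is_error(self):
        pw = PathwayCollection("toy", {"EGFR": {"A"}, "Q": {"X"}}, "EGFR")
        with pytest.raises(ValueError):
            enumerate_crosstalk_pairs(pw, {"X"})

    def test_output_records_satisfy_membership_invariant(self, rng):
        genes = [f"G{k}" for k in range(20)]
        pws = {"POI": set(rng.choice(genes, 6, replace=False))}
        for q in range(3):
            pws[f"Q{q}"] = set(rng.choice(genes, 5, replace=False))
        pw = PathwayCollection("toy", pws, "POI")
        for a, b, pj in enumerate_crosstalk_pairs(pw, genes):
            assert a in pws["POI"] and b in pws[pj]
            assert not (a in pws[pj] and b in pws[pj])
            assert not (a in pws["POI"] and b in pws["POI"])


class TestIntersectAndSummarize:
    def test_intersection_keeps_matching_triples(self):
        candidates = {frozenset(("A", "C")): (0.5, 0.03, 16.67)}
        triples = {("A", "C", "Notch"), ("A", "D", "Wnt")}
        table = intersect_crosstalks(candidates, triples)
        assert len(table) == 1
        assert table.loc[0, "pathway_j"] == "Notch"

    def test_empty_candidates_give_empty_table(self):
        table = intersect_crosstalks({}, {("A", "C", "Notch")})
        assert len(table) == 0
        assert summarize_crosstalks(table) == {
            "n_crosstalks": 0, "n_distinct_pairs": 0, "n_other_pathways": 0,
        }

    def test_sorted_by_descending_odds_then_genes(self):
        candidates = {
            frozenset(("A", "C")): (0.5, 0.04, 12.5),
            frozenset(("A", "B")): (0.5, 0.03, 16.67),
        }
        triples = {("A", "C", "Q1"), ("A", "B", "Q2")}
        table = intersect_crosstalks(candidates, triples)
        assert list(table["gene_j"]) == ["B", "C"]

    def test_matches_join_oracle(self, rng):
        genes = [f"G{k}" for k in range(12)]
        candidates = {}
        for _ in range(10):
            i, j = rng.choice(12, 2, replace=False)
            candidates[frozenset((genes[i], genes[j]))] = (0.6, 0.02, 30.0)
        triples = set()
        for _ in range(25):
            i, j = rng.choice(12, 2, replace=False)
            triples.add((genes[i], genes[j], f"Q{rng.integers(3)}"))
        table = intersect_crosstalks(candidates, triples)
        expected = {
            (a, b, q) for a, b, q in triples if frozenset((a, b)) in candidates
        }
        got = set(zip(table["gene_i"], table["gene_j"], table["pathway_j"]))
        assert got == expected

    def test_summary_counts_and_multi_source_overlap(self):
        table = pd.DataFrame(
            [
                ("A", "B", "Q1", 0.5, 0.03, 16.67, 1, 2, 3, 4),
                ("A", "B", "Q2", 0.5, 0.03, 16.67, 1, 2, 3, 4),
            ],
            columns=[
                "gene_i", "gene_j", "pathway_j", "pr_R", "pr_P", "odds",
                "avg_ge_i_P", "avg_ge_i_R", "avg_ge_j_P", "avg_ge_j_R",
            ],
        )
        s = summarize_crosstalks(table)
        assert (s["n_crosstalks"], s["n_distinct_pairs"], s["n_other_pathways"]) == (2, 1, 2)
        assert s["n_crosstalks"] >= s["n_distinct_pairs"]
        other = table.iloc[:1].assign(gene_i="A", gene_j="B")
        third = table.iloc[:1].assign(gene_i="X", gene_j="Y")
        s2 = summarize_crosstalks(table, multi={"r": table, "k": other, "w": third})
        assert s2["n_pairs_in_2plus_sources"] == 1


class TestPathwayIO:
    def test_gmt_round(self, tmp_path):
        gmt = tmp_path / "p.gmt"
        gmt.write_text("EGFR\tdesc\tA\tB\nNotch\tdesc\tB\tC\n")
        pw = read_gmt(gmt, "reactome", "EGFR")
        assert pw.pathways == {"EGFR": {"A", "B"}, "Notch": {"B", "C"}}

    def test_pathway_dir_reader(self, tmp_path):
        d = tmp_path / "pw"
        d.mkdir()
        (d / "EGFR.txt").write_text("A\tB\n")
        (d / "Wnt.txt").write_text("C\nD\n")
        pw = read_pathway_dir(d, "kegg", "EGFR")
        assert pw.pathways == {"EGFR": {"A", "B"}, "Wnt": {"C", "D"}}

    def test_missing_poi_rejected(self):
        with pytest.raises(ValueError):
            PathwayCollection("x", {"Q": {"A"}}, "EGFR")
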