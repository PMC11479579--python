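"""Gene ranking, CpG aggregation, enrichment tests and their oracles."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from decomix import (
    GeneSetCollection,
    RankedGeneList,
    adjust_bh,
    aggregate_cpg_to_gene,
    choose_method,
    gsea_preranked,
    interpret_components,
    nmf_deconvolve,
    ora,
    rank_component_genes,
    read_gmt,
    simulate_expression,
)
from decomix.engines import match_components


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------
class TestRankComponentGenes:
    def test_descending_order(self):
        T = pd.DataFrame({"C1": [1.0, 3.0, 2.0]}, index=["a", "b", "c"])
        ranked = rank_component_genes(T, 1)
        assert ranked.gene_ids == ["b", "c", "a"]

    def test_ties_broken_lexicographically(self):
        T = pd.DataFrame({"C1": [2.0, 2.0, 2.0]}, index=["c", "a", "b"])
        assert rank_component_genes(T, 1).gene_ids == ["a", "b", "c"]

    def test_out_of_range_component(self):
        T = pd.DataFrame({"C1": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="component"):
            rank_component_genes(T, 2)


class TestAggregateCpgToGene:
    def test_max_rule(self):
        scores = {"cg1": 0.1, "cg2": 0.9, "cg3": 0.4}
        mapping = {"cg1": "G", "cg2": "G", "cg3": "G"}
        assert aggregate_cpg_to_gene(scores, mapping) == {"G": 0.9}

    def test_one_cpg_per_gene_is_identity(self):
        scores = {"cg1": 0.3, "cg2": 0.8}
        mapping = {"cg1": "A", "cg2": "B"}
        assert aggregate_cpg_to_gene(scores, mapping) == {"A": 0.3, "B": 0.8}

    def test_matches_groupby_max_oracle(self, rng):
        cpgs = [f"cg{i}" for i in range(200)]
        scores = dict(zip(cpgs, rng.normal(size=200)))
        mapping = {c: f"g{rng.integers(0, 40)}" for c in cpgs}
        got = aggregate_cpg_to_gene(scores, mapping)
        frame = pd.DataFrame(
            {"gene": [mapping[c] for c in cpgs], "score": [scores[c] for c in cpgs]}
        )
        oracle = frame.groupby("gene")["score"].max().to_dict()
        assert got == oracle

    def test_unmapped_cpgs_dropped(self):
        got = aggregate_cpg_to_gene({"cg1": 0.5, "cgX": 0.9}, {"cg1": "G"})
        assert got == {"G": 0.5}

    def test_empty_mapping_result_is_error(self):
        with pytest.raises(ValueError, match="mapped"):
            aggregate_cpg_to_gene({"cg1": 0.5}, {})


class TestChooseMethod:
    def test_all_distinct_gives_gsea(self):
        assert choose_method(np.arange(100.0)) == "GSEA"

    def test_mostly_duplicated_gives_ora(self):
        scores = np.repeat(np.arange(10.0), 10)
        assert choose_method(scores) == "ORA"

    def test_boundary_thirty_percent_inclusive(self):
        # exactly 30 distinct of 100 -> ordering deemed reliable
        scores = np.concatenate([np.arange(30.0), np.zeros(70)])
        # 31 distinct values (0 repeated); construct exactly 30 distinct
        scores = np.concatenate([np.arange(1.0, 30.0), np.full(71, 0.0)])
        assert np.unique(scores).size == 30
        assert choose_method(scores) == "GSEA"

    def test_just_below_boundary_gives_ora(self):
        scores = np.concatenate([np.arange(1.0, 29.0), np.full(72, 0.0)])
        assert np.unique(scores).size == 29
        assert choose_method(scores) == "ORA"


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------
def _brute_force_es(scores, member_flags, weight_p=1.0):
    """Literal running-sum: independent of the vectorized implementation."""
    absw = np.abs(scores) ** weight_p
    w_sum = absw[member_flags].sum()
    n = member_flags.sum()
    N = len(scores)
    running = 0.0
    best = 0.0
    for i in range(N):
        if member_flags[i]:
            running += absw[i] / w_sum
        else:
            running -= 1.0 / (N - n)
        if abs(running) > abs(best):
            best = running
    return best


def _toy_ranking():
    genes = list("abcdefghij")
    scores = np.array([9.0, 7.5, 6.0, 5.0, 4.0, 3.0, 2.0, 1.5, 1.0, 0.5])
    return RankedGeneList(genes, scores)


class TestGseaPreranked:
    def test_es_matches_bruteforce_on_toy_ranking(self):
        ranked = _toy_ranking()
        sets = GeneSetCollection({"top": ("", {"a", "b", "d"})})
        res = gsea_preranked(ranked, sets, n_perm=50, seed=0)
        flags = np.array([g in {"a", "b", "d"} for g in ranked.gene_ids])
        assert res[0].statistic == pytest.approx(
            _brute_force_es(ranked.scores, flags), abs=1e-12
        )

    def test_es_matches_bruteforce_on_random_sets(self, rng):
        genes = [f"g{i}" for i in range(50)]
        scores = np.sort(rng.normal(size=50))[::-1]
        ranked = RankedGeneList(genes, scores)
        raw = {}
        for s in range(10):
            members = set(rng.choice(genes, size=rng.integers(3, 15), replace=False))
            raw[f"set{s}"] = ("", members)
        sets = GeneSetCollection(raw)
        for r in gsea_preranked(ranked, sets, n_perm=10, seed=1):
            members = sets.members(r.set_name)
            flags = np.array([g in members for g in genes])
            assert r.statistic == pytest.approx(
                _brute_force_es(scores, flags), abs=1e-12
            )

    def test_top_concentrated_set_has_positive_maximal_es(self, rng):
        ranked = _toy_ranking()
        top_set = set(ranked.gene_ids[:3])
        raw = {"best": ("", top_set)}
        for i, other in enumerate(itertools.combinations(ranked.gene_ids, 3)):
            if set(other) != top_set:
                raw[f"o{i}"] = ("", set(other))
        sets = GeneSetCollection(raw)
        res = {r.set_name: r.statistic for r in gsea_preranked(ranked, sets, n_perm=20, seed=0)}
        assert res["best"] > 0
        assert res["best"] == max(res.values())

    def test_small_sets_skipped(self):
        ranked = _toy_ranking()
        sets = GeneSetCollection({"tiny": ("", {"a", "b", "zz", "ww"})})
        # only 2 members intersect the ranking -> below min_size 3
        assert gsea_preranked(ranked, sets, n_perm=10, seed=0) == []

    def test_null_calibration_uniform(self, rng):
        """Random sets should not be called enriched: p under the null is
        roughly uniform, so P(p < 0.05) stays near 0.05."""
        genes = [f"g{i}" for i in range(400)]
        scores = np.sort(rng.normal(size=400))[::-1]
        ranked = RankedGeneList(genes, scores)
        raw = {
            f"r{i}": ("", set(rng.choice(genes, size=20, replace=False)))
            for i in range(100)
        }
        res = gsea_preranked(ranked, GeneSetCollection(raw), n_perm=500, seed=3)
        frac = np.mean([r.p_value < 0.05 for r in res])
        assert 0.0 <= frac <= 0.12


# ---------------------------------------------------------------------------
# ORA
# ---------------------------------------------------------------------------
def _brute_force_ora_p(N, set_idx, n_sel, observed):
    """Enumerate every selection of size n_sel from an N-gene universe."""
    hits = 0
    total = 0
    for sel in itertools.combinations(range(N), n_sel):
        total += 1
        if len(set(sel) & set_idx) >= observed:
            hits += 1
    return hits / total


class TestOra:
    def test_set_inside_selection_closed_form(self):
        genes = [f"g{i:03d}" for i in range(100)]
        scores = np.arange(100, 0, -1, dtype=float)
        ranked = RankedGeneList(genes, scores)
        sets = GeneSetCollection({"in": ("", set(genes[:5]))})
        res = ora(ranked, sets, top_fraction=0.20)
        expected = math.comb(20, 5) / math.comb(100, 5)
        assert res[0].overlap == 5
        assert res[0].p_value == pytest.approx(expected, rel=1e-12)

    def test_set_outside_selection_p_one(self):
        genes = [f"g{i:03d}" for i in range(50)]
        ranked = RankedGeneList(genes, np.arange(50, 0, -1, dtype=float))
        sets = GeneSetCollection({"out": ("", set(genes[-5:]))})
        res = ora(ranked, sets, top_fraction=0.2)
        assert res[0].overlap == 0
        assert res[0].p_value == pytest.approx(1.0)

    def test_matches_enumeration_on_twelve_gene_universe(self):
        genes = [f"g{i}" for i in range(12)]
        ranked = RankedGeneList(genes, np.arange(12, 0, -1, dtype=float))
        n_sel = math.ceil(0.2 * 12)  # 3
        for set_idx in [{0, 1, 2}, {0, 5, 9, 11}, {3, 4, 6, 7, 8}]:
            members = {genes[i] for i in set_idx}
            sets = GeneSetCollection({"s": ("", members)})
            res = ora(ranked, sets, top_fraction=0.2)
            brute = _brute_force_ora_p(12, set_idx, n_sel, res[0].overlap)
            assert res[0].p_value == pytest.approx(brute, abs=1e-12)

    def test_selection_size_rounds_up(self):
        genes = [f"g{i}" for i in range(11)]
        ranked = RankedGeneList(genes, np.arange(11, 0, -1, dtype=float))
        sets = GeneSetCollection({"s": ("", set(genes[:3]))})
        res = ora(ranked, sets, top_fraction=0.2)  # ceil(2.2) = 3
        assert res[0].overlap == 3


class TestAdjustBh:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.037]), [0.037])

    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=40)
        adj = adjust_bh(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])


# ---------------------------------------------------------------------------
# GMT parsing
# ---------------------------------------------------------------------------
class TestGmt:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("s1\tdesc one\ta\tb\tc\ns2\tdesc two\tx\ty\tz\tw\n")
        sets = read_gmt(path)
        assert sets.members("s1") == {"a", "b", "c"}
        assert sets.members("s2") == {"w", "x", "y", "z"}
        out = tmp_path / "back.gmt"
        sets.write_gmt(out)
        assert read_gmt(out).members("s1") == {"a", "b", "c"}

    def test_min_size_filter(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("small\td\ta\tb\nbig\td\ta\tb\tc\n")
        sets = read_gmt(path, min_size=3)
        assert list(dict(sets)) == ["big"]

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("onlyname\n")
        with pytest.raises(ValueError, match="GMT"):
            read_gmt(path)


# ---------------------------------------------------------------------------
# End-to-end interpretation
# ---------------------------------------------------------------------------
class TestInterpretComponents:
    def test_distinct_scores_dispatch_gsea_everywhere(self):
        m, truth = simulate_expression(
            k=2, n_features=200, n_samples=12, n_markers_per_component=10,
            noise_sd=0.05, seed=31,
        )
        res = nmf_deconvolve(m, 2, seed=1)
        sets = GeneSetCollection(
            {n: ("planted", g) for n, g in truth.marker_sets.items()}
        )
        enr = interpret_components(res, sets, n_perm=100, seed=0)
        assert enr and all(r.method == "GSEA" for r in enr)

    def test_methylation_without_cpg_map_is_error(self, small_methylation):
        from decomix import edec_deconvolve

        m, _, _ = small_methylation
        res = edec_deconvolve(m, 2, seed=0)
        sets = GeneSetCollection({"s": ("", {"gene0001", "gene0002", "gene0003"})})
        with pytest.raises(ValueError, match="cpg_map"):
            interpret_components(res, sets)

    def test_planted_marker_sets_rank_first(self):
        m, truth = simulate_expression(
            k=3, n_features=400, n_samples=24, n_markers_per_component=20,
            noise_sd=0.05, seed=603, n_pure_samples_per_component=1,
        )
        res = nmf_deconvolve(m, 3, seed=1)
        sets = GeneSetCollection(
            {n: ("planted", g) for n, g in truth.marker_sets.items()}
        )
        enr = interpret_components(res, sets, seed=1)
        mm = match_components(res, truth.A_true)
        for comp in range(1, 4):
            rows = {r.set_name: r.p_adjusted for r in enr if r.component == comp}
            truth_row = int(np.flatnonzero(mm.permutation == comp - 1)[0])
            assert rows[f"C{truth_row + 1}"] <= min(rows.values()) + 1e-15

    def test_deterministic_given_seed(self):
        m, truth = simulate_expression(
            k=2, n_features=150, n_samples=12, n_markers_per_component=8,
            noise_sd=0.05, seed=41,
        )
        res = nmf_deconvolve(m, 2, seed=1)
        sets = GeneSetCollection(
            {n: ("planted", g) for n, g in truth.marker_sets.items()}
        )
        e1 = interpret_components(res, sets, n_perm=200, seed=5)
        e2 = interpret_components(res, sets, n_perm=200, seed=5)
        assert [(r.set_name, r.p_value, r.p_adjusted) for r in e1] == [
            (r.set_name, r.p_value, r.p_adjusted) for r in e2
        ]
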