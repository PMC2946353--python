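"""Gene-set aggregation, summary statistics, and visual style mapping."""

from __future__ import annotations

import math
import random
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ersfviz import (
    DataError,
    ExpressionMatrix,
    OntologyGraph,
    aggregate_gene_sets,
    build_animation_frames,
    classify_differential,
    compute_cov,
    compute_node_stats,
    extract_spanning_tree,
    fisher_overrepresentation,
    style_by_value,
    style_differential_view,
)
from ersfviz.stats import DE_THRESHOLD, MIN_DE


def make_matrix(data: dict[str, list[float]], genes: list[str]) -> ExpressionMatrix:
    return ExpressionMatrix(
        values=pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    )


class TestAggregateGeneSets:
    def test_union_semantics(self):
        g = OntologyGraph(edges=[("P", "L1"), ("P", "L2")])
        tree = extract_spanning_tree(g)
        sets = aggregate_gene_sets({"L1": {"g1", "g2"}, "L2": {"g2", "g3"}}, tree)
        assert sets["P"] == {"g1", "g2", "g3"}

    def test_unannotated_subtree_is_empty(self, g1_tree):
        sets = aggregate_gene_sets({"A1": {"g1"}}, g1_tree)
        assert sets["B"] == set()
        assert sets["R"] == {"g1"}

    def test_matches_brute_force_union_over_descendants(self, g1_tree):
        rng = random.Random(3)
        annotation = {
            leaf: {f"g{rng.randrange(40)}" for _ in range(rng.randrange(1, 10))}
            for leaf in g1_tree.leaves
        }
        sets = aggregate_gene_sets(annotation, g1_tree)

        def descendants(node):
            out = {node}
            for c in g1_tree.tree_children(node):
                out |= descendants(c)
            return out

        for node in g1_tree.depth:
            expected = set().union(
                *(annotation.get(d, set()) for d in descendants(node))
            )
            assert sets[node] == expected

    def test_unknown_node_rejected(self, g1_tree):
        with pytest.raises(DataError, match="ZZZ"):
            aggregate_gene_sets({"ZZZ": {"g1"}}, g1_tree)

    def test_aggregation_idempotent(self, g1_tree):
        annotation = {"A1": {"g1"}, "C2": {"g2", "g3"}}
        assert aggregate_gene_sets(annotation, g1_tree) == aggregate_gene_sets(
            annotation, g1_tree
        )


class TestCov:
    def test_direct_formula(self):
        # sigma = sqrt(8/3), mu = 4
        assert compute_cov([2, 4, 6]) == pytest.approx(math.sqrt(8 / 3) / 4)
        assert compute_cov([2, 4, 6]) == pytest.approx(0.40825, abs=1e-5)

    def test_constant_vector_is_zero(self):
        assert compute_cov([5, 5, 5]) == 0.0

    def test_non_positive_mean_is_missing(self, caplog):
        with caplog.at_level("WARNING", logger="ersfviz"):
            assert compute_cov([1.0, -1.0]) is None
            assert compute_cov([-2.0, -4.0]) is None

    def test_nan_excluded_pairwise(self):
        assert compute_cov([2, float("nan"), 4, 6]) == pytest.approx(
            compute_cov([2, 4, 6])
        )

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(0.1, 1e4), min_size=2, max_size=20),
        st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, xs, c):
        """cov(c*x) = cov(x) for any c > 0."""
        base = compute_cov(xs)
        scaled = compute_cov([c * x for x in xs])
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)


class TestClassifyDifferential:
    @pytest.mark.parametrize(
        "control,treatment,expected",
        [
            (1.0, 2.0, "up"),
            (2.0, 1.3, "unchanged"),  # |delta| == threshold, strict rule
            (2.0, 1.2, "down"),
            (5.0, 5.0, "unchanged"),
            (float("nan"), 2.0, "unchanged"),
        ],
    )
    def test_threshold_rule(self, control, treatment, expected):
        assert classify_differential(control, treatment) == expected

    def test_default_threshold_value(self):
        assert DE_THRESHOLD == 0.7

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            classify_differential(0.0, 1.0, threshold=0.0)


class TestFisher:
    def test_worked_example(self):
        universe = {f"g{i}" for i in range(10)}
        node = {f"g{i}" for i in range(5)}
        selected = {"g0", "g1", "g2", "g3", "g9"}  # overlap k = 4
        p = fisher_overrepresentation(selected, node, universe)
        assert p == pytest.approx(26 / 252, abs=1e-12)

    def test_degenerate_tables(self):
        universe = {f"g{i}" for i in range(6)}
        assert fisher_overrepresentation(set(), {"g0"}, universe) == pytest.approx(1.0)
        assert fisher_overrepresentation({"g0", "g1"}, universe, universe) == (
            pytest.approx(1.0)
        )

    def test_empty_universe_rejected(self):
        with pytest.raises(DataError, match="universe"):
            fisher_overrepresentation(set(), set(), set())

    def test_matches_exhaustive_enumeration(self):
        """Upper-tail p equals the explicit hypergeometric sum, universe <= 12."""
        for M in range(1, 13):
            for K in range(M + 1):
                for n in range(M + 1):
                    lo, hi = max(0, n + K - M), min(n, K)
                    for k in range(lo, hi + 1):
                        expected = sum(
                            comb(K, i) * comb(M - K, n - i) for i in range(k, hi + 1)
                        ) / comb(M, n)
                        universe = {f"g{j}" for j in range(M)}
                        node = {f"g{j}" for j in range(K)}
                        selected = {f"g{j}" for j in range(k)} | {
                            f"g{K + j}" for j in range(n - k)
                        }
                        got = fisher_overrepresentation(selected, node, universe)
                        assert got == pytest.approx(expected, abs=1e-12)

    def test_bh_adjustment_matches_direct_formula(self):
        """q-values agree with the step-up formula on a small example."""
        from ersfviz.stats import adjust_p_values

        p = {"a": 0.01, "b": 0.04, "c": 0.03, "d": 0.5, "e": None}
        q = adjust_p_values(p)
        # BH: sort p, q_i = min over j>=i of p_j * m / j (m = 4 tested)
        assert q["a"] == pytest.approx(0.04)
        assert q["c"] == pytest.approx(min(0.03 * 4 / 2, 0.04 * 4 / 3, 0.5))
        assert q["b"] == pytest.approx(0.04 * 4 / 3)
        assert q["d"] == pytest.approx(0.5)
        assert "e" not in q

    def test_monotone_in_overlap(self):
        """Larger observed overlap never increases the one-sided p-value."""
        M, K, n = 40, 12, 15
        universe = {f"g{j}" for j in range(M)}
        node = {f"g{j}" for j in range(K)}
        last = 1.1
        for k in range(min(K, n) + 1):
            selected = {f"g{j}" for j in range(k)} | {
                f"g{K + j}" for j in range(n - k)
            }
            p = fisher_overrepresentation(selected, node, universe)
            assert p <= last + 1e-12
            last = p


class TestNodeStats:
    def test_de_counts_conserved(self, g1_tree):
        genes = [f"g{i}" for i in range(6)]
        matrix = make_matrix(
            {"c": [1, 1, 1, 1, 1, 1], "t": [2.0, 0.1, 1.0, 2.5, -0.2, 1.3]}, genes
        )
        annotation = {"A1": set(genes[:3]), "A2": set(genes[3:])}
        sets = aggregate_gene_sets(annotation, g1_tree)
        stats = compute_node_stats(sets, matrix, condition_pair=("c", "t"))
        calls = [classify_differential(1.0, t) for t in matrix.values["t"]]
        assert stats["R"].n_up == calls.count("up")
        assert stats["R"].n_down == calls.count("down")
        assert stats["R"].n_de == stats["R"].n_up + stats["R"].n_down
        assert stats["A"].n_de == stats["A1"].n_de + stats["A2"].n_de

    def test_mean_median_per_condition(self, g1_tree):
        matrix = make_matrix({"c": [1.0, 3.0, 8.0]}, ["g0", "g1", "g2"])
        sets = aggregate_gene_sets({"A1": {"g0", "g1", "g2"}}, g1_tree)
        stats = compute_node_stats(sets, matrix)
        assert stats["A1"].mean["c"] == pytest.approx(4.0)
        assert stats["A1"].median["c"] == pytest.approx(3.0)
        assert stats["A1"].n_genes == 3


class TestStyleMaps:
    def test_ramp_endpoints(self):
        style = style_by_value({"a": 0.0, "b": 1.0}, "color", value_range=(0.0, 1.0))
        assert style["a"].fill == (0.0, 1.0, 0.0, 1.0)  # pure green
        assert style["b"].fill == (1.0, 0.0, 0.0, 1.0)  # pure red

    def test_missing_stat_grey_and_flat(self):
        style = style_by_value({"a": None, "b": 2.0}, "height", h_max=10.0)
        assert style["a"].fill == (0.5, 0.5, 0.5, 1.0)
        assert style["a"].height == 0.0

    def test_fixed_range_gives_identical_colors_across_frames(self):
        s1 = style_by_value({"a": 0.3}, "color", value_range=(0.0, 1.0))
        s2 = style_by_value({"a": 0.3, "b": 9.9}, "color", value_range=(0.0, 1.0))
        assert s1["a"].fill == s2["a"].fill

    def test_degenerate_range_mid_palette(self, caplog):
        with caplog.at_level("WARNING", logger="ersfviz"):
            style = style_by_value({"a": 2.0, "b": 2.0}, "color")
        assert style["a"].fill == style["b"].fill == (1.0, 1.0, 0.0, 1.0)

    def test_differential_view_encoding(self):
        from ersfviz import NodeStats

        stats = {
            "balanced": NodeStats("balanced", 20, n_up=6, n_down=6),
            "silent": NodeStats("silent", 20, n_up=0, n_down=0),
            "up": NodeStats("up", 20, n_up=7, n_down=1),
        }
        style = style_differential_view(stats, min_de=5, h0=5.0)
        assert style["balanced"].fill == (1.0, 1.0, 1.0, 1.0)  # white
        assert style["silent"].height == 0.0 and not style["silent"].visible
        # s = log2(8/2) = 2 -> 2/3 toward red; height = 5 * log2(9)
        assert style["up"].fill == pytest.approx((1.0, 1 / 3, 1 / 3, 1.0))
        assert style["up"].height == pytest.approx(5.0 * math.log2(9))
        assert style["up"].visible
        assert MIN_DE == 5


class TestAnimationFrames:
    @pytest.fixture
    def matrix7(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(12)]
        conds = [f"c{i}" for i in range(1, 8)]
        return make_matrix(
            {c: rng.normal(8, 1, size=12).tolist() for c in conds}, genes
        )

    @pytest.fixture
    def gene_sets(self, g1_tree, matrix7):
        return aggregate_gene_sets({"A1": set(matrix7.genes)}, g1_tree)

    def test_one_frame_per_condition_in_order(self, matrix7, gene_sets):
        frames = build_animation_frames(matrix7, gene_sets)
        assert [label for label, _ in frames] == [f"c{i}" for i in range(1, 8)]

    def test_single_condition(self, matrix7, gene_sets):
        frames = build_animation_frames(matrix7, gene_sets, conditions=["c1"])
        assert len(frames) == 1

    def test_reorder_and_subset(self, matrix7, gene_sets):
        frames = build_animation_frames(matrix7, gene_sets, conditions=["c3", "c1"])
        assert [label for label, _ in frames] == ["c3", "c1"]

    def test_unknown_condition_rejected(self, matrix7, gene_sets):
        with pytest.raises(DataError, match="c99"):
            build_animation_frames(matrix7, gene_sets, conditions=["c99"])

    def test_shared_range_across_frames(self, matrix7, gene_sets):
        frames = build_animation_frames(matrix7, gene_sets)
        # the same statistic value must map to the same color in every frame:
        # re-style frame 1's values with the default (shared) range and compare
        means = {
            label: {n: st_.fill for n, st_ in style.items()}
            for label, style in frames
        }
        assert set(means["c1"]) == set(means["c2"])


class TestMatrixIO:
    def test_round_trip_with_missing(self, tmp_path):
        matrix = make_matrix({"c1": [1.0, float("nan")], "c2": [2.0, 3.0]}, ["a", "b"])
        path = tmp_path / "expr.csv"
        matrix.write_csv(path)
        back = ExpressionMatrix.read_csv(path)
        assert back.conditions == ["c1", "c2"]
        assert math.isnan(back.values.at["b", "c1"])
        assert back.values.at["b", "c2"] == 3.0

    def test_duplicate_gene_rejected(self):
        with pytest.raises(DataError, match="duplicate"):
            make_matrix({"c": [1.0, 2.0]}, ["a", "a"])
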