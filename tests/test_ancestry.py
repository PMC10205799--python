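"""Ancestor voting: correlation primitives, tie-breaks, oracle equality,
selection rules, DAG layering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import toy_adata
from oracle_utils import naive_ancestor_pipeline
from mamshift.ancestry import (
    ConversionGraph,
    spearman_to_previous,
    top_k_ancestors,
    vote_ancestor_subtype,
    conversion_matrix,
    infer_conversions,
    select_trajectory_subclusters,
    stage_order_graph,
    direction_consistent,
)


class TestSpearman:
    def test_identical_cell_rho_one(self):
        q = np.array([1.0, 5.0, 3.0, 2.0])
        prev = np.vstack([q, [4, 3, 2, 1]])
        rho = spearman_to_previous(q, prev)
        assert rho[0] == pytest.approx(1.0)

    def test_rank_reversal_rho_minus_one(self):
        q = np.array([1.0, 2.0, 3.0, 4.0])
        rho = spearman_to_previous(q, np.array([[8.0, 6.0, 4.0, 2.0]]))
        assert rho[0] == pytest.approx(-1.0)

    def test_six_gene_toy_pair_closed_form(self):
        """x=(1..6) vs y=(2,1,4,3,6,5): all six rank displacements are 1,
        so rho = 1 - 6*6/(6*35) = 29/35 (checked against scipy)."""
        from scipy.stats import spearmanr
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        rho = spearman_to_previous(x, y[None, :])
        assert rho[0] == pytest.approx(29 / 35)
        assert rho[0] == pytest.approx(spearmanr(x, y).statistic)

    def test_zero_variance_prev_cell_is_nan(self):
        q = np.array([1.0, 2.0, 3.0])
        rho = spearman_to_previous(q, np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        assert np.isnan(rho[0]) and rho[1] == pytest.approx(1.0)

    def test_empty_previous_stage_errors(self):
        with pytest.raises(ValueError, match="empty"):
            spearman_to_previous(np.array([1.0, 2, 3]), np.empty((0, 3)))


class TestTopK:
    def test_fewer_prev_cells_than_k(self):
        assignment = top_k_ancestors(np.array([0.5, 0.2, 0.9]),
                                     ["a", "b", "c"], k=5)
        assert [cid for cid, _ in assignment.ancestors] == ["c", "a", "b"]

    def test_cutoff_ties_break_by_cell_id(self):
        rho = np.array([0.9, 0.8, 0.8, 0.7, 0.7, 0.7, 0.1])
        ids = [f"p{i}" for i in range(7)]
        assignment = top_k_ancestors(rho, ids, k=5)
        assert [cid for cid, _ in assignment.ancestors] == ["p0", "p1", "p2", "p3", "p4"]
        again = top_k_ancestors(rho, ids, k=5)
        assert assignment.ancestors == again.ancestors

    def test_k_one_is_argmax(self):
        assignment = top_k_ancestors(np.array([0.1, 0.7, 0.3]), ["a", "b", "c"], k=1)
        assert assignment.ancestors == [("b", 0.7)]

    def test_all_nan_errors(self):
        with pytest.raises(ValueError, match="NaN"):
            top_k_ancestors(np.array([np.nan, np.nan]), ["a", "b"], k=2)


class TestVote:
    def _assignment(self, labeled_rhos):
        from mamshift.ancestry import AncestorAssignment
        return AncestorAssignment(cell_id="q", ancestors=[
            (f"p{i}", r) for i, (_, r) in enumerate(labeled_rhos)]), \
            {f"p{i}": lab for i, (lab, _) in enumerate(labeled_rhos)}

    def test_plurality(self):
        a, labels = self._assignment([("A", .9), ("A", .8), ("A", .7), ("B", .6), ("C", .5)])
        winner, tally = vote_ancestor_subtype(a, labels)
        assert winner == "A" and tally == {"A": 3, "B": 1, "C": 1}

    def test_tie_breaks_by_summed_rho(self):
        a, labels = self._assignment([("A", .9), ("A", .8), ("B", .85), ("B", .65), ("C", .5)])
        winner, _ = vote_ancestor_subtype(a, labels)  # A: 1.7 vs B: 1.5
        assert winner == "A"

    def test_tie_breaks_lexicographically_last(self):
        a, labels = self._assignment([("B", .5), ("A", .5)])
        winner, _ = vote_ancestor_subtype(a, labels)
        assert winner == "A"

    def test_k_one(self):
        a, labels = self._assignment([("B", .4)])
        assert vote_ancestor_subtype(a, labels)[0] == "B"


def _two_stage_adata(prev_X, curr_X, prev_subtypes, curr_subtypes):
    X = np.vstack([prev_X, curr_X])
    n_prev, n_curr = len(prev_X), len(curr_X)
    return toy_adata(
        X,
        cell_ids=[f"a{i:03d}" for i in range(n_prev)] + [f"b{i:03d}" for i in range(n_curr)],
        stage=["s0"] * n_prev + ["s1"] * n_curr,
        stages=["s0", "s1"],
        major_type=["CM"] * (n_prev + n_curr),
        subtype=list(prev_subtypes) + list(curr_subtypes),
    )


class TestConversionMatrix:
    def test_matches_quadruple_loop_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(3):
            n_prev, n_curr, g = 40, 35, 25
            prev = rng.normal(2, 1, size=(n_prev, g))
            curr = rng.normal(2, 1, size=(n_curr, g))
            # inject exact rho ties: duplicate rank profiles among prev cells
            prev[5] = prev[4] + 1.0          # same ranks as prev[4]
            prev[11] = 2 * prev[10]          # monotone copy when positive
            prev_sub = rng.choice(["CM1", "CM2", "CM3"], size=n_prev)
            curr_sub = rng.choice(["CM1", "CM2", "CM3"], size=n_curr)
            adata = _two_stage_adata(prev, curr, prev_sub, curr_sub)
            edges, n_valid, n_invalid = conversion_matrix(adata, "s0", "s1", k=5)
            prev_ids = [f"a{i:03d}" for i in range(n_prev)]
            curr_ids = [f"b{i:03d}" for i in range(n_curr)]
            support, votes, n_valid_o = naive_ancestor_pipeline(
                prev, prev_ids, prev_sub, curr, curr_ids, curr_sub, k=5)
            got = {(r.ancestor, r.descendant): r.support for r in edges.itertuples()}
            assert got == support
            assert n_valid == n_valid_o and n_invalid == 0

    def test_constant_query_is_invalid_vote(self):
        rng = np.random.default_rng(1)
        prev = rng.normal(0, 1, size=(6, 10))
        curr = rng.normal(0, 1, size=(4, 10))
        curr[2] = 3.14
        adata = _two_stage_adata(prev, curr, ["A"] * 6, ["B"] * 4)
        edges, n_valid, n_invalid = conversion_matrix(adata, "s0", "s1", k=3)
        assert n_valid == 3 and n_invalid == 1
        assert edges["support"].sum() == 3

    def test_single_prev_subtype_conservation(self):
        rng = np.random.default_rng(2)
        prev = rng.normal(0, 1, size=(8, 12))
        curr = rng.normal(0, 1, size=(10, 12))
        adata = _two_stage_adata(prev, curr, ["A"] * 8,
                                 ["B"] * 5 + ["C"] * 5)
        edges, n_valid, _ = conversion_matrix(adata, "s0", "s1", k=5)
        assert set(edges["ancestor"]) == {"A"}
        assert edges["support"].sum() == n_valid == 10

    def test_two_runs_identical(self):
        rng = np.random.default_rng(3)
        prev = rng.normal(0, 1, size=(12, 15))
        curr = rng.normal(0, 1, size=(12, 15))
        adata = _two_stage_adata(prev, curr, ["A", "B"] * 6, ["A", "B"] * 6)
        e1, *_ = conversion_matrix(adata, "s0", "s1")
        e2, *_ = conversion_matrix(adata, "s0", "s1")
        pd.testing.assert_frame_equal(e1, e2)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        prev = rng.normal(0, 1, size=(20, 18))
        curr = rng.normal(0, 1, size=(20, 18))
        subs = list(rng.choice(["A", "B"], size=20))
        adata = _two_stage_adata(prev, curr, subs, subs)
        e1, *_ = conversion_matrix(adata, "s0", "s1")
        transformed = _two_stage_adata(np.exp(prev) + prev ** 3,
                                       np.exp(curr) + curr ** 3, subs, subs)
        e2, *_ = conversion_matrix(transformed, "s0", "s1")
        pd.testing.assert_frame_equal(e1, e2)


def _graph(rows):
    edges = pd.DataFrame(rows, columns=["ancestor", "descendant", "transition",
                                        "support", "vote_fraction"])
    nodes = sorted(set(edges["ancestor"]) | set(edges["descendant"]))
    return ConversionGraph(nodes=nodes, edges=edges, params={})


def _props(d):
    return pd.DataFrame(d).T  # dict stage -> {subtype: frac}


class TestSelectionRules:
    def test_min_fraction_strict_boundary(self):
        graph = _graph([("CM2", "CM9", "0w->2w", 50, 1.0)])
        props = _props({"0w": {"CM2": 0.10, "CM9": 0.30},
                        "2w": {"CM2": 0.10, "CM9": 0.40}})
        sel = select_trajectory_subclusters(graph, props)
        assert "CM2" not in sel.retained_subtypes      # exactly 10% -> out
        assert "CM9" in sel.retained_subtypes
        reason = sel.edges.iloc[0]["exclusion_reason"]
        assert "ancestor_below_min_frac" in reason

    def test_support_boundary_inclusive(self):
        graph = _graph([("CM2", "CM9", "0w->2w", 10, 0.5),
                        ("CM3", "CM9", "0w->2w", 9, 0.5)])
        props = _props({"0w": {"CM2": 0.4, "CM3": 0.3, "CM9": 0.2},
                        "2w": {"CM2": 0.3, "CM3": 0.2, "CM9": 0.5}})
        sel = select_trajectory_subclusters(graph, props)
        by = sel.edges.set_index("ancestor")
        assert bool(by.loc["CM2", "retained"])
        assert not bool(by.loc["CM3", "retained"])
        assert by.loc["CM3", "exclusion_reason"] == "support_below_min"

    def test_direction_conflict_rule(self):
        # descendant fell while ancestor rose -> conflict
        assert not direction_consistent(0.1, 0.3, 0.4, 0.2)
        assert direction_consistent(0.3, 0.1, 0.2, 0.4)
        assert direction_consistent(0.3, 0.3, 0.2, 0.2)          # both flat
        # strict variant: any decline of the descendant is a conflict
        assert not direction_consistent(0.3, 0.1, 0.4, 0.39, strict=True)

    def test_planted_conversion_retained_reverse_flagged(self):
        graph = _graph([("CM2", "CM9", "0w->2w", 60, 0.8),
                        ("CM9", "CM2", "0w->2w", 15, 0.2)])
        props = _props({"0w": {"CM2": 0.30, "CM9": 0.02},
                        "2w": {"CM2": 0.05, "CM9": 0.25}})
        sel = select_trajectory_subclusters(graph, props)
        by = sel.edges.set_index(["ancestor", "descendant"])
        assert bool(by.loc[("CM2", "CM9"), "retained"])
        assert not bool(by.loc[("CM9", "CM2"), "consistent"])
        assert "inconsistent_direction" in by.loc[("CM9", "CM2"), "exclusion_reason"]

    def test_every_exclusion_names_a_rule(self):
        graph = _graph([("CM4", "CM5", "0w->2w", 3, 1.0)])
        props = _props({"0w": {"CM4": 0.05, "CM5": 0.05},
                        "2w": {"CM4": 0.05, "CM5": 0.05}})
        sel = select_trajectory_subclusters(graph, props)
        row = sel.edges.iloc[0]
        assert not row["retained"]
        for rule in ("ancestor_below_min_frac", "descendant_below_min_frac",
                     "support_below_min"):
            assert rule in row["exclusion_reason"]


class TestStageOrderGraph:
    def test_two_layer_example(self):
        edges = pd.DataFrame([
            {"ancestor": "CM2", "descendant": "CM9"},
            {"ancestor": "CM3", "descendant": "CM10"},
        ])
        assert stage_order_graph(edges) == [["CM2", "CM3"], ["CM10", "CM9"]]

    def test_empty_edges(self):
        assert stage_order_graph(pd.DataFrame(columns=["ancestor", "descendant"])) == []

    def test_chain_three_layers(self):
        edges = pd.DataFrame([
            {"ancestor": "CM2", "descendant": "CM9"},
            {"ancestor": "CM9", "descendant": "CM11"},
        ])
        assert stage_order_graph(edges) == [["CM2"], ["CM9"], ["CM11"]]

    def test_cycle_reported(self):
        edges = pd.DataFrame([
            {"ancestor": "CM2", "descendant": "CM9"},
            {"ancestor": "CM9", "descendant": "CM2"},
        ])
        with pytest.raises(ValueError, match="cycle"):
            stage_order_graph(edges)

    def test_self_loops_dropped(self):
        edges = pd.DataFrame([
            {"ancestor": "CM2", "descendant": "CM2"},
            {"ancestor": "CM2", "descendant": "CM9"},
        ])
        assert stage_order_graph(edges) == [["CM2"], ["CM9"]]


def test_infer_conversions_multi_transition_conservation(small_cohort):
    cfg, adata, _ = small_cohort
    from mamshift.preprocessing import log_normalize, qc_filter
    norm = log_normalize(qc_filter(adata)[0])
    graph = infer_conversions(norm, k=5, n_hvg=300)
    for s_prev, s_curr in zip(cfg.stages[:-1], cfg.stages[1:]):
        t = f"{s_prev}->{s_curr}"
        total = graph.edges.loc[graph.edges["transition"] == t, "support"].sum()
        assert total == graph.n_valid_votes[t]


@settings(derandomize=True, max_examples=15, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_spearman_monotone_invariance_property(seed):
    rng = np.random.default_rng(seed)
    q = rng.normal(0, 1, size=12)
    prev = rng.normal(0, 1, size=(5, 12))
    base = spearman_to_previous(q, prev)
    transformed = spearman_to_previous(np.exp(q) * 3 + 1, np.exp(prev) * 3 + 1)
    assert np.allclose(base, transformed, equal_nan=True)
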