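"""Clustering, expression filtering and gene-tree reconciliation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oracle_reconcile as oracle
from cucwgd import simdata
from cucwgd.dupmap import (
    DUPLICATION,
    SPECIATION,
    ClusteringConfig,
    branch_duplication_proportions,
    classify_homolog_pairs,
    expression_filter,
    reconcile_lca,
    transitive_cluster,
)


class TestTransitiveCluster:
    def test_transitivity(self):
        clusters = transitive_cluster(
            [("A", "B", 150, 98.0), ("B", "C", 120, 97.5)]
        )
        assert clusters == [{"A", "B", "C"}]

    def test_overlap_at_threshold_fails(self):
        clusters = transitive_cluster([("A", "B", 100, 99.0)])
        assert sorted(map(sorted, clusters)) == [["A"], ["B"]]

    def test_identity_at_threshold_fails(self):
        # "higher than 97%" is strict: exactly 97.0 does not link
        clusters = transitive_cluster([("A", "B", 150, 97.0)])
        assert sorted(map(sorted, clusters)) == [["A"], ["B"]]

    def test_singletons_from_all_ids(self):
        clusters = transitive_cluster([], all_ids=["X", "Y"])
        assert sorted(map(sorted, clusters)) == [["X"], ["Y"]]

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            transitive_cluster([("A", "B", -1, 99.0)])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_permutation_and_reversal(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"t{i}" for i in range(12)]
        hits = [
            (ids[int(rng.integers(12))], ids[int(rng.integers(12))],
             float(rng.integers(50, 200)), float(rng.uniform(90, 100)))
            for _ in range(15)
        ]
        ref = sorted(map(sorted, transitive_cluster(hits, all_ids=ids)))
        perm = list(hits)
        rng.shuffle(perm)
        perm = [(b, a, o, i) for a, b, o, i in perm]
        assert sorted(map(sorted, transitive_cluster(perm, all_ids=ids))) == ref


class TestExpressionFilter:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["transcript_id", "component", "expression"])

    def test_strict_one_percent_boundary(self):
        table = self._table(
            [("max", "c1", 1000.0), ("at", "c1", 10.0), ("below", "c1", 9.0)]
        )
        kept = expression_filter(table)
        assert set(kept["transcript_id"]) == {"max", "at"}

    def test_all_equal_kept(self):
        table = self._table([(f"t{i}", "c1", 5.0) for i in range(4)])
        assert len(expression_filter(table)) == 4

    def test_lone_zero_transcript_kept(self):
        table = self._table([("t", "c1", 0.0)])
        assert len(expression_filter(table)) == 1

    def test_negative_expression_rejected(self):
        with pytest.raises(ValueError):
            expression_filter(self._table([("t", "c1", -1.0)]))

    def test_recovers_planted_truth(self):
        table, truth = simdata.sim_expression_components(8, 60, 0.35, seed=4)
        kept = expression_filter(table)
        dropped = set(table["transcript_id"]) - set(kept["transcript_id"])
        assert dropped == set(truth.below_threshold_ids)


class TestReconcileHandExamples:
    S_TREE = "(A,B);"

    def test_root_duplication_two_copies(self):
        rec = reconcile_lca("((A__a1,B__b1),(A__a2,B__b2));", self.S_TREE)
        by_leaves = dict(zip(rec.events["leaves"], rec.events["event"]))
        assert by_leaves["A__a1,A__a2,B__b1,B__b2"] == DUPLICATION
        assert by_leaves["A__a1,B__b1"] == SPECIATION
        assert by_leaves["A__a2,B__b2"] == SPECIATION
        dup = rec.events[rec.events["event"] == DUPLICATION]
        assert dup["species_branch"].tolist() == ["A|B"]

    def test_simple_speciation(self):
        rec = reconcile_lca("(A__a1,B__b1);", self.S_TREE)
        assert rec.events["event"].tolist() == [SPECIATION]

    def test_terminal_branch_duplication(self):
        rec = reconcile_lca("((A__a1,A__a2),B__b1);", self.S_TREE)
        by_leaves = dict(zip(rec.events["leaves"], rec.events["event"]))
        assert by_leaves["A__a1,A__a2"] == DUPLICATION
        dup = rec.events[rec.events["event"] == DUPLICATION]
        assert dup["species_branch"].tolist() == ["A"]

    def test_missing_species_errors(self):
        with pytest.raises(ValueError, match="Z"):
            reconcile_lca("(Z__z1,B__b1);", self.S_TREE)

    def test_every_internal_node_labelled(self):
        rec = reconcile_lca(
            "(((A__1,B__2),(C__3,D__4)),((A__5,C__6),D__7));",
            "((A,B),(C,D));",
        )
        assert len(rec.events) == 6  # binary tree with 7 leaves
        assert set(rec.events["event"]) <= {SPECIATION, DUPLICATION}


class TestReconcileOracle:
    """Exhaustive agreement with set-based brute force, <= 5 leaves here
    (the full <= 6 sweep runs in the acceptance suite)."""

    S_TUPLE = (("A", "B"), ("C", "D"))
    S_NEWICK = "((A,B),(C,D));"

    @pytest.mark.parametrize("n_leaves", [2, 3, 4, 5])
    def test_agrees_with_bruteforce(self, n_leaves):
        clades = oracle.species_clades(self.S_TUPLE)
        for multiset in itertools.combinations_with_replacement("ABCD", n_leaves):
            for gtree in oracle.all_rooted_trees(multiset):
                newick, _ = oracle.tuple_to_newick(gtree)
                rec = reconcile_lca(newick, self.S_NEWICK)
                got = dict(zip(rec.events["leaves"], rec.events["event"]))
                expected = {
                    k: v[0]
                    for k, v in oracle.relabel_oracle_keys(
                        oracle.oracle_events(gtree, clades), gtree
                    ).items()
                }
                assert got == expected, f"mismatch on {newick}"


class TestBranchProportions:
    def test_ninety_percent_on_stem(self):
        stree = "((A,B)AB,C);"
        dup = "((A__1,B__2),(A__3,B__4));"
        nodup = "(A__1,B__2);"
        recs = [reconcile_lca(dup, stree)] * 9 + [reconcile_lca(nodup, stree)]
        table = branch_duplication_proportions(recs, stree)
        by_branch = dict(zip(table["species_branch"], table["proportion"]))
        assert by_branch["AB"] == pytest.approx(0.9)

    def test_no_duplications_all_zero(self):
        stree = "(A,B);"
        recs = [reconcile_lca("(A__1,B__2);", stree)]
        table = branch_duplication_proportions(recs, stree)
        assert (table["proportion"] == 0).all()

    def test_family_counts_once_per_branch(self):
        stree = "(A,B);"
        # two separate duplications on the terminal A branch in one family
        rec = reconcile_lca("(((A__1,A__2),(A__3,A__4)),B__5);", stree)
        assert rec.n_duplications == 3
        table = branch_duplication_proportions([rec], stree)
        by_branch = dict(zip(table["species_branch"], table["n_duplicated_families"]))
        assert by_branch["A"] == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            branch_duplication_proportions([], "(A,B);")

    def test_simulated_stem_wgd_recovered(self):
        scenario = simdata.WgdScenario(
            "((A:0.02,B:0.02)AB:0.03,C:0.05);", "AB",
            retention=1.0, n_families=50, seq_length_codons=10, seed=9,
        )
        _, truth = simdata.sim_cds_families(scenario)
        stree = "((A,B)AB,C);"
        recs = [reconcile_lca(nwk, stree) for nwk in truth.gene_trees.values()]
        table = branch_duplication_proportions(recs, stree)
        by_branch = dict(zip(table["species_branch"], table["proportion"]))
        assert by_branch["AB"] >= 0.9
        assert max(by_branch, key=by_branch.get) == "AB"


class TestHomologPairs:
    def test_pairs_from_root_duplication(self):
        rec = reconcile_lca("((A__a1,B__b1),(A__a2,B__b2));", "(A,B);")
        labels = dict(classify_homolog_pairs(rec))
        assert labels[("A__a1", "B__b1")] == "ortholog"
        assert labels[("A__a1", "A__a2")] == "paralog"
        assert labels[("A__a1", "B__b2")] == "paralog"
        assert len(labels) == 6

    def test_single_pair_tree(self):
        rec = reconcile_lca("(A__a1,B__b1);", "(A,B);")
        assert dict(classify_homolog_pairs(rec)) == {("A__a1", "B__b1"): "ortholog"}

    def test_agrees_with_simulator_truth(self):
        scenario = simdata.WgdScenario(
            "((A:0.02,B:0.02)AB:0.03,C:0.05);", "AB",
            retention=1.0, n_families=20, seq_length_codons=10, seed=1,
        )
        _, truth = simdata.sim_cds_families(scenario)
        stree = "((A,B)AB,C);"
        for fam, nwk in truth.gene_trees.items():
            rec = reconcile_lca(nwk, stree)
            got = {
                "|".join(pair): label for pair, label in classify_homolog_pairs(rec)
            }
            assert got == truth.pair_class[fam]


class TestConfig:
    def test_nonpositive_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ClusteringConfig(min_overlap_bp=0)
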