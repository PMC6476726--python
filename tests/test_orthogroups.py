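"""Presence/absence analytics: Jaccard metric axioms, clustering
cross-checked against scipy, Venn partition, single-copy extraction and
Robinson-Foulds distance."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from redyeast.errors import UsageError
from redyeast.io_formats import OrthoGroup
from redyeast.orthogroups import (
    ClusterParams,
    cluster_genomes,
    jaccard_distances,
    presence_matrix,
    rf_distance,
    single_copy_groups,
    venn_partition,
)
from redyeast.synthetic import simulate_gene_families


def _groups(design):
    """design: {group_id: {species: n_copies}}"""
    return [
        OrthoGroup(gid, {sp: tuple(f"{gid}_{sp}_{i}" for i in range(n)) for sp, n in mem.items()})
        for gid, mem in design.items()
    ]


class TestPresenceMatrix:
    def test_basic_cells_and_warning(self):
        groups = _groups({"OG1": {"A": 1, "B": 1}, "OG2": {"A": 2}})
        with pytest.warns(UserWarning, match="C"):
            mat = presence_matrix(groups, ["A", "B", "C"])
        assert mat.loc["A"].tolist() == [1, 1]
        assert mat.loc["B"].tolist() == [1, 0]
        assert mat.loc["C"].tolist() == [0, 0]

    def test_row_sums_equal_membership_counts(self):
        groups = _groups({"OG1": {"A": 1, "B": 3}, "OG2": {"B": 1}, "OG3": {"A": 1, "B": 1}})
        mat = presence_matrix(groups, ["A", "B"])
        assert mat.loc["A"].sum() == 2 and mat.loc["B"].sum() == 3

    def test_generator_round_trip(self):
        tree = "((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1,E:0.1);"
        groups, truth = simulate_gene_families(tree, 500, 9)
        mat = presence_matrix(groups, list(truth.index))
        assert (mat.values == truth.values).all()


class TestJaccard:
    def test_known_values(self):
        mat = pd.DataFrame(
            [[1, 1, 1, 0], [0, 1, 1, 1], [0, 0, 0, 0]],
            index=["A", "B", "C"], columns=list("wxyz"),
        )
        d = jaccard_distances(mat)
        assert d.loc["A", "B"] == pytest.approx(0.5)  # 1 - 2/4
        assert d.loc["A", "A"] == 0.0
        assert d.loc["A", "C"] == 1.0  # disjoint
        assert d.loc["C", "C"] == 0.0  # empty vs itself

    def test_identical_rows_distance_zero(self):
        mat = pd.DataFrame([[1, 0, 1], [1, 0, 1]], index=["A", "B"])
        assert jaccard_distances(mat).loc["A", "B"] == 0.0

    def test_matches_scipy_on_nonempty_rows(self, rng):
        from scipy.spatial.distance import pdist, squareform

        M = (rng.random((6, 40)) < 0.5).astype(int)
        M[:, 0] = 1  # no empty rows
        mat = pd.DataFrame(M, index=list("ABCDEF"))
        ours = jaccard_distances(mat).to_numpy()
        theirs = squareform(pdist(M, metric="jaccard"))
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_metric_axioms(self, rng):
        for _ in range(20):
            M = (rng.random((5, 30)) < rng.uniform(0.2, 0.8)).astype(int)
            mat = pd.DataFrame(M, index=list("ABCDE"))
            d = jaccard_distances(mat).to_numpy()
            assert (d >= 0).all() and (d <= 1).all()
            np.testing.assert_allclose(d, d.T)
            assert np.diag(d).sum() == 0
            for i, j, k in combinations(range(5), 3):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def _scipy_newick(dist: pd.DataFrame, method: str) -> str:
    from scipy.cluster.hierarchy import linkage, to_tree
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(dist.to_numpy(), checks=False), method=method)
    labels = list(dist.index)

    def walk(node):
        if node.is_leaf():
            return labels[node.id]
        return f"({walk(node.left)},{walk(node.right)})"

    return walk(to_tree(Z)) + ";"


class TestClusterGenomes:
    def test_two_genomes_cherry_at_half_distance(self):
        mat = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["A", "B"], columns=["A", "B"])
        nwk = cluster_genomes(mat)
        assert nwk == "(A:0.2,B:0.2);"

    def test_three_genome_topology(self):
        d = pd.DataFrame(
            [[0, 0.1, 0.8], [0.1, 0, 0.8], [0.8, 0.8, 0]],
            index=list("ABC"), columns=list("ABC"),
        )
        for linkage in ("average", "complete", "single"):
            nwk = cluster_genomes(d, ClusterParams(linkage))
            assert rf_distance(nwk, "((A,B),C);") == 0

    def test_merge_heights_non_decreasing(self, rng):
        from redyeast.io_formats import parse_newick

        M = (rng.random((6, 60)) < 0.5).astype(int)
        M[:, 0] = 1
        d = jaccard_distances(pd.DataFrame(M, index=list("ABCDEF")))
        tree = parse_newick(cluster_genomes(d))
        for node in tree.postorder_node_iter():
            for child in node.child_nodes():
                assert child.edge.length >= -1e-12

    def test_topology_matches_scipy(self, rng):
        for _ in range(10):
            M = (rng.random((6, 80)) < 0.5).astype(int)
            M[:, 0] = 1
            d = jaccard_distances(pd.DataFrame(M, index=list("ABCDEF")))
            ours = cluster_genomes(d, ClusterParams("average"))
            theirs = _scipy_newick(d, "average")
            assert rf_distance(ours, theirs) == 0


class TestVennAndSingleCopy:
    def test_all_core(self):
        groups = _groups({f"OG{i}": {"A": 1, "B": 1} for i in range(4)})
        mat = presence_matrix(groups, ["A", "B"])
        counts = venn_partition(mat)
        assert counts == {frozenset({"A", "B"}): 4}

    def test_manual_enumeration_three_genomes(self):
        design = {
            "OG1": {"A": 1, "B": 1, "C": 1},
            "OG2": {"A": 1, "B": 1, "C": 2},
            "OG3": {"A": 1},
            "OG4": {"A": 1},
            "OG5": {"B": 1, "C": 1},
            "OG6": {"C": 1},
        }
        mat = presence_matrix(_groups(design), ["A", "B", "C"])
        counts = venn_partition(mat)
        assert counts[frozenset("ABC")] == 2
        assert counts[frozenset("A")] == 2
        assert counts[frozenset({"B", "C"})] == 1
        assert counts[frozenset("C")] == 1
        assert sum(counts.values()) == 6

    def test_single_copy_rules(self):
        design = {
            "OG1": {"A": 1, "B": 1, "C": 1},   # kept
            "OG2": {"A": 1, "B": 1},            # missing C
            "OG3": {"A": 2, "B": 1, "C": 1},   # duplicated in A
        }
        sc = single_copy_groups(_groups(design), ["A", "B", "C"])
        assert [g.group_id for g in sc] == ["OG1"]

    def test_single_copy_groups_lie_in_core(self):
        tree = "((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1,E:0.2);"
        groups, _ = simulate_gene_families(tree, 400, 12)
        genomes = list("ABCDE")
        mat = presence_matrix(groups, genomes)
        counts = venn_partition(mat)
        core_ids = {
            g.group_id for g in groups if set(g.members) == set(genomes)
        }
        sc_ids = {g.group_id for g in single_copy_groups(groups, genomes)}
        assert sc_ids <= core_ids
        assert counts.get(frozenset(genomes), 0) == len(core_ids)


class TestRfDistance:
    def test_identical_trees(self):
        assert rf_distance("((A,B),(C,D));", "((A,B),(C,D));") == 0

    def test_one_nni_costs_two(self):
        assert rf_distance("((A,B),C,D);", "((A,C),B,D);") == 2

    def test_leaf_set_mismatch_raises(self):
        with pytest.raises(UsageError):
            rf_distance("(A,(B,C));", "(A,(B,D));")


class TestPipelineRecovery:
    def test_dendrogram_matches_generating_tree(self):
        """Loss-driven presence/absence profiles recover the species
        topology in the clear majority of replicates (small version of the
        full 100-replicate check)."""
        tree = "((A:0.05,B:0.07):0.12,(C:0.06,D:0.09):0.1,E:0.25);"
        hits = 0
        for seed in range(10):
            groups, _ = simulate_gene_families(tree, 2000, seed)
            mat = presence_matrix(groups, list("ABCDE"))
            nwk = cluster_genomes(jaccard_distances(mat))
            hits += rf_distance(nwk, tree) == 0
        assert hits >= 9
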