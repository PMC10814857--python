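"""p-distances, neighbor joining against the additive-matrix oracle, family cuts."""

import random

import numpy as np
import pytest
from skbio import DistanceMatrix
from sklearn.metrics import adjusted_rand_score

from sh3prm.interface_msa import Alignment, InterfaceColumns, extract_interface_alignment
from sh3prm.phylo import (
    alignment_distance_matrix,
    cut_into_families,
    neighbor_joining,
    p_distance,
    read_newick,
    read_phylip,
    tree_path_distances,
    tree_splits,
    write_newick,
    write_phylip,
)
from sh3prm.synthetic import GeneratorConfig, simulate_sh3_families

from conftest import random_additive_tree, tree_metric


class TestPDistance:
    def test_single_mismatch_over_six_sites(self):
        assert p_distance("ENDPEW", "ENKPEW") == pytest.approx(1 / 6)

    def test_identity_is_zero(self):
        assert p_distance("ACDEFG", "ACDEFG") == 0.0

    def test_gapped_sites_excluded(self):
        # comparable sites are {1, 4} only, both equal
        assert p_distance("A-CD", "AB-D") == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            p_distance("AC", "ACD")

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(ValueError):
            p_distance("A--", "-BB")


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float), ["A", "B", "C"])
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(np.array([[0, 1], [1, 0]], float), ["A", "B"])
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        rng = random.Random(1)
        edges, leaves = random_additive_tree(4, rng)
        dm = DistanceMatrix(tree_metric(edges, 4), leaves)
        tree = neighbor_joining(dm)
        recovered = tree_path_distances(tree)
        for a in leaves:
            for b in leaves:
                assert recovered[a, b] == pytest.approx(dm[a, b], abs=1e-9)

    @pytest.mark.parametrize("n_leaves", [5, 9, 14, 20])
    def test_additive_round_trip_topology_and_lengths(self, n_leaves):
        rng = random.Random(n_leaves)
        edges, leaves = random_additive_tree(n_leaves, rng)
        dm = DistanceMatrix(tree_metric(edges, n_leaves), leaves)
        tree = neighbor_joining(dm)
        recovered = tree_path_distances(tree)
        for i, a in enumerate(leaves):
            for b in leaves[i + 1 :]:
                assert recovered[a, b] == pytest.approx(dm[a, b], abs=1e-9)

    def test_taxon_order_does_not_change_splits_or_metric(self):
        rng = random.Random(99)
        edges, leaves = random_additive_tree(8, rng)
        m = tree_metric(edges, 8)
        dm = DistanceMatrix(m, leaves)
        perm = list(range(8))
        rng.shuffle(perm)
        dm_perm = DistanceMatrix(m[np.ix_(perm, perm)], [leaves[i] for i in perm])
        t1, t2 = neighbor_joining(dm), neighbor_joining(dm_perm)
        assert tree_splits(t1) == tree_splits(t2)
        d1, d2 = tree_path_distances(t1), tree_path_distances(t2)
        for i, a in enumerate(leaves):
            for b in leaves[i + 1 :]:
                assert d1[a, b] == pytest.approx(d2[a, b], abs=1e-9)

    def test_all_equal_distances_stable_across_runs(self):
        dm = DistanceMatrix(np.ones((5, 5)) - np.eye(5), list("ABCDE"))
        s1 = tree_splits(neighbor_joining(dm))
        s2 = tree_splits(neighbor_joining(dm))
        assert s1 == s2  # deterministic tie-break


class TestFamilyCut:
    @pytest.fixture()
    def cohort_tree(self):
        cohort = simulate_sh3_families(GeneratorConfig(seed=4, domains_per_family=3))
        aln = Alignment(cohort.alignment_records)
        iface = extract_interface_alignment(aln, InterfaceColumns(cohort.interface_columns))
        tree = neighbor_joining(alignment_distance_matrix(iface))
        return tree, cohort

    def test_k_one_yields_single_family(self, cohort_tree):
        tree, _ = cohort_tree
        part = cut_into_families(tree, 1)
        assert set(part.values()) == {1}

    def test_k_equal_leaf_count_yields_singletons(self, cohort_tree):
        tree, _ = cohort_tree
        n = len(list(tree.tips()))
        part = cut_into_families(tree, n)
        assert sorted(part.values()) == list(range(1, n + 1))

    def test_k_out_of_range_rejected(self, cohort_tree):
        tree, _ = cohort_tree
        with pytest.raises(ValueError):
            cut_into_families(tree, 0)
        with pytest.raises(ValueError):
            cut_into_families(tree, len(list(tree.tips())) + 1)

    def test_planted_families_recovered_with_perfect_ari(self, cohort_tree):
        tree, cohort = cohort_tree
        part = cut_into_families(tree, 10)
        ids = sorted(cohort.true_families)
        ari = adjusted_rand_score(
            [cohort.true_families[i] for i in ids], [part[i] for i in ids]
        )
        assert ari == pytest.approx(1.0)


class TestInterfaceVsFullContrast:
    def test_family_signal_lives_at_interface_columns_only(self):
        """Interface-restricted tree recovers families perfectly; the
        full-sequence tree, dominated by the orthogonal background clade
        structure, does strictly worse."""
        cohort = simulate_sh3_families(GeneratorConfig(seed=1))
        aln = Alignment(cohort.alignment_records)
        iface = extract_interface_alignment(aln, InterfaceColumns(cohort.interface_columns))
        ids = sorted(cohort.true_families)
        truth = [cohort.true_families[i] for i in ids]

        def ari_of(a: Alignment) -> float:
            tree = neighbor_joining(alignment_distance_matrix(a))
            part = cut_into_families(tree, 10)
            return adjusted_rand_score(truth, [part[i] for i in ids])

        ari_iface, ari_full = ari_of(iface), ari_of(aln)
        assert ari_iface == pytest.approx(1.0)
        assert ari_full < ari_iface


class TestSerialization:
    def test_newick_round_trip(self, tmp_path):
        rng = random.Random(3)
        edges, leaves = random_additive_tree(6, rng)
        tree = neighbor_joining(DistanceMatrix(tree_metric(edges, 6), leaves))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        again = read_newick(path)
        assert tree_splits(again) == tree_splits(tree)
        d1, d2 = tree_path_distances(tree), tree_path_distances(again)
        for i, a in enumerate(leaves):
            for b in leaves[i + 1 :]:
                assert d2[a, b] == pytest.approx(d1[a, b], rel=1e-6)

    def test_phylip_round_trip(self, tmp_path):
        aln = Alignment([("a", "ACDE"), ("b", "ACDD"), ("c", "AAAA")])
        dm = alignment_distance_matrix(aln)
        path = tmp_path / "d.phy"
        write_phylip(dm, path)
        again = read_phylip(path)
        for x in dm.ids:
            for y in dm.ids:
                assert again[x, y] == pytest.approx(dm[x, y], abs=1e-6)
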