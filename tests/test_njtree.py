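import io

import numpy as np
import pytest

import _oracles as oracles
from subspec.io_formats import MultipleAlignment
from subspec.njtree import (
    DistanceMatrix,
    neighbor_joining,
    pairwise_distances,
    read_partition_table,
    substrate_subgroups,
    tree_path_distances,
    write_partition_table,
)


class TestPairwiseDistances:
    @pytest.mark.parametrize(
        "row_a, row_b, expected",
        [
            ("AAAA", "AAAA", 0.0),
            ("AAAA", "AAAT", 0.25),
            ("A-CD", "AAC-", 0.0),  # only columns 1 and 3 comparable, both match
        ],
    )
    def test_examples(self, row_a, row_b, expected):
        aln = MultipleAlignment(["a", "b"], [row_a, row_b])
        assert pairwise_distances(aln).get("a", "b") == pytest.approx(expected)

    def test_no_comparable_columns_gives_distance_one(self, caplog):
        aln = MultipleAlignment(["a", "b"], ["A-", "-A"])
        assert pairwise_distances(aln).get("a", "b") == 1.0


class TestNeighborJoining:
    def test_hand_computed_four_taxon_case(self):
        d = np.array(
            [
                [0.0, 0.2, 0.4, 0.4],
                [0.2, 0.0, 0.4, 0.4],
                [0.4, 0.4, 0.0, 0.2],
                [0.4, 0.4, 0.2, 0.0],
            ]
        )
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c", "d"], d))
        back = tree_path_distances(tree)
        assert np.allclose(back.d, d, atol=1e-12)
        # all four external branches are 0.1 by hand calculation
        for leaf in tree.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(0.1)

    def test_three_taxon_closure(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.4], [0.5, 0.4, 0.0]])
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.4) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.4 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.4 - 0.3) / 2)

    def test_fewer_than_three_taxa_rejected(self):
        d = np.array([[0.0, 0.1], [0.1, 0.0]])
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(DistanceMatrix(["a", "b"], d))

    def test_additivity_on_random_additive_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            true = oracles.random_additive_tree(rng, n)
            dm = tree_path_distances(true)
            est = neighbor_joining(dm)
            assert np.allclose(tree_path_distances(est).d, dm.d, atol=1e-9)
            assert oracles.rf_distance(true, est) == 0

    def test_matches_dendropy_nj_topology(self):
        import dendropy

        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            true = oracles.random_additive_tree(rng, n)
            dm = tree_path_distances(true)
            mine = neighbor_joining(dm)
            csv_rows = ["," + ",".join(dm.ids)]
            for i, a in enumerate(dm.ids):
                csv_rows.append(a + "," + ",".join(str(v) for v in dm.d[i]))
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                src=io.StringIO("\n".join(csv_rows) + "\n")
            )
            theirs = pdm.nj_tree()
            assert oracles.rf_distance(mine, theirs) == 0

    def test_atteson_robustness_to_small_noise(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            true = oracles.random_additive_tree(rng, 6, min_branch=0.1, max_branch=0.3)
            dm = tree_path_distances(true)
            noise = rng.uniform(-0.02, 0.02, dm.d.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0.0)
            noisy = DistanceMatrix(dm.ids, np.abs(dm.d + noise))
            assert oracles.rf_distance(true, neighbor_joining(noisy)) == 0

    def test_agrees_with_exhaustive_minimum_evolution(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(4, 7))
            true = oracles.random_additive_tree(rng, n)
            dm = tree_path_distances(true)
            est = neighbor_joining(dm)
            est_len = sum(
                e.length for e in est.preorder_edge_iter() if e.length is not None
            )
            lengths = [
                oracles.ols_tree_length(edges, dm.d)
                for edges in oracles.all_unrooted_topologies(n)
            ]
            assert est_len == pytest.approx(min(lengths), abs=1e-8)


class TestSubstrateSubgroups:
    def _planted_tree_dataset(self):
        from subspec.synthetic import SimulationConfig, simulate_family

        # group S1 planted in two clades of sizes 8 and 7
        return simulate_family(
            SimulationConfig(
                seed=9,
                group_sizes=(15, 6),
                scaffold_length=80,
                specificity_positions=3,
                scaffold_mutation_rate=0.03,
                convergent_labels=("S1",),
                convergent_minor_size=7,
                backbone_edges=10,
            )
        )

    def test_recovers_planted_two_clade_partition(self):
        ds = self._planted_tree_dataset()
        tree = neighbor_joining(pairwise_distances(ds.core_alignment))
        labels = {s.id: s.substrate for s in ds.sequences}
        part = substrate_subgroups(tree, labels, "S1", max_parts=4, min_part_size=3)
        assert sorted(len(p) for p in part.subgroups) == [7, 8]
        got = {frozenset(p) for p in part.subgroups}
        want = {
            frozenset(ds.clade_members("S1/major")),
            frozenset(ds.clade_members("S1/minor")),
        }
        assert got == want

    def test_monophyletic_group_is_not_subdivided(self):
        ds = self._planted_tree_dataset()
        tree = neighbor_joining(pairwise_distances(ds.core_alignment))
        labels = {s.id: s.substrate for s in ds.sequences}
        part = substrate_subgroups(tree, labels, "S2", max_parts=4, min_part_size=2)
        assert part.not_subdivided and len(part.subgroups) == 1

    def test_too_small_group_flagged(self):
        ds = self._planted_tree_dataset()
        tree = neighbor_joining(pairwise_distances(ds.core_alignment))
        labels = {s.id: s.substrate for s in ds.sequences}
        part = substrate_subgroups(tree, labels, "S2", max_parts=4, min_part_size=5)
        assert part.not_subdivided

    def test_partition_invariant_to_leaf_input_order(self):
        ds = self._planted_tree_dataset()
        aln = ds.core_alignment
        labels = {s.id: s.substrate for s in ds.sequences}
        part1 = substrate_subgroups(
            neighbor_joining(pairwise_distances(aln)), labels, "S1", 4, 3
        )
        order = list(reversed(range(len(aln.ids))))
        shuffled = MultipleAlignment(
            [aln.ids[i] for i in order], [aln.rows[i] for i in order]
        )
        part2 = substrate_subgroups(
            neighbor_joining(pairwise_distances(shuffled)), labels, "S1", 4, 3
        )
        assert part1.subgroups == part2.subgroups

    def test_parts_table_round_trip(self, tmp_path):
        ds = self._planted_tree_dataset()
        tree = neighbor_joining(pairwise_distances(ds.core_alignment))
        labels = {s.id: s.substrate for s in ds.sequences}
        part = substrate_subgroups(tree, labels, "S1", 4, 3)
        p = tmp_path / "parts.tsv"
        write_partition_table({"S1": part}, p)
        back = read_partition_table(p)
        assert back["S1"].subgroups == part.subgroups
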