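"""Band distances, UPGMA construction, bootstrap support and Newick output."""

import numpy as np
import pytest

from plumprint.genotype_io import to_binary_matrix
from plumprint.model import AlleleMatrix
from plumprint.phylogeny import (
    DistanceMatrix,
    bootstrap_support,
    pairwise_distance,
    to_newick,
    upgma,
    write_newick,
)
from plumprint.simulate import SimConfig, simulate_groups, simulate_panel

from conftest import random_profiles


def matrix_from_rows(rows, ids=None):
    n, m = len(rows), len(rows[0])
    return AlleleMatrix(
        accession_ids=tuple(ids or (f"A{i}" for i in range(n))),
        columns=tuple(("L1", 100 + 2 * j) for j in range(m)),
        values=np.array(rows, dtype=np.int8),
    )


class TestPairwiseDistance:
    def test_identical_rows_are_zero(self):
        m = matrix_from_rows([[1, 0, 1], [1, 0, 1]])
        for metric in ("dice", "jaccard", "simple_matching"):
            assert pairwise_distance(m, metric).values[0, 1] == 0.0

    def test_hand_counted_dice_and_jaccard(self):
        m = matrix_from_rows([[1, 1, 0], [1, 0, 1]])
        assert pairwise_distance(m, "dice").values[0, 1] == pytest.approx(0.5)
        assert pairwise_distance(m, "jaccard").values[0, 1] == pytest.approx(2 / 3)
        assert pairwise_distance(m, "simple_matching").values[0, 1] == pytest.approx(
            2 / 3
        )

    def test_dice_never_exceeds_jaccard(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            rows = rng.integers(0, 2, size=(6, 15))
            rows[:, 0] = 1  # avoid all-absent pairs
            m = matrix_from_rows(rows.tolist())
            dice = pairwise_distance(m, "dice").values
            jac = pairwise_distance(m, "jaccard").values
            assert (dice <= jac + 1e-12).all()

    def test_missing_columns_pairwise_deleted(self):
        m = matrix_from_rows([[1, -1, 0], [1, 1, 0]])
        assert pairwise_distance(m, "dice").values[0, 1] == 0.0

    def test_no_comparable_columns_is_error(self):
        m = matrix_from_rows([[1, -1], [-1, 1]])
        with pytest.raises(ValueError, match="comparable"):
            pairwise_distance(m)


class TestUpgma:
    def test_two_leaves(self):
        dm = DistanceMatrix(ids=("A", "B"), values=[[0, 0.4], [0.4, 0]])
        tree = upgma(dm)
        assert tree.root.height == pytest.approx(0.2)
        assert set(tree.root.leaves()) == {"A", "B"}

    def test_four_taxon_worked_example(self):
        # d(A,B)=0.2, d(C,D)=0.3, all cross pairs 0.6:
        # merges at heights 0.1, 0.15, then (mean of 4 cross pairs)/2 = 0.3
        vals = np.array(
            [
                [0.0, 0.2, 0.6, 0.6],
                [0.2, 0.0, 0.6, 0.6],
                [0.6, 0.6, 0.0, 0.3],
                [0.6, 0.6, 0.3, 0.0],
            ]
        )
        tree = upgma(DistanceMatrix(ids=("A", "B", "C", "D"), values=vals))
        assert tree.clades() == {frozenset({"A", "B"}), frozenset({"C", "D"})}
        assert tree.root.height == pytest.approx(0.3)
        heights = sorted(c.height for c in tree.root.children)
        assert heights == [pytest.approx(0.1), pytest.approx(0.15)]
        assert tree.cophenetic_distance("A", "B") == pytest.approx(0.2)
        assert tree.cophenetic_distance("A", "C") == pytest.approx(0.6)

    def test_output_is_ultrametric(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            n = 8
            raw = rng.uniform(0.1, 1.0, size=(n, n))
            vals = (raw + raw.T) / 2
            np.fill_diagonal(vals, 0.0)
            tree = upgma(
                DistanceMatrix(ids=tuple(f"T{i}" for i in range(n)), values=vals)
            )

            def depth(node, acc=0.0, root_h=tree.root.height):
                if node.is_leaf:
                    return [root_h - node.height]
                return [d for c in node.children for d in depth(c)]

            depths = depth(tree.root)
            assert max(depths) - min(depths) < 1e-9

    def test_reconstructs_ultrametric_input_exactly(self):
        rng = np.random.default_rng(14)
        base = upgma(
            DistanceMatrix(
                ids=tuple(f"T{i}" for i in range(7)),
                values=_random_symmetric(rng, 7),
            )
        )
        rebuilt = upgma(
            DistanceMatrix(ids=base.ids, values=base.cophenetic)
        )
        assert rebuilt.clades() == base.clades()
        assert np.allclose(rebuilt.cophenetic, base.cophenetic)

    def test_deterministic_tie_break(self):
        vals = np.full((3, 3), 0.4)
        np.fill_diagonal(vals, 0.0)
        tree = upgma(DistanceMatrix(ids=("C", "A", "B"), values=vals))
        # all distances tie: A,B (lexicographically smallest pair) join first
        inner = next(c for c in tree.root.children if not c.is_leaf)
        assert set(inner.leaves()) == {"A", "B"}


def _random_symmetric(rng, n):
    raw = rng.uniform(0.1, 1.0, size=(n, n))
    vals = (raw + raw.T) / 2
    np.fill_diagonal(vals, 0.0)
    return vals


class TestBootstrap:
    @pytest.fixture(scope="class")
    def two_group_matrix(self):
        cfg = SimConfig(group_sizes=(8, 8), disjoint_pools=True, seed=3)
        sim_panel = simulate_panel(cfg)
        profiles = simulate_groups(cfg, sim_panel)
        return to_binary_matrix(profiles, sim_panel.panel), profiles

    def test_disjoint_groups_get_strong_split_support(self, two_group_matrix):
        matrix, profiles = two_group_matrix
        tree = bootstrap_support(matrix, replicates=100, seed=1)
        supports = tree.supports()
        for group in ("G1", "G2"):
            clade = frozenset(
                p.accession_id for p in profiles if p.group == group
            )
            if clade in supports:  # one side may be the root complement
                assert supports[clade] > 90.0

    def test_single_replicate_supports_are_binary(self, two_group_matrix):
        matrix, _ = two_group_matrix
        tree = bootstrap_support(matrix, replicates=1, seed=5)
        assert set(tree.supports().values()) <= {0.0, 100.0}

    def test_same_seed_is_bit_reproducible(self, two_group_matrix):
        matrix, _ = two_group_matrix
        a = bootstrap_support(matrix, replicates=50, seed=9)
        b = bootstrap_support(matrix, replicates=50, seed=9)
        assert a.supports() == b.supports()
        assert to_newick(a) == to_newick(b)

    def test_accession_order_invariance(self, two_group_matrix):
        matrix, _ = two_group_matrix
        perm = np.random.default_rng(0).permutation(len(matrix.accession_ids))
        shuffled = AlleleMatrix(
            accession_ids=tuple(matrix.accession_ids[i] for i in perm),
            columns=matrix.columns,
            values=matrix.values[perm],
        )
        a = bootstrap_support(matrix, replicates=30, seed=4)
        b = bootstrap_support(shuffled, replicates=30, seed=4)
        assert set(a.clades()) == set(b.clades())


class TestNewick:
    def test_two_leaf_output(self):
        dm = DistanceMatrix(ids=("A", "B"), values=[[0, 0.4], [0.4, 0]])
        assert to_newick(upgma(dm)) == "(A:0.200000,B:0.200000);"

    def test_round_trip_through_dendropy(self, tmp_path):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(23)
        profs = random_profiles(rng, n_acc=9, n_loci=6)
        tree = bootstrap_support(to_binary_matrix(profs), replicates=20, seed=2)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        assert {l.taxon.label for l in parsed.leaf_nodes()} == set(tree.ids)
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        for i, a in enumerate(tree.ids):
            for b in tree.ids[i + 1 :]:
                assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                    tree.cophenetic_distance(a, b), abs=1e-4
                )

    def test_metacharacter_labels_are_quoted(self):
        dm = DistanceMatrix(
            ids=("A (x)", "B;2"), values=[[0, 0.4], [0.4, 0]]
        )
        nwk = to_newick(upgma(dm))
        assert "'A (x)'" in nwk and "'B;2'" in nwk

    def test_low_supports_suppressed_in_rendered_output(self):
        rng = np.random.default_rng(4)
        profs = random_profiles(rng, n_acc=8, n_loci=5)
        tree = bootstrap_support(to_binary_matrix(profs), replicates=25, seed=3)
        rendered = to_newick(tree, min_support=30.0)
        # no support label below the cutoff may appear in the rendered text
        import re

        labels = {
            float(x) for x in re.findall(r"\)([0-9.]+):", rendered)
        }
        assert all(s >= 30.0 for s in labels)
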