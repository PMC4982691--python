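"""Fitch parsimony, gain/loss decomposition, and the clustering test."""

import random
from itertools import product

import dendropy
import pytest
from dendropy.model.parsimony import fitch_down_pass

import operon_recruit as opr
from operon_recruit import io as io_mod
from operon_recruit.itol import parse_colorstrip
from operon_recruit.model import DataError, TraitMap
from operon_recruit.trait_phylo import IndexedTree, _fitch_score_bits

from oracle_utils import (
    all_rooted_topologies,
    brute_force_score,
    tuple_tree_to_newick,
)


def traits_from(states):
    return TraitMap(states=dict(states), state_space=("0", "1"))


def quartet():
    return io_mod.read_tree("((A,B),(C,D));")


class TestFitchScore:
    def test_clade_trait_needs_one_change(self):
        tm = traits_from({"A": "1", "B": "1", "C": "0", "D": "0"})
        assert opr.fitch_score(quartet(), tm).score == 1

    def test_dispersed_trait_needs_two(self):
        tree = io_mod.read_tree("((A,C),(B,D));")
        tm = traits_from({"A": "1", "B": "1", "C": "0", "D": "0"})
        assert opr.fitch_score(tree, tm).score == 2

    def test_constant_trait_scores_zero(self):
        tm = traits_from({"A": "1", "B": "1", "C": "1", "D": "1"})
        assert opr.fitch_score(quartet(), tm).score == 0

    def test_missing_tip_rejected(self):
        tm = traits_from({"A": "1", "B": "1", "C": "0"})
        with pytest.raises(DataError, match="D"):
            opr.fitch_score(quartet(), tm)

    def test_extra_tip_rejected(self):
        tm = traits_from(
            {"A": "1", "B": "1", "C": "0", "D": "0", "E": "0"}
        )
        with pytest.raises(DataError, match="E"):
            opr.fitch_score(quartet(), tm)

    @pytest.mark.parametrize("n_tips", [4, 5])
    def test_exhaustive_oracle_small_trees(self, n_tips):
        """Equals brute-force enumeration for all topologies and all binary
        tip assignments."""
        for tup in all_rooted_topologies(n_tips):
            tree = io_mod.read_tree(tuple_tree_to_newick(tup) + ";")
            for assignment in product("01", repeat=n_tips):
                tm = traits_from(
                    {f"L{i}": assignment[i] for i in range(n_tips)}
                )
                expected = brute_force_score(
                    tup, [int(a) for a in assignment]
                )
                assert opr.fitch_score(tree, tm).score == expected

    def test_matches_dendropy_fitch_on_random_trees(self, rng):
        for _ in range(10):
            tree = opr.simulate_tree(25, seed=rng.randint(0, 10**6))
            states = {
                l.taxon.label: str(rng.randint(0, 1))
                for l in tree.leaf_node_iter()
            }
            mine = opr.fitch_score(tree, traits_from(states)).score
            tss = {
                leaf.taxon: [{int(states[leaf.taxon.label])}]
                for leaf in tree.leaf_node_iter()
            }
            ref = fitch_down_pass(
                tree.postorder_node_iter(), taxon_state_sets_map=tss
            )
            assert mine == ref

    def test_rooting_invariance(self, rng):
        tree = opr.simulate_tree(20, seed=5)
        states = {
            l.taxon.label: str(rng.randint(0, 1))
            for l in tree.leaf_node_iter()
        }
        tm = traits_from(states)
        base = opr.fitch_score(tree, tm).score
        edges = [
            e for e in tree.preorder_edge_iter()
            if e.head_node is not tree.seed_node and e.length
        ]
        for _ in range(30):
            clone = tree.clone(depth=1)
            clone_edges = [
                e for e in clone.preorder_edge_iter()
                if e.head_node is not clone.seed_node and e.length
            ]
            edge = rng.choice(clone_edges)
            clone.reroot_at_edge(edge, update_bipartitions=False)
            assert opr.fitch_score(clone, tm).score == base

    def test_score_bounded_by_minority_count(self, rng):
        tree = opr.simulate_tree(30, seed=17)
        for _ in range(20):
            states = {
                l.taxon.label: str(int(rng.random() < 0.3))
                for l in tree.leaf_node_iter()
            }
            values = list(states.values())
            minority = min(values.count("0"), values.count("1"))
            tm = traits_from(states)
            assert opr.fitch_score(tree, tm).score <= minority

    def test_categorical_trait(self):
        tree = io_mod.read_tree("(((A,B),(C,D)),((E,F),(G,H)));")
        tm = TraitMap(
            states={"A": "x", "B": "x", "C": "y", "D": "y", "E": "z",
                    "F": "z", "G": "z", "H": "z"},
            state_space=("x", "y", "z"),
        )
        assert opr.fitch_score(tree, tm).score == 2

    def test_polytomy_resolution_flagged(self):
        tree = io_mod.read_tree("((A,B,C),(D,E));")
        tm = traits_from(
            {"A": "1", "B": "1", "C": "1", "D": "0", "E": "0"}
        )
        res = opr.fitch_score(tree, tm)
        assert res.polytomies_resolved and res.score == 1


class TestCountEvents:
    def test_root_zero_gives_one_gain(self):
        tm = traits_from({"A": "1", "B": "1", "C": "0", "D": "0"})
        res = opr.count_events(quartet(), tm, "ACCTRAN", "0")
        assert (res.n_gains, res.n_losses) == (1, 0)

    def test_root_one_gives_one_loss(self):
        tm = traits_from({"A": "1", "B": "1", "C": "0", "D": "0"})
        res = opr.count_events(quartet(), tm, "DELTRAN", "1")
        assert (res.n_gains, res.n_losses) == (0, 1)

    def test_all_zero_no_events(self):
        tm = traits_from({k: "0" for k in "ABCD"})
        res = opr.count_events(quartet(), tm, "ACCTRAN", "0")
        assert (res.n_gains, res.n_losses) == (0, 0)

    def test_inconsistent_root_state_rejected(self):
        tm = traits_from({k: "0" for k in "ABCD"})
        with pytest.raises(DataError, match="most-parsimonious"):
            opr.count_events(quartet(), tm, "ACCTRAN", "1")

    def test_decomposition_sums_to_score(self, rng):
        for _ in range(25):
            tree = opr.simulate_tree(15, seed=rng.randint(0, 10**6))
            states = {
                l.taxon.label: str(rng.randint(0, 1))
                for l in tree.leaf_node_iter()
            }
            if len(set(states.values())) < 2:
                continue
            tm = traits_from(states)
            score = opr.fitch_score(tree, tm).score
            for resolution in ("ACCTRAN", "DELTRAN"):
                res = opr.count_events(tree, tm, resolution, "MP")
                assert res.n_gains + res.n_losses == res.score == score


class TestClusteringTest:
    def _caterpillar(self, n=32):
        tips = [f"L{i:02d}" for i in range(n)]
        nwk = tips[0]
        for t in tips[1:]:
            nwk = f"({nwk},{t})"
        return io_mod.read_tree(nwk + ";"), tips

    def test_clade_clustered_trait_is_significant(self):
        tree, tips = self._caterpillar()
        states = {t: ("1" if i < 8 else "0") for i, t in enumerate(tips)}
        res = opr.clustering_permutation_test(
            tree, traits_from(states), n_perm=999, seed=11
        )
        assert res.p_value <= 0.01
        assert res.observed_score == 1

    def test_p_value_formula(self):
        tree, tips = self._caterpillar(16)
        states = {t: ("1" if i % 2 else "0") for i, t in enumerate(tips)}
        res = opr.clustering_permutation_test(
            tree, traits_from(states), n_perm=99, seed=2
        )
        expected = (1 + sum(
            s <= res.observed_score for s in res.null_scores
        )) / 100
        assert res.p_value == expected

    def test_same_seed_identical_nulls(self):
        tree, tips = self._caterpillar(16)
        states = {t: ("1" if i < 4 else "0") for i, t in enumerate(tips)}
        a = opr.clustering_permutation_test(
            tree, traits_from(states), n_perm=199, seed=7
        )
        b = opr.clustering_permutation_test(
            tree, traits_from(states), n_perm=199, seed=7
        )
        assert a.null_scores == b.null_scores and a.p_value == b.p_value

    def test_constant_trait_rejected(self):
        tree, tips = self._caterpillar(8)
        states = {t: "1" for t in tips}
        with pytest.raises(DataError, match="constant"):
            opr.clustering_permutation_test(
                tree, traits_from(states), n_perm=99, seed=1
            )

    def test_null_true_p_values_super_uniform(self):
        """Rejection at alpha=0.05 under shuffled traits stays near or below
        nominal (small Monte-Carlo version; the full calibration runs in the
        acceptance suite)."""
        tree = opr.simulate_tree(24, seed=31)
        idx = IndexedTree(tree)
        rng = random.Random(31)
        base = ["1"] * 12 + ["0"] * 12
        rej = 0
        n_rep = 120
        for _ in range(n_rep):
            states = base[:]
            rng.shuffle(states)
            tm = traits_from(dict(zip(idx.leaf_labels, states)))
            res = opr.clustering_permutation_test(
                tree, tm, n_perm=99, seed=rng.randint(0, 2**30)
            )
            rej += res.p_value <= 0.05
        assert rej / n_rep <= 0.12  # generous binomial envelope around 0.05


class TestOverlay:
    def test_binary_roundtrip(self, tmp_path):
        tm = traits_from({"A": "1", "B": "0", "C": "1", "D": "0"})
        path = tmp_path / "itol.txt"
        opr.overlay_export(quartet(), tm, path)
        text = path.read_text()
        assert text.startswith("DATASET_COLORSTRIP")
        assert "#ff0000" in text and "#0000ff" in text
        assert parse_colorstrip(path) == tm

    def test_categorical_nine_states(self, tmp_path):
        tree = opr.simulate_tree(9, seed=2)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        tm = TraitMap(
            states={t: f"S{i + 1}" for i, t in enumerate(labels)},
            state_space=tuple(f"S{i + 1}" for i in range(9)),
        )
        path = tmp_path / "itol9.txt"
        opr.overlay_export(tree, tm, path)
        assert parse_colorstrip(path) == tm

    def test_unmapped_tip_rejected(self, tmp_path):
        tm = traits_from({"A": "1", "B": "0", "C": "1"})
        with pytest.raises(DataError):
            opr.overlay_export(quartet(), tm, tmp_path / "x.txt")
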