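"""Discrete-trait evolution on phylogenies: Fitch parsimony, gain/loss
decomposition, and a permutation test for phylogenetic clustering.

The parsimony score (minimum number of state changes needed to explain the
tip states) operationalizes "how many times was the trait gained or lost";
for binary traits a most-parsimonious internal labeling is decomposed into
gains (0->1 edges) and losses (1->0 edges) under the ACCTRAN (changes pushed
rootward) or DELTRAN (changes delayed tipward) convention. Phylogenetic
clustering of a trait is tested by comparing the observed score to scores
under uniform shuffles of the tip states (fixed state multiset): clustered
traits need fewer changes than shuffled ones.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy

from .itol import export_colorstrip, parse_colorstrip  # re-exported  # noqa: F401
from .model import DataError, TraitMap

_INF = float("inf")


@dataclass(frozen=True)
class ParsimonyResult:
    """Minimum state changes, optionally decomposed into gains and losses.

    ``n_gains``/``n_losses`` are filled only by :func:`count_events` (they
    depend on a resolution convention); ``polytomies_resolved`` flags that
    the input had non-root polytomies resolved deterministically, making the
    score an upper bound on the binary-tree minimum.
    """

    score: int
    n_gains: int | None = None
    n_losses: int | None = None
    resolution: str | None = None
    root_state_assumption: str = "MP"
    polytomies_resolved: bool = False


@dataclass(frozen=True)
class ClusteringTest:
    observed_score: int
    null_scores: tuple[int, ...]
    n_perm: int
    p_value: float
    seed: int


# ---------------------------------------------------------------------------
# indexed tree machinery
# ---------------------------------------------------------------------------

class IndexedTree:
    """Postorder array representation of a (deterministically binarized)
    tree, for fast repeated parsimony evaluation."""

    def __init__(self, tree: dendropy.Tree):
        work = tree.clone(depth=1)
        self.polytomies_resolved = _resolve_polytomies(work)
        nodes = list(work.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        self.children: list[tuple[int, ...]] = [
            tuple(index[id(c)] for c in n.child_nodes()) for n in nodes
        ]
        self.parent: list[int | None] = [None] * len(nodes)
        for i, ch in enumerate(self.children):
            for c in ch:
                self.parent[c] = i
        self.leaf_indices: list[int] = [
            i for i, n in enumerate(nodes) if n.is_leaf()
        ]
        self.leaf_labels: list[str] = [
            nodes[i].taxon.label for i in self.leaf_indices
        ]
        self.n_nodes = len(nodes)

    def leaf_bits(self, traits: TraitMap, state_to_bit: dict[str, int]) -> list[int]:
        bits = [0] * self.n_nodes
        missing = []
        for i, label in zip(self.leaf_indices, self.leaf_labels):
            state = traits.states.get(label)
            if state is None:
                missing.append(label)
            else:
                bits[i] = state_to_bit[state]
        if missing:
            raise DataError(f"tips missing from trait map: {sorted(missing)}")
        return bits


def _min_leaf_label(node: dendropy.Node) -> str:
    return min(leaf.taxon.label for leaf in node.leaf_iter())


def _resolve_polytomies(tree: dendropy.Tree) -> bool:
    """Binarize polytomies in place, deterministically by tip-label order.

    Children of a polytomy are sorted by their smallest descendant tip label
    and combined pairwise left-to-right. Returns True if any node (including
    a trifurcating pseudo-root) was resolved.
    """
    resolved = False
    for node in list(tree.postorder_node_iter()):
        kids = node.child_nodes()
        if len(kids) <= 2:
            continue
        resolved = True
        kids = sorted(kids, key=_min_leaf_label)
        for k in kids:
            node.remove_child(k)
        left = kids[0]
        for k in kids[1:-1]:
            joint = dendropy.Node()
            joint.add_child(left)
            joint.add_child(k)
            left = joint
        node.add_child(left)
        node.add_child(kids[-1])
    return resolved


def _check_traits(tree_labels: list[str], traits: TraitMap) -> None:
    tree_set = set(tree_labels)
    extra = set(traits.states) - tree_set
    if extra:
        raise DataError(f"trait tips absent from tree: {sorted(extra)}")
    missing = tree_set - set(traits.states)
    if missing:
        raise DataError(f"tips missing from trait map: {sorted(missing)}")


def _fitch_score_bits(children: list[tuple[int, ...]], bits: list[int]) -> int:
    """Classical Fitch down-pass over a postorder children array."""
    sets = [0] * len(children)
    score = 0
    for i, ch in enumerate(children):
        if not ch:
            sets[i] = bits[i]
            continue
        inter = union = sets[ch[0]]
        for c in ch[1:]:
            inter &= sets[c]
            union |= sets[c]
        if inter:
            sets[i] = inter
        else:
            sets[i] = union
            score += 1
    return score


def fitch_score(tree: dendropy.Tree, traits: TraitMap) -> ParsimonyResult:
    """Minimum number of state changes for a discrete trait on a tree.

    Works for binary or k-state categorical traits; the score is invariant
    to the rooting of the underlying unrooted topology. Polytomies are
    binarized deterministically first (flagged in the result; the score is
    then an upper bound).
    """
    idx = IndexedTree(tree)
    _check_traits(idx.leaf_labels, traits)
    state_to_bit = {s: 1 << i for i, s in enumerate(traits.state_space)}
    bits = idx.leaf_bits(traits, state_to_bit)
    score = _fitch_score_bits(idx.children, bits)
    return ParsimonyResult(
        score=score, polytomies_resolved=idx.polytomies_resolved
    )


def count_events(
    tree: dendropy.Tree,
    traits: TraitMap,
    resolution: str = "ACCTRAN",
    root_state: str = "MP",
) -> ParsimonyResult:
    """Decompose a most-parsimonious binary reconstruction into gains/losses.

    Uses unit-cost dynamic programming (Sankoff) over the rooted tree; the
    traceback breaks ties by the stated convention — ACCTRAN prefers placing
    a change as early (rootward) as possible, DELTRAN keeps the parent state
    as long as possible. ``root_state`` fixes the root ('0'/'1') or lets the
    most-parsimonious choice stand ('MP', ties to '0'); a fixed root state
    incompatible with the most-parsimonious set is an error. Gains are 0->1
    edges, losses 1->0; their sum always equals the parsimony score.
    """
    if resolution not in ("ACCTRAN", "DELTRAN"):
        raise DataError(f"unknown resolution {resolution!r}")
    if not traits.is_binary():
        raise DataError("gain/loss decomposition requires a binary trait")
    idx = IndexedTree(tree)
    _check_traits(idx.leaf_labels, traits)

    leaf_state = {
        i: int(traits.states[label])
        for i, label in zip(idx.leaf_indices, idx.leaf_labels)
    }
    n = idx.n_nodes
    cost = [[0.0, 0.0] for _ in range(n)]
    for i, ch in enumerate(idx.children):
        if not ch:
            s = leaf_state[i]
            cost[i][s] = 0.0
            cost[i][1 - s] = _INF
        else:
            for s in (0, 1):
                cost[i][s] = sum(
                    min(cost[c][0] + (s != 0), cost[c][1] + (s != 1))
                    for c in ch
                )

    root = n - 1  # postorder: root last
    best = min(cost[root])
    if root_state == "MP":
        chosen_root = 0 if cost[root][0] == best else 1
    else:
        chosen_root = int(root_state)
        if cost[root][chosen_root] != best:
            raise DataError(
                f"root_state={root_state} is not most-parsimonious "
                f"(cost {cost[root][chosen_root]:.0f} vs {best:.0f})"
            )

    assigned = [0] * n
    assigned[root] = chosen_root
    gains = losses = 0
    # preorder = reversed postorder
    for i in range(n - 1, -1, -1):
        p_state = assigned[i]
        for c in idx.children[i]:
            options = [
                (cost[c][t] + (t != p_state), t) for t in (0, 1)
            ]
            mn = min(o[0] for o in options)
            minimizers = [t for v, t in options if v == mn]
            if len(minimizers) == 1:
                t = minimizers[0]
            elif resolution == "DELTRAN":
                t = p_state
            else:  # ACCTRAN: accelerate the change
                t = 1 - p_state
            assigned[c] = t
            if t != p_state:
                if t == 1:
                    gains += 1
                else:
                    losses += 1

    score = int(best)
    assert gains + losses == score
    return ParsimonyResult(
        score=score,
        n_gains=gains,
        n_losses=losses,
        resolution=resolution,
        root_state_assumption=root_state,
        polytomies_resolved=idx.polytomies_resolved,
    )


def clustering_permutation_test(
    tree: dendropy.Tree,
    traits: TraitMap,
    n_perm: int = 999,
    seed: int = 0,
) -> ClusteringTest:
    """Tip-label shuffle test for phylogenetic clustering of a trait.

    The statistic is the Fitch parsimony score; the null distribution comes
    from ``n_perm`` uniform permutations of the tip states (state multiset
    fixed). Small observed scores relative to the null indicate clustering;
    the p-value uses the +1 correction
    ``p = (1 + #{null <= observed}) / (1 + n_perm)``.
    """
    if n_perm < 99:
        raise DataError("n_perm must be at least 99")
    if len(set(traits.states.values())) < 2:
        raise DataError("clustering test undefined for a constant trait")
    idx = IndexedTree(tree)
    _check_traits(idx.leaf_labels, traits)
    state_to_bit = {s: 1 << i for i, s in enumerate(traits.state_space)}
    bits = idx.leaf_bits(traits, state_to_bit)
    observed = _fitch_score_bits(idx.children, bits)

    rng = random.Random(seed)
    leaf_bits = [bits[i] for i in idx.leaf_indices]
    null_scores = []
    shuffled = [0] * idx.n_nodes
    for _ in range(n_perm):
        rng.shuffle(leaf_bits)
        for i, b in zip(idx.leaf_indices, leaf_bits):
            shuffled[i] = b
        null_scores.append(_fitch_score_bits(idx.children, shuffled))
    p = (1 + sum(s <= observed for s in null_scores)) / (1 + n_perm)
    return ClusteringTest(
        observed_score=observed,
        null_scores=tuple(null_scores),
        n_perm=n_perm,
        p_value=p,
        seed=seed,
    )


def overlay_export(tree, traits: TraitMap, path, palette=None,
                   dataset_label: str = "trait") -> None:
    """Export an iTOL color-strip overlay for the tree's tips.

    All tree tips must be mapped in ``traits``; the binary default palette
    is red (state 1, operon associated) / blue (state 0).
    """
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    _check_traits(labels, traits)
    export_colorstrip(traits, path, palette=palette, dataset_label=dataset_label)
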