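"""Independent brute-force parsimony oracle on tuple-encoded trees.

Trees are nested 2-tuples with integer leaf ids. The oracle enumerates every
possible internal-node labeling and takes the minimum change count; it
shares no code with the package's Fitch implementation.
"""

from itertools import product


def all_rooted_topologies(n_leaves):
    """Every rooted binary topology on leaves 0..n-1 (tuple encoding)."""
    trees = [0]
    for leaf in range(1, n_leaves):
        nxt = []
        for t in trees:
            for s in _insert_everywhere(t, leaf):
                nxt.append(s)
        trees = nxt
    return trees


def _insert_everywhere(tree, leaf):
    # new root joining the whole tree with the new leaf
    yield (tree, leaf)
    if isinstance(tree, tuple):
        left, right = tree
        for sub in _insert_everywhere(left, leaf):
            yield (sub, right)
        for sub in _insert_everywhere(right, leaf):
            yield (left, sub)


def tree_nodes(tree):
    """Postorder (node, children-indices) arrays for a tuple tree."""
    children = []
    leaf_of = []

    def walk(node):
        if isinstance(node, tuple):
            l = walk(node[0])
            r = walk(node[1])
            children.append((l, r))
            leaf_of.append(None)
        else:
            children.append(())
            leaf_of.append(node)
        return len(children) - 1

    walk(tree)
    return children, leaf_of


def brute_force_score(tree, leaf_states, n_states=2):
    """Minimum changes over every internal labeling (exhaustive)."""
    children, leaf_of = tree_nodes(tree)
    internal = [i for i, ch in enumerate(children) if ch]
    best = None
    for labels in product(range(n_states), repeat=len(internal)):
        state = {}
        for idx, i in enumerate(internal):
            state[i] = labels[idx]
        for i, leaf in enumerate(leaf_of):
            if leaf is not None:
                state[i] = leaf_states[leaf]
        changes = 0
        for i, ch in enumerate(children):
            for c in ch:
                changes += state[c] != state[i]
        if best is None or changes < best:
            best = changes
    return best


def tuple_tree_to_newick(tree, prefix="L"):
    if isinstance(tree, tuple):
        return (
            "(" + tuple_tree_to_newick(tree[0], prefix) + ","
            + tuple_tree_to_newick(tree[1], prefix) + ")"
        )
    return f"{prefix}{tree}"


def tuple_tree_children(tree):
    """Postorder children arrays plus leaf-index map, for the package's
    internal Fitch evaluation without going through newick."""
    children, leaf_of = tree_nodes(tree)
    leaf_index = {leaf: i for i, leaf in enumerate(leaf_of) if leaf is not None}
    return children, leaf_index
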