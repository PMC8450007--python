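"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's bitset/matrix code paths: splits are
recomputed by undirected graph traversal, parsimony by exhaustive
enumeration of internal labelings, and the reduction filter by a naive
double loop.
"""

from itertools import product

import numpy as np


def adjacency(tree):
    """Undirected adjacency map {id(node): [neighbor nodes]} plus node index."""
    adj = {}
    nodes = {}
    for node in tree.postorder():
        nodes[id(node)] = node
        adj.setdefault(id(node), [])
        for child in node.children:
            adj.setdefault(id(child), [])
            adj[id(node)].append(child)
            adj[id(child)].append(node)
    return adj, nodes


def split_set_oracle(tree):
    """Non-trivial splits as frozensets-of-frozensets, found by removing each
    edge and flood-filling leaf labels from both endpoints."""
    adj, nodes = adjacency(tree)
    all_leaves = frozenset(tree.leaf_labels())
    splits = set()
    edges = []
    for node in tree.postorder():
        for child in node.children:
            edges.append((node, child))
    for a, b in edges:
        # collect leaves reachable from b without crossing edge (a, b)
        seen = {id(b), id(a)}
        stack = [b]
        side = set()
        while stack:
            cur = stack.pop()
            if cur.is_leaf():
                side.add(cur.label)
            for nb in adj[id(cur)]:
                if id(nb) not in seen:
                    seen.add(id(nb))
                    stack.append(nb)
        side = frozenset(side)
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset([side, other]))
    return splits


def rf_oracle(t1, t2):
    return len(split_set_oracle(t1) ^ split_set_oracle(t2))


def brute_force_parsimony(tree, tip_states):
    """Exhaustive minimum over all internal-node state assignments."""
    internals = [n for n in tree.postorder() if not n.is_leaf()]
    states = sorted({tip_states[l] for l in tree.leaf_labels()}, key=repr)
    edges = []
    for node in tree.postorder():
        for child in node.children:
            edges.append((node, child))

    def state_of(node, assign):
        if node.is_leaf():
            return tip_states[node.label]
        return assign[id(node)]

    best = None
    for combo in product(states, repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        cost = sum(
            1 for a, b in edges if state_of(a, assign) != state_of(b, assign)
        )
        if best is None or cost < best:
            best = cost
    return best


def naive_reduce_kept(matrix, scheme, min_support, min_presence):
    """Double-loop reimplementation of the backbone reduction filter.

    Returns the set of kept column indices, computed from the split's
    taxon sides and group memberships without touching the package's
    is_group_respecting/reduce_matrix code.
    """
    taxa = matrix.taxa
    n_rows = len(matrix.tree_ids)
    kept = set()
    for j, split in enumerate(matrix.splits):
        side0 = set(split.side_labels(taxa))
        side1 = set(taxa.labels) - side0
        groups0, groups1, broken = set(), set(), False
        for group in scheme.groups:
            members = [t for t, g in scheme.assignment.items() if g == group]
            in0 = [t for t in members if t in side0]
            in1 = [t for t in members if t in side1]
            if in0 and in1:
                broken = True
                break
            (groups0 if in0 else groups1).add(group)
        if broken or not groups0 or not groups1:
            continue
        n_pass = 0
        for i in range(n_rows):
            v = matrix.values[i, j]
            if not np.isnan(v) and v >= min_support:
                n_pass += 1
        if n_pass / n_rows >= min_presence:
            kept.add(j)
    return kept


def reroot_at(tree, target):
    """Rooted copy of the same unrooted topology, rooted at ``target``.

    Rebuilds the node structure by walking the undirected adjacency away
    from the new root; supports/lengths are not preserved (not needed by
    the parsimony invariance checks).
    """
    from phylostab.io import Node, SupportTree

    adj, _ = adjacency(tree)

    def build(node, parent):
        out = Node(label=node.label)
        for nb in adj[id(node)]:
            if nb is not parent:
                out.children.append(build(nb, node))
        return out

    return SupportTree(build(target, None), scale=tree.scale)
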