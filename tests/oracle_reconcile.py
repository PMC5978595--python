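"""Independent brute-force reconciliation oracle and tree enumeration.

Gene trees are nested tuples whose leaves are species labels; the oracle
computes each node's species-tree LCA by explicit clade enumeration
(smallest species-tree clade containing the node's species set), fully
independent of the package's traversal-based implementation.
"""

from functools import lru_cache
from itertools import combinations


def species_clades(species_tree_tuple):
    """All clades (frozensets of species) of a nested-tuple species tree."""
    clades = []

    def walk(node):
        if isinstance(node, str):
            s = frozenset([node])
        else:
            s = frozenset().union(*(walk(c) for c in node))
        clades.append(s)
        return s

    walk(species_tree_tuple)
    return clades


def oracle_events(gene_tree, clades):
    """{sorted-leafset-key: event} for every internal node, by brute force."""

    def lca_set(species):
        candidates = [c for c in clades if species <= c]
        return min(candidates, key=len)

    events = {}

    def walk(node, path):
        if isinstance(node, str):
            return [node + "#" + path], frozenset([node])
        leaves, sets = [], []
        for i, child in enumerate(node):
            l, s = walk(child, path + str(i))
            leaves.append(l)
            sets.append(s)
        all_leaves = [x for l in leaves for x in l]
        union = frozenset().union(*sets)
        node_lca = lca_set(union)
        dup = any(lca_set(s) == node_lca for s in sets)
        events[",".join(sorted(all_leaves))] = (
            "duplication" if dup else "speciation",
            node_lca,
        )
        return all_leaves, union

    walk(gene_tree, "r")
    return events


@lru_cache(maxsize=None)
def all_rooted_trees(multiset):
    """All canonical rooted binary trees over a sorted tuple of species."""
    if len(multiset) == 1:
        return (multiset[0],)
    out = set()
    n = len(multiset)
    idx = range(n)
    seen = set()
    for k in range(1, n // 2 + 1):
        for left_idx in combinations(idx, k):
            left = tuple(sorted(multiset[i] for i in left_idx))
            rest = set(idx) - set(left_idx)
            right = tuple(sorted(multiset[i] for i in rest))
            if (left, right) in seen:
                continue
            seen.add((left, right))
            if k == n - k and left > right:
                continue
            for lt in all_rooted_trees(left):
                for rt in all_rooted_trees(right):
                    out.add(tuple(sorted((lt, rt), key=repr)))
    return tuple(sorted(out, key=repr))


def tuple_to_newick(gene_tree):
    """Nested species tuple -> newick with unique SPECIES__gN leaf names."""
    counter = [0]

    def walk(node):
        if isinstance(node, str):
            counter[0] += 1
            return f"{node}__g{counter[0]}"
        return "(" + ",".join(walk(c) for c in node) + ")"

    return walk(gene_tree) + ";", counter[0]


def relabel_oracle_keys(events, gene_tree):
    """Map oracle leafset keys (species#path) onto SPECIES__gN leaf names.

    Leaves are numbered in the same left-to-right order tuple_to_newick
    uses, so the path-tagged oracle leaves and the newick leaf names line
    up one-to-one.
    """
    order = []

    def walk(node, path):
        if isinstance(node, str):
            order.append(node + "#" + path)
            return
        for i, child in enumerate(node):
            walk(child, path + str(i))

    walk(gene_tree, "r")
    rename = {tag: f"{tag.split('#')[0]}__g{i + 1}" for i, tag in enumerate(order)}
    out = {}
    for key, value in events.items():
        leaves = sorted(rename[t] for t in key.split(","))
        out[",".join(leaves)] = value
    return out
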