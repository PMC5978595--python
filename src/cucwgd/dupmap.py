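"""Gene-family clustering, expression filtering and duplication placement.

The centrepiece is classical LCA (species-overlap) reconciliation: each
node of a rooted gene tree is mapped to the lowest common ancestor, in the
species tree, of the species below it; a node is a duplication precisely
when it maps to the same species-tree node as at least one of its children,
and each duplication is charged to the species-tree branch directly above
its mapped node.  Aggregating over many families gives the proportion of
families duplicated on each species-tree branch -- a whole-genome
duplication shows up as a branch on which most families carry a
duplication.

Also here: the transitive overlap/identity clustering rule used to group
assembled transcripts into unigenes, and the relative-expression filter
that removes transcripts expressed below a fraction of their component's
maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import networkx as nx
import pandas as pd

__all__ = [
    "ClusteringConfig",
    "ReconciledGeneTree",
    "transitive_cluster",
    "expression_filter",
    "reconcile_lca",
    "branch_duplication_proportions",
    "classify_homolog_pairs",
    "species_of_leaf",
]

SPECIATION = "speciation"
DUPLICATION = "duplication"

#: Leaf-name convention "SPECIES__geneid".
DEFAULT_SEPARATOR = "__"


@dataclass
class ClusteringConfig:
    """Thresholds of the unigene clustering and expression filter.

    All comparisons are strict: an edge requires overlap > min_overlap_bp
    AND identity > min_identity_pct; a transcript is dropped when its
    expression is < expression_floor_fraction x its component maximum.
    """

    min_overlap_bp: float = 100.0
    min_identity_pct: float = 97.0
    expression_floor_fraction: float = 0.01

    def __post_init__(self) -> None:
        if min(self.min_overlap_bp, self.min_identity_pct,
               self.expression_floor_fraction) <= 0:
            raise ValueError("all clustering thresholds must be positive")


def transitive_cluster(
    hits: Iterable[tuple[str, str, float, float]],
    cfg: ClusteringConfig | None = None,
    all_ids: Iterable[str] | None = None,
) -> list[set[str]]:
    """Connected components of the graph of qualifying pairwise hits.

    ``hits`` rows are (id_a, id_b, overlap_bp, identity_pct).  Ids listed in
    ``all_ids`` but in no qualifying hit come out as singletons; ids seen
    only in failing hits do too.
    """
    cfg = cfg or ClusteringConfig()
    g = nx.Graph()
    if all_ids is not None:
        g.add_nodes_from(all_ids)
    for id_a, id_b, overlap, identity in hits:
        if overlap < 0 or identity < 0:
            raise ValueError(
                f"negative overlap/identity in hit ({id_a}, {id_b}): "
                f"{overlap}, {identity}"
            )
        g.add_node(id_a)
        g.add_node(id_b)
        if overlap > cfg.min_overlap_bp and identity > cfg.min_identity_pct:
            g.add_edge(id_a, id_b)
    return [set(c) for c in nx.connected_components(g)]


def expression_filter(
    table: pd.DataFrame, cfg: ClusteringConfig | None = None
) -> pd.DataFrame:
    """Drop transcripts expressed below the in-component relative floor.

    ``table`` needs columns transcript_id, component, expression.  A
    transcript is dropped iff expression < floor_fraction x the maximum
    expression of its component (strict, so a transcript at exactly the
    floor is kept, and the component maximum itself always survives).
    """
    cfg = cfg or ClusteringConfig()
    if (table["expression"] < 0).any():
        raise ValueError("expression values must be nonnegative")
    comp_max = table.groupby("component")["expression"].transform("max")
    keep = ~(table["expression"] < cfg.expression_floor_fraction * comp_max)
    return table[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# LCA reconciliation
# ---------------------------------------------------------------------------

def species_of_leaf(label: str, separator: str = DEFAULT_SEPARATOR) -> str:
    """Species identifier from a "SPECIES__geneid" leaf label."""
    return label.split(separator, 1)[0]


def _as_tree(tree: "dendropy.Tree | str") -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)


def _branch_label(node: dendropy.Node) -> str:
    """Stable identifier of the species-tree branch above ``node``."""
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
    return "|".join(leaves)


@dataclass
class ReconciledGeneTree:
    """A rooted gene tree with per-node event labels.

    ``events`` has one row per internal gene-tree node: its descendant
    leaves, the event (speciation/duplication) and, for duplications, the
    species-tree branch the event is assigned to (identified by the branch's
    child node: a species name for terminal branches, otherwise the sorted
    '|'-joined species below it).
    """

    gene_tree: dendropy.Tree
    species_tree: dendropy.Tree
    leaf_species: dict[str, str]
    events: pd.DataFrame

    @property
    def n_duplications(self) -> int:
        return int((self.events["event"] == DUPLICATION).sum())

    def duplication_branches(self) -> set[str]:
        dup = self.events[self.events["event"] == DUPLICATION]
        return set(dup["species_branch"])


def _species_index(species_tree: dendropy.Tree):
    """Per-node species sets and parent pointers for set-based LCA lookup."""
    node_leafset = {}
    for node in species_tree.postorder_node_iter():
        if node.is_leaf():
            node_leafset[node] = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*(node_leafset[c] for c in node.child_nodes()))
            node_leafset[node] = s
    leaf_of = {next(iter(s)): n for n, s in node_leafset.items() if n.is_leaf()}
    return node_leafset, leaf_of


def reconcile_lca(
    gene_tree: "dendropy.Tree | str",
    species_tree: "dendropy.Tree | str",
    leaf_map: Mapping[str, str] | None = None,
    separator: str = DEFAULT_SEPARATOR,
) -> ReconciledGeneTree:
    """LCA-map a rooted gene tree onto a species tree and label events.

    Each gene-tree node maps to the species-tree LCA of its leaf species;
    it is a duplication iff its mapping coincides with the mapping of at
    least one child.  Non-binary species-tree nodes are allowed (the LCA is
    well defined); unrooted gene trees are midpoint-rooted with a warning.
    Leaf species come from ``leaf_map`` or, by default, from the
    "SPECIES__geneid" naming convention.
    """
    gtree = _as_tree(gene_tree)
    stree = _as_tree(species_tree)

    root = gtree.seed_node
    if len(root.child_nodes()) > 2:
        warnings.warn(
            "gene tree root is not binary; midpoint-rooting before "
            "reconciliation", stacklevel=2,
        )
        gtree.reroot_at_midpoint(update_bipartitions=False)
        root = gtree.seed_node

    leafset, species_leaf_node = _species_index(stree)
    parent = {n: n.parent_node for n in stree.preorder_node_iter()}

    def lca_of(species: frozenset[str]) -> dendropy.Node:
        node = species_leaf_node[next(iter(species))]
        while not species <= leafset[node]:
            node = parent[node]
        return node

    def species_of(leaf_label: str) -> str:
        if leaf_map is not None:
            try:
                return leaf_map[leaf_label]
            except KeyError:
                raise KeyError(f"leaf {leaf_label!r} missing from leaf_map") from None
        return species_of_leaf(leaf_label, separator)

    gene_species: dict[str, str] = {}
    mapping: dict[dendropy.Node, dendropy.Node] = {}
    subtree_species: dict[dendropy.Node, frozenset[str]] = {}
    rows = []
    for node in gtree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            sp = species_of(label)
            if sp not in species_leaf_node:
                raise ValueError(
                    f"species {sp!r} of gene-tree leaf {label!r} is absent "
                    "from the species tree"
                )
            gene_species[label] = sp
            subtree_species[node] = frozenset([sp])
            mapping[node] = species_leaf_node[sp]
            continue
        children = node.child_nodes()
        subtree_species[node] = frozenset().union(
            *(subtree_species[c] for c in children)
        )
        mapping[node] = lca_of(subtree_species[node])
        event = (
            DUPLICATION
            if any(mapping[c] is mapping[node] for c in children)
            else SPECIATION
        )
        node.event = event
        node.species_node = mapping[node]
        rows.append(
            {
                "leaves": ",".join(sorted(lf.taxon.label for lf in node.leaf_iter())),
                "event": event,
                "species_branch": _branch_label(mapping[node]),
            }
        )
    events = pd.DataFrame(rows, columns=["leaves", "event", "species_branch"])
    return ReconciledGeneTree(gtree, stree, gene_species, events)


def branch_duplication_proportions(
    reconciliations: Sequence[ReconciledGeneTree],
    species_tree: "dendropy.Tree | str",
) -> pd.DataFrame:
    """Per species-tree branch, the proportion of families duplicated there.

    A family counts once per branch regardless of how many duplications it
    carries on it.  Every branch of the species tree appears in the output,
    including the root (stem) branch.
    """
    reconciliations = list(reconciliations)
    if not reconciliations:
        raise ValueError("no reconciliations supplied")
    stree = _as_tree(species_tree)
    branches = [_branch_label(n) for n in stree.preorder_node_iter()]
    counts = dict.fromkeys(branches, 0)
    for rec in reconciliations:
        for branch in rec.duplication_branches():
            counts[branch] = counts.get(branch, 0) + 1
    n = len(reconciliations)
    return pd.DataFrame(
        {
            "species_branch": branches,
            "n_duplicated_families": [counts[b] for b in branches],
            "proportion": [counts[b] / n for b in branches],
        }
    )


def classify_homolog_pairs(
    rec: ReconciledGeneTree,
) -> list[tuple[tuple[str, str], str]]:
    """Every leaf pair labelled paralog/ortholog by its MRCA's event.

    A pair is a paralog pair iff the gene-tree MRCA of the two leaves is a
    duplication node, an ortholog pair iff it is a speciation node.
    """
    out = []
    for node in rec.gene_tree.postorder_internal_node_iter():
        event = getattr(node, "event", None)
        if event is None:
            continue
        children = node.child_nodes()
        label = "paralog" if event == DUPLICATION else "ortholog"
        for i in range(len(children)):
            for j in range(i + 1, len(children)):
                for la in children[i].leaf_iter():
                    for lb in children[j].leaf_iter():
                        pair = tuple(sorted((la.taxon.label, lb.taxon.label)))
                        out.append((pair, label))
    return out
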