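"""Gene-tree orthology: species-overlap event labeling and ortholog extraction.

Internal nodes of a rooted gene tree are labeled *speciation* or *duplication*
by the species-overlap rule: a node is a duplication when its child subtrees
share species.  The overlap score is the Jaccard index of the child species
sets; a node is called a duplication when that score strictly exceeds a
threshold (default 0, i.e. any shared species implies duplication).
Multifurcating nodes are duplications if any pair of children overlaps.

Fine-grained orthologs of a seed leaf are the leaves of other species whose
LCA with the seed is a speciation; in-paralogs (same-species leaves joined to
the seed through duplications) are identified so downstream annotation
transfer can exclude them.  Relation types (one2one / one2many / many2one /
many2many) count, at the joining LCA, how many leaves of the seed's species
sit on the seed's side and how many of the target's species on the target's
side.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy

from .ogdb import taxid_of

SPECIATION = "S"
DUPLICATION = "D"


class TreeError(Exception):
    pass


@dataclass
class TreeNode:
    name: Optional[str] = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None
    length: Optional[float] = None
    #: free slot for simulators / annotators (true event label, etc.)
    event: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]


class GeneTree:
    """Rooted gene tree whose leaf labels are ``<taxid>.<name>`` protein ids."""

    def __init__(self, root: TreeNode):
        self.root = root
        leaves = root.leaves()
        if not leaves:
            raise TreeError("gene tree has no leaves")
        names = [leaf.name for leaf in leaves]
        if len(set(names)) != len(names):
            raise TreeError("duplicate leaf labels in gene tree")
        self._leaf_by_name = {leaf.name: leaf for leaf in leaves}
        self.species = {name: taxid_of(name) for name in names}

    @classmethod
    def from_newick(cls, newick: str) -> "GeneTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises format-specific subclasses
            raise TreeError(f"invalid newick: {exc}") from exc
        if tree.seed_node is None:
            raise TreeError("empty newick string")

        def convert(dnode: dendropy.Node) -> TreeNode:
            name = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = TreeNode(name=name, length=dnode.edge.length)
            for dchild in dnode.child_nodes():
                node.add(convert(dchild))
            return node

        return cls(convert(tree.seed_node))

    def to_newick(self, labeling: Optional["EventLabeling"] = None) -> str:
        """Serialise; if a labeling is given, event labels become internal node names."""

        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                label = ""
                if labeling is not None and id(node) in labeling._by_id:
                    label = labeling._by_id[id(node)]
                elif node.name:
                    label = node.name
                s = "(" + ",".join(fmt(c) for c in node.children) + ")" + label
            if node.length is not None:
                s += f":{node.length:g}"
            return s

        return fmt(self.root) + ";"

    def leaf_names(self) -> list[str]:
        return sorted(self._leaf_by_name)

    def leaf(self, name: str) -> TreeNode:
        try:
            return self._leaf_by_name[name]
        except KeyError as exc:
            raise KeyError(f"leaf {name!r} not in gene tree") from exc

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.root.postorder() if not n.is_leaf]

    # -- per-node caches -----------------------------------------------------

    def species_sets(self) -> dict[int, set[int]]:
        """Species (taxid) set of every subtree, keyed by id(node)."""
        out: dict[int, set[int]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                out[id(node)] = {self.species[node.name]}
            else:
                s: set[int] = set()
                for child in node.children:
                    s |= out[id(child)]
                out[id(node)] = s
        return out

    def lca(self, a: TreeNode, b: TreeNode) -> TreeNode:
        ancestors = set()
        node: Optional[TreeNode] = a
        while node is not None:
            ancestors.add(id(node))
            node = node.parent
        node = b
        while node is not None:
            if id(node) in ancestors:
                return node
            node = node.parent
        raise TreeError("nodes share no ancestor (disconnected tree)")


@dataclass
class EventLabeling:
    """Speciation/duplication label per internal node of one GeneTree."""

    overlap_threshold: float
    _by_id: dict[int, str] = field(default_factory=dict)

    def label(self, node: TreeNode) -> str:
        return self._by_id[id(node)]

    def is_duplication(self, node: TreeNode) -> bool:
        return self._by_id[id(node)] == DUPLICATION

    def __len__(self) -> int:
        return len(self._by_id)


def label_events(tree: GeneTree, overlap_threshold: float = 0.0) -> EventLabeling:
    """Label every internal node by the species-overlap rule.

    Jaccard overlap of the child species sets strictly above the threshold
    means duplication; multifurcations are duplications if any child pair
    overlaps above it.
    """
    if not 0.0 <= overlap_threshold < 1.0:
        raise ValueError("overlap_threshold must lie in [0, 1)")
    species = tree.species_sets()
    labeling = EventLabeling(overlap_threshold=overlap_threshold)
    for node in tree.internal_nodes():
        dup = False
        kids = node.children
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                si, sj = species[id(kids[i])], species[id(kids[j])]
                inter = len(si & sj)
                if inter and inter / len(si | sj) > overlap_threshold:
                    dup = True
                    break
            if dup:
                break
        labeling._by_id[id(node)] = DUPLICATION if dup else SPECIATION
    return labeling


ONE2ONE = "one2one"
ONE2MANY = "one2many"
MANY2ONE = "many2one"
MANY2MANY = "many2many"
SEED = "seed"  # used by the annotation layer for the seed's own slot


@dataclass
class OrthologAssignment:
    seed: str
    orthologs: set[tuple[str, str]]  # (protein_id, relation)
    inparalogs: set[str]

    def ortholog_ids(self) -> set[str]:
        return {pid for pid, _ in self.orthologs}


def _relation(m: int, n: int) -> str:
    if m == 1 and n == 1:
        return ONE2ONE
    if m == 1:
        return ONE2MANY
    if n == 1:
        return MANY2ONE
    return MANY2MANY


def infer_orthologs(tree: GeneTree, labeling: EventLabeling, seed: str) -> OrthologAssignment:
    """Orthologs (with relation types) and in-paralogs of one seed leaf.

    A leaf of a different species is an ortholog iff its LCA with the seed is
    a speciation.  In-paralogs are same-species leaves whose LCA with the
    seed is a duplication.
    """
    seed_leaf = tree.leaf(seed)
    seed_species = tree.species[seed]

    # species-count per subtree, computed lazily per needed (node, species)
    species_count_cache: dict[tuple[int, int], int] = {}

    def count_species(node: TreeNode, taxid: int) -> int:
        key = (id(node), taxid)
        if key not in species_count_cache:
            species_count_cache[key] = sum(
                1 for leaf in node.leaves() if tree.species[leaf.name] == taxid
            )
        return species_count_cache[key]

    # ancestor chain of the seed, with the child subtree the seed sits in
    chain: list[tuple[TreeNode, TreeNode]] = []  # (ancestor, child-of-ancestor-containing-seed)
    node = seed_leaf
    while node.parent is not None:
        chain.append((node.parent, node))
        node = node.parent
    depth_of = {id(anc): i for i, (anc, _) in enumerate(chain)}

    orthologs: set[tuple[str, str]] = set()
    inparalogs: set[str] = set()
    for leaf in tree.root.leaves():
        if leaf is seed_leaf:
            continue
        # climb from the target until hitting the seed's ancestor chain
        node = leaf
        while node.parent is not None and id(node.parent) not in depth_of:
            node = node.parent
        if node.parent is None:
            continue  # disconnected; cannot happen in a valid tree
        lca_node = node.parent
        seed_side = chain[depth_of[id(lca_node)]][1]
        target_side = node
        target_species = tree.species[leaf.name]
        if target_species == seed_species:
            if labeling.is_duplication(lca_node):
                inparalogs.add(leaf.name)
            continue
        if labeling.is_duplication(lca_node):
            continue
        m = count_species(seed_side, seed_species)
        n = count_species(target_side, target_species)
        orthologs.add((leaf.name, _relation(m, n)))
    return OrthologAssignment(seed=seed, orthologs=orthologs, inparalogs=inparalogs)


def orthologs_pairwise(tree: GeneTree, labeling: EventLabeling) -> set[frozenset[str]]:
    """Unordered ortholog pairs over all leaves (symmetric by construction)."""
    pairs: set[frozenset[str]] = set()
    for seed in tree.leaf_names():
        assignment = infer_orthologs(tree, labeling, seed)
        for pid, _ in assignment.orthologs:
            pairs.add(frozenset((seed, pid)))
    return pairs
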