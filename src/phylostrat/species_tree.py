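"""Rooted, dated species trees.

The species tree defines the age scale for the whole pipeline: every internal
node carries a taxon label and a divergence-time estimate in millions of
years ago (mya), and a protein's "age" is the age of the node on which its
family is inferred to have originated.  Trees are read from Newick text
(parsed with dendropy) with ages supplied either as an explicit two-column
node-age table or derived from branch lengths with extant leaves fixed at 0.

Ages only need to nest monotonically (a parent is at least as old as each
child); the tree is not required to be ultrametric.  Polytomies are allowed
and handled natively downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import dendropy

from .errors import (
    ArgumentError,
    DatingError,
    NewickParseError,
    TreeValidationError,
    UnknownLeafError,
)

__all__ = [
    "TreeNode",
    "SpeciesTree",
    "parse_species_tree",
    "read_age_table",
    "leaf_to_root_path",
    "mrca",
]

#: Tolerated disagreement (mya) between a node-age table and ages derived
#: from branch lengths when both are supplied.
AGE_MISMATCH_TOL = 1e-6


@dataclass
class TreeNode:
    """A node of the species tree.

    Parameters
    ----------
    label:
        Taxon name.  Required (and unique) for every node because ages are
        reported as taxon names; unlabeled internal nodes are auto-named
        ``node_<preorder-index>`` at parse time.
    age_mya:
        Divergence-time estimate in millions of years ago.  0 for extant
        leaves.
    children:
        Ordered child list; empty for leaves.
    """

    label: str
    age_mya: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = field(default=None, repr=False, compare=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["TreeNode"]:
        out: list[TreeNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]


class SpeciesTree:
    """A rooted, dated species tree with unique node labels.

    Attributes
    ----------
    root:
        The root :class:`TreeNode`.
    node_index:
        Map label -> node, over all nodes.
    leaf_index:
        Map label -> node, restricted to leaves.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self.node_index: dict[str, TreeNode] = {}
        self.leaf_index: dict[str, TreeNode] = {}
        dupes = []
        for node in root.preorder():
            if node.label in self.node_index:
                dupes.append(node.label)
            self.node_index[node.label] = node
            if node.is_leaf:
                self.leaf_index[node.label] = node
        if dupes:
            raise TreeValidationError(
                "duplicate node labels: " + ", ".join(sorted(set(dupes)))
            )
        self._validate_ages()

    def _validate_ages(self) -> None:
        for node in self.root.preorder():
            if node.age_mya < 0:
                raise TreeValidationError(
                    f"node {node.label!r} has negative age {node.age_mya}"
                )
            for child in node.children:
                if child.age_mya > node.age_mya:
                    raise DatingError(
                        f"child {child.label!r} (age {child.age_mya} mya) is "
                        f"older than its parent {node.label!r} "
                        f"(age {node.age_mya} mya)"
                    )

    # -- queries ---------------------------------------------------------

    @property
    def leaf_labels(self) -> list[str]:
        """Leaf labels in canonical (left-to-right preorder) order."""
        return [n.label for n in self.root.leaves()]

    def node(self, label: str) -> TreeNode:
        try:
            return self.node_index[label]
        except KeyError:
            raise UnknownLeafError(f"no node labeled {label!r} in tree") from None

    def leaf(self, label: str) -> TreeNode:
        try:
            return self.leaf_index[label]
        except KeyError:
            raise UnknownLeafError(f"no leaf labeled {label!r} in tree") from None

    def age_of(self, label: str) -> float:
        return self.node(label).age_mya

    # -- serialization ---------------------------------------------------

    def to_newick(self, with_branch_lengths: bool = True) -> str:
        """Serialize to Newick; branch lengths are parent age minus child age."""

        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                s = node.label
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")" + node.label
            if with_branch_lengths and node.parent is not None:
                s += f":{node.parent.age_mya - node.age_mya!r}"
            return s

        return fmt(self.root) + ";"

    def age_table(self) -> str:
        """Two-column tab-delimited node-age table (preorder)."""
        lines = ["#node\tage_mya"]
        lines += [f"{n.label}\t{n.age_mya!r}" for n in self.root.preorder()]
        return "\n".join(lines) + "\n"


def read_age_table(source: str | io.TextIOBase) -> dict[str, float]:
    """Read a two-column (label, age_mya) tab-delimited table.

    Lines starting with '#' and blank lines are ignored.
    """
    if isinstance(source, str):
        fh: Iterable[str] = open(source)
    else:
        fh = source
    ages: dict[str, float] = {}
    for lineno, raw in enumerate(fh, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise TreeValidationError(
                f"age table line {lineno}: expected 2 tab-separated columns, "
                f"got {len(parts)}"
            )
        label, age_s = parts[0].strip(), parts[1].strip()
        try:
            age = float(age_s)
        except ValueError:
            raise TreeValidationError(
                f"age table line {lineno}: non-numeric age {age_s!r}"
            ) from None
        if label in ages:
            raise TreeValidationError(f"age table: duplicate label {label!r}")
        ages[label] = age
    if isinstance(source, str):
        fh.close()  # type: ignore[union-attr]
    return ages


def parse_species_tree(
    text: str, ages: Optional[Mapping[str, float]] = None
) -> SpeciesTree:
    """Parse a Newick string into a dated :class:`SpeciesTree`.

    Ages come from the ``ages`` table when given (leaves default to 0 when
    omitted from the table); otherwise they are derived from branch lengths
    with every leaf at 0, a node's age being its maximum path length to a
    descendant leaf.  When both a table and complete branch lengths are
    present, the table wins but a disagreement larger than
    ``AGE_MISMATCH_TOL`` mya raises :class:`TreeValidationError`.

    Unlabeled internal nodes are auto-named ``node_<preorder-index>`` so that
    reported ages are stable across runs.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy's parse errors are not one class
        col = getattr(exc, "col_num", None)
        loc = f" near character offset {col}" if col is not None else ""
        raise NewickParseError(f"malformed Newick{loc}: {exc}") from exc

    # Convert to our node type, auto-naming as we go (preorder numbering).
    def convert(dnode: dendropy.Node) -> TreeNode:
        if dnode.taxon is not None and dnode.taxon.label:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        else:
            label = None  # type: ignore[assignment]
        node = TreeNode(label=label, age_mya=0.0)  # type: ignore[arg-type]
        node._edge_length = dnode.edge.length  # type: ignore[attr-defined]
        for dchild in dnode.child_nodes():
            child = convert(dchild)
            child.parent = node
            node.children.append(child)
        return node

    root = convert(dtree.seed_node)
    # collapse a unary chain at the root ("(A);" and friends): the single
    # child becomes the root, summing edge lengths
    while len(root.children) == 1:
        child = root.children[0]
        if (
            root._edge_length is not None  # type: ignore[attr-defined]
            and child._edge_length is not None  # type: ignore[attr-defined]
        ):
            child._edge_length += root._edge_length  # type: ignore[attr-defined]
        if root.label is not None and child.label is None:
            child.label = root.label
        child.parent = None
        root = child
    for i, node in enumerate(root.preorder()):
        if node.label is None:
            node.label = f"node_{i}"

    edge_lengths_complete = all(
        n._edge_length is not None  # type: ignore[attr-defined]
        for n in root.preorder()
        if n.parent is not None
    )
    derived: dict[int, float] = {}
    if edge_lengths_complete:
        for node in root.postorder():
            if node.is_leaf:
                derived[id(node)] = 0.0
            else:
                derived[id(node)] = max(
                    derived[id(c)] + c._edge_length  # type: ignore[attr-defined]
                    for c in node.children
                )

    if ages is not None:
        known = {n.label for n in root.preorder()}
        unknown = sorted(set(ages) - known)
        if unknown:
            raise TreeValidationError(
                "age table labels not in tree: " + ", ".join(unknown)
            )
        for node in root.preorder():
            if node.label in ages:
                node.age_mya = float(ages[node.label])
            elif node.is_leaf:
                node.age_mya = 0.0
            else:
                raise TreeValidationError(
                    f"no age given for internal node {node.label!r}"
                )
        if edge_lengths_complete:
            for node in root.preorder():
                if node.label in ages:
                    diff = abs(node.age_mya - derived[id(node)])
                    if diff > AGE_MISMATCH_TOL:
                        raise TreeValidationError(
                            f"age table and branch lengths disagree for node "
                            f"{node.label!r}: table {node.age_mya} vs derived "
                            f"{derived[id(node)]} mya"
                        )
    elif edge_lengths_complete:
        for node in root.preorder():
            node.age_mya = derived[id(node)]
    else:
        raise TreeValidationError(
            "no node-age table supplied and branch lengths are incomplete; "
            "cannot date the tree"
        )

    for node in root.preorder():
        if hasattr(node, "_edge_length"):
            del node._edge_length  # type: ignore[attr-defined]
    return SpeciesTree(root)


def leaf_to_root_path(tree: SpeciesTree, leaf_label: str) -> list[TreeNode]:
    """Nodes from the given leaf up to the root, leaf first."""
    node: Optional[TreeNode] = tree.leaf(leaf_label)
    path = []
    while node is not None:
        path.append(node)
        node = node.parent
    return path


def mrca(tree: SpeciesTree, leaf_labels: Iterable[str]) -> TreeNode:
    """Most recent common ancestor of a nonempty set of leaves.

    ``mrca({x})`` is the leaf ``x`` itself.
    """
    labels = list(leaf_labels)
    if not labels:
        raise ArgumentError("mrca requires a nonempty set of leaf labels")
    paths = [leaf_to_root_path(tree, lab) for lab in labels]
    common = set(id(n) for n in paths[0])
    for p in paths[1:]:
        common &= {id(n) for n in p}
    # deepest common node = first one met walking up from any leaf
    for node in paths[0]:
        if id(node) in common:
            return node
    raise TreeValidationError("tree has no common ancestor; not rooted?")
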