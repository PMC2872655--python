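"""Reading, writing and topological editing of rooted source phylogenies.

Source trees live in NEXUS tree files (a TREES block holding Newick
strings, optionally with a translate table) or as bare Newick.  Everything
downstream — overlap checks, substitutions, MRP coding — is purely
topological, so branch lengths and support values are stripped at parse
time and leaf labels are normalised (quotes removed, internal spaces
converted to underscores) so that taxon equality is plain string equality.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional, Sequence, Set

import dendropy

__all__ = [
    "Node",
    "SourceTree",
    "TreeError",
    "TreeParseError",
    "normalize_label",
    "is_valid_taxon_name",
    "paraphyly_base",
    "read_tree_file",
    "read_tree_files",
    "tree_from_newick",
    "fix_treeview_dialect",
    "write_tree_file",
    "write_trees",
    "prune_taxa",
    "graft_polytomy",
    "leaf_set",
    "clade_sets",
    "same_topology",
    "newick_string",
]


class TreeError(ValueError):
    """Invalid tree content or operation."""


class TreeParseError(TreeError):
    """A file could not be parsed as a tree."""


_PARAPHYLY_RE = re.compile(r"^(?P<base>[^%]+)%(?P<index>[1-9]\d*)$")


def normalize_label(raw: str) -> str:
    """Canonicalise a taxon label: strip surrounding quotes and whitespace,
    convert internal whitespace runs to single underscores."""
    label = raw.strip()
    if len(label) >= 2 and label[0] == label[-1] and label[0] in "'\"":
        label = label[1:-1]
    label = re.sub(r"\s+", "_", label.strip())
    return label


def is_valid_taxon_name(name: str) -> bool:
    """Check the canonical-name grammar: no whitespace, quotes, '=' or ',',
    first character uppercase, at most one paraphyly marker '%N'."""
    if not name or re.search(r"[\s'\"=,]", name):
        return False
    if not name[0].isupper():
        return False
    if "%" in name:
        return _PARAPHYLY_RE.match(name) is not None
    return True


def paraphyly_base(name: str) -> Optional[str]:
    """Return the base name if *name* carries a paraphyly marker (Ardea%2 ->
    Ardea), else None."""
    m = _PARAPHYLY_RE.match(name)
    return m.group("base") if m else None


class Node:
    """A node of a rooted, possibly polytomous topology.

    Leaves carry a label; internal nodes are unlabelled and have >=2
    children once unifurcations are suppressed.
    """

    __slots__ = ("label", "children")

    def __init__(self, label: Optional[str] = None,
                 children: Optional[List["Node"]] = None):
        self.label = label
        self.children: List[Node] = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        if self.is_leaf:
            return Node(label=self.label)
        return Node(children=[c.copy() for c in self.children])

    def iter_leaves(self) -> Iterator["Node"]:
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.iter_leaves()

    def iter_preorder(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.iter_preorder()

    def leaf_labels(self) -> List[str]:
        return [leaf.label for leaf in self.iter_leaves()]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({newick_string(self)})"


@dataclass
class SourceTree:
    """One rooted source phylogeny parsed from one file.

    ``rooted_flag`` records whether the file carried an explicit unrooted
    marker ([&U] -> False); the curation protocol expects rooted inputs, so
    check_data reports unrooted trees as warnings rather than rejecting
    them at parse time.
    """

    id: str
    root: Node
    tree_name: str = "tree_1"
    rooted_flag: bool = True

    @property
    def is_valid(self) -> bool:
        """A usable tree has at least two leaves."""
        return sum(1 for _ in self.root.iter_leaves()) >= 2

    def copy(self) -> "SourceTree":
        return SourceTree(id=self.id, root=self.root.copy(),
                          tree_name=self.tree_name,
                          rooted_flag=self.rooted_flag)


# ---------------------------------------------------------------------------
# parsing

def _from_dendropy(dnode: "dendropy.Node") -> Node:
    if dnode.is_leaf():
        raw = dnode.taxon.label if dnode.taxon is not None \
            else (dnode.label or "")
        return Node(label=normalize_label(raw))
    return Node(children=[_from_dendropy(c) for c in dnode.child_nodes()])


def _suppress_unifurcations(node: Node) -> Node:
    """Collapse every chain of single-child internal nodes, including at
    the root.  Returns the (possibly new) subtree root."""
    while len(node.children) == 1:
        node = node.children[0]
    if not node.is_leaf:
        node.children = [_suppress_unifurcations(c) for c in node.children]
    return node


def _looks_like_nexus(text: str) -> bool:
    return text.lstrip().lower().startswith("#nexus")


def _parse_trees(text: str, source_name: str) -> dendropy.TreeList:
    schema = "nexus" if _looks_like_nexus(text) else "newick"
    kwargs = dict(data=text, schema=schema, preserve_underscores=True,
                  rooting="default-rooted",
                  suppress_internal_node_taxa=True)
    try:
        try:
            trees = dendropy.TreeList.get(**kwargs)
        except Exception as exc:
            # duplicate leaf labels are a dataset defect to *report*, not a
            # parse failure: retry treating labels as plain node labels
            if "Duplicate taxon labels" not in str(exc):
                raise
            trees = dendropy.TreeList.get(suppress_leaf_node_taxa=True,
                                          **kwargs)
    except Exception as exc:
        snippet = text.strip().splitlines()[0][:80] if text.strip() else ""
        raise TreeParseError(
            f"{source_name}: cannot parse tree data ({exc}); "
            f"offending text starts: {snippet!r}"
        ) from None
    if len(trees) == 0:
        raise TreeParseError(f"{source_name}: file contains no trees")
    return trees


def tree_from_newick(newick: str, tree_id: str = "tree") -> SourceTree:
    """Parse a Newick string in memory (same normalisation as files)."""
    dtree = _parse_trees(newick, "<string>")[0]
    root = _suppress_unifurcations(_from_dendropy(dtree.seed_node))
    return SourceTree(id=tree_id, root=root,
                      rooted_flag=bool(dtree.is_rooted))


def read_tree_files(path) -> List[SourceTree]:
    """Parse every tree in a file (used by amalgamated-file round trips)."""
    path = str(path)
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    stem = re.sub(r"\.[^.]*$", "", path.rsplit("/", 1)[-1])
    out: List[SourceTree] = []
    for i, dtree in enumerate(_parse_trees(text, path), start=1):
        root = _suppress_unifurcations(_from_dendropy(dtree.seed_node))
        name = dtree.label or f"tree_{i}"
        out.append(SourceTree(id=stem if i == 1 else f"{stem}_{i}",
                              root=root,
                              tree_name=normalize_label(name),
                              rooted_flag=bool(dtree.is_rooted)))
    return out


def read_tree_file(path) -> SourceTree:
    """Read the first tree in a NEXUS or bare-Newick file.

    Branch lengths and support values are dropped, translate tables are
    resolved and labels are normalised.  Files holding more than one tree
    trigger a warning naming the ignored trees (the pairing convention is
    one source tree per file).
    """
    trees = read_tree_files(path)
    if len(trees) > 1:
        ignored = ", ".join(t.tree_name for t in trees[1:])
        warnings.warn(
            f"{path}: {len(trees)} trees found; using the first, "
            f"ignoring: {ignored}",
            stacklevel=2,
        )
    return trees[0]


def fix_treeview_dialect(path) -> SourceTree:
    """Read a tree file written in a drawing-program NEXUS variant
    (translate table, quoted labels, [&R]/[&U] comments) and return the
    normalised SourceTree; writing it back yields the standard dialect."""
    return read_tree_file(path)


# ---------------------------------------------------------------------------
# writing

def newick_string(node: Node) -> str:
    if node.is_leaf:
        return node.label or ""
    return "(" + ",".join(newick_string(c) for c in node.children) + ")"


def write_trees(trees: Sequence[SourceTree], path) -> None:
    """Write trees in the standard dialect: a #NEXUS TREES block, no
    translate table, one 'TREE name = [&R] ...;' line per tree,
    unquoted underscore labels."""
    for tree in trees:
        if not tree.is_valid:
            raise TreeError(
                f"refusing to write tree {tree.id!r}: fewer than 2 leaves")
    lines = ["#NEXUS", "BEGIN TREES;"]
    for tree in trees:
        marker = "[&R]" if tree.rooted_flag else "[&U]"
        lines.append(
            f"\tTREE {tree.tree_name} = {marker} {newick_string(tree.root)};")
    lines.append("END;")
    with open(str(path), "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def write_tree_file(tree: SourceTree, path) -> None:
    """Write a single tree in the standard dialect (round-trips through
    read_tree_file with identical topology and labels)."""
    write_trees([tree], path)


# ---------------------------------------------------------------------------
# topological edits

def leaf_set(tree: SourceTree) -> Set[str]:
    """Distinct leaf labels (duplicates collapse here; dataset checks report
    them)."""
    return set(tree.root.leaf_labels())


def prune_taxa(tree: SourceTree, taxa: Iterable[str]) -> SourceTree:
    """Remove the named leaves and suppress resulting unifurcations.

    Pruning absent taxa is a no-op.  If fewer than two leaves remain the
    result's ``is_valid`` is False so callers can drop the tree.
    """
    drop = set(taxa)

    def _prune(node: Node) -> Optional[Node]:
        if node.is_leaf:
            return None if node.label in drop else Node(label=node.label)
        kept = [c for c in (_prune(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        return Node(children=kept)

    new_root = _prune(tree.root)
    if new_root is None:
        new_root = Node(children=[])
    return SourceTree(id=tree.id, root=new_root, tree_name=tree.tree_name,
                      rooted_flag=tree.rooted_flag)


def graft_polytomy(tree: SourceTree, old: str,
                   new: Sequence[str]) -> SourceTree:
    """Replace leaf *old* with the taxa in *new*.

    Replacement names already present elsewhere in the tree are dropped
    from the graft list first (substitutions must never create duplicate
    leaves).  With >=2 surviving names the leaf becomes a polytomy of
    them, with exactly one it is relabelled, with none it is pruned.
    """
    if old not in leaf_set(tree):
        warnings.warn(f"tree {tree.id!r}: taxon {old!r} not present; "
                      "graft is a no-op", stacklevel=2)
        return tree.copy()
    present_elsewhere = leaf_set(tree) - {old}
    filtered: List[str] = []
    for name in new:
        if name not in present_elsewhere and name not in filtered:
            filtered.append(name)
    return _replace_leaf(tree, old, filtered)


def _replace_leaf(tree: SourceTree, old: str,
                  replacement: Sequence[str]) -> SourceTree:
    """Low-level simultaneous replacement of every leaf labelled *old* with
    the already-filtered *replacement* list (no duplicate avoidance here)."""
    if not replacement:
        return prune_taxa(tree, {old})

    def _rebuild(node: Node) -> Node:
        if node.is_leaf:
            if node.label == old:
                if len(replacement) == 1:
                    return Node(label=replacement[0])
                return Node(children=[Node(label=n) for n in replacement])
            return Node(label=node.label)
        return Node(children=[_rebuild(c) for c in node.children])

    return SourceTree(id=tree.id, root=_rebuild(tree.root),
                      tree_name=tree.tree_name, rooted_flag=tree.rooted_flag)


# ---------------------------------------------------------------------------
# topology comparison

def clade_sets(tree: SourceTree) -> List[frozenset]:
    """Leaf sets of every internal non-root node, deterministic preorder."""
    out: List[frozenset] = []

    def _walk(node: Node, is_root: bool) -> None:
        if node.is_leaf:
            return
        if not is_root:
            out.append(frozenset(node.leaf_labels()))
        for child in node.children:
            _walk(child, False)

    _walk(tree.root, True)
    return out


def same_topology(a: SourceTree, b: SourceTree) -> bool:
    """Label- and topology-identity: equal leaf sets and equal clade sets."""
    return (leaf_set(a) == leaf_set(b)
            and set(clade_sets(a)) == set(clade_sets(b)))
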