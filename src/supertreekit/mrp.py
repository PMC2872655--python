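"""Matrix representation with parsimony (MRP) coding.

Every informative clade (internal non-root node) of every source tree
becomes one binary character under Baum-Ragan component coding: taxa
inside the clade score 1, taxa elsewhere in the same source tree score 0,
and taxa absent from that tree score '?'.  The concatenated matrix over
all source trees is then analysable with parsimony software (PAUP*, TNT),
whose most-parsimonious trees are the MRP supertrees.

An all-zero hypothetical outgroup row (``MRP_Outgroup``) is included by
default; rooting the parsimony analysis on it recovers the source trees'
root orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from . import dataset as dsmod
from . import trees as tr
from .trees import Node, SourceTree

__all__ = ["MRPColumn", "MRPMatrix", "MatrixError", "OUTGROUP_NAME",
           "enumerate_clades", "create_matrix", "write_matrix",
           "tree_from_clades"]

OUTGROUP_NAME = "MRP_Outgroup"


class MatrixError(ValueError):
    pass


@dataclass(frozen=True)
class MRPColumn:
    """One binary character: the members of one clade of one source tree."""
    member_taxa: FrozenSet[str]
    tree_taxa: FrozenSet[str]
    source_tree: str
    clade_index: int

    def cell(self, taxon: str) -> str:
        if taxon in self.member_taxa:
            return "1"
        if taxon in self.tree_taxa:
            return "0"
        return "?"


@dataclass
class MRPMatrix:
    taxa: List[str]                # alphabetical union (+ outgroup first)
    columns: List[MRPColumn]

    @property
    def ntax(self) -> int:
        return len(self.taxa)

    @property
    def nchar(self) -> int:
        return len(self.columns)

    def row(self, taxon: str) -> str:
        if taxon == OUTGROUP_NAME and taxon in self.taxa:
            return "0" * self.nchar
        return "".join(col.cell(taxon) for col in self.columns)

    def rows(self) -> List[Tuple[str, str]]:
        return [(taxon, self.row(taxon)) for taxon in self.taxa]

    def provenance(self) -> List[Tuple[str, int]]:
        """(source tree id, clade index) per column."""
        return [(c.source_tree, c.clade_index) for c in self.columns]


def enumerate_clades(tree: SourceTree) -> List[Set[str]]:
    """Leaf sets of the internal non-root nodes, deterministic preorder.

    These are exactly the informative clades: each has >=2 members and
    excludes at least one taxon of its tree.
    """
    return [set(c) for c in tr.clade_sets(tree)]


def create_matrix(ds: dsmod.Dataset,
                  outgroup_row: bool = True) -> MRPMatrix:
    """Baum-Ragan code a whole dataset.

    The dataset must pass check_data (error-level issues block coding);
    columns are concatenated in dataset order, clades of each tree in
    preorder, so the matrix is reproducible for a given dataset ordering.
    """
    report = dsmod.check_data(ds)
    if not report.passed:
        blocking = "; ".join(str(i) for i in report.errors()[:5])
        raise MatrixError(
            f"dataset fails integrity checks; fix before coding: {blocking}")
    tree_recs = [rec for rec in ds.records if rec.tree is not None]
    if not tree_recs:
        raise MatrixError("no trees to encode")
    columns: List[MRPColumn] = []
    for rec in tree_recs:
        tree_taxa = frozenset(tr.leaf_set(rec.tree))
        for idx, clade in enumerate(enumerate_clades(rec.tree)):
            columns.append(MRPColumn(member_taxa=frozenset(clade),
                                     tree_taxa=tree_taxa,
                                     source_tree=rec.id,
                                     clade_index=idx))
    taxa = sorted(set().union(*(c.tree_taxa for c in columns)))
    if outgroup_row:
        taxa = [OUTGROUP_NAME] + taxa
    return MRPMatrix(taxa=taxa, columns=columns)


def write_matrix(m: MRPMatrix, path, fmt: str = "nexus") -> None:
    """Write an analysis-ready matrix file.

    ``nexus``: a DATA block with DIMENSIONS/FORMAT/MATRIX (PAUP* input);
    ``tnt``: an xread block ('nchar ntax' header).  Cell content is
    identical across formats and output is byte-deterministic.
    """
    if fmt not in ("nexus", "tnt"):
        raise ValueError(f"unknown matrix format {fmt!r}")
    width = max(len(t) for t in m.taxa) + 2
    body = [f"{taxon:<{width}}{row}" for taxon, row in m.rows()]
    if fmt == "nexus":
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"\tDIMENSIONS NTAX={m.ntax} NCHAR={m.nchar};",
            '\tFORMAT MISSING=? SYMBOLS="01";',
            "\tMATRIX",
        ]
        lines += ["\t" + row for row in body]
        lines += ["\t;", "END;"]
    else:
        lines = ["xread", f"{m.nchar} {m.ntax}"]
        lines += body
        lines += [";"]
    with open(str(path), "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def tree_from_clades(clades: Iterable[Set[str]],
                     taxa: Iterable[str]) -> SourceTree:
    """Assemble the rooted tree displaying a compatible clade collection.

    Clades are nested by containment under an implicit root clade of all
    *taxa*; incompatible (properly overlapping) clades raise MatrixError.
    Applied to the column clades of a matrix built from one tree, this
    inverts the coding and recovers that tree exactly.
    """
    all_taxa = set(taxa)
    unique = {frozenset(c) for c in clades}
    for clade in unique:
        if not clade <= all_taxa:
            raise MatrixError(f"clade {sorted(clade)} not within taxon set")
    for a in unique:
        for b in unique:
            inter = a & b
            if inter and inter != a and inter != b:
                raise MatrixError(
                    f"incompatible clades: {sorted(a)} vs {sorted(b)}")
    ordered = sorted(unique, key=lambda c: (-len(c), sorted(c)))

    root = Node(children=[])
    clade_node: Dict[FrozenSet[str], Node] = {frozenset(all_taxa): root}
    parent_sets = [frozenset(all_taxa)]
    for clade in ordered:
        if clade == frozenset(all_taxa):
            continue
        # smallest already-placed clade containing this one is its parent
        parent = min((p for p in parent_sets if clade <= p), key=len)
        node = Node(children=[])
        clade_node[parent].children.append(node)
        clade_node[clade] = node
        parent_sets.append(clade)
    # attach each taxon to its smallest containing clade
    for taxon in sorted(all_taxa):
        parent = min((p for p in parent_sets if taxon in p), key=len)
        clade_node[parent].children.append(Node(label=taxon))
    return SourceTree(id="reconstructed",
                      root=tr._suppress_unifurcations(root))
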