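"""Taxonomic overlap between source trees.

Two rooted source trees can only be combined into a supertree if they
share at least two taxa.  The overlap graph has one node per source tree
and an edge between two trees whenever they share at least ``n`` taxa
(default n=2, the theoretical minimum; larger n applies a more stringent
requirement).  "Adequate overlap" for a whole dataset is formalised as
connectivity of this graph: a disconnected component cannot be related to
the rest of the data by any supertree method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Set, Tuple

import networkx as nx

from . import dataset as dsmod
from . import trees as tr

__all__ = ["OverlapGraph", "OverlapResult", "build_overlap_graph",
           "check_overlap", "write_dot"]


@dataclass
class OverlapGraph:
    graph: nx.Graph
    threshold: int

    @property
    def nodes(self) -> List[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> List[Tuple[str, str, int]]:
        return sorted((min(u, v), max(u, v), d["weight"])
                      for u, v, d in self.graph.edges(data=True))


@dataclass
class OverlapResult:
    passed: bool
    components: List[Set[str]]   # largest first
    excluded: Set[str]
    tie: bool = False            # >1 component ties for largest


def build_overlap_graph(ds: dsmod.Dataset, n: int = 2) -> OverlapGraph:
    """Pairwise leaf-set intersections; edge iff the two trees share at
    least *n* taxa, with the shared count as the edge weight."""
    if n < 2:
        raise ValueError(f"overlap threshold must be >= 2, got {n}")
    g = nx.Graph()
    leafsets = [(rec.id, tr.leaf_set(rec.tree)) for rec in ds.records
                if rec.tree is not None]
    for rec_id, _ in leafsets:
        g.add_node(rec_id)
    for i, (id_a, taxa_a) in enumerate(leafsets):
        for id_b, taxa_b in leafsets[i + 1:]:
            weight = len(taxa_a & taxa_b)
            if weight >= n:
                g.add_edge(id_a, id_b, weight=weight)
    return OverlapGraph(graph=g, threshold=n)


def check_overlap(ds: dsmod.Dataset, n: int = 2) -> OverlapResult:
    """Connectivity verdict for the n-taxon overlap graph.

    ``excluded`` lists every tree outside the single largest connected
    component — the trees that would have to be dropped (or augmented
    with more data) before supertree construction.  When several
    components tie for largest no exclusion is recommended; ``tie`` is
    set so the user can choose manually.
    """
    og = build_overlap_graph(ds, n=n)
    if og.graph.number_of_nodes() == 0:
        return OverlapResult(passed=True, components=[], excluded=set())
    comps = sorted((set(c) for c in nx.connected_components(og.graph)),
                   key=lambda c: (-len(c), sorted(c)))
    passed = len(comps) == 1
    tie = len(comps) > 1 and len(comps[0]) == len(comps[1])
    if passed or tie:
        excluded: Set[str] = set()
    else:
        excluded = set().union(*comps[1:])
    return OverlapResult(passed=passed, components=comps, excluded=excluded,
                         tie=tie)


def write_dot(g: OverlapGraph, path) -> None:
    """Emit the overlap graph as plain DOT for layout with graph tools:
    one node line per tree, one undirected edge line per pair sharing
    enough taxa, the shared-taxon count as the edge label."""
    lines = ["graph overlap {"]
    for node in g.nodes:
        lines.append(f'    "{node}";')
    for u, v, weight in g.edges:
        lines.append(f'    "{u}" -- "{v}" [label="{weight}"];')
    lines.append("}")
    with open(str(path), "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
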