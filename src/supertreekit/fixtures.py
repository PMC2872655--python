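"""Synthetic dataset generator.

Builds on-disk datasets (paired ``.tre``/``.xml`` files) with controlled
properties — taxon-pool size, per-tree leaf counts, overlap structure
(connected or split into k components), seeded defects, paraphyly markers
— so every check and algorithm in the toolkit is exercisable without any
external data.  Output is fully deterministic for a given settings+seed
pair, and every seeded defect is recorded in a ``manifest.json`` next to
the data so tests can assert exact detection.

Random topologies are built by sequential random leaf attachment (each new
leaf splits a uniformly chosen edge).  This is simple and seed-stable; it
makes no claim to match any biological tree-shape model such as
birth-death.
"""

from __future__ import annotations

import json
import os
import random
import string
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

from . import dataset as dsmod
from . import metadata as md
from . import trees as tr
from .trees import Node, SourceTree

__all__ = ["GeneratorSettings", "FixtureError", "random_topology",
           "make_taxon_pool", "generate_dataset", "generate_figure1_like",
           "settings_from_dict"]

DEFECT_KINDS = ("duplicate-leaf", "xml-mismatch", "unrooted", "missing-xml")

_AUTHORS = ("Smith, A.", "Jones, B.", "Garcia, C.", "Chen, D.",
            "Okafor, E.", "Novak, F.")
_VOCAB = (("molecular", "cytb"), ("molecular", "12S rRNA"),
          ("molecular", "RAG1"), ("morphological", "osteology"),
          ("behavioural", "display behaviour"))
_ANALYSES = ("parsimony", "likelihood", "Bayesian")


class FixtureError(ValueError):
    pass


@dataclass
class GeneratorSettings:
    n_trees: int = 10
    taxon_pool_size: int = 40
    leaf_range: Tuple[int, int] = (5, 10)
    n_components: int = 1          # target overlap components
    min_overlap: int = 2           # taxa shared with an earlier tree
    defects: Tuple[str, ...] = ()  # each seeded exactly once
    duplicate_taxon_name: Optional[str] = None
    paraphyly: bool = False
    character_vocab: Tuple[Tuple[str, str], ...] = _VOCAB
    species_per_genus: int = 3


def settings_from_dict(cfg: dict) -> GeneratorSettings:
    """Build settings from a plain key/value mapping (the CLI config)."""
    kwargs = dict(cfg)
    for key in ("leaf_range", "defects", "character_vocab"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(tuple(v) if isinstance(v, list) else v
                                for v in kwargs[key])
    unknown = set(kwargs) - {f for f in GeneratorSettings.__dataclass_fields__}
    if unknown:
        raise FixtureError(f"unknown generator settings: {sorted(unknown)}")
    return GeneratorSettings(**kwargs)


def make_taxon_pool(size: int, species_per_genus: int = 3) -> List[str]:
    """Deterministic pool of binomial names, ``species_per_genus`` species
    per synthetic genus (Ga_s1, Ga_s2, ..., Gb_s1, ...)."""
    pool: List[str] = []
    genus_idx = 0
    while len(pool) < size:
        letters = ""
        i = genus_idx
        while True:
            letters = string.ascii_lowercase[i % 26] + letters
            i //= 26
            if i == 0:
                break
        genus = "G" + letters
        for j in range(1, species_per_genus + 1):
            pool.append(f"{genus}_s{j}")
            if len(pool) == size:
                break
        genus_idx += 1
    return pool


def random_topology(labels: Sequence[str], rng: random.Random) -> Node:
    """Random binary topology over *labels* by sequential attachment: each
    new leaf splits an edge chosen uniformly at random."""
    labels = list(labels)
    if not labels:
        raise FixtureError("cannot build a tree with no leaves")
    if len(labels) == 1:
        return Node(label=labels[0])
    first, second = Node(label=labels[0]), Node(label=labels[1])
    root = Node(children=[first, second])
    edges: List[Tuple[Node, Node]] = [(root, first), (root, second)]
    for label in labels[2:]:
        parent, child = edges.pop(rng.randrange(len(edges)))
        leaf = Node(label=label)
        joint = Node(children=[child, leaf])
        parent.children[parent.children.index(child)] = joint
        edges.extend([(parent, joint), (joint, child), (joint, leaf)])
    return root


def _random_metadata(rng: random.Random, taxa: Sequence[str],
                     vocab: Sequence[Tuple[str, str]],
                     tree_file: str) -> md.SourceMetadata:
    n_chars = rng.randint(1, min(2, len(vocab)))
    chars = [md.CharacterRecord(ctype=t, name=n)
             for t, n in rng.sample(list(vocab), n_chars)]
    return md.SourceMetadata(
        authors=list(rng.sample(_AUTHORS, rng.randint(1, 3))),
        year=rng.randint(1985, 2010),
        title=f"Phylogenetic relationships of the {taxa[0].split('_')[0]} "
              "group",
        journal="Journal of Synthetic Systematics",
        taxa=sorted(taxa),
        characters=chars,
        analysis=rng.choice(_ANALYSES),
        tree_file=tree_file,
    )


def _sample_leaf_sets(settings: GeneratorSettings,
                      rng: random.Random) -> List[List[str]]:
    """Leaf sets per tree honouring the overlap structure: within each
    component every tree after the first shares >= min_overlap taxa with
    some earlier tree of the same component; components use disjoint
    sub-pools so they can never connect by accident."""
    lo, hi = settings.leaf_range
    if lo < 2:
        raise FixtureError("leaf_range minimum must be >= 2")
    if settings.n_components < 1:
        raise FixtureError("n_components must be >= 1")
    if settings.n_components > settings.n_trees:
        raise FixtureError("more components than trees")
    pool = make_taxon_pool(settings.taxon_pool_size,
                           settings.species_per_genus)
    k = settings.n_components
    chunk = len(pool) // k
    if chunk < hi:
        raise FixtureError(
            f"taxon pool of {len(pool)} split into {k} components gives "
            f"{chunk} taxa each; cannot draw up to {hi} leaves per tree")
    subpools = [pool[i * chunk:(i + 1) * chunk] for i in range(k)]
    comp_of_tree = [i % k for i in range(settings.n_trees)]
    used_leaf_sets: Dict[int, List[List[str]]] = {i: [] for i in range(k)}
    out: List[List[str]] = []
    for tree_idx in range(settings.n_trees):
        comp = comp_of_tree[tree_idx]
        subpool = subpools[comp]
        n_leaves = rng.randint(lo, hi)
        previous = used_leaf_sets[comp]
        if previous:
            anchor = previous[rng.randrange(len(previous))]
            n_shared = min(settings.min_overlap, len(anchor), n_leaves)
            leaves = rng.sample(anchor, n_shared)
        else:
            leaves = []
        rest = [t for t in subpool if t not in leaves]
        leaves += rng.sample(rest, n_leaves - len(leaves))
        rng.shuffle(leaves)
        used_leaf_sets[comp].append(leaves)
        out.append(leaves)
    return out


def generate_dataset(settings: GeneratorSettings, seed: int,
                     out_dir) -> dsmod.Dataset:
    """Write a synthetic dataset to *out_dir* and load it back.

    With no defects ("clean" mode) the result passes check_data with zero
    issues.  Each requested defect is injected into a distinct tree and
    described in ``manifest.json`` as the exact (severity, file, message)
    triple check_data will report.
    """
    for defect in settings.defects:
        if defect not in DEFECT_KINDS:
            raise FixtureError(f"unknown defect kind {defect!r}")
    if len(settings.defects) != len(set(settings.defects)):
        raise FixtureError("each defect kind may be requested once")
    if len(settings.defects) > settings.n_trees:
        raise FixtureError("more defects than trees to host them")
    rng = random.Random(seed)
    leaf_sets = _sample_leaf_sets(settings, rng)
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)

    trees: List[SourceTree] = []
    for i, leaves in enumerate(leaf_sets, start=1):
        root = random_topology(leaves, rng)
        trees.append(SourceTree(id=f"tree{i:03d}", root=root))

    if settings.paraphyly:
        # mark the first tree's first leaf as paraphyletic in two places
        target = trees[0]
        leaves = list(target.root.iter_leaves())
        base = leaves[0].label
        leaves[0].label = f"{base}%1"
        other = leaves[rng.randrange(1, len(leaves))]
        parent_label = f"{base}%2"
        other_copy = Node(label=other.label)
        other.label = None
        other.children = [other_copy, Node(label=parent_label)]

    manifest: List[dict] = []
    skip_xml: Set[str] = set()
    extra_xml_taxon: Dict[str, str] = {}

    for defect_idx, defect in enumerate(settings.defects):
        target = trees[defect_idx]
        fname = f"{target.id}.tre"
        if defect == "duplicate-leaf":
            leaves = list(target.root.iter_leaves())
            dup = settings.duplicate_taxon_name or leaves[0].label
            leaves[0].label = dup
            leaves[1].label = dup
            manifest.append({"kind": defect, "severity": "error",
                             "file": fname,
                             "message": f"Duplicate taxon: {dup}"})
        elif defect == "unrooted":
            target.rooted_flag = False
            manifest.append({"kind": defect, "severity": "warning",
                             "file": fname,
                             "message": "tree is marked unrooted; the "
                                        "protocol requires rooted source "
                                        "trees"})
        elif defect == "missing-xml":
            skip_xml.add(target.id)
            manifest.append({"kind": defect, "severity": "warning",
                             "file": fname,
                             "message": "no meta-data XML paired with "
                                        "this tree"})
        elif defect == "xml-mismatch":
            extra_xml_taxon[target.id] = "Phantom_taxon"
            manifest.append({"kind": defect, "severity": "error",
                             "file": f"{target.id}.xml",
                             "message": "taxon Phantom_taxon in XML but "
                                        "not in tree"})

    for tree in trees:
        tre_path = os.path.join(out_dir, f"{tree.id}.tre")
        tr.write_tree_file(tree, tre_path)
        if tree.id in skip_xml:
            continue
        taxa = sorted(tr.leaf_set(tree))
        if tree.id in extra_xml_taxon:
            taxa = sorted(taxa + [extra_xml_taxon[tree.id]])
        meta = _random_metadata(rng, taxa, settings.character_vocab,
                                tree_file=f"{tree.id}.tre")
        md.write_metadata(meta, os.path.join(out_dir, f"{tree.id}.xml"))

    with open(os.path.join(out_dir, "manifest.json"), "w",
              encoding="utf-8") as fh:
        json.dump({"seed": seed, "defects": manifest}, fh, indent=2,
                  sort_keys=True)
        fh.write("\n")
    return dsmod.load_dataset(out_dir)


def generate_figure1_like(seed: int, out_dir) -> dsmod.Dataset:
    """A ~20-tree dataset exhibiting threshold-dependent overlap failure.

    Eighteen "core" trees all share a four-taxon backbone (pairwise
    overlap 4).  One satellite tree shares exactly two backbone taxa with
    each core tree, and one isolated tree shares at most one taxon with
    anything.  Hence at the minimum requirement (n=2) exactly one tree is
    disconnected, while raising the requirement to n=4 disconnects the
    satellite as well and strictly reduces the edge count.
    """
    rng = random.Random(seed)
    pool = make_taxon_pool(200, species_per_genus=3)
    backbone = pool[:4]
    extras = pool[4:]
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    trees: List[SourceTree] = []
    cursor = 0

    def take(n: int) -> List[str]:
        nonlocal cursor
        chunk = extras[cursor:cursor + n]
        cursor += n
        return chunk

    for i in range(1, 19):
        leaves = backbone + take(rng.randint(3, 5))
        rng.shuffle(leaves)
        trees.append(SourceTree(id=f"t{i:02d}",
                                root=random_topology(leaves, rng)))
    satellite = backbone[:2] + take(rng.randint(3, 5))
    rng.shuffle(satellite)
    trees.append(SourceTree(id="t19", root=random_topology(satellite, rng)))
    isolated = [backbone[0]] + take(rng.randint(4, 6))
    rng.shuffle(isolated)
    trees.append(SourceTree(id="t20", root=random_topology(isolated, rng)))

    for tree in trees:
        tr.write_tree_file(tree, os.path.join(out_dir, f"{tree.id}.tre"))
        meta = _random_metadata(rng, sorted(tr.leaf_set(tree)), _VOCAB,
                                tree_file=f"{tree.id}.tre")
        md.write_metadata(meta, os.path.join(out_dir, f"{tree.id}.xml"))
    return dsmod.load_dataset(out_dir)
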