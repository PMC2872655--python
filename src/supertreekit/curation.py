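"""Taxon standardisation: substitution files, replace/delete, genus-to-
species conversion, name standardisation and paraphyly permutation.

Substitution files use the grammar ``old = new1, new2, ...`` (one rule per
line; an empty right-hand side deletes the taxon; a multi-name right-hand
side grafts a polytomy where the old leaf stood).  All rules in a file are
applied *simultaneously* — every rule is interpreted against the
pre-substitution state of each tree, so rule order can never chain and a
pair of rules can swap two labels without oscillating.

Duplicate avoidance: a replacement name that would collide with a taxon
surviving elsewhere in the same tree is dropped from the graft list, so
substitutions can never create duplicate leaves (which check_data treats
as errors).
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from . import dataset as dsmod
from . import trees as tr
from .metadata import Issue
from .trees import Node, SourceTree, paraphyly_base

__all__ = [
    "SubstitutionRule",
    "SubstitutionFile",
    "SubstitutionError",
    "parse_substitution_file",
    "parse_substitution_text",
    "write_substitution_file",
    "apply_substitutions",
    "apply_substitutions_to_tree",
    "replace_taxon",
    "check_substitutions",
    "replace_genera",
    "standardise_names",
    "permute_paraphyly",
]


class SubstitutionError(ValueError):
    pass


@dataclass(frozen=True)
class SubstitutionRule:
    """Replace *old* with the taxa in *new* (empty *new* = deletion)."""
    old: str
    new: Tuple[str, ...] = ()

    def __post_init__(self):
        if self.old in self.new:
            raise SubstitutionError(
                f"rule for {self.old!r}: old name may not appear among "
                "its replacements")
        if len(set(self.new)) != len(self.new):
            raise SubstitutionError(
                f"rule for {self.old!r}: duplicate replacement names")


@dataclass
class SubstitutionFile:
    rules: List[SubstitutionRule] = field(default_factory=list)

    def __post_init__(self):
        olds = [r.old for r in self.rules]
        dupes = {o for o in olds if olds.count(o) > 1}
        if dupes:
            raise SubstitutionError(
                f"multiple rules for the same taxon: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def by_old(self) -> Dict[str, SubstitutionRule]:
        return {r.old: r for r in self.rules}


def _norm_name(token: str) -> str:
    return re.sub(r"\s+", "_", token.strip())


def parse_substitution_text(text: str,
                            source: str = "<string>") -> SubstitutionFile:
    rules: List[SubstitutionRule] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise SubstitutionError(
                f"{source}:{lineno}: missing '=' in rule: {stripped!r}")
        old_part, new_part = stripped.split("=", 1)
        old = _norm_name(old_part)
        if not old:
            raise SubstitutionError(
                f"{source}:{lineno}: empty old-taxon name")
        new = tuple(_norm_name(t) for t in new_part.split(",")
                    if _norm_name(t))
        try:
            rules.append(SubstitutionRule(old=old, new=new))
        except SubstitutionError as exc:
            raise SubstitutionError(f"{source}:{lineno}: {exc}") from None
    try:
        return SubstitutionFile(rules=rules)
    except SubstitutionError as exc:
        raise SubstitutionError(f"{source}: {exc}") from None


def parse_substitution_file(path) -> SubstitutionFile:
    """Parse a ``old = new1, new2`` substitution file (blank lines and
    ``#`` comments ignored; spaces inside names become underscores)."""
    with open(str(path), "r", encoding="utf-8") as fh:
        return parse_substitution_text(fh.read(), source=str(path))


def write_substitution_file(subs: SubstitutionFile, path) -> None:
    with open(str(path), "w", encoding="utf-8") as fh:
        for rule in subs.rules:
            fh.write(f"{rule.old} = {', '.join(rule.new)}\n")


# ---------------------------------------------------------------------------
# applying substitutions

def apply_substitutions_to_tree(tree: SourceTree,
                                subs: SubstitutionFile) -> SourceTree:
    """Apply every rule to one tree under simultaneous semantics.

    Leaves without a rule keep their labels; rule-bearing leaves are
    rewritten in tree order with duplicate avoidance against surviving
    labels and replacements already placed by earlier rules.  The result
    may have fewer than two leaves (``is_valid`` False) when deletions
    empty the tree.
    """
    rules = subs.by_old()
    pre_leaves = tree.root.leaf_labels()
    if not any(lbl in rules for lbl in pre_leaves):
        return tree.copy()
    kept = {lbl for lbl in pre_leaves if lbl not in rules}
    placed: Set[str] = set()

    def _rebuild(node: Node) -> Optional[Node]:
        if node.is_leaf:
            rule = rules.get(node.label)
            if rule is None:
                return Node(label=node.label)
            filtered = [n for n in rule.new
                        if n not in kept and n not in placed]
            placed.update(filtered)
            if not filtered:
                return None
            if len(filtered) == 1:
                return Node(label=filtered[0])
            return Node(children=[Node(label=n) for n in filtered])
        children = [c for c in (_rebuild(ch) for ch in node.children)
                    if c is not None]
        if not children:
            return None
        if len(children) == 1:
            return children[0]
        return Node(children=children)

    new_root = _rebuild(tree.root)
    if new_root is None:
        new_root = Node(children=[])
    return SourceTree(id=tree.id, root=new_root, tree_name=tree.tree_name,
                      rooted_flag=tree.rooted_flag)


def apply_substitutions(ds: dsmod.Dataset,
                        subs: SubstitutionFile) -> dsmod.Dataset:
    """Apply a substitution file to every tree and XML taxa list.

    Absent old names are silent per-tree no-ops.  Trees reduced below two
    leaves are kept but flagged invalid and reported with a warning so the
    caller can drop them.  Meta-data taxa lists are rewritten to equal the
    new leaf sets, keeping the tree/XML cross-check green.
    """
    out = dsmod.Dataset(records=[], root_dir=ds.root_dir)
    rules = subs.by_old()
    for rec in ds.records:
        new_rec = rec.copy()
        if rec.tree is not None:
            new_rec.tree = apply_substitutions_to_tree(rec.tree, subs)
            if not new_rec.tree.is_valid:
                warnings.warn(
                    f"tree {rec.id!r} reduced below 2 leaves by "
                    "substitutions; flagged invalid", stacklevel=2)
            if new_rec.meta is not None:
                new_rec.meta.taxa = sorted(tr.leaf_set(new_rec.tree))
        elif new_rec.meta is not None:
            # metadata-only record: plain set substitution
            taxa: List[str] = []
            present = set(new_rec.meta.taxa)
            for taxon in new_rec.meta.taxa:
                rule = rules.get(taxon)
                if rule is None:
                    taxa.append(taxon)
                else:
                    taxa.extend(n for n in rule.new
                                if n not in present and n not in taxa)
            new_rec.meta.taxa = sorted(dict.fromkeys(taxa))
        out.records.append(new_rec)
    return out


def replace_taxon(ds: dsmod.Dataset, old: str,
                  new: Sequence[str] = ()) -> dsmod.Dataset:
    """Single-rule convenience wrapper: rename, polytomise or (with empty
    *new*) delete one taxon across the whole dataset."""
    present = any(rec.tree is not None and old in tr.leaf_set(rec.tree)
                  for rec in ds.records)
    if not present:
        warnings.warn(f"taxon {old!r} not present in any tree; "
                      "dataset unchanged", stacklevel=2)
    subs = SubstitutionFile(rules=[SubstitutionRule(old=old,
                                                    new=tuple(new))])
    return apply_substitutions(ds, subs)


def check_substitutions(ds: dsmod.Dataset, subs) -> List[Issue]:
    """Vet a substitution file against a dataset: report format problems
    and replacement taxa that would be newly introduced (not present in
    any tree of the dataset)."""
    issues: List[Issue] = []
    if not isinstance(subs, SubstitutionFile):
        try:
            subs = parse_substitution_file(subs)
        except SubstitutionError as exc:
            return [Issue("error", "format", str(exc))]
    pool = ds.taxon_union()
    for rule in subs.rules:
        for name in rule.new:
            if name not in pool:
                issues.append(Issue(
                    "warning", "introduces",
                    f"rule for {rule.old} introduces taxon {name} "
                    "not present anywhere in the dataset"))
        if not tr.is_valid_taxon_name(rule.old):
            issues.append(Issue("warning", "format",
                                f"non-canonical old name {rule.old!r}"))
    return issues


# ---------------------------------------------------------------------------
# higher-level standardisation

def replace_genera(ds: dsmod.Dataset
                   ) -> Tuple[dsmod.Dataset, SubstitutionFile]:
    """Convert genus-level terminals to species level as far as possible.

    For every single-word leaf label G, the replacement pool is every
    species ``G_*`` occurring anywhere in the dataset; genera with no
    congeneric species are left untouched.  Returns the converted dataset
    and the generated substitution file as the audit trail.
    """
    pool = ds.taxon_union()
    species_by_genus: Dict[str, List[str]] = {}
    for name in sorted(pool):
        if "_" in name:
            genus = name.split("_", 1)[0]
            species_by_genus.setdefault(genus, []).append(name)
    rules: List[SubstitutionRule] = []
    for name in sorted(pool):
        if "_" not in name and "%" not in name:
            species = species_by_genus.get(name, [])
            if species:
                rules.append(SubstitutionRule(old=name, new=tuple(species)))
    subs = SubstitutionFile(rules=rules)
    return apply_substitutions(ds, subs), subs


def standardise_names(ds: dsmod.Dataset,
                      synonyms: Optional[SubstitutionFile] = None,
                      collapse_subspecies: bool = False
                      ) -> Tuple[dsmod.Dataset, List[Tuple[str, Tuple[str, ...]]]]:
    """Standardise terminal names: optionally collapse trinomials
    (Genus_species_subsp -> Genus_species, duplicates merged by the graft
    duplicate rule) and apply a user synonym table dataset-wide.

    Subspecies collapse is opt-in because some studies deliberately use
    trinomials.  Returns the dataset and a change log of applied rules.
    """
    changes: List[Tuple[str, Tuple[str, ...]]] = []
    out = ds
    if collapse_subspecies:
        rules: List[SubstitutionRule] = []
        for name in sorted(out.taxon_union()):
            if "%" in name:
                continue
            parts = name.split("_")
            if len(parts) >= 3:
                rules.append(SubstitutionRule(
                    old=name, new=("_".join(parts[:2]),)))
        if rules:
            subs = SubstitutionFile(rules=rules)
            out = apply_substitutions(out, subs)
            changes.extend((r.old, r.new) for r in rules)
    if synonyms is not None and synonyms.rules:
        out = apply_substitutions(out, synonyms)
        changes.extend((r.old, r.new) for r in synonyms.rules)
    return out, changes


# ---------------------------------------------------------------------------
# paraphyly permutation

def permute_paraphyly(tree: SourceTree) -> List[SourceTree]:
    """Expand a tree with marked paraphyletic terminals (``Base%k``) into
    every placement choice.

    For each marked base name exactly one occurrence is kept (renamed to
    the bare base name) and the others are pruned; the output enumerates
    the cartesian product across base names, so its length is the product
    of the per-base occurrence counts.  A tree without markers returns a
    singleton list.
    """
    # leaf positions of each marked base, in leaf order
    positions: Dict[str, List[int]] = {}
    for idx, leaf in enumerate(tree.root.iter_leaves()):
        base = paraphyly_base(leaf.label or "")
        if base is not None:
            positions.setdefault(base, []).append(idx)
    if not positions:
        out = tree.copy()
        out.tree_name = "tree_1"
        return [out]

    bases = sorted(positions)
    results: List[SourceTree] = []
    for combo in itertools.product(*(positions[b] for b in bases)):
        chosen = dict(zip(bases, combo))

        counter = itertools.count()

        def _rebuild(node: Node) -> Optional[Node]:
            if node.is_leaf:
                idx = next(counter)
                base = paraphyly_base(node.label or "")
                if base is None:
                    return Node(label=node.label)
                if chosen[base] == idx:
                    return Node(label=base)
                return None
            children = [c for c in (_rebuild(ch) for ch in node.children)
                        if c is not None]
            if not children:
                return None
            if len(children) == 1:
                return children[0]
            return Node(children=children)

        new_root = _rebuild(tree.root)
        assert new_root is not None
        n = len(results) + 1
        results.append(SourceTree(id=f"{tree.id}_p{n}", root=new_root,
                                  tree_name=f"tree_{n}",
                                  rooted_flag=tree.rooted_flag))
    return results
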