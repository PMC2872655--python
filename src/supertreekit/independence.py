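"""Source-tree independence screening.

Two studies are treated as non-independent when they analysed the same
character data and one taxon set equals or nests inside the other; keeping
both would up-weight that evidence in the supertree.  This is an
operational, set-algebraic definition — it carries no statistical meaning
and cannot detect, say, two studies re-using the same underlying
sequences under different character names.

"Same character data" means equality of normalised character-name sets
(lowercased, whitespace-collapsed, alias-mapped, e.g. 'cytochrome b' and
'cytb' compare equal).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import networkx as nx

from . import dataset as dsmod
from . import trees as tr
from .metadata import normalize_character

__all__ = ["IndependenceGroup", "find_nonindependent", "apply_independence"]

logger = logging.getLogger(__name__)


@dataclass
class IndependenceGroup:
    member_ids: List[str]          # subset groups ordered superset-first
    relation: str                  # "identical" | "subset"
    recommended_keep: Optional[str]


def _signatures(ds: dsmod.Dataset
                ) -> List[Tuple[str, FrozenSet[str], FrozenSet[str]]]:
    out = []
    for rec in ds.records:
        if rec.meta is None or not rec.meta.characters:
            warnings.warn(
                f"record {rec.id!r} lacks character meta-data; skipped by "
                "the independence check", stacklevel=3)
            continue
        chars = frozenset(normalize_character(c.name)
                          for c in rec.meta.characters)
        taxa = frozenset(tr.leaf_set(rec.tree)) if rec.tree is not None \
            else frozenset(rec.meta.taxa)
        out.append((rec.id, chars, taxa))
    return out


def find_nonindependent(ds: dsmod.Dataset) -> List[IndependenceGroup]:
    """Pair two trees iff their character sets are equal and one taxon set
    equals or properly contains the other; merge pairs into maximal
    groups (connected components of the conflict graph).

    Identical-taxa groups get no recommended keep (a manual decision);
    subset groups recommend the unique largest taxon set when one exists.
    """
    sigs = _signatures(ds)
    conflicts = nx.Graph()
    for i, (id_a, chars_a, taxa_a) in enumerate(sigs):
        for id_b, chars_b, taxa_b in sigs[i + 1:]:
            if chars_a != chars_b:
                continue
            if taxa_a == taxa_b or taxa_a < taxa_b or taxa_b < taxa_a:
                conflicts.add_edge(id_a, id_b)
    taxa_of = {rec_id: taxa for rec_id, _, taxa in sigs}
    groups: List[IndependenceGroup] = []
    for comp in nx.connected_components(conflicts):
        members = sorted(comp, key=lambda i: (-len(taxa_of[i]), i))
        sizes = [len(taxa_of[m]) for m in members]
        sets = [taxa_of[m] for m in members]
        if all(s == sets[0] for s in sets[1:]):
            groups.append(IndependenceGroup(member_ids=members,
                                            relation="identical",
                                            recommended_keep=None))
        else:
            top = [m for m in members if len(taxa_of[m]) == sizes[0]]
            keep = top[0] if len(top) == 1 else None
            groups.append(IndependenceGroup(member_ids=members,
                                            relation="subset",
                                            recommended_keep=keep))
    groups.sort(key=lambda g: g.member_ids)
    return groups


def apply_independence(ds: dsmod.Dataset, groups: List[IndependenceGroup],
                       mode: str = "report") -> dsmod.Dataset:
    """Resolve non-independence.

    ``report`` mode returns the dataset unchanged.  ``auto`` mode drops
    the non-kept members of subset groups with a recommended keep;
    identical-taxa groups are never auto-resolved (no defensible
    tiebreak) and are re-flagged with a warning instead.  Every removal
    is logged.
    """
    if mode not in ("report", "auto"):
        raise ValueError(f"mode must be 'report' or 'auto', got {mode!r}")
    if mode == "report" or not groups:
        return ds.copy()
    drop: Set[str] = set()
    for group in groups:
        if group.relation == "subset" and group.recommended_keep is not None:
            for member in group.member_ids:
                if member != group.recommended_keep:
                    drop.add(member)
                    logger.info("independence: removing %r (taxa nested "
                                "inside %r, same characters)",
                                member, group.recommended_keep)
        elif group.relation == "identical":
            warnings.warn(
                "identical-taxa non-independence among "
                f"{group.member_ids}: not auto-resolved, manual choice "
                "required", stacklevel=2)
    out = ds.copy()
    out.records = [r for r in out.records if r.id not in drop]
    return out
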