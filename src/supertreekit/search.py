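"""Query a dataset by taxa or meta-data and materialise matching subsets.

Criteria combine with AND; OR queries are achieved by running twice and
merging output directories.  Matching is a brute-force linear scan, which
is ample at the scale of curated source-tree collections.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import List, Optional, Tuple

from . import dataset as dsmod
from . import metadata as md
from . import trees as tr

__all__ = ["SearchCriteria", "SearchError", "search_data", "copy_subset"]


class SearchError(ValueError):
    pass


@dataclass
class SearchCriteria:
    """AND-combined query fields; None fields are ignored."""
    taxon: Optional[str] = None
    charterm: Optional[str] = None
    chartype: Optional[str] = None
    analysis: Optional[str] = None
    year_range: Optional[Tuple[int, int]] = None
    author: Optional[str] = None

    def is_empty(self) -> bool:
        return all(v is None for v in (self.taxon, self.charterm,
                                       self.chartype, self.analysis,
                                       self.year_range, self.author))


def _matches(rec: dsmod.Record, q: SearchCriteria) -> bool:
    meta = rec.meta
    if q.taxon is not None:
        taxa = tr.leaf_set(rec.tree) if rec.tree is not None else \
            set(meta.taxa if meta else ())
        if q.taxon not in taxa:
            return False
    if q.charterm is not None:
        if meta is None or not md.character_matches(meta.characters,
                                                    q.charterm):
            return False
    if q.chartype is not None:
        if meta is None or q.chartype not in {c.ctype
                                              for c in meta.characters}:
            return False
    if q.analysis is not None:
        if meta is None or meta.analysis is None \
                or meta.analysis.lower() != q.analysis.lower():
            return False
    if q.year_range is not None:
        lo, hi = q.year_range
        if meta is None or meta.year is None or not lo <= meta.year <= hi:
            return False
    if q.author is not None:
        if meta is None or not any(q.author.lower() in a.lower()
                                   for a in meta.authors):
            return False
    return True


def search_data(ds: dsmod.Dataset, query: SearchCriteria) -> List[str]:
    """Ids of records matching every given criterion.  An empty query is
    refused (copy the whole dataset explicitly instead of matching
    everything by accident)."""
    if query.is_empty():
        raise SearchError("empty search criteria; to copy everything use "
                          "copy_subset with all ids")
    return [rec.id for rec in ds.records if _matches(rec, query)]


def copy_subset(ds: dsmod.Dataset, ids: List[str],
                out_dir) -> dsmod.Dataset:
    """Write dialect-normalised .tre/.xml pairs for the selected ids into
    *out_dir* and return the dataset loaded back from it.  Originals are
    untouched."""
    known = set(ds.ids())
    unknown = [i for i in ids if i not in known]
    if unknown:
        raise SearchError(f"unknown dataset ids: {unknown}")
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    for rec_id in ids:
        rec = ds.get(rec_id)
        if rec.tree is not None:
            tr.write_tree_file(rec.tree, os.path.join(out_dir,
                                                      f"{rec_id}.tre"))
        if rec.meta is not None:
            md.write_metadata(rec.meta, os.path.join(out_dir,
                                                     f"{rec_id}.xml"))
    return dsmod.load_dataset(out_dir)
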