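"""Datasets: paired tree + meta-data files, integrity checks and summaries.

A dataset is a directory tree holding ``<stem>.tre`` NEXUS tree files with
optional ``<stem>.xml`` meta-data partners.  Pairing is by identical file
stem; ids are stems and must be unique across the whole directory.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from . import metadata as md
from . import trees as tr

__all__ = [
    "Record",
    "Dataset",
    "CheckIssue",
    "CheckReport",
    "DatasetError",
    "load_dataset",
    "check_data",
    "data_summary",
    "write_dataset",
    "amalgamate_trees",
]


class DatasetError(ValueError):
    pass


@dataclass
class Record:
    id: str
    tree: Optional[tr.SourceTree]
    meta: Optional[md.SourceMetadata]
    tree_path: Optional[str] = None
    xml_path: Optional[str] = None
    load_error: Optional[str] = None

    def copy(self) -> "Record":
        return Record(id=self.id,
                      tree=self.tree.copy() if self.tree else None,
                      meta=self.meta.copy() if self.meta else None,
                      tree_path=self.tree_path, xml_path=self.xml_path,
                      load_error=self.load_error)


@dataclass
class Dataset:
    records: List[Record] = field(default_factory=list)
    root_dir: Optional[str] = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> List[str]:
        return [r.id for r in self.records]

    def get(self, rec_id: str) -> Record:
        for rec in self.records:
            if rec.id == rec_id:
                return rec
        raise KeyError(rec_id)

    def copy(self) -> "Dataset":
        return Dataset(records=[r.copy() for r in self.records],
                       root_dir=self.root_dir)

    def taxon_union(self) -> Set[str]:
        out: Set[str] = set()
        for rec in self.records:
            if rec.tree is not None:
                out |= tr.leaf_set(rec.tree)
        return out


@dataclass(frozen=True)
class CheckIssue:
    severity: str  # "error" | "warning"
    file: str
    message: str

    def __str__(self) -> str:
        return f"[{self.severity}] {self.file}: {self.message}"


@dataclass
class CheckReport:
    issues: List[CheckIssue]

    @property
    def passed(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def errors(self) -> List[CheckIssue]:
        return [i for i in self.issues if i.severity == "error"]

    def warnings(self) -> List[CheckIssue]:
        return [i for i in self.issues if i.severity == "warning"]


def load_dataset(root_dir) -> Dataset:
    """Recursively load every ``*.tre`` under *root_dir*, pairing each with
    its same-stem ``*.xml`` when present.  Parse failures do not abort the
    load: they are recorded on the record and surface in check_data."""
    root_dir = str(root_dir)
    if not os.path.isdir(root_dir):
        raise DatasetError(f"not a readable directory: {root_dir}")
    tre_paths: List[str] = []
    for dirpath, dirnames, filenames in os.walk(root_dir):
        dirnames.sort()
        for fname in sorted(filenames):
            if fname.endswith(".tre"):
                tre_paths.append(os.path.join(dirpath, fname))
    records: List[Record] = []
    seen: Dict[str, str] = {}
    for tre_path in tre_paths:
        stem = os.path.splitext(os.path.basename(tre_path))[0]
        if stem in seen:
            raise DatasetError(
                f"duplicate dataset id {stem!r}: {seen[stem]} and {tre_path}")
        seen[stem] = tre_path
        xml_path = os.path.splitext(tre_path)[0] + ".xml"
        rec = Record(id=stem, tree=None, meta=None, tree_path=tre_path,
                     xml_path=xml_path if os.path.exists(xml_path) else None)
        try:
            rec.tree = tr.read_tree_file(tre_path)
        except tr.TreeError as exc:
            rec.load_error = str(exc)
        if rec.xml_path:
            try:
                rec.meta = md.read_metadata(rec.xml_path)
            except md.MetadataError as exc:
                rec.load_error = ((rec.load_error + "; ") if rec.load_error
                                  else "") + str(exc)
        records.append(rec)
    return Dataset(records=records, root_dir=root_dir)


def _duplicate_leaves(tree: tr.SourceTree) -> List[str]:
    counts = Counter(tree.root.leaf_labels())
    return sorted(label for label, n in counts.items() if n > 1)


def check_data(ds: Dataset) -> CheckReport:
    """Three-way integrity check.

    1. Tree files: parse failures, duplicate leaf taxa, unrooted flags,
       degenerate (<2 leaf) trees.
    2. Meta-data: required-field validation per record.
    3. Cross-check: the XML taxa set must equal the tree's leaf set;
       discrepancies in either direction are errors.

    Missing XML partners are warnings (a tree-only dataset is usable for
    overlap and matrix steps but not for independence or search).
    """
    issues: List[CheckIssue] = []
    for rec in ds.records:
        fname = rec.tree_path or rec.id
        if rec.load_error:
            issues.append(CheckIssue("error", fname, rec.load_error))
        if rec.tree is not None:
            for label in _duplicate_leaves(rec.tree):
                issues.append(
                    CheckIssue("error", fname, f"Duplicate taxon: {label}"))
            if not rec.tree.rooted_flag:
                issues.append(CheckIssue(
                    "warning", fname,
                    "tree is marked unrooted; the protocol requires "
                    "rooted source trees"))
            if not rec.tree.is_valid:
                issues.append(CheckIssue(
                    "error", fname, "tree has fewer than 2 leaves"))
            for label in sorted(tr.leaf_set(rec.tree)):
                if not tr.is_valid_taxon_name(label):
                    issues.append(CheckIssue(
                        "warning", fname,
                        f"non-canonical taxon name {label!r}"))
        if rec.xml_path is None:
            issues.append(CheckIssue(
                "warning", fname, "no meta-data XML paired with this tree"))
        elif rec.meta is not None:
            for issue in md.validate_metadata(rec.meta):
                issues.append(CheckIssue(issue.severity, rec.xml_path,
                                         str(issue)))
            if rec.tree is not None:
                tree_taxa = tr.leaf_set(rec.tree)
                xml_taxa = set(rec.meta.taxa)
                for taxon in sorted(xml_taxa - tree_taxa):
                    issues.append(CheckIssue(
                        "error", rec.xml_path,
                        f"taxon {taxon} in XML but not in tree"))
                for taxon in sorted(tree_taxa - xml_taxa):
                    issues.append(CheckIssue(
                        "error", rec.xml_path,
                        f"taxon {taxon} in tree but not in XML"))
    return CheckReport(issues=issues)


def data_summary(ds: Dataset) -> dict:
    """Dataset statistics: tree count, distinct-taxon list and count,
    per-character-type source counts, publication-year range."""
    taxa = sorted(ds.taxon_union())
    type_counts: Counter = Counter()
    years: List[int] = []
    for rec in ds.records:
        if rec.meta is not None:
            for ctype in {c.ctype for c in rec.meta.characters}:
                type_counts[ctype] += 1
            if rec.meta.year is not None:
                years.append(rec.meta.year)
    return {
        "n_trees": sum(1 for r in ds.records if r.tree is not None),
        "taxa": taxa,
        "n_taxa": len(taxa),
        "character_type_counts": dict(type_counts),
        "year_range": (min(years), max(years)) if years else None,
    }


def write_dataset(ds: Dataset, out_dir) -> None:
    """Write every record's tree and meta-data as ``<id>.tre``/``<id>.xml``
    pairs in *out_dir* (dialect-normalised; flat layout)."""
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    for rec in ds.records:
        if rec.tree is not None:
            tr.write_tree_file(rec.tree, os.path.join(out_dir,
                                                      f"{rec.id}.tre"))
        if rec.meta is not None:
            md.write_metadata(rec.meta, os.path.join(out_dir,
                                                     f"{rec.id}.xml"))


def amalgamate_trees(ds: Dataset, out_path) -> None:
    """Write every tree in the dataset into one NEXUS file, renamed
    tree_1..tree_N in dataset order."""
    if not ds.records:
        raise DatasetError("cannot amalgamate an empty dataset")
    out_trees: List[tr.SourceTree] = []
    for i, rec in enumerate(ds.records, start=1):
        if rec.tree is None or not rec.tree.is_valid:
            raise DatasetError(
                f"cannot amalgamate: invalid or unreadable tree {rec.id!r}")
        t = rec.tree.copy()
        t.tree_name = f"tree_{i}"
        out_trees.append(t)
    tr.write_trees(out_trees, out_path)
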