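"""Per-tree XML meta-data records.

Each source tree is paired with an XML file recording where it came from
(authors, year, title, journal), which taxa it contains, which characters
the original study analysed and with what method.  These records drive the
independence check (same characters + nested taxa), the search facility and
the tree/XML cross-checks.

Schema of record::

    <SourceTree>
      <Source>
        <Author>..</Author>+ <Year>..</Year> <Title>..</Title>
        <Journal>..</Journal>? <Volume>..</Volume>? <Pages>..</Pages>?
      </Source>
      <Taxa> <Taxon name=".."/>+ </Taxa>
      <Characters> <Character type="molecular|morphological|behavioural|other"
                              name=".."/>+ </Characters>
      <Analysis type=".."/>?
      <TreeFile name=".."/>?
    </SourceTree>
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from lxml import etree

from .trees import is_valid_taxon_name

__all__ = [
    "CharacterRecord",
    "SourceMetadata",
    "Issue",
    "MetadataError",
    "CHARACTER_TYPES",
    "DEFAULT_ALIASES",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "normalize_character",
    "character_matches",
]

CHARACTER_TYPES = ("molecular", "morphological", "behavioural", "other")

# Built-in character-name aliases used by search and the independence
# check; keys and members are compared lowercase.  User tables extend this.
DEFAULT_ALIASES: Dict[str, Tuple[str, ...]] = {
    "cytb": ("cytb", "cytochrome b", "cyt b", "cyt-b"),
    "12s": ("12s", "12s rrna", "12s rdna"),
    "16s": ("16s", "16s rrna", "16s rdna"),
    "18s": ("18s", "18s rrna", "18s rdna"),
    "coi": ("coi", "co1", "cox1", "cytochrome oxidase i"),
    "rag1": ("rag1", "rag-1"),
    "morphology": ("morphology", "osteology", "anatomy"),
}


class MetadataError(ValueError):
    """Malformed or schema-violating meta-data file."""


@dataclass(frozen=True)
class CharacterRecord:
    ctype: str
    name: str


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    field: str
    message: str

    def __str__(self) -> str:
        return f"{self.severity}: {self.field}: {self.message}"


@dataclass
class SourceMetadata:
    authors: List[str]
    year: Optional[int]
    title: str
    taxa: List[str]
    characters: List[CharacterRecord]
    journal: Optional[str] = None
    volume: Optional[str] = None
    pages: Optional[str] = None
    analysis: Optional[str] = None
    tree_file: Optional[str] = None

    def copy(self) -> "SourceMetadata":
        return SourceMetadata(
            authors=list(self.authors), year=self.year, title=self.title,
            taxa=list(self.taxa), characters=list(self.characters),
            journal=self.journal, volume=self.volume, pages=self.pages,
            analysis=self.analysis, tree_file=self.tree_file)


_KNOWN_TAGS = {"Source", "Taxa", "Characters", "Analysis", "TreeFile"}
_KNOWN_SOURCE_TAGS = {"Author", "Year", "Title", "Journal", "Volume", "Pages"}


def read_metadata(path) -> SourceMetadata:
    """Parse one XML meta-data file.

    Unknown tags are ignored with a warning; a missing required section
    raises MetadataError naming it.
    """
    path = str(path)
    try:
        doc = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        raise MetadataError(f"{path}: malformed XML: {exc}") from None
    root = doc.getroot()
    if root.tag != "SourceTree":
        raise MetadataError(f"{path}: root element must be SourceTree, "
                            f"got {root.tag!r}")

    unknown = [el.tag for el in root if isinstance(el.tag, str)
               and el.tag not in _KNOWN_TAGS]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown tags: {unknown}",
                      stacklevel=2)

    source = root.find("Source")
    if source is None:
        raise MetadataError(f"{path}: missing required section: source")

    authors = [a.text.strip() for a in source.findall("Author")
               if a.text and a.text.strip()]
    year_el = source.find("Year")
    year: Optional[int] = None
    if year_el is not None and year_el.text and year_el.text.strip():
        try:
            year = int(year_el.text.strip())
        except ValueError:
            raise MetadataError(
                f"{path}: Year must be an integer, got {year_el.text!r}")

    def _opt(tag: str) -> Optional[str]:
        el = source.find(tag)
        return el.text.strip() if el is not None and el.text else None

    taxa_el = root.find("Taxa")
    if taxa_el is None:
        raise MetadataError(f"{path}: missing required section: taxa")
    taxa = [t.get("name", "").strip() for t in taxa_el.findall("Taxon")]
    taxa = [t for t in taxa if t]

    chars_el = root.find("Characters")
    if chars_el is None:
        raise MetadataError(f"{path}: missing required section: characters")
    characters = [CharacterRecord(ctype=c.get("type", "other"),
                                  name=(c.get("name") or "").strip())
                  for c in chars_el.findall("Character")]

    analysis_el = root.find("Analysis")
    tree_el = root.find("TreeFile")
    return SourceMetadata(
        authors=authors,
        year=year,
        title=_opt("Title") or "",
        journal=_opt("Journal"),
        volume=_opt("Volume"),
        pages=_opt("Pages"),
        taxa=taxa,
        characters=characters,
        analysis=analysis_el.get("type") if analysis_el is not None else None,
        tree_file=tree_el.get("name") if tree_el is not None else None,
    )


def write_metadata(meta: SourceMetadata, path) -> None:
    """Serialise a record; refuses records violating the required-field
    invariants so that write/read round-trips are total on valid records."""
    errors = [i for i in validate_metadata(meta) if i.severity == "error"]
    if errors:
        raise MetadataError(
            "refusing to write invalid meta-data: "
            + "; ".join(str(e) for e in errors))
    root = etree.Element("SourceTree")
    source = etree.SubElement(root, "Source")
    for author in meta.authors:
        etree.SubElement(source, "Author").text = author
    etree.SubElement(source, "Year").text = str(meta.year)
    etree.SubElement(source, "Title").text = meta.title
    for tag, value in (("Journal", meta.journal), ("Volume", meta.volume),
                       ("Pages", meta.pages)):
        if value is not None:
            etree.SubElement(source, tag).text = value
    taxa_el = etree.SubElement(root, "Taxa")
    for taxon in meta.taxa:
        etree.SubElement(taxa_el, "Taxon", name=taxon)
    chars_el = etree.SubElement(root, "Characters")
    for char in meta.characters:
        etree.SubElement(chars_el, "Character", type=char.ctype,
                         name=char.name)
    if meta.analysis is not None:
        etree.SubElement(root, "Analysis", type=meta.analysis)
    if meta.tree_file is not None:
        etree.SubElement(root, "TreeFile", name=meta.tree_file)
    etree.ElementTree(root).write(str(path), encoding="utf-8",
                                  xml_declaration=True, pretty_print=True)


def validate_metadata(meta: SourceMetadata) -> List[Issue]:
    """Pure validation: empty list iff the minimal-information invariants
    hold.  Required fields missing -> errors; optional fields absent and
    name-format problems -> warnings."""
    issues: List[Issue] = []
    if not meta.authors:
        issues.append(Issue("error", "authors", "no authors listed"))
    if meta.year is None:
        issues.append(Issue("error", "year", "publication year missing"))
    if not meta.title:
        issues.append(Issue("error", "title", "title missing"))
    if not meta.taxa:
        issues.append(Issue("error", "taxa", "taxa list empty"))
    if not meta.characters:
        issues.append(Issue("error", "characters",
                            "no characters recorded for the study"))
    for char in meta.characters:
        if char.ctype not in CHARACTER_TYPES:
            issues.append(Issue("error", "characters",
                                f"unknown character type {char.ctype!r}"))
        if not char.name:
            issues.append(Issue("error", "characters",
                                "character with empty name"))
    for taxon in meta.taxa:
        if not is_valid_taxon_name(taxon):
            issues.append(Issue("warning", "taxon-name format",
                                f"non-canonical taxon name {taxon!r}"))
    for fname, value in (("journal", meta.journal),
                         ("analysis", meta.analysis)):
        if value is None:
            issues.append(Issue("warning", fname, f"{fname} not recorded"))
    return issues


def _alias_map(extra: Optional[Dict[str, Tuple[str, ...]]] = None
               ) -> Dict[str, str]:
    """member (lowercase) -> canonical key, merging user aliases over the
    built-in table."""
    table = dict(DEFAULT_ALIASES)
    if extra:
        for key, members in extra.items():
            table[key.lower()] = tuple(m.lower() for m in members)
    out: Dict[str, str] = {}
    for key, members in table.items():
        out[key.lower()] = key.lower()
        for member in members:
            out[member.lower()] = key.lower()
    return out


def normalize_character(name: str,
                        aliases: Optional[Dict[str, Tuple[str, ...]]] = None
                        ) -> str:
    """Canonical form of a character name for set comparison: lowercase,
    collapsed whitespace, alias members mapped to their canonical key."""
    norm = " ".join(name.lower().split())
    return _alias_map(aliases).get(norm, norm)


def character_matches(characters: List[CharacterRecord], term: str,
                      aliases: Optional[Dict[str, Tuple[str, ...]]] = None
                      ) -> bool:
    """Case-insensitive substring match with alias expansion: 'cytb'
    matches a character named 'cytochrome b' and vice versa."""
    amap = _alias_map(aliases)
    term_norm = " ".join(term.lower().split())
    term_keys = {term_norm, amap.get(term_norm, term_norm)}
    for char in characters:
        cname = " ".join(char.name.lower().split())
        ckey = amap.get(cname, cname)
        if ckey in term_keys:
            return True
        if any(t in cname or cname in t for t in term_keys if t):
            return True
    return False
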