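# Methods

This note records the procedures the toolkit implements, the choices
made where the design was genuinely open, and what the synthetic data
does and does not demonstrate.

## Data model

A dataset is a directory of paired files: `<id>.tre` (a NEXUS TREES
block or bare Newick holding one rooted, possibly polytomous tree) and
`<id>.xml` (bibliography, taxa list, characters, analysis method).
Pairing is by identical file stem, searched recursively; ids must be
unique across the directory.

Everything downstream of parsing is purely topological, so branch
lengths and support values are discarded at parse time and never
round-trip.  Labels are normalised once at parse time — surrounding
quotes stripped, internal whitespace converted to underscores — so all
later taxon comparisons are plain string equality.  Canonical names are
`Genus` or `Genus_species` (first character uppercase); the paraphyly
marker is a `%k` suffix with a positive integer `k`, chosen because `%`
is illegal in canonical names and therefore unambiguous.  This marker
syntax is this package's own convention.

Files carrying an explicit unrooted marker (`[&U]`) are read and
flagged rather than rejected; `check_data` downgrades this to a warning
because the curation protocol requires rooted inputs but the fix (a
rooting decision) is the curator's, not the parser's.  Similarly a
duplicated leaf label parses fine and is reported by `check_data` as
`Duplicate taxon: <name>` — detection is a check, not a parse failure,
so the curator sees the file named rather than a stack trace.  Files
with several trees use the first and warn, matching the one-tree-per-
file pairing convention.

The standard output dialect is deliberately minimal: `#NEXUS`, one
TREES block, no translate table, one `TREE name = [&R] <newick>;` line,
unquoted underscore labels.  Any accepted input dialect (translate
tables, quoted labels, drawing-program output) re-serialises into this
form, which makes writes byte-deterministic and diffs meaningful.
Parsing is delegated to dendropy; writing is done directly so the
dialect is fixed.

## Substitution semantics

A substitution file holds one rule per line, `old = new1, new2, ...`;
an empty right side deletes, one name renames, several names graft a
polytomy where the old leaf stood.  Two properties are guaranteed:

* **Simultaneity.** All rules are interpreted against the
  pre-substitution state: leaves without a rule keep their labels, and
  rule-bearing leaves are rewritten in one pass.  Rule order therefore
  cannot chain (`A = B` followed by `B = C` never turns A into C), and
  a rule pair `A = B`, `B = A` swaps the two labels without
  oscillating.
* **Duplicate avoidance.** A replacement name colliding with a label
  that survives elsewhere in the same tree (or already placed by an
  earlier rule in the same pass) is dropped from the graft list, so a
  substitution can never create the duplicate leaves `check_data`
  treats as errors.  If the whole graft list empties this way, the old
  leaf is simply pruned.

Pruning always suppresses unifurcations, including at the root.  A tree
reduced below two leaves is flagged invalid and reported; the caller
(or the pipeline) decides to drop it.  After any substitution the XML
taxa lists are rewritten to equal the new leaf sets, which keeps the
cross-check green by construction.

Genus expansion (`replace_genera`) replaces a single-word terminal `G`
with a polytomy of every `G_*` species found anywhere in the dataset's
leaf-set union — the whole dataset, not just the host tree, because a
genus terminal stands for whatever congeners the combined analysis will
contain.  Genera with no congeneric species are left untouched.
Subspecies collapse (`Genus_species_subsp` → `Genus_species`) is
opt-in, since some studies deliberately analyse trinomials; duplicates
created by collapse merge through the graft rule above.

Paraphyly permutation keeps exactly one occurrence per marked base name
(renamed to the base) and prunes the rest, enumerating the cartesian
product across base names; the output count is always the product of
per-base occurrence counts.

## Independence

Two trees conflict when their normalised character-name sets are equal
*and* their taxon sets are identical or properly nested.  Character
names are lowercased, whitespace-collapsed and mapped through a small
extensible alias table (`cytb` ≡ `cytochrome b`, `12S` ≡ `12S rRNA`,
…), so the comparison is by evidence, not spelling.  Set equality —
rather than mere overlap — was chosen deliberately: partially
overlapping character sets are partially independent evidence, and
dropping either tree would discard data.  This definition is purely
set-algebraic and has no statistical force; it cannot detect two
studies re-using the same sequences under different names.

Conflicting pairs are merged into maximal groups.  Nested groups
recommend keeping the unique largest taxon set; identical-taxa groups
are never auto-resolved because no defensible tiebreak exists (keeping
the newer study, say, would silently bias the dataset), so they are
flagged for a manual decision even in `auto` mode.

## Overlap

The overlap graph has one node per tree and an edge wherever two trees
share at least `n` taxa (`n` ≥ 2, default 2, the minimum for two rooted
trees to constrain each other; edge weight = shared count).  "Adequate
overlap" is formalised as connectivity of the whole graph: a component
disconnected from the rest can never be placed relative to it, whatever
the supertree method.  The verdict lists components largest-first and
recommends excluding everything outside the largest; when several
components tie for largest no recommendation is made and the tie is
flagged.  Raising `n` only removes edges, so the component count is
non-decreasing in `n` — a property the tests assert.  The graph
exports as plain DOT for external layout.

## MRP coding

Baum–Ragan component coding: every internal non-root node of every
tree contributes one column — members 1, other taxa of that tree 0,
taxa absent from that tree `?`.  The root clade and single-leaf clades
are omitted as uninformative, so a tree with *m* internal nodes
contributes *m* − 1 columns.  Column order is dataset order, clades in
deterministic preorder, making output reproducible; reordering the
dataset permutes columns but never changes a cell for a given
(taxon, source-clade) pair.  An all-zero `MRP_Outgroup` row is included
by default (standard practice for rooting the parsimony analysis) and
can be disabled.  Character weighting and other coding variants
(Purvis, irreversible) are out of scope — parsed trees carry no
supports to weight by.

`tree_from_clades` inverts the coding for a compatible clade set by
containment nesting; on the matrix of a single tree it recovers that
tree exactly, which is the main correctness check on the coder
(100/100 random trees in the acceptance run).

## Synthetic data

The generator emulates the *structural* properties the toolkit cares
about, not biology: random binary topologies by sequential uniform edge
attachment (not a birth–death model), binomial names from a synthetic
pool, per-tree leaf counts uniform in a range (default 5–10 from a pool
of 40 across 10 trees), and overlap structure imposed by making each
tree share at least 2 taxa with an earlier tree of its component, with
disjoint sub-pools across components.  Meta-data fields are drawn from
small fixed vocabularies.  Output is byte-deterministic for a given
settings+seed pair.

Defects are seeded exactly once each into distinct trees and recorded
in `manifest.json` as the exact (severity, file, message) triple the
checker must report, so tests can assert detection with no slack.  The
threshold-behaviour fixture consists of 18 trees sharing a four-taxon
backbone, one satellite sharing exactly two backbone taxa, and one
isolated tree sharing at most one — hence exactly one exclusion at
n = 2, exactly two at n = 4, and strictly fewer edges at n = 4.

Because the generator's trees are clean by construction, passing tests
demonstrate correct mechanics (parsing, checking, coding, graph logic),
not robustness to the full messiness of literature data — hand-encoded
trees with inconsistent spellings, vernacular names or mixed taxonomic
levels still need the curator's eye; the toolkit's role is to make
every such decision explicit, checked and repeatable.

## Problem sizes and numerical choices

The acceptance run uses 200 random datasets (3–7 trees each) for the
overlap oracle, 100 random trees (4–18 leaves) for coding inversion and
500 trees (3–12 leaves, three input dialects) for round-trip identity —
sizes at which the brute-force oracles are still exact and instant
while exercising all code paths.  All randomness flows from a single
seed argument.  There are no floating-point computations anywhere in
the toolkit; every comparison is exact set or string equality, so no
tolerances are needed.  Ties are broken deterministically throughout
(alphabetical taxa order in matrices and XML, dataset order for
columns, sorted component listings).

## Known limitations

* One tree per file and 1:1 tree/XML pairing are enforced; datasets
  with one XML describing several trees must be split first.
* Synonym resolution is table-driven only; there is no lookup against
  external taxonomies.
* The independence check is only as good as the recorded character
  names plus the alias table.
* `search` composes criteria with AND only; run it twice and merge
  directories for OR.
* The pipeline works on a flat copy of the dataset (sub-directory
  structure is not preserved in the working copy).
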