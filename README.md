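# supertreekit

Tools for assembling and curating the *input* side of a supertree
analysis: collections of published source phylogenies and their
meta-data, cleaned and encoded into a parsimony-ready matrix.

Supertrees estimate a large phylogeny by combining many smaller,
partially overlapping source trees.  At the scale of modern studies
(hundreds of source trees, thousands of terminal taxa) the limiting
factor is rarely the tree search — it is keeping the input data
consistent: taxon names standardised across studies, redundant trees
removed, sufficient taxonomic overlap verified, and the final matrix
encoded without transcription errors.  `supertreekit` is a Python
library plus a command line (`stk`) that carries a dataset through that
curation protocol:

1. **Data entry** — each source tree is a NEXUS tree file (`<id>.tre`)
   paired by file stem with an XML meta-data record (`<id>.xml`) holding
   bibliographic details, the taxa list, the characters analysed and the
   inference method.
2. **Taxon standardisation** — substitution files in the
   `old = new1, new2` grammar rename, delete or polytomise terminals
   dataset-wide; genus-level terminals can be expanded to the species
   observed elsewhere in the dataset; trinomials collapsed; paraphyletic
   terminals (marked `Name%1`, `Name%2`, …) expanded into all placement
   permutations.
3. **Independence** — two trees built from the same character data whose
   taxon sets are identical or nested would up-weight that evidence; the
   toolkit finds such groups and can drop the nested member.
4. **Taxonomic overlap** — builds the graph with one node per source
   tree and an edge whenever two trees share ≥ *n* taxa (*n* = 2 is the
   minimum for combinability); the dataset is usable when the graph is
   connected, and disconnected trees are listed for exclusion.  The
   graph exports to DOT for visualisation.
5. **Matrix creation** — Baum–Ragan matrix representation with parsimony
   (MRP): every informative clade *C* of every source tree *T* becomes a
   binary character with state 1 for taxa in *C*, 0 for taxa of *T*
   outside *C*, and `?` for taxa absent from *T*, plus an all-zero
   hypothetical outgroup row for rooting.  Output is a NEXUS `DATA`
   block (PAUP\*) or a TNT `xread`.

Integrity checks (`check_data`) run between every step: valid tree
files, no duplicate leaves, required meta-data present, and XML taxa
lists identical to tree leaf sets.

A deterministic synthetic-data generator (`supertreekit.fixtures`)
builds datasets with controlled overlap structure and precisely seeded
defects, so the whole toolkit is testable without downloading anything.

## Worked example

Generate a small synthetic dataset and run it through the main steps:

```sh
$ python -c "from supertreekit import fixtures as fx; \
    fx.generate_dataset(fx.GeneratorSettings(n_trees=5, taxon_pool_size=30), \
                        seed=4, out_dir='data')"
$ stk summary --dir data
Trees: 5
Distinct taxa: 21
  Ga_s1
  Ga_s2
  ...
Sources with molecular characters: 4
Sources with morphological characters: 1
Years: 1985-1999

$ stk check-data --dir data
OK: 5 records, no errors (0 warnings)

$ stk check-overlap --dir data --graphic overlap.dot
overlap OK at n=2: one connected component of 5 trees

$ stk create-matrix --dir data --out matrix.nex
wrote 22 taxa x 22 characters to matrix.nex
```

The summary counts the union of all leaf sets (21 taxa over 5 trees);
the overlap check reports that every tree shares at least two taxa with
some chain of other trees, so the collection can be combined; the matrix
has one row per taxon plus the `MRP_Outgroup` row (hence 22) and one
column per informative clade across all five trees:

```
#NEXUS
BEGIN DATA;
	DIMENSIONS NTAX=22 NCHAR=22;
	FORMAT MISSING=? SYMBOLS="01";
	MATRIX
	MRP_Outgroup  0000000000000000000000
	Ga_s1         ??????????11101111????
	...
```

`?` marks taxa absent from the column's source tree.  The same steps are
available as library calls (`load_dataset`, `check_data`,
`check_overlap`, `create_matrix`, …), and `stk pipeline --config
pipeline.yaml --dir data --out results` chains them on a working copy,
re-checking integrity between stages.

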