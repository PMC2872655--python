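import random

import pytest

from supertreekit import dataset as dsmod
from supertreekit import metadata as md
from supertreekit import trees as tr
from supertreekit.fixtures import random_topology


def make_meta(taxa, characters=(("molecular", "cytb"),), year=2001,
              authors=("Smith, A.",), analysis="parsimony"):
    return md.SourceMetadata(
        authors=list(authors), year=year, title="A study",
        journal="J. Test", taxa=sorted(taxa),
        characters=[md.CharacterRecord(ctype=t, name=n)
                    for t, n in characters],
        analysis=analysis)


def make_dataset(newicks, metas=None):
    """In-memory dataset from {id: newick}; metadata auto-filled to match
    leaf sets unless overridden via metas={id: SourceMetadata}."""
    records = []
    for rec_id, nwk in newicks.items():
        tree = tr.tree_from_newick(nwk, tree_id=rec_id)
        meta = (metas or {}).get(rec_id)
        if meta is None:
            meta = make_meta(tr.leaf_set(tree))
        records.append(dsmod.Record(id=rec_id, tree=tree, meta=meta,
                                    tree_path=f"{rec_id}.tre",
                                    xml_path=f"{rec_id}.xml"))
    return dsmod.Dataset(records=records)


@pytest.fixture
def rng():
    return random.Random(20260919)


@pytest.fixture
def random_source_tree(rng):
    def _make(n_leaves=None, prefix="T"):
        n = n_leaves or rng.randint(4, 12)
        labels = [f"{prefix}{i}" for i in range(n)]
        rng.shuffle(labels)
        return tr.SourceTree(id="rand", root=random_topology(labels, rng))
    return _make
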