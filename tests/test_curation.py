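"""Substitution files, simultaneous substitution semantics, genus
expansion, name standardisation and paraphyly permutation."""

import itertools
import random

import pytest

from supertreekit import curation as cu
from supertreekit import dataset as dsmod
from supertreekit import trees as tr
from supertreekit.fixtures import random_topology

from conftest import make_dataset

WORKED_EXAMPLE = """taxon_1 = taxon_2
taxon_3 = taxon_4, taxon_5, taxon_6
taxon_7 =
"""


class TestParseSubstitutionFile:
    def test_worked_example(self):
        subs = cu.parse_substitution_text(WORKED_EXAMPLE)
        assert [(r.old, list(r.new)) for r in subs] == [
            ("taxon_1", ["taxon_2"]),
            ("taxon_3", ["taxon_4", "taxon_5", "taxon_6"]),
            ("taxon_7", []),
        ]

    def test_spaces_become_underscores(self):
        subs = cu.parse_substitution_text(
            "Gallus gallus = Gallus sonneratii\n")
        assert subs.rules[0].old == "Gallus_gallus"
        assert subs.rules[0].new == ("Gallus_sonneratii",)

    def test_self_substitution_rejected(self):
        with pytest.raises(cu.SubstitutionError, match="old name"):
            cu.parse_substitution_text("A = A\n")

    def test_missing_equals_names_line(self):
        with pytest.raises(cu.SubstitutionError, match=":1:"):
            cu.parse_substitution_text("A taxon_2\n")

    def test_duplicate_old_rejected(self):
        with pytest.raises(cu.SubstitutionError, match="multiple rules"):
            cu.parse_substitution_text("A = B\nA = C\n")

    def test_file_round_trip(self, tmp_path):
        subs = cu.parse_substitution_text(WORKED_EXAMPLE)
        path = tmp_path / "subs.txt"
        cu.write_substitution_file(subs, path)
        assert cu.parse_substitution_file(path).rules == subs.rules


class TestApplySubstitutions:
    def test_worked_example_on_tree(self):
        ds = make_dataset({"a": "((taxon_1,taxon_3),taxon_7);"})
        subs = cu.parse_substitution_text(WORKED_EXAMPLE)
        out = cu.apply_substitutions(ds, subs)
        expected = tr.tree_from_newick(
            "(taxon_2,(taxon_4,taxon_5,taxon_6));")
        assert tr.same_topology(out.records[0].tree, expected)
        assert out.records[0].meta.taxa == sorted(
            tr.leaf_set(out.records[0].tree))

    def test_simultaneous_swap_no_chaining(self):
        ds = make_dataset({"a": "(A,B,C);"})
        subs = cu.parse_substitution_text("A = B\nB = A\n")
        out = cu.apply_substitutions(ds, subs)
        assert tr.leaf_set(out.records[0].tree) == {"A", "B", "C"}

    def test_absent_old_is_silent_noop(self):
        ds = make_dataset({"a": "((A,B),C);"})
        out = cu.apply_substitutions(
            ds, cu.parse_substitution_text("Zz_gone =\n"))
        assert tr.same_topology(out.records[0].tree, ds.records[0].tree)

    def test_tree_reduced_below_two_leaves_flagged(self):
        ds = make_dataset({"a": "((A,B),C);"})
        with pytest.warns(UserWarning, match="below 2 leaves"):
            out = cu.apply_substitutions(
                ds, cu.parse_substitution_text("A =\nB =\n"))
        assert not out.records[0].tree.is_valid

    def test_deletion_idempotent(self):
        ds = make_dataset({"a": "((A,B),(C,D));"})
        subs = cu.parse_substitution_text("A =\nC =\n")
        once = cu.apply_substitutions(ds, subs)
        twice = cu.apply_substitutions(once, subs)
        assert tr.same_topology(once.records[0].tree,
                                twice.records[0].tree)

    def test_global_taxon_set_oracle(self, rng):
        """After substitution the dataset taxon set equals the brute-force
        prediction (olds removed, fired news added modulo collisions)."""
        for _ in range(20):
            pool = [f"T{i}" for i in range(14)]
            newicks = {}
            for k in range(3):
                labels = rng.sample(pool, rng.randint(4, 8))
                newicks[f"t{k}"] = (
                    tr.newick_string(random_topology(labels, rng)) + ";")
            ds = make_dataset(newicks)
            olds = rng.sample(pool, 3)
            news = [tuple(rng.sample([f"N{i}" for i in range(5)],
                                     rng.randint(0, 2))) for _ in olds]
            subs = cu.SubstitutionFile(rules=[
                cu.SubstitutionRule(old=o, new=n)
                for o, n in zip(olds, news)])
            out = cu.apply_substitutions(ds, subs)
            expected = set()
            for rec in ds.records:
                leaves = tr.leaf_set(rec.tree)
                expected |= leaves - set(olds)
                for o, n in zip(olds, news):
                    if o in leaves:
                        expected |= set(n)
            assert out.taxon_union() == expected

    def test_crosscheck_green_after_substitution(self):
        ds = make_dataset({"a": "((Aus_a,Bus_b),Cus_c);",
                           "b": "((Bus_b,Cus_c),Dus_d);"})
        subs = cu.parse_substitution_text("Aus_a = Eus_e, Fus_f\nBus_b =\n")
        out = cu.apply_substitutions(ds, subs)
        assert dsmod.check_data(out).passed


class TestReplaceTaxon:
    def test_delete_everywhere(self):
        ds = make_dataset({
            "a": "((Xiphocolaptes_promeropirhynchus,Aus_a),Bus_b);",
            "b": "((Aus_a,Bus_b),Xiphocolaptes_promeropirhynchus);"})
        out = cu.replace_taxon(ds, "Xiphocolaptes_promeropirhynchus")
        assert "Xiphocolaptes_promeropirhynchus" not in out.taxon_union()
        assert all("Xiphocolaptes_promeropirhynchus" not in r.meta.taxa
                   for r in out.records)

    def test_misspelling_fix(self):
        ds = make_dataset({"a": "((Gallus_sonnerati,Aus_a),Bus_b);"})
        out = cu.replace_taxon(ds, "Gallus_sonnerati",
                               ["Gallus_sonneratii"])
        assert tr.leaf_set(out.records[0].tree) == {
            "Gallus_sonneratii", "Aus_a", "Bus_b"}

    def test_absent_taxon_warns(self):
        ds = make_dataset({"a": "((A,B),C);"})
        with pytest.warns(UserWarning, match="not present"):
            out = cu.replace_taxon(ds, "Zz_gone", ["Yy_new"])
        assert out.taxon_union() == {"A", "B", "C"}


class TestCheckSubstitutions:
    def test_replacement_present_elsewhere_ok(self):
        ds = make_dataset({"a": "((A,B),C);", "b": "((C,D),E);"})
        subs = cu.parse_substitution_text("A = D\n")
        assert cu.check_substitutions(ds, subs) == []

    def test_novel_replacement_flagged(self):
        ds = make_dataset({"a": "((A,B),C);"})
        subs = cu.parse_substitution_text("A = Zz_novel\n")
        issues = cu.check_substitutions(ds, subs)
        assert any("Zz_novel" in i.message and i.severity == "warning"
                   for i in issues)

    def test_malformed_file_reported(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("A taxon_2\n")
        ds = make_dataset({"a": "((A,B),C);"})
        issues = cu.check_substitutions(ds, path)
        assert issues[0].severity == "error"


class TestReplaceGenera:
    def test_genus_expanded_to_species_polytomy(self):
        ds = make_dataset({
            "a": "((Gallus,Crax_rubra),Rhea_americana);",
            "b": "((Gallus_gallus,Gallus_sonneratii),Crax_rubra);"})
        out, subs = cu.replace_genera(ds)
        assert subs.by_old()["Gallus"].new == ("Gallus_gallus",
                                               "Gallus_sonneratii")
        expected = tr.tree_from_newick(
            "(((Gallus_gallus,Gallus_sonneratii),Crax_rubra),"
            "Rhea_americana);")
        assert tr.same_topology(out.records[0].tree, expected)

    def test_genus_without_species_untouched(self):
        ds = make_dataset({"a": "((Rhea,Crax_rubra),Aus_bus);"})
        out, subs = cu.replace_genera(ds)
        assert len(subs) == 0
        assert "Rhea" in out.taxon_union()

    def test_species_already_in_same_tree_prunes_genus(self):
        ds = make_dataset({"a": "((Gallus,Gallus_gallus),Crax_rubra);"})
        out, _ = cu.replace_genera(ds)
        got = out.records[0].tree
        assert sorted(got.root.leaf_labels()) == ["Crax_rubra",
                                                  "Gallus_gallus"]


class TestStandardiseNames:
    def test_trinomial_collapse(self):
        ds = make_dataset({"a": "((Corvus_corone_cornix,Aus_a),Bus_b);"})
        out, changes = cu.standardise_names(ds, collapse_subspecies=True)
        assert "Corvus_corone" in out.taxon_union()
        assert "Corvus_corone_cornix" not in out.taxon_union()
        assert ("Corvus_corone_cornix", ("Corvus_corone",)) in changes

    def test_collapse_merges_with_existing_binomial(self):
        ds = make_dataset({
            "a": "((Corvus_corone,Corvus_corone_cornix),Aus_a);"})
        out, _ = cu.standardise_names(ds, collapse_subspecies=True)
        got = out.records[0].tree
        assert sorted(got.root.leaf_labels()) == ["Aus_a", "Corvus_corone"]

    def test_collapse_is_opt_in(self):
        ds = make_dataset({"a": "((Corvus_corone_cornix,Aus_a),Bus_b);"})
        out, changes = cu.standardise_names(ds)
        assert changes == []
        assert "Corvus_corone_cornix" in out.taxon_union()

    def test_synonym_table_applied_dataset_wide(self):
        ds = make_dataset({"a": "((Corvus_corone,Aus_a),Bus_b);",
                           "b": "((Corvus_corone,Bus_b),Cus_c);"})
        syn = cu.parse_substitution_text("Corvus_corone = Corvus_cornix\n")
        out, _ = cu.standardise_names(ds, synonyms=syn)
        assert "Corvus_corone" not in out.taxon_union()
        assert "Corvus_cornix" in out.taxon_union()


class TestPermuteParaphyly:
    def test_two_position_example(self):
        t = tr.tree_from_newick("((A%1,B),(A%2,C));")
        perms = cu.permute_paraphyly(t)
        got = {frozenset(tr.clade_sets(p)) for p in perms}
        expected = {
            frozenset(tr.clade_sets(tr.tree_from_newick("((A,B),C);"))),
            frozenset(tr.clade_sets(tr.tree_from_newick("(B,(A,C));"))),
        }
        assert len(perms) == 2 and got == expected

    def test_product_rule_three_by_two(self):
        t = tr.tree_from_newick(
            "(((A%1,B),(A%2,C)),((A%3,D),(E%1,(E%2,F))));")
        perms = cu.permute_paraphyly(t)
        assert len(perms) == 6
        for p in perms:
            assert tr.leaf_set(p) == {"A", "B", "C", "D", "E", "F"}
            labels = p.root.leaf_labels()
            assert len(labels) == len(set(labels))

    def test_unmarked_tree_is_identity(self):
        t = tr.tree_from_newick("((A,B),C);")
        perms = cu.permute_paraphyly(t)
        assert len(perms) == 1
        assert tr.same_topology(perms[0], t)

    def test_single_occurrence_marker_is_factor_one(self):
        t = tr.tree_from_newick("((A%1,B),C);")
        perms = cu.permute_paraphyly(t)
        assert len(perms) == 1
        assert tr.leaf_set(perms[0]) == {"A", "B", "C"}

    def test_count_matches_enumeration_oracle(self, rng):
        """Output count equals the product of per-base occurrence counts
        on randomly marked trees, and every output leaf set is right."""
        for _ in range(15):
            n = rng.randint(6, 12)
            labels = [f"T{i}" for i in range(n)]
            bases = rng.sample(["P", "Q"], rng.randint(1, 2))
            counts = {}
            for base in bases:
                counts[base] = rng.randint(1, 3)
                for k in range(1, counts[base] + 1):
                    labels.append(f"{base}%{k}")
            rng.shuffle(labels)
            t = tr.SourceTree(id="m", root=random_topology(labels, rng))
            perms = cu.permute_paraphyly(t)
            expected_n = 1
            for c in counts.values():
                expected_n *= c
            assert len(perms) == expected_n
            unmarked = {l for l in labels if "%" not in l}
            for p in perms:
                assert tr.leaf_set(p) == unmarked | set(bases)
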