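"""Per-protein age assignment, domain strategies, and the age database file."""

import io

import numpy as np
import pytest

from phylostrat import (
    CostScheme,
    ProteinList,
    assign_protein_ages,
    dollo_reconstruct,
    domain_based_ages,
    lookup_ages,
    read_age_database,
    wagner_reconstruct,
)
from phylostrat.age_assignment import NO_FAMILY
from phylostrat.errors import ArgumentError, PhylostratError
from phylostrat.family_db import FamilyTable
from phylostrat.fixtures import simulate_families, simulate_tree


def make_fams(*members):
    t = FamilyTable()
    for fam, sp, pid in members:
        t.add(fam, sp, pid)
    return t


class TestAssign:
    def test_dollo_origin_and_age(self, four_leaf_tree):
        fams = make_fams(("F1", "A", "p1"), ("F1", "B", "p2"))
        lab = dollo_reconstruct({"A": 1, "B": 1, "C": 0, "D": 0}, four_leaf_tree, "F1")
        db = assign_protein_ages({"F1": lab}, fams, four_leaf_tree, "A", "dollo")
        assert db.ages["p1"].origin_taxon == "AB"
        assert db.ages["p1"].age_mya == 100

    def test_wagner_two_gain_family_gets_leaf_origin(self, four_leaf_tree):
        fams = make_fams(("F1", "A", "p1"), ("F1", "D", "p4"))
        row = {"A": 1, "B": 0, "C": 0, "D": 1}
        lab = wagner_reconstruct(row, four_leaf_tree, family="F1")
        db_a = assign_protein_ages({"F1": lab}, fams, four_leaf_tree, "A", "wagner")
        assert db_a.ages["p1"].origin_taxon == "A"
        assert db_a.ages["p1"].age_mya == 0
        db_d = assign_protein_ages({"F1": lab}, fams, four_leaf_tree, "D", "wagner")
        assert db_d.ages["p4"].origin_taxon == "D"

    def test_singleton_family_age_zero(self, four_leaf_tree):
        fams = make_fams(("F1", "A", "p1"))
        lab = dollo_reconstruct({"A": 1, "B": 0, "C": 0, "D": 0}, four_leaf_tree, "F1")
        db = assign_protein_ages({"F1": lab}, fams, four_leaf_tree, "A", "dollo")
        assert db.ages["p1"].origin_taxon == "A"
        assert db.ages["p1"].age_mya == 0

    def test_proteome_fills_no_family_records(self, four_leaf_tree):
        fams = make_fams(("F1", "A", "p1"))
        lab = dollo_reconstruct({"A": 1, "B": 0, "C": 0, "D": 0}, four_leaf_tree, "F1")
        db = assign_protein_ages(
            {"F1": lab}, fams, four_leaf_tree, "A", "dollo", proteome=["p1", "orphan"]
        )
        rec = db.ages["orphan"]
        assert rec.family == NO_FAMILY and rec.no_family
        assert rec.origin_taxon == "A" and rec.age_mya == 0

    def test_labeling_contradicting_leaf_presence_errors(self, four_leaf_tree):
        fams = make_fams(("F1", "A", "p1"))
        # labeling claims the family absent in A although p1 lives there
        lab = dollo_reconstruct({"A": 0, "B": 1, "C": 0, "D": 0}, four_leaf_tree, "F1")
        with pytest.raises(PhylostratError, match="absent"):
            assign_protein_ages({"F1": lab}, fams, four_leaf_tree, "A", "dollo")

    def test_missing_labeling_errors(self, four_leaf_tree):
        fams = make_fams(("F1", "A", "p1"))
        with pytest.raises(ArgumentError, match="F1"):
            assign_protein_ages({}, fams, four_leaf_tree, "A", "dollo")

    def test_dollo_members_share_origin_wagner_may_differ(self):
        tree = simulate_tree(10, seed=7)
        hist = simulate_families(tree, 60, loss_prob=0.25, seed=8)
        labs = {
            fam: dollo_reconstruct(hist.matrix.loc[fam].to_dict(), tree, fam)
            for fam in hist.families
        }
        origins: dict[str, set] = {fam: set() for fam in hist.families}
        for sp in tree.leaf_labels:
            db = assign_protein_ages(labs, hist.family_table, tree, sp, "dollo")
            for rec in db.ages.values():
                origins[rec.family].add(rec.origin_taxon)
        for fam in hist.families:
            assert len(origins[fam]) == 1  # Dollo: one origin per family

    def test_origin_always_on_leaf_to_root_path(self):
        tree = simulate_tree(8, seed=3)
        hist = simulate_families(tree, 40, loss_prob=0.2, seed=4)
        from phylostrat import leaf_to_root_path

        labs = {
            fam: wagner_reconstruct(hist.matrix.loc[fam].to_dict(), tree,
                                    family=fam)
            for fam in hist.families
        }
        for sp in tree.leaf_labels:
            db = assign_protein_ages(labs, hist.family_table, tree, sp, "wagner")
            path = [n.label for n in leaf_to_root_path(tree, sp)]
            for rec in db.ages.values():
                assert rec.origin_taxon in path
                assert rec.age_mya == tree.age_of(rec.origin_taxon)


DOMAINS = {
    "D_old": ("Root", 500.0),
    "D_mid": ("AB", 100.0),
    "D_leaf": ("A", 0.0),
    "D_mid2": ("CD", 150.0),
}


class TestDomainAges:
    def test_oldest_vs_youngest(self, four_leaf_tree):
        pdoms = {"p1": {"D_old", "D_mid"}}
        oldest = domain_based_ages(DOMAINS, pdoms, "oldest", four_leaf_tree, "A")
        youngest = domain_based_ages(DOMAINS, pdoms, "youngest", four_leaf_tree, "A")
        assert oldest.ages["p1"].age_mya == 500
        assert youngest.ages["p1"].age_mya == 100

    def test_no_domains_means_species_specific(self, four_leaf_tree):
        db = domain_based_ages(DOMAINS, {"p1": set()}, "oldest", four_leaf_tree, "A")
        rec = db.ages["p1"]
        assert rec.origin_taxon == "A" and rec.age_mya == 0 and rec.no_family

    def test_single_domain_strategies_agree(self, four_leaf_tree):
        pdoms = {"p1": {"D_mid"}}
        o = domain_based_ages(DOMAINS, pdoms, "oldest", four_leaf_tree, "A")
        y = domain_based_ages(DOMAINS, pdoms, "youngest", four_leaf_tree, "A")
        ro, ry = o.ages["p1"], y.ages["p1"]
        assert (ro.origin_taxon, ro.age_mya, ro.family) == (
            ry.origin_taxon, ry.age_mya, ry.family
        )

    def test_age_tie_prefers_leafward_taxon_on_path(self, four_leaf_tree):
        doms = {"X": ("Root", 500.0), "Y": ("AB", 100.0), "Z": ("CD", 100.0)}
        db = domain_based_ages(doms, {"p1": {"Y", "Z"}}, "oldest", four_leaf_tree, "A")
        # both candidates aged 100; AB is on A's path, CD is not
        assert db.ages["p1"].origin_taxon == "AB"

    def test_unknown_domain_age_errors(self, four_leaf_tree):
        with pytest.raises(ArgumentError, match="D_missing"):
            domain_based_ages(DOMAINS, {"p1": {"D_missing"}}, "oldest",
                              four_leaf_tree, "A")

    def test_bad_strategy(self, four_leaf_tree):
        with pytest.raises(ArgumentError):
            domain_based_ages(DOMAINS, {}, "median", four_leaf_tree, "A")

    def test_oldest_ge_youngest_on_random_tables(self, four_leaf_tree):
        rng = np.random.default_rng(11)
        dom_ids = list(DOMAINS)
        pdoms = {
            f"p{i}": set(
                rng.choice(dom_ids, size=rng.integers(0, 5), replace=False)
            )
            for i in range(60)
        }
        oldest = domain_based_ages(DOMAINS, pdoms, "oldest", four_leaf_tree, "A")
        youngest = domain_based_ages(DOMAINS, pdoms, "youngest", four_leaf_tree, "A")
        for pid in pdoms:
            ao, ay = oldest.ages[pid].age_mya, youngest.ages[pid].age_mya
            assert ao >= ay
            distinct = {DOMAINS[d][1] for d in pdoms[pid]}
            assert (ao == ay) == (len(distinct) <= 1)


class TestLookupAndIO:
    def test_lookup_partitions(self, four_leaf_tree):
        fams = make_fams(("F1", "A", "p1"))
        lab = dollo_reconstruct({"A": 1, "B": 0, "C": 0, "D": 0}, four_leaf_tree, "F1")
        db = assign_protein_ages({"F1": lab}, fams, four_leaf_tree, "A", "dollo")
        matched, missing = lookup_ages(db, ProteinList(ids=["p1", "pX"]))
        assert [m.protein for m in matched] == ["p1"]
        assert missing == ["pX"]
        matched, missing = lookup_ages(db, ProteinList(ids=[]))
        assert matched == [] and missing == []

    def test_lookup_uses_gaf_alias_fallback(self, four_leaf_tree):
        fams = make_fams(("F1", "A", "SYM1"))
        lab = dollo_reconstruct({"A": 1, "B": 0, "C": 0, "D": 0}, four_leaf_tree, "F1")
        db = assign_protein_ages({"F1": lab}, fams, four_leaf_tree, "A", "dollo")
        pl = ProteinList(ids=["Q9XYZ1"], aliases={"Q9XYZ1": "SYM1"})
        matched, missing = lookup_ages(db, pl)
        assert [m.protein for m in matched] == ["SYM1"] and not missing

    def test_file_roundtrip_bit_exact(self, four_leaf_tree):
        fams = make_fams(("F1", "A", "p1"), ("F1", "B", "p2"), ("F2", "A", "q1"))
        labs = {
            "F1": dollo_reconstruct({"A": 1, "B": 1, "C": 0, "D": 0},
                                    four_leaf_tree, "F1"),
            "F2": dollo_reconstruct({"A": 1, "B": 0, "C": 0, "D": 0},
                                    four_leaf_tree, "F2"),
        }
        db = assign_protein_ages(labs, fams, four_leaf_tree, "A", "dollo",
                                 metadata={"algorithm": "dollo"})
        buf1 = io.StringIO()
        db.write(buf1)
        db2 = read_age_database(io.StringIO(buf1.getvalue()))
        assert db2.species == db.species
        assert db2.ages == db.ages
        buf2 = io.StringIO()
        db2.write(buf2)
        assert buf1.getvalue() == buf2.getvalue()
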