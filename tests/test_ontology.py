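"""Ontology loading, annotation lookup and non-overlapping class selection."""

import pytest

from chemrich.ontology import (
    ClassAssignment,
    MeshTerm,
    OntologyDB,
    OntologyError,
    direct_annotations,
    load_ontology,
    select_nonoverlapping_classes,
    write_ontology,
)


def term(tid, name, *trees):
    return MeshTerm(tid, name, frozenset(trees))


class Rec:
    def __init__(self, name=None, smiles=None, cid=None):
        self.name, self.smiles, self.pubchem_cid = name, smiles, cid


class TestMeshTerm:
    def test_specificity_is_max_depth(self):
        t = term("1", "x", "D02.092.877", "D02.675")
        assert t.specificity == 3

    def test_malformed_tree_number_rejected(self):
        with pytest.raises(OntologyError):
            term("1", "x", "XYZ")
        with pytest.raises(OntologyError):
            term("1", "x", "")

    def test_prefix_carrying_respects_component_boundaries(self):
        parent = term("p", "parent", "D02.67")
        child = term("c", "child", "D02.675")
        assert not parent.is_prefix_of(child)  # D02.67 is not a dot-prefix
        assert term("p2", "p2", "D02").is_prefix_of(child)


class TestLoadOntology:
    def _write(self, path, rows):
        with open(path, "w") as fh:
            fh.write("key_type\tkey\tterm_id\tterm_name\ttree_number\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")

    def test_three_term_fixture(self, tmp_path):
        path = tmp_path / "onto.tsv"
        self._write(
            path,
            [
                ("cid", "247", "68007211", "quaternary ammonium compounds", "D02.092.877"),
                ("cid", "247", "68009005", "onium compounds", "D02.675"),
                ("name", "glucose", "68006601", "hexoses", "D09.100.400"),
            ],
        )
        db = load_ontology(path)
        assert len(db.terms) == 3
        assert db.lookup("cid", "247") == {"68007211", "68009005"}

    def test_malformed_tree_number_reports_line(self, tmp_path):
        path = tmp_path / "onto.tsv"
        self._write(path, [("name", "x", "1", "y", "D09.100"),
                           ("name", "z", "2", "w", "XYZ")])
        with pytest.raises(OntologyError, match=r":3"):
            load_ontology(path)

    def test_cid_and_smiles_keys_normalize_to_one_annotation_set(self, tmp_path):
        path = tmp_path / "onto.tsv"
        # same molecule keyed by two SMILES spellings: one normalized key
        self._write(path, [("smiles", "CCO", "1", "alcohols", "D02.033"),
                           ("smiles", "OCC", "1", "alcohols", "D02.033")])
        db = load_ontology(path)
        assert len(db.annotations) == 1
        assert db.lookup("smiles", "C(O)C") == {"1"}

    def test_round_trip(self, tmp_path):
        from chemrich.fixtures import mini_ontology

        db = mini_ontology()
        path = tmp_path / "mini.tsv"
        write_ontology(db, path)
        back = load_ontology(path)
        # the TSV format is annotation-driven: every annotated term survives
        annotated = {tid for tids in db.annotations.values() for tid in tids}
        assert annotated <= set(back.terms)
        for tid in annotated:
            assert back.terms[tid] == db.terms[tid]
        assert back.annotations == db.annotations


class TestDirectAnnotations:
    def test_parent_and_child_sorted_most_specific_first(self, mini_db):
        terms = direct_annotations(Rec(name="betaine"), mini_db)
        names = [t.name for t in terms]
        assert names == ["quaternary ammonium compounds", "onium compounds"]

    def test_absent_compound_empty(self, mini_db):
        assert direct_annotations(Rec(name="unobtainium"), mini_db) == []

    def test_equal_depth_tie_broken_by_term_id(self):
        db = OntologyDB()
        db.add_term(term("B2", "beta", "D01.200"))
        db.add_term(term("A1", "alpha", "D01.100"))
        db.annotate("name", "x", "B2")
        db.annotate("name", "x", "A1")
        terms = direct_annotations(Rec(name="x"), db)
        assert [t.term_id for t in terms] == ["A1", "B2"]


class TestClassSelection:
    def test_three_compounds_at_shared_leaf(self):
        leaf = term("L", "leafers", "D01.100.200")
        ann = {f"c{i}": [leaf] for i in range(3)}
        out = select_nonoverlapping_classes(ann)
        assert out.classes() == {"leafers": ["c0", "c1", "c2"]}
        assert all(p == "mesh_direct" for _, p in out.assignments.values())

    def test_parent_completes_class_from_sibling(self):
        parent = term("P", "parents", "D01.100")
        leaf = term("L", "leafers", "D01.100.200")
        ann = {"a": [leaf, parent], "b": [leaf, parent], "c": [parent]}
        out = select_nonoverlapping_classes(ann)
        assert out.classes() == {"parents": ["a", "b", "c"]}

    def test_lone_compound_stays_singleton_with_most_specific_term(self):
        leaf = term("L", "leafers", "D01.100.200")
        lone = term("X", "exotics", "D09.500")
        ann = {f"c{i}": [leaf] for i in range(3)}
        ann["lone"] = [lone]
        out = select_nonoverlapping_classes(ann)
        assert out.singletons() == {"lone": "exotics"}

    def test_nonoverlap_accounting(self, mini_db, study_and_truth):
        study, _ = study_and_truth
        ann = {
            r.compound_id: direct_annotations(r, mini_db)
            for r in study
            if direct_annotations(r, mini_db)
        }
        out = select_nonoverlapping_classes(ann)
        n_in_classes = sum(len(m) for m in out.classes().values())
        assert n_in_classes + len(out.singletons()) == len(ann)
        out.validate()

    def test_raising_min_size_never_adds_classes(self, mini_db, study_and_truth):
        study, _ = study_and_truth
        ann = {
            r.compound_id: direct_annotations(r, mini_db)
            for r in study
            if direct_annotations(r, mini_db)
        }
        counts = [
            len(select_nonoverlapping_classes(ann, min_size=k).classes())
            for k in (3, 4, 5, 8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_permutation_invariance(self, mini_db, study_and_truth):
        study, _ = study_and_truth
        ann = {
            r.compound_id: direct_annotations(r, mini_db)
            for r in study
            if direct_annotations(r, mini_db)
        }
        out1 = select_nonoverlapping_classes(ann)
        reversed_ann = dict(reversed(list(ann.items())))
        out2 = select_nonoverlapping_classes(reversed_ann)
        assert out1.assignments == out2.assignments


class TestClassAssignment:
    def test_double_assignment_rejected(self):
        a = ClassAssignment()
        a.add("x", "sugars", "mesh_direct")
        with pytest.raises(ValueError):
            a.add("x", "lipids", "mesh_direct")

    def test_unknown_provenance_rejected(self):
        with pytest.raises(ValueError):
            ClassAssignment().add("x", "sugars", "guesswork")

    def test_validate_flags_small_classes(self):
        a = ClassAssignment()
        a.add("x", "sugars", "mesh_direct")
        a.add("y", "sugars", "mesh_direct")
        with pytest.raises(ValueError):
            a.validate(min_size=3)
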