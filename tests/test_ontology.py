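"""Ontology parsing, equivalence canonicalization and ancestor reasoning."""

import numpy as np
import pytest

from phenosim.ontology import (
    OntologyError,
    OntologyGraph,
    PhenotypeClass,
    PhenotypePattern,
    build_phenotype_class,
    cross_species_subsumption_counts,
    parse_obo,
    write_obo,
)

from .conftest import brute_force_ancestors, random_dag

MINIMAL_OBO = """format-version: 1.2

[Term]
id: R:0
name: root

[Term]
id: A:1
name: child
is_a: R:0
"""


def _write(tmp_path, text, name="onto.obo"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestParseObo:
    def test_minimal_file(self, tmp_path):
        g = parse_obo(_write(tmp_path, MINIMAL_OBO))
        assert len(g) == 2
        assert g.subclass_edges == {("A:1", "R:0")}

    def test_equivalent_to_shares_canonical(self, tmp_path):
        text = MINIMAL_OBO + "\n[Term]\nid: ZFA:0000396\nname: nervous system\nis_a: R:0\nequivalent_to: FBbt:00005093\n"
        g = parse_obo(text and _write(tmp_path, text))
        assert g.canonical("ZFA:0000396") == g.canonical("FBbt:00005093")

    def test_reciprocal_is_a_folds_to_equivalence(self, tmp_path):
        text = (
            "format-version: 1.2\n\n[Term]\nid: X:1\nname: x\nis_a: Y:1\n"
            "\n[Term]\nid: Y:1\nname: y\nis_a: X:1\n"
        )
        g = parse_obo(_write(tmp_path, text))
        assert g.canonical("X:1") == g.canonical("Y:1")

    def test_three_way_cycle_is_error(self, tmp_path):
        text = (
            "format-version: 1.2\n\n[Term]\nid: X:1\nis_a: Y:1\n"
            "\n[Term]\nid: Y:1\nis_a: Z:1\n\n[Term]\nid: Z:1\nis_a: X:1\n"
        )
        with pytest.raises(OntologyError, match="cycle"):
            parse_obo(_write(tmp_path, text))

    def test_duplicate_id_is_error(self, tmp_path):
        text = "format-version: 1.2\n\n[Term]\nid: A:1\n\n[Term]\nid: A:1\n"
        with pytest.raises(OntologyError, match="A:1"):
            parse_obo(_write(tmp_path, text))

    def test_unknown_is_a_target_is_error(self, tmp_path):
        text = "format-version: 1.2\n\n[Term]\nid: A:1\nis_a: NOPE:1\n"
        with pytest.raises(OntologyError, match="NOPE:1"):
            parse_obo(_write(tmp_path, text))

    def test_species_map_assigns_tags(self, tmp_path):
        g = parse_obo(_write(tmp_path, MINIMAL_OBO), species_map={"A": "human"})
        assert g.classes["A:1"].species_tag == "human"
        assert g.classes["R:0"].species_tag == "integrated"


class TestRoundTrip:
    def test_parse_write_parse_isomorphic(self, toy_graph, tmp_path):
        path = tmp_path / "out.obo"
        write_obo(toy_graph, path)
        again = parse_obo(
            path, species_map={"A": "human", "B": "human", "Z": "fish"}
        )
        assert set(again.classes) == set(toy_graph.classes)
        assert again.subclass_edges == toy_graph.subclass_edges
        assert sorted(map(sorted, again.equivalence_sets)) == sorted(
            map(sorted, toy_graph.equivalence_sets)
        )
        assert again.canonical_map == toy_graph.canonical_map


class TestAncestors:
    def test_root_is_its_own_closure(self, toy_graph):
        assert toy_graph.ancestors("R:0") == {"R:0"}

    def test_equivalence_is_congruence(self, toy_graph):
        assert toy_graph.ancestors("A:1") == toy_graph.ancestors("Z:1")
        # descendants of equivalent classes share the merged ancestor
        assert toy_graph.canonical("A:1") in toy_graph.ancestors("Z:2")
        assert toy_graph.canonical("A:1") in toy_graph.ancestors("A:2")

    def test_unknown_id_raises(self, toy_graph):
        with pytest.raises(OntologyError):
            toy_graph.ancestors("missing:1")

    def test_matches_brute_force_on_random_dags(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            g = random_dag(rng, int(rng.integers(2, 51)))
            for cid in g.classes:
                assert g.ancestors(cid) == brute_force_ancestors(g, cid)

    def test_matches_brute_force_with_random_equivalences(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = random_dag(rng, 30)
            ids = sorted(g.classes)
            for _ in range(3):
                a, b = rng.choice(len(ids), size=2, replace=False)
                saved = dict(g._uf_parent)
                g.add_equivalence(ids[a], ids[b])
                try:
                    g.validate()
                except OntologyError:
                    g._uf_parent = saved
                    g._closure = None
            for cid in ids:
                assert g.ancestors(cid) == brute_force_ancestors(g, cid)


class TestDepth:
    def test_longest_path_and_bridged_depth(self, toy_graph):
        assert toy_graph.depth("R:0") == 0
        assert toy_graph.depth("A:1") == 1
        assert toy_graph.depth("A:2") == 2
        # bridged class shares its partner's depth, not the union of chains
        assert toy_graph.depth("Z:1") == 1


class TestPatternTypes:
    def test_pattern_validates_relations(self):
        PhenotypePattern(entity="FBbt:1", relations=("part-of", "towards"))
        with pytest.raises(ValueError, match="unknown pattern relations"):
            PhenotypePattern(entity="FBbt:1", relations=("sibling-of",))

    def test_species_tag_checked(self):
        with pytest.raises(ValueError):
            PhenotypeClass("X:1", species_tag="martian")


class TestBuildPhenotypeClass:
    @pytest.fixture
    def anatomy(self):
        g = OntologyGraph()
        g.add_class(PhenotypeClass("FBbt:00000001", label="organism", species_tag="fly"))
        g.add_class(PhenotypeClass("FBbt:00005093", label="wing", species_tag="fly"))
        g.add_subclass_edge("FBbt:00005093", "FBbt:00000001")
        return g

    def test_creates_labeled_abnormality_class(self, anatomy):
        cls = build_phenotype_class("FBbt:00005093", anatomy, "fly")
        assert cls.id == "FBbtAB:00005093"
        assert cls.label == "phenotypic abnormality of wing"
        assert cls.definition_pattern.entity == "FBbt:00005093"
        assert cls.definition_pattern.modifier == "Abnormal"

    def test_anatomy_root_sits_under_abnormality_root(self, anatomy):
        cls = build_phenotype_class("FBbt:00000001", anatomy, "fly")
        assert (cls.id, "FBbtAB:ROOT") in anatomy.subclass_edges

    def test_idempotent(self, anatomy):
        first = build_phenotype_class("FBbt:00005093", anatomy, "fly")
        second = build_phenotype_class("FBbt:00005093", anatomy, "fly")
        assert first.id == second.id
        n = len(anatomy)
        build_phenotype_class("FBbt:00005093", anatomy, "fly")
        assert len(anatomy) == n

    def test_mirrors_anatomy_hierarchy(self, anatomy):
        build_phenotype_class("FBbt:00000001", anatomy, "fly")
        wing_ab = build_phenotype_class("FBbt:00005093", anatomy, "fly")
        assert (wing_ab.id, "FBbtAB:00000001") in anatomy.subclass_edges

    def test_unknown_entity_raises(self, anatomy):
        with pytest.raises(OntologyError):
            build_phenotype_class("FBbt:99999999", anatomy, "fly")


def _two_trees(bridge: bool) -> OntologyGraph:
    """Two 3-class single-species trees, optionally bridged at the middle."""
    g = OntologyGraph()
    for prefix, tag in (("HP", "human"), ("MP", "mouse")):
        for i in (1, 2, 3):
            g.add_class(PhenotypeClass(f"{prefix}:{i}", species_tag=tag))
        g.add_subclass_edge(f"{prefix}:2", f"{prefix}:1")
        g.add_subclass_edge(f"{prefix}:3", f"{prefix}:2")
    if bridge:
        g.add_equivalence("HP:2", "MP:2")
    return g


class TestCrossSpeciesCounts:
    def test_disjoint_trees_have_zero_cross_counts(self):
        counts = cross_species_subsumption_counts(_two_trees(False), "mouse", "human")
        assert all(v == 0 for v in counts.values())

    def test_single_bridge_counts_match_pair_enumeration(self):
        g = _two_trees(True)
        counts = cross_species_subsumption_counts(g, "mouse", "human")
        # enumeration oracle: all ordered (mouse, human) pairs in the closure
        expected_sub = sum(
            1
            for m in ("MP:1", "MP:2", "MP:3")
            for h in ("HP:1", "HP:2", "HP:3")
            if g.canonical(h) in g.ancestors(m) and g.canonical(h) != g.canonical(m)
        )
        assert counts["subclass_direct"] + counts["subclass_inferred"] == expected_sub
        # MP:3 under merged HP:2/MP:2 is asserted; MP:3 under HP:1 is inferred
        assert counts["subclass_direct"] == 2  # MP:3->merged, merged->HP:1
        assert counts["subclass_inferred"] == 1  # MP:3 under HP:1
        assert counts["equivalent"] == 1

    def test_adding_equivalence_never_decreases_counts(self):
        before = cross_species_subsumption_counts(_two_trees(False), "mouse", "human")
        after = cross_species_subsumption_counts(_two_trees(True), "mouse", "human")
        for key in ("subclass_direct", "subclass_inferred", "superclass_direct",
                    "superclass_inferred", "equivalent"):
            assert after[key] >= before[key]

    def test_unknown_species_tag_raises(self):
        with pytest.raises(OntologyError):
            cross_species_subsumption_counts(_two_trees(True), "mouse", "martian")
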