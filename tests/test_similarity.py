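"""Information content, Resnik/MICA and best-match-average similarity."""

import math

import numpy as np
import pytest

from phenosim.annotations import AnnotationCorpus
from phenosim.ontology import PhenotypeClass
from phenosim.similarity import (
    bma_similarity,
    compute_ic,
    resnik_pair,
    similarity_matrix_resnik,
)

from .conftest import random_dag

IC_A = -math.log2(3 / 4)  # ≈ 0.415 bits: the merged A class covers 3 of 4 entities


class TestComputeIC:
    def test_hand_computed_values(self, toy_graph, toy_ic):
        assert toy_ic.total_entities == 4
        assert toy_ic[toy_graph.canonical("A:1")] == pytest.approx(IC_A)
        assert toy_ic["R:0"] == 0.0  # annotates every entity
        assert toy_ic["A:2"] == pytest.approx(2.0)  # 1 of 4 → 2 bits
        assert toy_ic["B:1"] == pytest.approx(2.0)

    def test_zero_frequency_classes_absent(self, toy_graph, toy_corpus):
        toy_graph.add_class(PhenotypeClass("C:9", species_tag="human"))
        toy_graph.add_subclass_edge("C:9", "R:0")
        ic = compute_ic([toy_corpus])
        assert "C:9" not in ic

    def test_union_counts_entities_once(self, toy_graph, toy_corpus):
        ic_once = compute_ic([toy_corpus])
        ic_twice = compute_ic([toy_corpus, toy_corpus])
        assert ic_once.ic == ic_twice.ic
        assert ic_twice.total_entities == 4

    def test_empty_corpus_list_is_error(self):
        with pytest.raises(ValueError):
            compute_ic([])

    def test_ic_is_antitone_along_subclass_edges(self):
        rng = np.random.default_rng(11)
        g = random_dag(rng, 30)
        ids = sorted(g.classes)
        direct = {
            f"e{i}": set(rng.choice(ids, size=3, replace=False))
            for i in range(20)
        }
        corpus = AnnotationCorpus.from_direct(direct, g, "gene", "human")
        ic = compute_ic([corpus])
        for child, parent in g.subclass_edges:
            cc, cp = g.canonical(child), g.canonical(parent)
            if cc in ic and cp in ic:
                assert ic[cc] >= ic[cp] - 1e-12


class TestResnikPair:
    def test_cross_species_mica_is_merged_class(self, toy_graph, toy_ic):
        # human A1 vs model A1': MICA is the merged A/A' class
        assert resnik_pair(toy_ic, toy_graph, "A:2", "Z:2") == pytest.approx(IC_A)

    def test_self_similarity_is_own_ic(self, toy_graph, toy_ic):
        assert resnik_pair(toy_ic, toy_graph, "A:2", "A:2") == pytest.approx(2.0)

    def test_only_root_shared_gives_zero(self, toy_graph, toy_ic):
        assert resnik_pair(toy_ic, toy_graph, "A:2", "B:1") == 0.0

    def test_unknown_class_raises(self, toy_graph, toy_ic):
        with pytest.raises(Exception):
            resnik_pair(toy_ic, toy_graph, "A:2", "missing:1")

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            g = random_dag(rng, 25)
            ids = sorted(g.classes)
            direct = {
                f"e{i}": set(rng.choice(ids, size=2, replace=False))
                for i in range(15)
            }
            corpus = AnnotationCorpus.from_direct(direct, g, "gene", "human")
            ic = compute_ic([corpus])
            for _ in range(20):
                c1, c2 = (ids[int(k)] for k in rng.integers(len(ids), size=2))
                common = g.ancestors(c1) & g.ancestors(c2)
                expected = max((ic.ic[a] for a in common if a in ic.ic), default=0.0)
                assert resnik_pair(ic, g, c1, c2) == pytest.approx(expected)


class TestBMA:
    def test_hand_computed_value(self, toy_graph, toy_ic):
        # gene {A1'}, disease {A1, B}: ½·(0.415 + (0.415 + 0)/2) ≈ 0.311
        expected = 0.5 * (IC_A + (IC_A + 0.0) / 2)
        got = bma_similarity({"Z:2"}, {"A:2", "B:1"}, toy_ic, toy_graph)
        assert got == pytest.approx(expected)

    def test_identical_singletons(self, toy_graph, toy_ic):
        assert bma_similarity({"A:2"}, {"A:2"}, toy_ic, toy_graph) == pytest.approx(2.0)

    def test_empty_set_scores_zero_with_warning(self, toy_graph, toy_ic, caplog):
        with caplog.at_level("WARNING"):
            assert bma_similarity(set(), {"A:2"}, toy_ic, toy_graph) == 0.0
        assert "empty" in caplog.text

    def test_symmetric_on_random_set_pairs(self):
        rng = np.random.default_rng(3)
        g = random_dag(rng, 30)
        ids = sorted(g.classes)
        direct = {
            f"e{i}": set(rng.choice(ids, size=3, replace=False)) for i in range(20)
        }
        ic = compute_ic([AnnotationCorpus.from_direct(direct, g, "gene", "human")])
        for _ in range(100):
            a = set(rng.choice(ids, size=int(rng.integers(1, 5)), replace=False))
            b = set(rng.choice(ids, size=int(rng.integers(1, 5)), replace=False))
            assert bma_similarity(a, b, ic, g) == pytest.approx(
                bma_similarity(b, a, ic, g)
            )


class TestSimilarityMatrix:
    def test_single_cell_equals_bma(self, toy_graph, toy_ic):
        genes = AnnotationCorpus.from_direct({"g": {"Z:2"}}, toy_graph, "gene", "fish")
        diseases = AnnotationCorpus.from_direct(
            {"d": {"A:2", "B:1"}}, toy_graph, "disease", "human"
        )
        m = similarity_matrix_resnik(genes, diseases, toy_ic, toy_graph)
        assert m.values[0, 0] == pytest.approx(
            bma_similarity({"Z:2"}, {"A:2", "B:1"}, toy_ic, toy_graph)
        )

    def test_matches_per_cell_recomputation(self):
        rng = np.random.default_rng(9)
        g = random_dag(rng, 40)
        ids = sorted(g.classes)
        gene_direct = {
            f"g{i}": set(rng.choice(ids, size=3, replace=False)) for i in range(20)
        }
        dis_direct = {
            f"d{i}": set(rng.choice(ids, size=3, replace=False)) for i in range(10)
        }
        genes = AnnotationCorpus.from_direct(gene_direct, g, "gene", "mouse")
        diseases = AnnotationCorpus.from_direct(dis_direct, g, "disease", "human")
        ic = compute_ic([genes, diseases])
        m = similarity_matrix_resnik(genes, diseases, ic, g)
        for i, gene in enumerate(m.gene_ids):
            for j, dis in enumerate(m.disease_ids):
                assert m.values[i, j] == pytest.approx(
                    bma_similarity(gene_direct[gene], dis_direct[dis], ic, g)
                )

    def test_matrix_round_trips_through_tsv(self, toy_graph, toy_ic, tmp_path):
        from phenosim.similarity import SimilarityMatrix

        genes = AnnotationCorpus.from_direct({"g": {"Z:2"}}, toy_graph, "gene", "fish")
        diseases = AnnotationCorpus.from_direct(
            {"d": {"A:2"}}, toy_graph, "disease", "human"
        )
        m = similarity_matrix_resnik(genes, diseases, toy_ic, toy_graph)
        m.to_tsv(tmp_path / "sim.tsv")
        again = SimilarityMatrix.from_tsv(tmp_path / "sim.tsv")
        np.testing.assert_allclose(again.values, m.values)
        assert again.gene_ids == m.gene_ids


class TestBMAProperties:
    """Algebraic properties of BMA, explored over generated class-set pairs."""

    from hypothesis import HealthCheck, given, settings
    from hypothesis import strategies as st

    # the fixtures are read-only here, so sharing them across examples is safe
    fixture_ok = settings(
        max_examples=50,
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )

    ids = st.sampled_from(["R:0", "A:1", "A:2", "Z:1", "Z:2", "B:1"])

    @given(a=st.sets(ids, min_size=1, max_size=4), b=st.sets(ids, min_size=1, max_size=4))
    @fixture_ok
    def test_symmetric_and_bounded(self, toy_graph, toy_ic, a, b):
        fwd = bma_similarity(a, b, toy_ic, toy_graph)
        rev = bma_similarity(b, a, toy_ic, toy_graph)
        assert fwd == pytest.approx(rev)
        assert 0.0 <= fwd <= max(toy_ic.ic.values())
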