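import numpy as np
import pytest

from phenorare.ontology import information_content
from phenorare.similarity import (
    CoverageError,
    EmbeddingTable,
    SimilarityModel,
    cosine_similarity,
    lin_similarity,
    restricted_lin_similarity,
    similarity_matrix,
)

from conftest import random_dag

LIN_T3_T4 = 2 * 0.5596157879354227 / (1.252762968495368 + 1.9459101090932196)
RESTR_T5_T3 = 2 * 1.252762968495368 / (1.9459101090932196 + 1.252762968495368)


class TestLin:
    def test_self_similarity_is_one(self, toy7_lin):
        assert lin_similarity(toy7_lin, "T5", "T5") == 1.0
        assert lin_similarity(toy7_lin, "T0", "T0") == 1.0  # 0/0 root case

    def test_root_mica_gives_zero(self, toy7_lin):
        assert lin_similarity(toy7_lin, "T4", "T6") == 0.0

    def test_sibling_value(self, toy7_lin):
        assert lin_similarity(toy7_lin, "T3", "T4") == pytest.approx(LIN_T3_T4, abs=1e-4)
        assert lin_similarity(toy7_lin, "T3", "T4") == pytest.approx(0.3499, abs=1e-4)


class TestRestrictedLin:
    def test_siblings_are_null(self, toy7_restricted):
        assert restricted_lin_similarity(toy7_restricted, "T3", "T4") == 0.0

    def test_subsumption_pair_equals_lin(self, toy7_restricted, toy7_lin):
        value = restricted_lin_similarity(toy7_restricted, "T5", "T3")
        assert value == pytest.approx(RESTR_T5_T3, abs=1e-4)
        assert value == pytest.approx(0.7833, abs=1e-4)
        assert value == lin_similarity(toy7_lin, "T5", "T3")

    def test_renal_siblings_null_but_lin_positive(self, renal):
        """CKD and AKI share an informative parent yet must not count as similar."""
        stats = information_content(renal)
        lin = SimilarityModel(method="lin", graph=renal, stats=stats)
        restr = SimilarityModel(method="restricted_lin", graph=renal, stats=stats)
        pair = ("chronic_kidney_disease", "acute_kidney_injury")
        assert restricted_lin_similarity(restr, *pair) == 0.0
        assert lin_similarity(lin, *pair) > 0.0


@pytest.fixture(scope="module")
def table():
    return EmbeddingTable(
        vectors={
            "a": np.array([1.0, 0.0]),
            "b": np.array([0.0, 1.0]),
            "c": np.array([1.0, 1.0]),
            "d": np.array([-1.0, 0.0]),
        },
        dim=2,
    )


class TestCosine:

    def test_hand_computed_values(self, table):
        model = SimilarityModel(method="embedding_cosine", embeddings=table)
        assert cosine_similarity(model, "a", "a") == pytest.approx(1.0)
        assert cosine_similarity(model, "a", "b") == pytest.approx(0.0)
        assert cosine_similarity(model, "c", "a") == pytest.approx(1 / np.sqrt(2))

    def test_raw_cosine_can_be_negative_but_sim_clips(self, table):
        model = SimilarityModel(method="embedding_cosine", embeddings=table)
        assert cosine_similarity(model, "a", "d") == pytest.approx(-1.0)
        assert model.sim("a", "d") == 0.0

    def test_missing_embedding_raises_coverage_error(self, table):
        model = SimilarityModel(method="embedding_cosine", embeddings=table)
        with pytest.raises(CoverageError):
            cosine_similarity(model, "a", "zzz")

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            EmbeddingTable(vectors={"a": np.zeros(3)}, dim=3)


class TestSimilarityMatrix:
    def test_binary_is_identity(self, toy7):
        model = SimilarityModel(method="binary", graph=toy7)
        np.testing.assert_array_equal(
            similarity_matrix(model, ("T3", "T4", "T5")), np.eye(3)
        )

    def test_toy7_restricted_matrix(self, toy7_restricted):
        m = similarity_matrix(toy7_restricted, ("T3", "T4", "T5"))
        expected = np.array(
            [[1, 0, 0.7833], [0, 1, 0], [0.7833, 0, 1]]
        )
        np.testing.assert_allclose(m, expected, atol=1e-4)

    def test_symmetric_with_unit_diagonal_on_random_dags(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            g = random_dag(rng, 15)
            model = SimilarityModel(
                method="lin", graph=g, stats=information_content(g)
            )
            terms = sorted(g.terms)[:10]
            m = similarity_matrix(model, terms)
            np.testing.assert_allclose(m, m.T)
            np.testing.assert_allclose(np.diag(m), 1.0)

    def test_uncovered_terms_listed(self, toy7_restricted):
        with pytest.raises(CoverageError, match="T99"):
            similarity_matrix(toy7_restricted, ("T3", "T99"))


class TestProperties:
    def test_restricted_never_exceeds_lin(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            g = random_dag(rng, 20)
            stats = information_content(g)
            lin = SimilarityModel(method="lin", graph=g, stats=stats)
            restr = SimilarityModel(method="restricted_lin", graph=g, stats=stats)
            terms = sorted(g.terms)
            for _ in range(30):
                p1, p2 = rng.choice(terms, size=2)
                assert restr.sim(p1, p2) <= lin.sim(p1, p2) + 1e-12

    def test_lin_invariant_to_log_base(self, toy7):
        nat = SimilarityModel(method="lin", graph=toy7, stats=information_content(toy7))
        b10 = SimilarityModel(
            method="lin", graph=toy7, stats=information_content(toy7, base=10)
        )
        for p1 in toy7.terms:
            for p2 in toy7.terms:
                assert nat.sim(p1, p2) == pytest.approx(b10.sim(p1, p2), abs=1e-12)

    def test_binary_is_kronecker_delta(self, toy7):
        model = SimilarityModel(method="binary", graph=toy7)
        for p1 in toy7.terms:
            for p2 in toy7.terms:
                assert model.sim(p1, p2) == (1.0 if p1 == p2 else 0.0)
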