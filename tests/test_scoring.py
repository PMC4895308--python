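"""Bell kernel, sign product, PDOD/PDD scores and their symmetries."""

import math

import numpy as np
import pytest

from pdod import (
    DiseaseGeneSet,
    DrugRecord,
    ScoreParams,
    bell_kernel,
    build_graph,
    pdd_score,
    pdod_score,
    score_all,
    sgn_term,
)
from pdod.network import INFINITE_DISTANCE, ConflictDistance

from conftest import random_signed_graph


class TestBellKernel:
    def test_maximum_at_zero(self):
        assert bell_kernel(0.0, ScoreParams(alpha=3)) == 1.0

    def test_half_width(self):
        assert bell_kernel(3.0, ScoreParams(alpha=3)) == 0.5
        assert bell_kernel(-3.0, ScoreParams(alpha=3)) == 0.5
        assert bell_kernel(5.0, ScoreParams(alpha=5)) == 0.5

    def test_infinity_sentinel_is_exact_zero(self):
        assert bell_kernel(INFINITE_DISTANCE, ScoreParams(alpha=3)) == 0.0
        assert bell_kernel(ConflictDistance(math.inf, True), ScoreParams()) == 0.0

    def test_monotone_decreasing_in_distance_increasing_in_alpha(self):
        params = ScoreParams(alpha=3)
        values = [bell_kernel(float(d), params) for d in range(8)]
        assert values == sorted(values, reverse=True)
        assert all(
            bell_kernel(2.0, ScoreParams(alpha=a2)) >= bell_kernel(2.0, ScoreParams(alpha=a1))
            for a1, a2 in [(1, 2), (2, 3), (3, 5)]
        )

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            ScoreParams(alpha=0)
        with pytest.raises(ValueError):
            ScoreParams(alpha=-1)


class TestSgnTerm:
    @pytest.mark.parametrize(
        "i_effect, dc_sign, state, expected",
        [
            (-1, 1, -1, 1),   # inhibitor, net activation, up-regulated gene: opposes
            (-1, -1, 1, 1),   # inhibitor, net inhibition, down-regulated gene: opposes
            (1, 1, -1, -1),   # activator pushing an up-regulated gene further up
            (1, 1, 1, 1),
            (1, -1, -1, 1),
        ],
    )
    def test_sign_product(self, i_effect, dc_sign, state, expected):
        assert sgn_term(i_effect, dc_sign, state) == expected

    def test_bad_factor_rejected(self):
        with pytest.raises(ValueError):
            sgn_term(0, 1, 1)


def _two_gene_case():
    """One inhibitory target r; up-regulated gene g1 at d_c = +1 and
    down-regulated gene g2 at d_c = -3 (3-hop path, one inhibition)."""
    graph = build_graph(
        [("r", "g1", 1), ("r", "a", 1), ("a", "b", 1), ("b", "g2", -1)]
    )
    drug = DrugRecord("D1", "inhibitor-drug", (("r", -1),))
    disease = DiseaseGeneSet("dis", (("g1", -1), ("g2", 1)))
    return graph, drug, disease


class TestPdodScore:
    def test_hand_evaluated_two_gene_case(self):
        """Both pairs oppose the disease: (0.9 + 0.5) / 2 = 0.7 at alpha 3."""
        graph, drug, disease = _two_gene_case()
        assert pdod_score(drug, disease, graph) == pytest.approx(0.7)

    def test_all_unreachable_scores_zero(self):
        graph = build_graph([("r", "x", 1), ("g", "y", -1)])
        drug = DrugRecord("D1", "x", (("r", 1),))
        disease = DiseaseGeneSet("dis", (("g", -1),))
        assert pdod_score(drug, disease, graph) == 0.0

    def test_target_on_disease_gene_is_maximal(self):
        """An activating target sitting directly on a down-regulated disease
        gene gives the maximal score +1 under the hop-0 convention."""
        graph = build_graph([("r", "x", 1)])
        drug = DrugRecord("D1", "x", (("r", 1),))
        disease = DiseaseGeneSet("dis", (("r", 1),))
        assert pdod_score(drug, disease, graph) == 1.0

    def test_conflict_tied_pair_contributes_zero(self):
        graph = build_graph([("r", "a", 1), ("a", "g", 1), ("r", "b", 1), ("b", "g", -1)])
        drug = DrugRecord("D1", "x", (("r", 1),))
        disease = DiseaseGeneSet("dis", (("g", 1),))
        assert pdod_score(drug, disease, graph) == 0.0

    def test_unrestricted_input_rejected(self):
        graph, drug, disease = _two_gene_case()
        stray = DrugRecord("D2", "x", (("not-here", 1),))
        with pytest.raises(KeyError):
            pdod_score(stray, disease, graph)


class TestPddScore:
    def test_coincides_with_pdod_when_all_terms_oppose(self):
        graph, drug, disease = _two_gene_case()
        assert pdd_score(drug, disease, graph) == pytest.approx(0.7)

    def test_cannot_distinguish_aggravating_from_therapeutic(self):
        """A drug activating an up-regulated gene at hop 1 scores -0.9 under
        PDOD but 0.9 under the directionless baseline."""
        graph = build_graph([("r", "g", 1), ("g", "z", 1)])
        drug = DrugRecord("D1", "x", (("r", 1),))
        disease = DiseaseGeneSet("dis", (("g", -1),))
        assert pdod_score(drug, disease, graph) == pytest.approx(-0.9)
        assert pdd_score(drug, disease, graph) == pytest.approx(0.9)

    def test_uses_undirected_hops_by_default(self):
        # edge points g -> r only; undirected projection still connects them
        graph = build_graph([("g", "r", 1), ("g", "z", 1)])
        drug = DrugRecord("D1", "x", (("r", 1),))
        disease = DiseaseGeneSet("dis", (("g", -1),))
        assert pdod_score(drug, disease, graph) == 0.0
        assert pdd_score(drug, disease, graph) == pytest.approx(0.9)
        directed = ScoreParams(pdd_projection="directed")
        assert pdd_score(drug, disease, graph, directed) == 0.0

    def test_invariant_under_sign_and_state_reassignment(self):
        rng = np.random.default_rng(11)
        graph, drug, disease = _random_case(rng, n=14)
        baseline = pdd_score(drug, disease, graph)
        flipped_graph = build_graph([(u, v, -s) for u, v, s in graph.edges()])
        for node in graph.nodes:
            flipped_graph.add_node(node)
        assert pdd_score(_flip_drug(drug), _flip_disease(disease), flipped_graph) == pytest.approx(baseline)


def _random_case(rng, n=12, p=0.25):
    graph = random_signed_graph(rng, n, p)
    names = sorted(graph.nodes)
    n_t = int(rng.integers(1, 4))
    n_g = int(rng.integers(1, 5))
    t_idx = rng.choice(len(names), size=n_t, replace=False)
    g_idx = rng.choice(len(names), size=n_g, replace=False)
    drug = DrugRecord(
        "D", "d", tuple((names[int(i)], int(rng.choice([1, -1]))) for i in t_idx)
    )
    disease = DiseaseGeneSet(
        "G", tuple((names[int(i)], int(rng.choice([1, -1]))) for i in g_idx)
    )
    return graph, drug, disease


def _flip_drug(drug):
    return DrugRecord(drug.drug_id, drug.name, tuple((g, -e) for g, e in drug.targets))


def _flip_disease(disease):
    return DiseaseGeneSet(disease.disease_id, tuple((g, -s) for g, s in disease.genes))


class TestScoreProperties:
    def test_bounds_on_random_fixtures(self):
        """PDOD scores stay within [-1, 1] and PDD within [0, 1]."""
        rng = np.random.default_rng(5)
        for _ in range(300):
            graph, drug, disease = _random_case(rng)
            s = pdod_score(drug, disease, graph)
            assert -1.0 <= s <= 1.0
            b = pdd_score(drug, disease, graph)
            assert 0.0 <= b <= 1.0

    def test_state_flip_negates_pdod(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            graph, drug, disease = _random_case(rng)
            assert pdod_score(drug, _flip_disease(disease), graph) == pytest.approx(
                -pdod_score(drug, disease, graph), abs=1e-12
            )

    def test_effect_flip_negates_pdod(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            graph, drug, disease = _random_case(rng)
            assert pdod_score(_flip_drug(drug), disease, graph) == pytest.approx(
                -pdod_score(drug, disease, graph), abs=1e-12
            )


class TestScoreAll:
    def test_matches_independent_per_pair_calls(self):
        """The cached bulk scorer must be bit-identical to naive per-pair
        recomputation."""
        rng = np.random.default_rng(21)
        graph = random_signed_graph(rng, 20, 0.15)
        names = sorted(graph.nodes)
        drugs = []
        for i in range(10):
            idx = rng.choice(len(names), size=int(rng.integers(1, 4)), replace=False)
            drugs.append(
                DrugRecord(
                    f"D{i}", f"drug {i}",
                    tuple((names[int(j)], int(rng.choice([1, -1]))) for j in idx),
                )
            )
        diseases = []
        for i in range(2):
            idx = rng.choice(len(names), size=4, replace=False)
            diseases.append(
                DiseaseGeneSet(
                    f"dis{i}",
                    tuple((names[int(j)], int(rng.choice([1, -1]))) for j in idx),
                )
            )
        matrix = score_all(drugs, diseases, graph, keep_detail=True)
        for drug in drugs:
            for disease in diseases:
                key = (drug.drug_id, disease.disease_id)
                assert matrix.pdod[key] == pdod_score(drug, disease, graph)
                assert matrix.pdd[key] == pdd_score(drug, disease, graph)
                # per-pair detail recomposes the score exactly
                recomposed = sum(t.contribution for t in matrix.detail[key]) / (
                    drug.n_targets * disease.n_genes
                )
                assert matrix.pdod[key] == recomposed

    def test_empty_drug_list_gives_empty_matrix(self):
        graph = build_graph([("a", "b", 1)])
        matrix = score_all([], [DiseaseGeneSet("d", (("a", 1),))], graph)
        assert matrix.pdod == {} and matrix.pdd == {}

    def test_ranking_orders_by_score(self):
        graph, drug, disease = _two_gene_case()
        other = DrugRecord("D0", "activator-drug", (("r", 1),))
        matrix = score_all([drug, other], [disease], graph)
        frame = matrix.ranking("dis")
        assert list(frame["drug_id"]) == ["D1", "D0"]
        assert frame["rank"].tolist() == [1.0, 2.0]
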