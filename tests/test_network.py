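"""SAS scores, candidate edges, CSN construction and hub selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import memoryscreen as ms
from memoryscreen.screen import GearSet


def brute_force_sas(vec_a, vec_b):
    """Independent set-based count: positions significant in A, B, both."""
    pos_a = {i for i, v in enumerate(vec_a) if v}
    pos_b = {i for i, v in enumerate(vec_b) if v}
    a, b, c = len(pos_a), len(pos_b), len(pos_a & pos_b)
    return c / (a + b - 2 * c + 1)


def _gearset(gene_ids):
    gene_ids = np.asarray(gene_ids, dtype=object)
    return GearSet(
        gene_ids=gene_ids,
        probabilities=np.ones(len(gene_ids)),
        saturation_index=0,
        threshold=0.8,
        mode="saturation",
    )


def _tensor_from_vectors(vectors):
    vectors = np.asarray(vectors, dtype=np.uint8)[None, :, :]  # one gradient
    genes = np.asarray([f"G{i:03d}" for i in range(vectors.shape[1])], dtype=object)
    return ms.SignificanceTensor(
        values=vectors,
        gene_ids=genes,
        gradient_sizes=(vectors.shape[2],),
        seed=0,
        alpha=0.05,
        diagnostics=pd.DataFrame({"gradient_size": [vectors.shape[2]]}),
    )


class TestSasScore:
    @pytest.mark.parametrize(
        "vec_a, vec_b, expected",
        [
            ([1, 0, 1], [0, 1, 0], 0.0),  # disjoint significance
            ([1, 0, 0], [1, 0, 0], 1.0),  # a=b=c=1
            ([1, 1, 1, 0, 0], [1, 0, 0, 1, 0], 0.25),  # a=3, b=2, c=1
            ([1, 1, 0], [1, 1, 0], 2.0),  # a=b=c=2: formula exceeds 1 as printed
        ],
    )
    def test_closed_form_cases(self, vec_a, vec_b, expected):
        assert ms.sas_score(np.array(vec_a), np.array(vec_b)) == expected

    def test_normalized_variant_is_jaccard(self):
        assert ms.sas_score(np.array([1, 1, 0]), np.array([1, 1, 0]), normalized=True) == 1.0
        assert ms.sas_score(np.array([1, 1, 0]), np.array([1, 0, 1]), normalized=True) == pytest.approx(1 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ms.sas_score(np.array([1, 0]), np.array([1, 0, 1]))

    @given(st.lists(st.booleans(), min_size=1, max_size=30), st.data())
    def test_symmetry_and_oracle(self, bits_a, data):
        bits_b = data.draw(
            st.lists(st.booleans(), min_size=len(bits_a), max_size=len(bits_a))
        )
        va = np.array(bits_a, dtype=int)
        vb = np.array(bits_b, dtype=int)
        assert ms.sas_score(va, vb) == ms.sas_score(vb, va)
        assert ms.sas_score(va, vb) == brute_force_sas(bits_a, bits_b)

    def test_exhaustive_short_vectors_match_brute_force(self):
        for length in (1, 2, 3, 4, 5):
            for bits_a in itertools.product((0, 1), repeat=length):
                for bits_b in itertools.product((0, 1), repeat=length):
                    got = ms.sas_score(np.array(bits_a), np.array(bits_b))
                    assert got == brute_force_sas(bits_a, bits_b)


class TestComputeSasEdges:
    def test_two_gears_among_four_genes_give_five_pairs(self):
        rng = np.random.default_rng(1)
        tensor = _tensor_from_vectors(rng.integers(0, 2, size=(4, 12)))
        edges = ms.compute_sas_edges(tensor, _gearset(["G000", "G001"]))
        assert len(edges) == 5  # 2*3 ordered minus the duplicated GEAR-GEAR pair

    def test_all_zero_tensor_gives_zero_scores(self):
        tensor = _tensor_from_vectors(np.zeros((4, 10), dtype=int))
        edges = ms.compute_sas_edges(tensor, _gearset(["G000"]))
        assert (edges["sas"] == 0.0).all()

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(7)
        vectors = rng.integers(0, 2, size=(50, 40))
        tensor = _tensor_from_vectors(vectors)
        gears = _gearset([f"G{i:03d}" for i in range(0, 50, 5)])
        edges = ms.compute_sas_edges(tensor, gears)
        gene_index = {g: i for i, g in enumerate(tensor.gene_ids)}
        for row in edges.itertuples(index=False):
            expected = brute_force_sas(
                vectors[gene_index[row.gene_u]], vectors[gene_index[row.gene_v]]
            )
            assert row.sas == expected

    def test_empty_gear_set_rejected(self):
        tensor = _tensor_from_vectors(np.zeros((2, 4), dtype=int))
        with pytest.raises(ValueError):
            ms.compute_sas_edges(tensor, _gearset([]))


class TestBuildCsn:
    def test_top_k_largest_retained(self):
        edges = pd.DataFrame(
            {
                "gene_u": ["A", "A", "B", "C", "D"],
                "gene_v": ["B", "C", "C", "D", "E"],
                "sas": [0.9, 0.1, 0.8, 0.7, 0.2],
                "c": [9, 1, 8, 7, 2],
            }
        )
        csn = ms.build_csn(edges, top_k=3)
        assert list(csn.edges["sas"]) == [0.9, 0.8, 0.7]

    def test_tie_at_cutoff_resolved_lexicographically(self):
        edges = pd.DataFrame(
            {
                "gene_u": ["X", "A", "B"],
                "gene_v": ["Y", "Z", "C"],
                "sas": [0.9, 0.5, 0.5],
                "c": [9, 5, 5],
            }
        )
        csn = ms.build_csn(edges, top_k=2)
        assert list(zip(csn.edges["gene_u"], csn.edges["gene_v"])) == [("X", "Y"), ("A", "Z")]

    def test_degrees_match_brute_force_incidence(self):
        rng = np.random.default_rng(3)
        nodes = [f"N{i}" for i in range(30)]
        pairs = set()
        while len(pairs) < 30:
            u, v = rng.choice(30, size=2, replace=False)
            pairs.add((nodes[min(u, v)], nodes[max(u, v)]))
        edges = pd.DataFrame(
            [(u, v, rng.random(), 1) for u, v in sorted(pairs)],
            columns=["gene_u", "gene_v", "sas", "c"],
        )
        csn = ms.build_csn(edges, top_k=1000)
        counts: dict[str, int] = {}
        for u, v in pairs:
            counts[u] = counts.get(u, 0) + 1
            counts[v] = counts.get(v, 0) + 1
        degrees = csn.degrees()
        assert {n: int(degrees[n]) for n in degrees.index} == counts

    def test_pure_function_of_edge_collection(self):
        edges = pd.DataFrame(
            {"gene_u": ["A", "B"], "gene_v": ["B", "C"], "sas": [0.5, 0.4], "c": [5, 4]}
        )
        csn1 = ms.build_csn(edges.sample(frac=1, random_state=0), top_k=10)
        csn2 = ms.build_csn(edges, top_k=10)
        pd.testing.assert_frame_equal(csn1.edges, csn2.edges)


class TestHubSelection:
    def _setup(self, mean_tpms):
        genes = sorted(mean_tpms)
        samples = ["S1", "S2"]
        values = np.array([[mean_tpms[g], mean_tpms[g]] for g in genes], dtype=float)
        expr = ms.ExpressionMatrix(gene_ids=genes, sample_ids=samples, values=values)
        edges = pd.DataFrame(
            [
                ("A", "B", 0.9, 9),
                ("A", "C", 0.8, 8),
                ("A", "D", 0.7, 7),
                ("B", "C", 0.6, 6),
                ("B", "D", 0.5, 5),
            ],
            columns=["gene_u", "gene_v", "sas", "c"],
        )
        return ms.build_csn(edges, top_k=10), expr

    def test_mean_tpm_boundary_is_strict(self):
        csn, expr = self._setup({"A": 10.0, "B": 11.0, "C": 12.0, "D": 13.0})
        hubs = ms.select_hub_genes(csn, expr, _gearset(["A", "B", "C", "D"]), top_n=10)
        assert "A" not in hubs.gene_ids  # exactly 10 TPM excluded
        assert set(hubs.gene_ids) == {"B", "C", "D"}

    def test_only_gears_eligible(self):
        csn, expr = self._setup({"A": 50.0, "B": 50.0, "C": 50.0, "D": 50.0})
        hubs = ms.select_hub_genes(csn, expr, _gearset(["B", "C"]), top_n=10)
        assert set(hubs.gene_ids) == {"B", "C"}

    def test_degree_ranking_and_top_n(self):
        csn, expr = self._setup({"A": 50.0, "B": 50.0, "C": 50.0, "D": 50.0})
        hubs = ms.select_hub_genes(csn, expr, _gearset(["A", "B", "C", "D"]), top_n=2)
        assert list(hubs.gene_ids) == ["A", "B"]  # degrees 3 and 3; A wins on weight
        assert list(hubs.degrees) == [3, 3]
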