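import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from symh2.abundance import NormalizedAbundanceTable
from symh2.diversity import (
    DistanceMatrix,
    SimilarityMatrix,
    diversity_phenotypes,
    leinster_cobbold,
    raw_distances,
    similarity_from_distances,
)
from symh2.io import OtuSequenceSet

from _oracles import classical_hill, similarity_diversity_bruteforce


class TestRawDistances:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 0.0),
            ("ACGT", "ACGA", 0.25),
            ("AC-T", "ACGT", 0.25),  # gap vs base counts as a difference
            ("AC--", "AC-T", 1 / 3),  # both-gap column excluded from denominator
            ("ACNT", "ACGA", 1 / 3),  # N column excluded
        ],
    )
    def test_pairwise_rules(self, a, b, expected):
        d = raw_distances(OtuSequenceSet({"x": a, "y": b}))
        assert d.values[0, 1] == pytest.approx(expected)
        assert d.values[1, 0] == pytest.approx(expected)
        assert d.values[0, 0] == 0.0

    def test_no_comparable_positions_named(self):
        seqs = OtuSequenceSet({"x": "NN--", "y": "AC--"})
        with pytest.raises(ValueError, match="x.*y"):
            raw_distances(seqs)

    def test_matrix_invariants(self, rng):
        seqs = OtuSequenceSet(
            {f"o{i}": "".join(rng.choice(list("ACGT"), size=40)) for i in range(12)}
        )
        d = raw_distances(seqs)
        assert np.allclose(d.values, d.values.T)
        assert np.all((d.values >= 0) & (d.values <= 1))


class TestSimilarity:
    def test_complement_of_distance(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 0.25], [0.25, 0.0]]))
        Z = similarity_from_distances(d)
        assert Z.values[0, 1] == 0.75
        assert np.allclose(np.diag(Z.values), 1.0)


class TestLeinsterCobbold:
    def test_identity_similarity_recovers_richness(self):
        Z = SimilarityMatrix.identity(["a", "b", "c", "d"])
        p = np.full(4, 0.25)
        assert leinster_cobbold(p, Z, 0.0) == pytest.approx(4.0)

    def test_all_identical_otus_give_unit_diversity(self, rng):
        ids = [f"o{i}" for i in range(5)]
        Z = SimilarityMatrix(ids, np.ones((5, 5)))
        p = rng.dirichlet(np.ones(5))
        for q in (0.0, 0.5, 1.0, 2.0, math.inf):
            assert leinster_cobbold(p, Z, q) == pytest.approx(1.0)

    def test_inverse_simpson(self):
        Z = SimilarityMatrix.identity(["a", "b"])
        assert leinster_cobbold(np.array([0.5, 0.5]), Z, 2.0) == pytest.approx(2.0)

    def test_three_otu_bruteforce_and_q1_limit(self):
        ids = ["a", "b", "c"]
        Zm = np.full((3, 3), 0.9)
        np.fill_diagonal(Zm, 1.0)
        Z = SimilarityMatrix(ids, Zm)
        p = np.array([0.6, 0.3, 0.1])
        got = leinster_cobbold(p, Z, 2.0)
        assert got == pytest.approx(
            similarity_diversity_bruteforce(p, Zm, 2.0), abs=1e-12
        )
        d1 = leinster_cobbold(p, Z, 1.0)
        lo = leinster_cobbold(p, Z, 1.0 + 1e-6)
        hi = leinster_cobbold(p, Z, 1.0 - 1e-6)
        assert min(lo, hi) <= d1 <= max(lo, hi)

    @pytest.mark.parametrize("q", [0.0, 0.5, 1.0, 2.0, 5.0, math.inf])
    def test_matches_classical_hill_under_identity(self, rng, q):
        p = rng.dirichlet(np.ones(8))
        Z = SimilarityMatrix.identity([f"o{i}" for i in range(8)])
        assert leinster_cobbold(p, Z, q) == pytest.approx(classical_hill(p, q), abs=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_monotone_in_q_and_range(self, draw_seed):
        rng = np.random.default_rng(draw_seed)
        n = int(rng.integers(2, 8))
        p = rng.dirichlet(np.ones(n))
        d = rng.uniform(0, 1, size=(n, n))
        d = np.triu(d, 1)
        d = d + d.T
        Z = SimilarityMatrix([f"o{i}" for i in range(n)], 1.0 - d)
        qs = [0.0, 0.5, 1.0, 2.0, 4.0, math.inf]
        values = [leinster_cobbold(p, Z, q) for q in qs]
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))
        assert 1.0 - 1e-9 <= values[-1]
        assert values[0] <= np.count_nonzero(p) + 1e-9

    def test_replication_invariance_of_identical_otus(self, rng):
        # merging two OTUs with identical sequences leaves D unchanged
        ids = ["a", "a2", "b", "c"]
        d = np.array(
            [
                [0.0, 0.0, 0.3, 0.4],
                [0.0, 0.0, 0.3, 0.4],
                [0.3, 0.3, 0.0, 0.2],
                [0.4, 0.4, 0.2, 0.0],
            ]
        )
        Z = SimilarityMatrix(ids, 1.0 - d)
        p = np.array([0.25, 0.15, 0.35, 0.25])
        merged_Z = SimilarityMatrix(["a", "b", "c"], 1.0 - d[np.ix_([0, 2, 3], [0, 2, 3])])
        merged_p = np.array([0.4, 0.35, 0.25])
        for q in (0.5, 1.0, 2.0):
            assert leinster_cobbold(p, Z, q) == pytest.approx(
                leinster_cobbold(merged_p, merged_Z, q), abs=1e-9
            )

    def test_invalid_inputs(self):
        Z = SimilarityMatrix.identity(["a", "b"])
        with pytest.raises(ValueError):
            leinster_cobbold(np.array([0.6, 0.6]), Z, 1.0)
        with pytest.raises(ValueError):
            leinster_cobbold(np.array([0.5, 0.5]), Z, -1.0)


class TestDiversityPhenotypes:
    def _norm(self, values, otu_ids, sample_ids):
        return NormalizedAbundanceTable(
            otu_ids, sample_ids, np.asarray(values, float), np.ones(len(sample_ids))
        )

    def test_single_otu_sample_has_unit_diversity(self):
        norm = self._norm([[10.0, 5.0], [0.0, 5.0]], ["a", "b"], ["s1", "s2"])
        Zm = np.array([[1.0, 0.4], [0.4, 1.0]])
        Z = SimilarityMatrix(["a", "b"], Zm)
        for q in (0.0, 1.0, 2.0):
            traits = diversity_phenotypes(norm, Z, q)
            assert traits[0].D == pytest.approx(1.0)

    def test_duplicated_samples_duplicate_traits(self):
        norm = self._norm([[3.0, 3.0], [7.0, 7.0]], ["a", "b"], ["s1", "s2"])
        Z = SimilarityMatrix.identity(["a", "b"])
        traits = diversity_phenotypes(norm, Z, 1.0)
        assert traits[0].D == pytest.approx(traits[1].D)

    def test_matches_scalar_loop(self, rng):
        values = rng.random((50, 100)) * (rng.random((50, 100)) < 0.4)
        values[0] += 0.5
        otus = [f"o{i}" for i in range(50)]
        norm = self._norm(values, otus, [f"s{j}" for j in range(100)])
        d = rng.uniform(0, 0.5, size=(50, 50))
        d = np.triu(d, 1)
        d = d + d.T
        Z = SimilarityMatrix(otus, 1.0 - d)
        traits = diversity_phenotypes(norm, Z, 1.0)
        for j in (0, 17, 99):
            p = values[:, j] / values[:, j].sum()
            assert traits[j].D == pytest.approx(leinster_cobbold(p, Z, 1.0), abs=1e-12)

    def test_axis_mismatch_rejected(self):
        norm = self._norm([[1.0, 1.0]], ["a"], ["s1", "s2"])
        Z = SimilarityMatrix.identity(["b"])
        with pytest.raises(ValueError):
            diversity_phenotypes(norm, Z, 1.0)
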