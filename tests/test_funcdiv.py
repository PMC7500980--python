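"""Gower dissimilarity, corrected PCoA and functional dispersion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from mothdrift import funcdiv, traits
from mothdrift.funcdiv import DissimilarityMatrix
from mothdrift.synthetic_data import generate_species_pool
from mothdrift.traits import BINARY, CATEGORICAL, QUANTITATIVE, FunctionalMatrix


def _fm(data: dict, types: dict, weights=None) -> FunctionalMatrix:
    df = pd.DataFrame(data)
    return FunctionalMatrix(df, types, weights or {c: 1.0 for c in df.columns})


def euclid_dm(points, labels=None) -> DissimilarityMatrix:
    pts = np.asarray(points, dtype=float)
    labels = labels or [f"p{i}" for i in range(len(pts))]
    return DissimilarityMatrix(labels, squareform(pdist(pts)))


class TestGower:
    def test_identical_rows_have_zero_distance(self):
        fm = _fm({"a": [1.0, 1.0], "b": ["x", "x"]}, {"a": QUANTITATIVE, "b": CATEGORICAL})
        d = funcdiv.gower_matrix(fm, ranges={"a": 1.0})
        assert d.values[0, 1] == 0.0

    def test_all_binary_mismatch_is_one(self):
        fm = _fm(
            {"a": [True, False], "b": [False, True], "c": [True, False]},
            {"a": BINARY, "b": BINARY, "c": BINARY},
        )
        assert funcdiv.gower_matrix(fm).values[0, 1] == 1.0

    def test_hand_computed_mixed_example(self):
        # wingspans 30 vs 40 with declared range 20 (0.5), one binary and one
        # categorical mismatch (1 each): mean = (0.5 + 1 + 1)/3
        fm = _fm(
            {"w": [30.0, 40.0], "b": [True, False], "c": ["woody", "herb"]},
            {"w": QUANTITATIVE, "b": BINARY, "c": CATEGORICAL},
        )
        d = funcdiv.gower_matrix(fm, ranges={"w": 20.0})
        assert d.values[0, 1] == pytest.approx(0.833333, abs=1e-6)

    def test_entries_in_unit_interval_and_symmetric(self, small_pool):
        fm = traits.build_functional_matrix(small_pool)
        d = funcdiv.gower_matrix(fm).values
        assert d.min() >= 0 and d.max() <= 1 + 1e-12
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_row_order_invariance(self, small_pool):
        fm1 = traits.build_functional_matrix(small_pool)
        order = list(small_pool["species_id"].sample(frac=1.0, random_state=5))
        fm2 = traits.build_functional_matrix(small_pool, species_order=order)
        d1 = funcdiv.gower_matrix(fm1).to_frame().loc[order, order]
        d2 = funcdiv.gower_matrix(fm2).to_frame()
        pd.testing.assert_frame_equal(d1, d2)

    @given(st.floats(0.1, 50), st.floats(-100, 100))
    @settings(max_examples=30, deadline=None)
    def test_affine_rescaling_of_quantitative_column_cancels(self, scale, shift):
        vals = np.array([3.0, 9.0, 27.0, 5.0])
        base = _fm({"w": vals, "c": ["a", "b", "a", "c"]}, {"w": QUANTITATIVE, "c": CATEGORICAL})
        scaled = _fm({"w": vals * scale + shift, "c": ["a", "b", "a", "c"]},
                     {"w": QUANTITATIVE, "c": CATEGORICAL})
        np.testing.assert_allclose(
            funcdiv.gower_matrix(base).values, funcdiv.gower_matrix(scaled).values, atol=1e-9
        )

    def test_missing_values_excluded_pairwise(self):
        fm = _fm(
            {"w": [1.0, np.nan, 3.0], "b": [True, True, False]},
            {"w": QUANTITATIVE, "b": BINARY},
        )
        d = funcdiv.gower_matrix(fm, ranges={"w": 2.0})
        # pair (0,1): only the binary trait observed in both -> d = 0
        assert d.values[0, 1] == 0.0
        # pair (0,2): (|1-3|/2 + 1)/2
        assert d.values[0, 2] == pytest.approx(1.0)

    def test_all_missing_pair_errors(self):
        fm = _fm({"w": [1.0, np.nan], "b": [None, True]}, {"w": QUANTITATIVE, "b": BINARY})
        with pytest.raises(ValueError, match="shares no observed trait"):
            funcdiv.gower_matrix(fm, ranges={"w": 1.0})

    def test_zero_range_column_dropped(self):
        fm = _fm({"w": [5.0, 5.0], "c": ["x", "y"]}, {"w": QUANTITATIVE, "c": CATEGORICAL})
        d = funcdiv.gower_matrix(fm)
        assert d.values[0, 1] == 1.0  # only the categorical column remains


class TestPCoA:
    def test_two_points_embed_at_plus_minus_half_distance(self):
        D = DissimilarityMatrix(["a", "b"], np.array([[0.0, 0.8], [0.8, 0.0]]))
        emb = funcdiv.pcoa_embed(D, correction="none")
        assert emb.coordinates.shape[1] == 1
        np.testing.assert_allclose(np.sort(emb.coordinates[:, 0]), [-0.4, 0.4], atol=1e-12)

    def test_planar_distances_recovered(self, rng):
        pts = rng.random((4, 2)) * 3
        D = euclid_dm(pts)
        emb = funcdiv.pcoa_embed(D, correction="none")
        rec = squareform(pdist(emb.coordinates))
        np.testing.assert_allclose(rec, D.values, atol=1e-8)

    def test_semimetric_triggers_sqrt_correction(self):
        # violates Euclidean embeddability (near-degenerate triangle blowup)
        d = np.array([
            [0, 1, 1, 1.9],
            [1, 0, 1, 1],
            [1, 1, 0, 1],
            [1.9, 1, 1, 0.0],
        ])
        D = DissimilarityMatrix(list("abcd"), d)
        with pytest.raises(ValueError, match="not Euclidean-embeddable"):
            funcdiv.pcoa_embed(D, correction="none")
        emb = funcdiv.pcoa_embed(D, correction="sqrt")
        assert emb.correction_applied == "sqrt"
        rec = squareform(pdist(emb.coordinates))
        np.testing.assert_allclose(rec, np.sqrt(d), atol=1e-8)

    @pytest.mark.parametrize("correction", ["cailliez", "lingoes"])
    def test_additive_corrections_remove_negative_eigenvalues(self, correction):
        d = np.array([
            [0, 1, 1, 1.9],
            [1, 0, 1, 1],
            [1, 1, 0, 1],
            [1.9, 1, 1, 0.0],
        ])
        emb = funcdiv.pcoa_embed(DissimilarityMatrix(list("abcd"), d), correction=correction)
        assert emb.correction_applied == correction
        assert (emb.eigenvalues > 0).all()

    def test_matches_reference_pcoa_eigenvalues(self, small_pool):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as sk_pcoa

        fm = traits.build_functional_matrix(small_pool)
        G = funcdiv.gower_matrix(fm)
        ours = funcdiv.pcoa_embed(G, correction="sqrt")
        ref = sk_pcoa(skbio.DistanceMatrix(np.sqrt(G.values), ids=G.labels))
        ev_ref = np.sort(ref.eigvals.values)[::-1][: len(ours.eigenvalues)]
        np.testing.assert_allclose(np.sort(ours.eigenvalues)[::-1], ev_ref, atol=1e-10)


class TestFDis:
    def test_coincident_species_give_zero(self):
        D = DissimilarityMatrix(list("abc"), np.zeros((3, 3)))
        emb = funcdiv.pcoa_embed(D, correction="none")
        assert funcdiv.fdis(emb, np.ones(3)).value == 0.0

    def test_two_species_at_distance_d_give_half_d(self):
        D = DissimilarityMatrix(["a", "b"], np.array([[0.0, 0.6], [0.6, 0.0]]))
        emb = funcdiv.pcoa_embed(D, correction="none")
        assert funcdiv.fdis(emb, np.ones(2)).value == pytest.approx(0.3)

    def test_unit_square_corners(self):
        emb = funcdiv.pcoa_embed(
            euclid_dm([[0, 0], [1, 0], [0, 1], [1, 1]]), correction="none"
        )
        assert funcdiv.fdis(emb, np.ones(4)).value == pytest.approx(np.sqrt(2) / 2, abs=1e-10)

    def test_single_present_species_is_zero_with_note(self):
        emb = funcdiv.pcoa_embed(euclid_dm([[0, 0], [1, 0], [0, 1]]), correction="none")
        res = funcdiv.fdis(emb, np.array([0.0, 1.0, 0.0]))
        assert res.value == 0.0 and "single" in res.note

    def test_all_zero_weights_error(self):
        emb = funcdiv.pcoa_embed(euclid_dm([[0, 0], [1, 0]]), correction="none")
        with pytest.raises(ValueError, match="all weights zero"):
            funcdiv.fdis(emb, np.zeros(2))

    def test_weight_scaling_invariance(self, rng):
        emb = funcdiv.pcoa_embed(euclid_dm(rng.random((6, 3))), correction="none")
        w = rng.random(6)
        a = funcdiv.fdis(emb, w).value
        b = funcdiv.fdis(emb, 10.0 * w).value
        assert a == pytest.approx(b, rel=1e-12)

    def test_duplicating_a_species_with_summed_weight_is_invariant(self, rng):
        pts = rng.random((5, 2))
        emb1 = funcdiv.pcoa_embed(euclid_dm(pts), correction="none")
        base = funcdiv.fdis(emb1, np.array([2.0, 1, 1, 1, 1])).value
        pts2 = np.vstack([pts, pts[0]])
        emb2 = funcdiv.pcoa_embed(euclid_dm(pts2), correction="none")
        dup = funcdiv.fdis(emb2, np.array([1.0, 1, 1, 1, 1, 1])).value
        assert dup == pytest.approx(base, abs=1e-10)

    def test_euclidean_limit_matches_direct_computation(self, rng):
        pts = rng.random((8, 3))
        w = rng.random(8) + 0.1
        emb = funcdiv.pcoa_embed(euclid_dm(pts), correction="none")
        c = (w[:, None] * pts).sum(axis=0) / w.sum()
        direct = float((w * np.linalg.norm(pts - c, axis=1)).sum() / w.sum())
        assert funcdiv.fdis(emb, w).value == pytest.approx(direct, abs=1e-10)


class TestBruteOracle:
    def test_agrees_with_production_on_mixed_fixtures(self, rng):
        for rep in range(10):
            pool = generate_species_pool(n_species=12, seed=500 + rep)
            fm = traits.build_functional_matrix(pool)
            D = funcdiv.gower_matrix(fm)
            emb = funcdiv.pcoa_embed(D)
            w = (rng.random(12) < 0.7).astype(float)
            if w.sum() == 0:
                w[0] = 1.0
            assert funcdiv.fdis(emb, w).value == pytest.approx(
                funcdiv.fdis_brute_oracle(D, w), abs=1e-8
            )

    def test_zero_on_constant_trait_matrix(self):
        D = DissimilarityMatrix(list("abcd"), np.zeros((4, 4)))
        assert funcdiv.fdis_brute_oracle(D, np.ones(4)) == 0.0

    def test_monotone_under_radial_expansion(self, rng):
        pts = rng.random((7, 2))
        centred = pts - pts.mean(axis=0)
        small = funcdiv.fdis_brute_oracle(euclid_dm(centred), np.ones(7))
        big = funcdiv.fdis_brute_oracle(euclid_dm(2 * centred), np.ones(7))
        assert big >= small
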