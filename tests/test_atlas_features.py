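"""Functional-connectivity feature extraction: formulas, ordering, oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from maacnn.atlas import (AtlasSpec, DegenerateSignalWarning, ROITimeSeries,
                          build_view_features, connectivity_matrix,
                          feature_count, pearson_correlation,
                          vectorize_lower_triangle)


def oracle_pearson(u, v):
    """Textbook covariance/sigma formula, coded independently of the package."""
    n = len(u)
    mu = sum(u) / n
    mv = sum(v) / n
    cov = sum((a - mu) * (b - mv) for a, b in zip(u, v))
    su = math.sqrt(sum((a - mu) ** 2 for a in u))
    sv = math.sqrt(sum((b - mv) ** 2 for b in v))
    return cov / (su * sv)


class TestPearson:
    def test_positive_affine_image_is_one(self):
        assert pearson_correlation((1, 2, 3, 4), (2, 4, 6, 8)) == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        assert pearson_correlation((1, 2, 3, 4), (-1, -2, -3, -4)) == pytest.approx(-1.0)

    def test_against_textbook_oracle(self):
        # oracle_pearson((1,2,3,4),(1,3,2,4)) = 4/5, frozen
        assert pearson_correlation((1, 2, 3, 4), (1, 3, 2, 4)) == pytest.approx(0.8)
        assert oracle_pearson((1, 2, 3, 4), (1, 3, 2, 4)) == pytest.approx(0.8)

    def test_symmetric_in_arguments(self, rng):
        u, v = rng.standard_normal((2, 20))
        assert pearson_correlation(u, v) == pearson_correlation(v, u)

    def test_zero_variance_warns_and_returns_zero(self):
        with pytest.warns(DegenerateSignalWarning):
            assert pearson_correlation((3, 3, 3), (1, 2, 3)) == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation((1,), (2,))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1),
           st.floats(0.1, 10), st.floats(-5, 5), st.floats(0.1, 10), st.floats(-5, 5))
    def test_invariant_under_positive_affine_transforms(self, seed, a1, b1, a2, b2):
        g = np.random.default_rng(seed)
        u = g.standard_normal(15)
        v = g.standard_normal(15)
        r = pearson_correlation(u, v)
        assert pearson_correlation(a1 * u + b1, a2 * v + b2) == pytest.approx(r, abs=1e-10)


class TestFeatureCount:
    @pytest.mark.parametrize("n,expected", [(116, 6670), (200, 19900), (111, 6105),
                                            (160, 12720), (2, 1)])
    def test_known_parcellations(self, n, expected):
        assert feature_count(n) == expected

    def test_invalid_atlas(self):
        with pytest.raises(ValueError):
            feature_count(1)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(2, 300))
    def test_matches_pair_enumeration(self, n):
        assert feature_count(n) == len(list(itertools.combinations(range(n), 2)))
        assert AtlasSpec("x", n).feature_dim == feature_count(n)


def _ts(data, name="t", n=None):
    data = np.asarray(data, float)
    return ROITimeSeries(name, AtlasSpec("a", data.shape[1]), data)


class TestConnectivityMatrix:
    def test_perfectly_correlated_pair(self):
        t = np.arange(10.0)
        fc = connectivity_matrix(_ts(np.c_[t, 2 * t + 1]))
        np.testing.assert_allclose(fc.values, np.ones((2, 2)), atol=1e-12)

    def test_orthogonal_mean_zero_columns(self):
        x = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], float)
        fc = connectivity_matrix(_ts(x))
        np.testing.assert_allclose(fc.values, np.eye(2), atol=1e-12)

    def test_matches_bruteforce_double_loop(self, rng):
        x = rng.standard_normal((30, 5))
        fc = connectivity_matrix(_ts(x)).values
        for i in range(5):
            for j in range(5):
                assert fc[i, j] == pytest.approx(
                    oracle_pearson(x[:, i], x[:, j]), abs=1e-10)

    def test_constant_column_zeroed_with_warning(self, rng):
        x = rng.standard_normal((20, 3))
        x[:, 1] = 7.0
        with pytest.warns(DegenerateSignalWarning, match=r"\[1\]"):
            fc = connectivity_matrix(_ts(x)).values
        assert np.all(fc[1, :] == 0) and np.all(fc[:, 1] == 0)
        assert fc[0, 0] == 1.0 and fc[2, 2] == 1.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            _ts(np.zeros((1, 3)))


class TestVectorize:
    def test_two_by_two(self):
        out = vectorize_lower_triangle(np.array([[1.0, 0.3], [0.3, 1.0]]))
        np.testing.assert_array_equal(out.values, [0.3])

    def test_row_major_ordering(self):
        m = np.eye(3)
        m[1, 0] = m[0, 1] = 0.1  # a = (1,0)
        m[2, 0] = m[0, 2] = 0.2  # b = (2,0)
        m[2, 1] = m[1, 2] = 0.3  # c = (2,1)
        np.testing.assert_array_equal(vectorize_lower_triangle(m).values,
                                      [0.1, 0.2, 0.3])

    def test_matches_index_pair_enumeration_oracle(self, rng):
        a = rng.standard_normal((4, 4))
        m = (a + a.T) / 2
        # independent enumeration: (i, j) for i in rows, j < i
        oracle = [m[i, j] for i in range(4) for j in range(i)]
        np.testing.assert_array_equal(vectorize_lower_triangle(m).values, oracle)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            vectorize_lower_triangle(np.zeros((3, 4)))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1), st.integers(2, 12))
    def test_roundtrip_recovers_off_diagonal(self, seed, n):
        g = np.random.default_rng(seed)
        a = g.standard_normal((n, n))
        m = (a + a.T) / 2
        vec = vectorize_lower_triangle(m).values
        assert len(vec) == feature_count(n)
        rec = np.zeros((n, n))
        i, j = np.tril_indices(n, -1)
        rec[i, j] = vec
        rec = rec + rec.T
        np.testing.assert_array_equal(rec[i, j], m[i, j])
        np.testing.assert_array_equal(rec.T[i, j], m.T[i, j])


class TestBuildViewFeatures:
    def test_shape_and_determinism(self, rng):
        atlas = AtlasSpec("toy", 5)
        data = rng.standard_normal((30, 5))
        cohort = [ROITimeSeries("s1", atlas, data),
                  ROITimeSeries("s2", atlas, rng.standard_normal((30, 5))),
                  ROITimeSeries("s3", atlas, data)]  # s3 duplicates s1
        table = build_view_features(cohort, atlas)
        assert table.shape == (3, atlas.feature_dim)
        np.testing.assert_array_equal(table.loc["s1"], table.loc["s3"])
        assert np.all(np.abs(table.to_numpy()) <= 1.0)

    def test_empty_cohort(self):
        atlas = AtlasSpec("toy", 4)
        table = build_view_features([], atlas)
        assert table.shape == (0, 6)

    def test_mixed_atlases_rejected(self, rng):
        a5, a6 = AtlasSpec("a5", 5), AtlasSpec("a6", 6)
        cohort = [ROITimeSeries("s1", a5, rng.standard_normal((20, 5))),
                  ROITimeSeries("s2", a6, rng.standard_normal((20, 6)))]
        with pytest.raises(ValueError, match="mixed atlases"):
            build_view_features(cohort, a5)
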