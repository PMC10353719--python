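"""Distance-correlation machinery against brute-force oracles and identities."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sidcor import dcor_core as dc
from sidcor import io_validate as iov

import oracle

# Frozen from the independent double-loop oracle (x = 1..20, y = x^2).
DCOR_1TO20_SQUARED = 0.9842661378167491


def _fm(values, names=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    names = names or tuple(f"F{j}" for j in range(m))
    return iov.validate(iov.RawTable(
        tuple(f"S{i}" for i in range(n)), tuple(names), values))


class TestDistanceMatrices:
    def test_pairwise_definition(self):
        np.testing.assert_array_equal(
            dc.pairwise_distance([0.0, 3.0]), [[0, 3], [3, 0]])

    def test_constant_vector_all_zero(self):
        np.testing.assert_array_equal(
            dc.pairwise_distance(np.full(5, 2.5)), np.zeros((5, 5)))

    def test_pairwise_matches_double_loop(self, rng):
        x = rng.normal(size=10)
        np.testing.assert_array_equal(dc.pairwise_distance(x),
                                      oracle.dist_loop(list(x)))

    def test_joint_single_column_reduces_to_pairwise(self, rng):
        x = rng.normal(size=7)
        np.testing.assert_allclose(dc.joint_distance(x[:, None]),
                                   dc.pairwise_distance(x), atol=1e-14)

    def test_joint_pythagoras(self):
        block = np.array([[0.0, 0.0], [1.0, 1.0]])
        assert dc.joint_distance(block)[0, 1] == pytest.approx(math.sqrt(2))

    def test_joint_matches_double_loop(self, rng):
        block = rng.normal(size=(8, 4))
        np.testing.assert_allclose(
            dc.joint_distance(block),
            oracle.joint_dist_loop([list(r) for r in block]), atol=1e-12)


class TestDoubleCenter:
    def test_two_point_hand_value(self):
        delta = 1.7
        c = dc.double_center(np.array([[0.0, delta], [delta, 0.0]])).c
        np.testing.assert_allclose(
            c, [[-delta / 2, delta / 2], [delta / 2, -delta / 2]], atol=1e-14)

    def test_all_zero(self):
        np.testing.assert_array_equal(
            dc.double_center(np.zeros((4, 4))).c, np.zeros((4, 4)))

    def test_matches_elementwise_oracle_and_sums_vanish(self, rng):
        x = rng.normal(size=7)
        d = dc.pairwise_distance(x)
        cd = dc.double_center(d)
        np.testing.assert_allclose(cd.c, oracle.center_loop(
            [list(r) for r in d]), atol=1e-12)
        tol = 1e-10 * d.shape[0] * max(1.0, d.max())
        assert np.abs(cd.c.sum(axis=0)).max() < tol
        assert np.abs(cd.c.sum(axis=1)).max() < tol


class TestDcovDcor:
    def test_dcov2_of_self_is_dvar(self, rng):
        A = dc.double_center(dc.pairwise_distance(rng.normal(size=9)))
        assert dc.dcov2(A, A) == pytest.approx(dc.dvar(A), abs=0)

    def test_all_zero_centered_gives_zero(self):
        A = dc.double_center(np.zeros((5, 5)))
        assert dc.dcov2(A, A) == 0.0

    def test_dcov2_matches_double_loop(self, rng):
        A = dc.double_center(dc.pairwise_distance(rng.normal(size=9)))
        B = dc.double_center(dc.pairwise_distance(rng.normal(size=9)))
        want = oracle.dcov2_loop([list(r) for r in A.c], [list(r) for r in B.c])
        assert dc.dcov2(A, B) == pytest.approx(want, abs=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        A = dc.double_center(dc.pairwise_distance(rng.normal(size=5)))
        B = dc.double_center(dc.pairwise_distance(rng.normal(size=6)))
        with pytest.raises(iov.SidcorError):
            dc.dcov2(A, B)

    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=12)
        assert dc.dcor_pair(x, x).dcor == pytest.approx(1.0, abs=1e-12)

    def test_n2_pairs_give_one(self):
        r = dc.dcor_pair(np.array([1.0, 5.0]), np.array([2.0, -7.0]))
        assert r.dcor == pytest.approx(1.0, abs=1e-12)

    def test_quadratic_matches_independent_oracle(self):
        x = np.arange(1.0, 21.0)
        r = dc.dcor_pair(x, x ** 2)
        assert r.dcor == pytest.approx(DCOR_1TO20_SQUARED, abs=1e-12)
        assert r.dcor == pytest.approx(
            oracle.dcor_loop(list(x), list(x ** 2)), abs=1e-12)

    def test_zero_dvar_rejected(self):
        with pytest.raises(dc.DegenerateFeatureError):
            dc.dcor_from_stats(0.0, 0.0, 1.0)


class TestMatrixModes:
    def test_duplicated_feature_gives_off_diagonal_one(self, rng):
        x = rng.normal(size=10)
        res = dc.one_to_one_matrix(_fm(np.column_stack([x, x.copy()])))
        assert res.dcor[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_two_feature_matrix_equals_direct_call(self, rng):
        vals = rng.normal(size=(11, 2))
        res = dc.one_to_one_matrix(_fm(vals))
        direct = dc.dcor_pair(vals[:, 0], vals[:, 1])
        assert res.dcor[0, 1] == direct.dcor
        assert res.pair(0, 1).dcov2 == direct.dcov2

    def test_grid_symmetric_in_range_unit_diagonal(self, rng):
        res = dc.one_to_one_matrix(_fm(rng.normal(size=(50, 10))))
        assert np.array_equal(res.dcor, res.dcor.T)
        np.testing.assert_array_equal(np.diag(res.dcor), 1.0)
        assert np.all((res.dcor >= 0.0) & (res.dcor <= 1.0))

    def test_constant_feature_excluded_from_grid(self, rng):
        vals = rng.normal(size=(10, 3))
        vals[:, 1] = 4.0
        res = dc.one_to_one_matrix(_fm(vals))
        assert res.features == ("F0", "F2")
        assert res.dcor.shape == (2, 2)

    def test_fewer_than_two_usable_features_rejected(self, rng):
        vals = np.column_stack([rng.normal(size=8), np.full(8, 1.0)])
        with pytest.raises(iov.SidcorError):
            dc.one_to_one_matrix(_fm(vals))

    def test_one_to_all_reduces_to_pair_at_m2(self, rng):
        vals = rng.normal(size=(9, 2))
        r = dc.one_to_all(_fm(vals), 0)
        assert r.dcor == pytest.approx(
            dc.dcor_pair(vals[:, 0], vals[:, 1]).dcor, abs=1e-12)

    def test_one_to_all_of_duplicate_is_one(self, rng):
        x = rng.normal(size=9)
        r = dc.one_to_all(_fm(np.column_stack([x, x.copy()])), 0)
        assert r.dcor == pytest.approx(1.0, abs=1e-12)

    def test_one_to_all_matches_explicit_loop_oracle(self, rng):
        vals = rng.normal(size=(10, 6))
        fm = _fm(vals)
        for i in range(6):
            got = dc.one_to_all(fm, i).dcor
            want = oracle.one_to_all_loop([list(r) for r in vals], i)
            assert got == pytest.approx(want, abs=1e-12)

    def test_one_to_all_constant_feature_rejected(self, rng):
        vals = rng.normal(size=(8, 3))
        vals[:, 0] = 1.0
        with pytest.raises(dc.DegenerateFeatureError):
            dc.one_to_all(_fm(vals), 0)


@st.composite
def vector_pairs(draw):
    n = draw(st.integers(3, 12))
    elems = st.floats(-50, 50, allow_nan=False)
    x = np.asarray(draw(arrays(np.float64, n, elements=elems)
                        .filter(lambda v: np.ptp(v) > 1e-3)))
    y = np.asarray(draw(arrays(np.float64, n, elements=elems)
                        .filter(lambda v: np.ptp(v) > 1e-3)))
    return x, y


class TestProperties:
    @given(vector_pairs())
    def test_symmetry(self, xy):
        x, y = xy
        assert dc.dcor_pair(x, y).dcor == dc.dcor_pair(y, x).dcor

    @given(vector_pairs(), st.sampled_from([-3.0, 0.5, 10.0]),
           st.floats(-5, 5, allow_nan=False))
    def test_affine_invariance(self, xy, a, b):
        x, y = xy
        r0 = dc.dcor_pair(x, y).dcor
        r1 = dc.dcor_pair(a * x + b, y).dcor
        assert r1 == pytest.approx(r0, abs=1e-10)

    @given(vector_pairs(), st.sampled_from([-2.0, 0.3, 7.0]),
           st.floats(-5, 5, allow_nan=False))
    def test_perfect_linear_dependence(self, xy, a, b):
        x, _ = xy
        assert dc.dcor_pair(x, a * x + b).dcor == pytest.approx(1.0, abs=1e-10)

    def test_oracle_equivalence_on_random_matrices(self, rng):
        """Every statistic matches the naive double-loop reference."""
        for _ in range(25):
            n = int(rng.integers(4, 21))
            m = int(rng.integers(2, 7))
            vals = rng.normal(size=(n, m))
            fm = _fm(vals)
            res = dc.one_to_one_matrix(fm)
            for a in range(m):
                for b in range(a + 1, m):
                    want = oracle.dcor_loop(list(vals[:, a]), list(vals[:, b]))
                    assert res.dcor[a, b] == pytest.approx(want, abs=1e-12)
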