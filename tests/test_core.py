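"""Scaling and slope-distance behaviour, checked against hand-derived values
and a literal double-loop oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smg.core import (
    _scale_vector,
    distance_matrix,
    minmax_scale,
    opposite_profile,
    slope_distance,
    validate_table,
)

from conftest import naive_slope_distance, random_table


def as_table(rows):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return pd.DataFrame(
        rows,
        index=[f"T{i}" for i in range(rows.shape[0])],
        columns=[f"S{j}" for j in range(rows.shape[1])],
    )


class TestMinMaxScale:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([0, 0, 0, 0], [0, 0, 0, 0]),  # constant rows collapse to zeros
            ([1, 0, 0], [1, 0, 0]),
            ([2, 4, 6], [0, 0.5, 1]),
            ([5, 10], [0, 1]),
            ([1, 2], [0, 1]),  # scaling removes multiplicative constants
            ([7, 7, 7], [0, 0, 0]),
        ],
    )
    def test_examples(self, row, expected):
        out = minmax_scale(as_table(row))
        np.testing.assert_allclose(out.to_numpy()[0], expected)

    def test_nonconstant_rows_span_unit_interval(self, rng):
        table = random_table(rng, 20, 8)
        scaled = minmax_scale(table)
        values = scaled.to_numpy()
        assert values.min() >= 0 and values.max() <= 1
        spans = table.max(axis=1) != table.min(axis=1)
        for i, nonconstant in enumerate(spans):
            if nonconstant:
                assert values[i].min() == 0.0 and values[i].max() == 1.0
            else:
                assert (values[i] == 0).all()

    def test_identifiers_preserved(self, toy_table):
        scaled = minmax_scale(toy_table)
        assert list(scaled.index) == list(toy_table.index)
        assert list(scaled.columns) == list(toy_table.columns)

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError, match="at least 2 samples"):
            minmax_scale(pd.DataFrame({"S1": [1.0, 2.0]}, index=["a", "b"]))


class TestValidation:
    def test_duplicate_taxa_rejected(self):
        bad = pd.DataFrame([[1, 2], [3, 4]], index=["a", "a"], columns=["S1", "S2"])
        with pytest.raises(ValueError, match="duplicate taxon"):
            validate_table(bad)

    def test_negative_value_names_cell(self):
        bad = pd.DataFrame([[1, 2], [3, -4]], index=["a", "b"], columns=["S1", "S2"])
        with pytest.raises(ValueError, match="'b'.*'S2'"):
            validate_table(bad)

    def test_missing_cell_rejected(self):
        bad = pd.DataFrame([[1, np.nan]], index=["a"], columns=["S1", "S2"])
        with pytest.raises(ValueError, match="missing value"):
            validate_table(bad)


class TestOppositeProfile:
    def test_negation(self):
        np.testing.assert_array_equal(opposite_profile([0, 1, 2]), [0, -1, -2])
        np.testing.assert_array_equal(opposite_profile([0, 0, 0]), [0, 0, 0])

    def test_scaled_opposite_is_one_minus_scaled(self):
        g = np.array([0.0, 1.0, 2.0])
        np.testing.assert_allclose(
            _scale_vector(opposite_profile(g)), 1.0 - _scale_vector(g)
        )

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=12,
        )
    )
    def test_negation_identity_property(self, row):
        row = np.asarray(row)
        if np.ptp(row) == 0:
            return  # constant rows scale to zeros on both sides of the identity
        np.testing.assert_allclose(
            _scale_vector(opposite_profile(row)),
            1.0 - _scale_vector(row),
            atol=1e-12,
        )


class TestSlopeDistance:
    def test_indicative_pair_identity(self):
        # d(O, P) = 2(n - 1): the basis of the n - 1 correlation threshold
        for n in range(2, 51):
            o = np.zeros(n)
            p = np.r_[1.0, np.zeros(n - 1)]
            assert slope_distance(o, p) == 2 * (n - 1)

    def test_hand_enumerated_example(self):
        assert slope_distance([0, 0.5, 1], [1, 0.5, 0]) == pytest.approx(8.0)

    def test_identity_and_symmetry(self, rng):
        a, b = rng.random(7), rng.random(7)
        assert slope_distance(a, a) == 0.0
        assert slope_distance(a, b) == pytest.approx(slope_distance(b, a))

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 21))
            a, b = rng.random(n), rng.random(n)
            assert slope_distance(a, b) == pytest.approx(
                naive_slope_distance(a, b), abs=1e-9
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            slope_distance([0, 1], [0, 1, 2])


class TestDistanceMatrix:
    def test_identical_and_proportional_rows_at_zero(self):
        table = as_table([[0, 1, 2], [5, 10, 15], [0, 1, 2]])
        dm = distance_matrix(table)
        assert dm.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert dm.iloc[0, 2] == 0.0

    def test_indicative_objects_in_matrix(self):
        # zero row vs unit-coordinate rows: both at d = 2(n-1) = 4 for n = 3
        table = as_table([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        dm = distance_matrix(table)
        assert dm.iloc[0, 1] == 4.0
        assert dm.iloc[0, 2] == 4.0

    def test_symmetry_zero_diagonal_and_bounds(self, rng):
        table = random_table(rng, 15, 9)
        dm = distance_matrix(table).to_numpy()
        n = 9
        np.testing.assert_allclose(dm, dm.T)
        assert np.diag(dm).max() == 0.0
        assert dm.min() >= 0.0
        assert dm.max() <= 2 * n * (n - 1)

    def test_pseudometric_triangle_inequality(self, rng):
        for _ in range(50):
            table = random_table(rng, 3, int(rng.integers(2, 10)))
            d = distance_matrix(table).to_numpy()
            assert d[0, 2] <= d[0, 1] + d[1, 2] + 1e-9

    def test_affine_invariance(self, rng):
        base = random_table(rng, 6, 8)
        c, k = 3.7, 11.0
        shifted = base * c + k
        np.testing.assert_allclose(
            distance_matrix(base).to_numpy(),
            distance_matrix(shifted).to_numpy(),
            atol=1e-9,
        )

    def test_matrix_matches_pairwise_oracle(self, rng):
        table = random_table(rng, 10, 7)
        from smg.core import _minmax_rows

        scaled = _minmax_rows(table.to_numpy())
        dm = distance_matrix(table).to_numpy()
        for i in range(10):
            for j in range(10):
                assert dm[i, j] == pytest.approx(
                    naive_slope_distance(scaled[i], scaled[j]), abs=1e-9
                )
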