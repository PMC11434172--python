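"""Min-max scaling and the slope-based distance between taxon profiles.

A taxon's abundance profile across ``n`` samples is first min-max scaled to
``[0, 1]`` (constant profiles, including all-zero taxa, map to the zero
vector).  The slope-based distance between two scaled profiles ``alpha`` and
``beta`` is the sum over *all ordered* sample index pairs ``(i, j)`` of
``|(alpha_j - alpha_i) - (beta_j - beta_i)|`` — the total disagreement in
between-sample slopes.  The ordered-pair convention (each unordered pair
counted twice) is fixed by the analytic identity ``d(O, P) = 2(n - 1)`` for
the indicative profiles ``O = (0, ..., 0)`` and ``P = (1, 0, ..., 0)``, which
underlies the positive-correlation threshold ``n - 1``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "validate_table",
    "minmax_scale",
    "opposite_profile",
    "slope_distance",
    "distance_matrix",
]


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a taxa x samples abundance table.

    Parameters
    ----------
    table : pandas.DataFrame
        Rows are taxa, columns are samples.  Values must be finite,
        non-negative reals; at least two samples are required; taxon and
        sample identifiers must be unique.

    Returns
    -------
    pandas.DataFrame
        The validated table with a float dtype.

    Raises
    ------
    ValueError
        If any invariant is violated.
    """
    if not isinstance(table, pd.DataFrame):
        raise ValueError("abundance table must be a pandas DataFrame")
    if table.shape[0] < 1:
        raise ValueError("abundance table has no taxa (rows)")
    if table.shape[1] < 2:
        raise ValueError(
            f"abundance table needs at least 2 samples, got {table.shape[1]}"
        )
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate taxon identifiers: {dups}")
    if table.columns.has_duplicates:
        dups = table.columns[table.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dups}")
    values = table.to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"missing value at taxon {table.index[r]!r}, sample {table.columns[c]!r}"
        )
    if not np.isfinite(values).all():
        raise ValueError("abundance table contains non-finite values")
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative abundance at taxon {table.index[r]!r}, "
            f"sample {table.columns[c]!r}: {values[r, c]}"
        )
    return table.astype(float)


def _minmax_rows(values: np.ndarray) -> np.ndarray:
    """Row-wise min-max scaling; constant rows map to all zeros."""
    values = np.asarray(values, dtype=float)
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = hi - lo
    constant = (span == 0).ravel()
    span[constant] = 1.0  # avoid 0/0; rows overwritten below
    scaled = (values - lo) / span
    scaled[constant] = 0.0
    return scaled


def minmax_scale(table: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each taxon's profile to ``[0, 1]``.

    For a row ``A`` with ``min A != max A`` each entry becomes
    ``(a_k - min A) / (max A - min A)``; constant rows (``min A = max A``,
    including all-zero taxa) become all zeros.  Shape and identifiers are
    preserved.
    """
    table = validate_table(table)
    return pd.DataFrame(
        _minmax_rows(table.to_numpy()), index=table.index, columns=table.columns
    )


def opposite_profile(row) -> np.ndarray:
    """Elementwise negation of a profile (``A -> A- = (-a_1, ..., -a_n)``).

    Min-max scaling the opposite of a non-constant profile yields
    ``1 - scaled(A)``, which is how negative correlation is probed.
    """
    return -np.asarray(row, dtype=float)


def _scale_vector(row) -> np.ndarray:
    """Min-max scale a single profile (constant profiles -> zeros)."""
    return _minmax_rows(np.asarray(row, dtype=float)[None, :])[0]


# Per-pair weights for the sorted-difference identity:
# sum_{i<j} (g_(j) - g_(i)) = sum_k (2k - n + 1) g_(k)  (0-indexed, g sorted).
def _ordered_pair_sum(gamma: np.ndarray) -> np.ndarray:
    """Sum of |gamma_j - gamma_i| over all ordered (i, j), rows of ``gamma``."""
    gamma = np.atleast_2d(gamma)
    n = gamma.shape[1]
    weights = 2.0 * np.arange(n) - (n - 1)
    return 2.0 * (np.sort(gamma, axis=1) @ weights)


def slope_distance(alpha, beta) -> float:
    """Slope-based distance between two min-max-scaled profiles.

    Parameters
    ----------
    alpha, beta : array-like of shape (n,)
        Scaled profiles with values in ``[0, 1]``, ``n >= 2``.

    Returns
    -------
    float
        ``sum_{i,j} |(alpha_j - alpha_i) - (beta_j - beta_i)|`` over all
        ordered index pairs.  Zero iff the two profiles differ by a constant.

    Notes
    -----
    The sum depends only on ``gamma = alpha - beta`` and is evaluated as
    ``2 * sum_{i<j} |gamma_(j) - gamma_(i)|`` via sorting, which is
    ``O(n log n)`` instead of the naive ``O(n^2)`` double loop.
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if alpha.ndim != 1 or beta.ndim != 1 or alpha.shape != beta.shape:
        raise ValueError(
            f"profiles must be 1-d and equal length, got {alpha.shape} and {beta.shape}"
        )
    if alpha.size < 2:
        raise ValueError("profiles need at least 2 samples")
    return float(_ordered_pair_sum(alpha - beta)[0])


def _pairwise_slope(scaled: np.ndarray) -> np.ndarray:
    """Pairwise slope distances between the rows of a scaled matrix."""
    scaled = np.asarray(scaled, dtype=float)
    t = scaled.shape[0]
    out = np.zeros((t, t))
    for a in range(t - 1):
        # one row against all later rows, vectorized over the pair axis
        d = _ordered_pair_sum(scaled[a + 1 :] - scaled[a])
        out[a, a + 1 :] = d
        out[a + 1 :, a] = d
    # sorting noise can leave tiny negative values on identical rows
    np.maximum(out, 0.0, out=out)
    return out


def distance_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Slope-based distance matrix between all taxa of an abundance table.

    Each row is min-max scaled, then every pair of scaled profiles is
    compared with :func:`slope_distance`.  The result is symmetric with a
    zero diagonal; taxon order is preserved.
    """
    table = validate_table(table)
    scaled = _minmax_rows(table.to_numpy())
    return pd.DataFrame(
        _pairwise_slope(scaled), index=table.index, columns=table.index
    )
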