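"""Comparison filter with proportional zeroing.

Rare taxa are min-max scaled to the same ``[0, 1]`` band as dominant taxa,
so a table with many rare rows can drown structural differences in noise.
The comparison filter keeps the smallest set of largest taxa whose cumulative
share of the grand total reaches a proportion ``p`` and *zeroes every sample*
of the remaining taxa ("proportional zeroing"), rather than dropping their
rows — zeroed rows stay in the table so that two filtered conditions keep
identical taxon sets for graph comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import validate_table

__all__ = ["FilterResult", "comparison_filter", "filter_sweep", "parse_filter_value"]


def parse_filter_value(value) -> float:
    """Normalize a filter level given as a fraction or percentage.

    ``"0.975"`` and ``"97.5"`` both parse to ``0.975``; values in ``(1, 100]``
    are treated as percentages.
    """
    p = float(value)
    if p > 1.0:
        p = p / 100.0
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"filter level must be in [0, 1] (or [0, 100] %), got {value}")
    return p


@dataclass(frozen=True)
class FilterResult:
    """Outcome of the comparison filter at level ``p``.

    Attributes
    ----------
    p : float
        Cumulative-abundance proportion to retain.
    retained_taxa : tuple
        Retained taxon identifiers, largest total first (ties keep original
        row order).
    m : int
        Number of retained taxa (``m = len(retained_taxa)``, the smallest
        count whose cumulative totals reach ``p`` of the grand total).
    filtered_table : pandas.DataFrame
        Same shape and order as the input; excluded taxa's rows are exactly
        zero, retained rows are unchanged.
    """

    p: float
    retained_taxa: tuple
    filtered_table: pd.DataFrame

    @property
    def m(self) -> int:
        return len(self.retained_taxa)


def _retained_count(sorted_totals: np.ndarray, p: float) -> int:
    """Smallest m with cumulative sorted totals >= p * grand total.

    The empty prefix (m = 0) never qualifies for p = 0 because the second
    minimality condition uses an empty sum; at least the single largest taxon
    is always retained.
    """
    csum = np.cumsum(sorted_totals)
    total = csum[-1]
    return int(np.argmax(csum >= p * total)) + 1


def comparison_filter(
    table: pd.DataFrame, p: float, totals: pd.Series | None = None
) -> FilterResult:
    """Retain the largest taxa reaching a cumulative share ``p``; zero the rest.

    Parameters
    ----------
    table : pandas.DataFrame
        Taxa x samples abundance table with a positive grand total.
    p : float
        Proportion of the grand total to retain, in ``[0, 1]``.
    totals : pandas.Series, optional
        Row totals to rank by instead of ``table``'s own row sums.  Used for
        pooled filtering of multi-condition comparisons, where totals come
        from the column-concatenated table so every condition retains the
        identical taxon set.

    Returns
    -------
    FilterResult
    """
    table = validate_table(table)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"filter level p must be in [0, 1], got {p}")
    if totals is None:
        totals = table.sum(axis=1)
    else:
        totals = totals.reindex(table.index)
        if totals.isna().any():
            raise ValueError("totals must cover every taxon in the table")
    tvals = totals.to_numpy(dtype=float)
    if tvals.sum() <= 0:
        raise ValueError("cannot filter a table whose grand total is zero")
    # stable sort: total descending, original row order breaking ties
    order = np.argsort(-tvals, kind="stable")
    m = _retained_count(tvals[order], p)
    retained_idx = order[:m]
    retained = tuple(table.index[i] for i in retained_idx)
    mask = np.zeros(len(table), dtype=bool)
    mask[retained_idx] = True
    filtered = table.copy()
    filtered.loc[~mask] = 0.0
    return FilterResult(p=float(p), retained_taxa=retained, filtered_table=filtered)


def filter_grid(p_start: float = 0.95, p_end: float = 1.0, step: float = 0.005):
    """Inclusive grid of filter levels, rounded to avoid float drift."""
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if p_start > p_end:
        raise ValueError(f"p_start {p_start} exceeds p_end {p_end}")
    n_steps = int(round((p_end - p_start) / step))
    grid = [round(p_start + k * step, 10) for k in range(n_steps + 1)]
    if grid[-1] > p_end + 1e-12:
        grid.pop()
    if not grid or grid[-1] < p_end - 1e-12:
        grid.append(round(p_end, 10))
    return grid


def filter_sweep(
    table: pd.DataFrame,
    p_start: float = 0.95,
    p_end: float = 1.0,
    step: float = 0.005,
) -> list[FilterResult]:
    """Comparison filter over a grid of levels (default 95%..100% by 0.5%)."""
    return [comparison_filter(table, p) for p in filter_grid(p_start, p_end, step)]
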