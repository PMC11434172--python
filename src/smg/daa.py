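"""Differential abundance analysis from changes in correlation structure.

Instead of per-taxon tests with p-values, SMG flags taxa whose *positive
correlation neighbourhood* changes between two conditions: both tables are
rare-taxon filtered against pooled totals (so they keep identical taxon
sets), a positive-correlation graph is built per condition (each with its own
``n - 1`` threshold), and the symmetric difference of the two graphs is
taken.  A taxon's evidence of differential abundance is its degree in the
difference graph — the number of correlations it gained or lost — and a
taxon is called differentially abundant when it carries at least a fraction
(default 5%) of all per-taxon edge changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import distance_matrix, validate_table
from .filtering import comparison_filter, filter_grid
from .graph import GraphDiff, build_positive_graph, symmetric_difference

__all__ = ["DaaReport", "smg_daa", "daa_filter_sweep", "optimal_filter"]


@dataclass(frozen=True)
class DaaReport:
    """Result of one graph-edge-change differential abundance analysis.

    Attributes
    ----------
    filter_p : float
        Comparison-filter level applied (pooled across conditions by default).
    n1, n2 : int
        Per-condition sample counts (thresholds are ``n1 - 1`` and ``n2 - 1``).
    total_changed_edges : int
        ``|E(G1 Δ G2)|``.
    per_taxon_changes : dict
        Taxon -> degree in the symmetric-difference graph.  Sums to twice
        ``total_changed_edges``.
    da_threshold_fraction : float
        A taxon is flagged when its change count is at least this fraction of
        the summed change counts.
    da_taxa : frozenset
        Taxa called differentially abundant.
    diff : GraphDiff
        The underlying symmetric difference.
    """

    filter_p: float
    n1: int
    n2: int
    da_threshold_fraction: float
    per_taxon_changes: dict
    da_taxa: frozenset
    diff: GraphDiff = field(repr=False)

    @property
    def total_changed_edges(self) -> int:
        return self.diff.magnitude

    def to_dict(self) -> dict:
        return {
            "filter_p": self.filter_p,
            "n1": self.n1,
            "n2": self.n2,
            "da_threshold_fraction": self.da_threshold_fraction,
            "total_changed_edges": self.total_changed_edges,
            "n_da_taxa": len(self.da_taxa),
            "da_taxa": sorted(map(str, self.da_taxa)),
            "per_taxon_changes": {
                str(k): int(v) for k, v in sorted(self.per_taxon_changes.items())
            },
        }


def _harmonize(table1: pd.DataFrame, table2: pd.DataFrame):
    """Check both conditions share one taxon set; align row order."""
    s1, s2 = set(table1.index), set(table2.index)
    if s1 != s2:
        raise ValueError(
            "conditions must share one taxon set; harmonize first "
            f"({len(s1 ^ s2)} mismatched taxa, e.g. {sorted(map(str, s1 ^ s2))[:5]})"
        )
    return table1, table2.reindex(table1.index)


def smg_daa(
    table1: pd.DataFrame,
    table2: pd.DataFrame,
    filter_p: float = 0.975,
    da_threshold_fraction: float = 0.05,
    filter_scope: str = "pooled",
) -> DaaReport:
    """Call differentially abundant taxa between two conditions.

    Parameters
    ----------
    table1, table2 : pandas.DataFrame
        Taxa x samples abundance tables for the two conditions, sharing one
        taxon set (each with >= 2 samples).
    filter_p : float, default 0.975
        Comparison-filter level.  Row totals are ranked on the pooled
        (column-concatenated) table by default, so both conditions retain the
        identical taxon set; set ``filter_scope='per-condition'`` to rank
        each condition by its own totals instead.
    da_threshold_fraction : float, default 0.05
        Minimum share of the summed per-taxon edge changes for a DA call.
    filter_scope : {'pooled', 'per-condition'}
        Where the ranking totals come from.

    Returns
    -------
    DaaReport
    """
    table1 = validate_table(table1)
    table2 = validate_table(table2)
    table1, table2 = _harmonize(table1, table2)
    if filter_scope not in ("pooled", "per-condition"):
        raise ValueError(f"unknown filter_scope {filter_scope!r}")

    if filter_scope == "pooled":
        pooled = pd.concat(
            [table1.add_suffix("|1", axis=1), table2.add_suffix("|2", axis=1)], axis=1
        )
        totals = pooled.sum(axis=1)
        f1 = comparison_filter(table1, filter_p, totals=totals)
        f2 = comparison_filter(table2, filter_p, totals=totals)
    else:
        f1 = comparison_filter(table1, filter_p)
        f2 = comparison_filter(table2, filter_p)

    n1, n2 = table1.shape[1], table2.shape[1]
    g1 = build_positive_graph(distance_matrix(f1.filtered_table), n_samples=n1)
    g2 = build_positive_graph(distance_matrix(f2.filtered_table), n_samples=n2)
    diff = symmetric_difference(g1, g2)
    changes = diff.degrees()
    total_degree = sum(changes.values())  # = 2 * |E(G1 Δ G2)|
    if total_degree > 0:
        cut = da_threshold_fraction * total_degree
        da = frozenset(v for v, c in changes.items() if c >= cut and c > 0)
    else:
        da = frozenset()
    return DaaReport(
        filter_p=float(filter_p),
        n1=n1,
        n2=n2,
        da_threshold_fraction=float(da_threshold_fraction),
        per_taxon_changes=changes,
        da_taxa=da,
        diff=diff,
    )


def optimal_filter(p_values, da_counts) -> float:
    """Heuristic optimal filter: the point just before the sharpest decline.

    Operates on the number of DA calls per filter level (a ground-truth-free
    proxy for an accuracy curve): the optimum is the grid point immediately
    preceding the largest *relative* drop in call counts between consecutive
    levels.  With no drop anywhere, the last grid point is returned.
    """
    p_values = list(p_values)
    da_counts = list(da_counts)
    if len(p_values) != len(da_counts) or not p_values:
        raise ValueError("need one DA count per filter level")
    if len(p_values) == 1:
        return p_values[0]
    best_k, best_drop = None, 0.0
    for k in range(len(p_values) - 1):
        if da_counts[k] > 0:
            drop = (da_counts[k] - da_counts[k + 1]) / da_counts[k]
            if drop > best_drop:
                best_k, best_drop = k, drop
    return p_values[best_k] if best_k is not None else p_values[-1]


def daa_filter_sweep(
    table1: pd.DataFrame,
    table2: pd.DataFrame,
    p_grid=None,
    da_threshold_fraction: float = 0.05,
    filter_scope: str = "pooled",
):
    """Run :func:`smg_daa` over a grid of filter levels.

    Returns
    -------
    (reports, optimal_p) : (list of DaaReport, float)
        One report per grid point (default 95%..100% in 0.5% steps) plus the
        heuristic optimal level from :func:`optimal_filter`.
    """
    if p_grid is None:
        p_grid = filter_grid()
    reports = [
        smg_daa(table1, table2, p, da_threshold_fraction, filter_scope)
        for p in p_grid
    ]
    opt = optimal_filter(list(p_grid), [len(r.da_taxa) for r in reports])
    return reports, opt
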