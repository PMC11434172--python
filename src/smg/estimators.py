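"""scikit-learn-compatible estimators over the slope-graph primitives.

These follow the sklearn sample orientation — ``X`` is ``(n_samples,
n_taxa)``, i.e. the *transpose* of the field's taxa x samples tables — so
they compose with pipelines and model selection:

* :class:`SlopeDistance` — covariance-estimator-shaped: ``fit(X)`` exposes
  the taxa x taxa slope-distance matrix as ``distance_matrix_``.
* :class:`SlopeNetwork` — graphical-model-shaped: ``fit(X)`` builds the
  positive-correlation graph over taxa and labels each taxon with its
  connected component (``labels_``).
* :class:`CumulativeAbundanceFilter` — transformer applying the comparison
  filter with proportional zeroing to taxon columns.
* :class:`SlopeGraphDAA` — feature selector: ``fit(X, y)`` with a two-group
  sample label ``y`` runs the graph-edge-change differential abundance
  pipeline; ``get_support()`` marks the DA taxa.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .core import _minmax_rows, _pairwise_slope, validate_table
from .filtering import comparison_filter
from .graph import build_positive_graph, connected_components

__all__ = [
    "SlopeDistance",
    "SlopeNetwork",
    "CumulativeAbundanceFilter",
    "SlopeGraphDAA",
]


def _as_table(X) -> pd.DataFrame:
    """sklearn-oriented input (samples x taxa) -> taxa x samples DataFrame."""
    if isinstance(X, pd.DataFrame):
        table = X.T.copy()
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-d, got shape {X.shape}")
        table = pd.DataFrame(
            X.T,
            index=[f"taxon{i}" for i in range(X.shape[1])],
            columns=[f"sample{j}" for j in range(X.shape[0])],
        )
    return validate_table(table)


class SlopeDistance(BaseEstimator):
    """Pairwise slope-based distances between taxa.

    ``fit(X)`` min-max scales each taxon profile (a column of ``X``) and
    stores all pairwise slope distances, in the spirit of sklearn's
    covariance estimators.

    Attributes
    ----------
    distance_matrix_ : pandas.DataFrame of shape (n_taxa, n_taxa)
        Symmetric, zero-diagonal slope-distance matrix.
    n_samples_ : int
        Number of samples the distances were computed over.
    """

    def fit(self, X, y=None):
        table = _as_table(X)
        scaled = _minmax_rows(table.to_numpy())
        self.distance_matrix_ = pd.DataFrame(
            _pairwise_slope(scaled), index=table.index, columns=table.index
        )
        self.distance_matrix_.attrs["n_samples"] = table.shape[1]
        self.n_samples_ = table.shape[1]
        self.n_features_in_ = table.shape[0]
        return self

    def fit_transform(self, X, y=None):
        """Fit and return the distance matrix as an array."""
        return self.fit(X).distance_matrix_.to_numpy()


class SlopeNetwork(BaseEstimator):
    """Positive-correlation network and clusters over taxa.

    ``fit(X)`` computes slope distances and links taxa closer than the
    ``n_samples - 1`` threshold; connected components are the clusters.

    Attributes
    ----------
    graph_ : networkx.Graph
        The positive-correlation graph over taxa.
    components_ : list of set
        Connected components, sorted by smallest member.
    labels_ : ndarray of shape (n_taxa,)
        Component index per taxon (the clustering labels).
    threshold_ : float
        The edge threshold ``n_samples - 1``.
    """

    def fit(self, X, y=None):
        table = _as_table(X)
        est = SlopeDistance().fit(X)
        self.distance_matrix_ = est.distance_matrix_
        self.n_samples_ = est.n_samples_
        self.threshold_ = float(est.n_samples_ - 1)
        self.graph_ = build_positive_graph(
            self.distance_matrix_, n_samples=est.n_samples_
        )
        self.components_ = connected_components(self.graph_)
        membership = {
            taxon: k for k, comp in enumerate(self.components_) for taxon in comp
        }
        self.labels_ = np.array([membership[t] for t in table.index])
        self.n_features_in_ = table.shape[0]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class CumulativeAbundanceFilter(TransformerMixin, BaseEstimator):
    """Comparison filter with proportional zeroing as a transformer.

    Parameters
    ----------
    p : float, default 0.975
        Cumulative-abundance share to retain.  The smallest set of
        largest-total taxa reaching ``p`` of the grand total is kept;
        all other taxon columns are zeroed (not dropped).
    """

    def __init__(self, p: float = 0.975):
        self.p = p

    def fit(self, X, y=None):
        table = _as_table(X)
        result = comparison_filter(table, self.p)
        retained = set(result.retained_taxa)
        self.support_ = np.array([t in retained for t in table.index])
        self.retained_taxa_ = result.retained_taxa
        self.m_ = result.m
        self.n_features_in_ = table.shape[0]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            out = X.copy()
            out.loc[:, ~self.support_] = 0.0
            return out
        X = np.asarray(X, dtype=float).copy()
        X[:, ~self.support_] = 0.0
        return X

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return np.flatnonzero(self.support_) if indices else self.support_


class SlopeGraphDAA(SelectorMixin, BaseEstimator):
    """Graph-edge-change differential abundance as a feature selector.

    ``fit(X, y)`` splits the samples into the two groups given by ``y``,
    runs the pooled comparison filter, builds per-group positive-correlation
    graphs, takes their symmetric difference and flags taxa carrying at
    least ``da_threshold_fraction`` of the summed per-taxon edge changes.

    Parameters
    ----------
    filter_p : float, default 0.975
        Comparison-filter level (pooled across the two groups by default).
    da_threshold_fraction : float, default 0.05
        Minimum share of summed edge changes for a DA call.
    filter_scope : {'pooled', 'per-condition'}
        Whether filter totals are pooled over both groups.

    Attributes
    ----------
    report_ : smg.daa.DaaReport
        Full pipeline report.
    support_ : ndarray of bool, shape (n_taxa,)
        DA mask over taxa (``get_support()``).
    per_taxon_changes_ : ndarray of int
        Degree of each taxon in the symmetric-difference graph.
    """

    def __init__(
        self,
        filter_p: float = 0.975,
        da_threshold_fraction: float = 0.05,
        filter_scope: str = "pooled",
    ):
        self.filter_p = filter_p
        self.da_threshold_fraction = da_threshold_fraction
        self.filter_scope = filter_scope

    def fit(self, X, y):
        from .daa import smg_daa

        table = _as_table(X)
        y = np.asarray(y)
        if y.shape[0] != table.shape[1]:
            raise ValueError(
                f"y has {y.shape[0]} labels for {table.shape[1]} samples"
            )
        groups = np.unique(y)
        if groups.size != 2:
            raise ValueError(f"y must define exactly 2 groups, got {groups.size}")
        t1 = table.loc[:, y == groups[0]]
        t2 = table.loc[:, y == groups[1]]
        self.report_ = smg_daa(
            t1,
            t2,
            filter_p=self.filter_p,
            da_threshold_fraction=self.da_threshold_fraction,
            filter_scope=self.filter_scope,
        )
        self.support_ = np.array([t in self.report_.da_taxa for t in table.index])
        self.per_taxon_changes_ = np.array(
            [self.report_.per_taxon_changes[t] for t in table.index]
        )
        self.n_features_in_ = table.shape[0]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
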