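"""Benchmark harness: confusion metrics and the two simulation protocols.

The type-1 protocol checks that the positive-correlation graph groups every
designated positive correlate into the target's cluster and that negative
correlation calling flags exactly the designated negative rows.  The type-2
protocol scores graph-edge-change differential abundance calls against the
generator's ground truth with the accuracy ``(TP + TN) / (TP + TN + FP + FN)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import distance_matrix
from .daa import smg_daa
from .graph import build_positive_graph, connected_components, is_negative_correlation
from .simulate import Type1Spec, Type2Spec, generate_type1, generate_type2

__all__ = [
    "ConfusionMetrics",
    "score_type1_run",
    "evaluate_type1_replicate",
    "run_type1_benchmark",
    "run_type2_benchmark",
    "DEFAULT_FILTER_MAP",
]

#: Filter levels used per DA fraction in the type-2 protocol: 0.975 for
#: 3-10% DA, the more aggressive 0.955 for 20% DA.
DEFAULT_FILTER_MAP = {0.03: 0.975, 0.05: 0.975, 0.07: 0.975, 0.10: 0.975, 0.20: 0.955}


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts with derived rates.

    ``accuracy = (tp + tn) / (tp + tn + fp + fn)``;
    ``sensitivity = tp / (tp + fn)``; ``specificity = tn / (tn + fp)``.
    Rates with a zero denominator are NaN, never silently 0.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def accuracy(self) -> float:
        denom = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / denom if denom else math.nan

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else math.nan

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else math.nan

    @classmethod
    def from_sets(cls, predicted: set, truth: set, universe: set) -> "ConfusionMetrics":
        """Score a predicted member set against a true member set."""
        predicted, truth = set(predicted), set(truth)
        if not predicted <= universe or not truth <= universe:
            raise ValueError("predicted and truth sets must lie inside the universe")
        tp = len(predicted & truth)
        fp = len(predicted - truth)
        fn = len(truth - predicted)
        tn = len(universe) - tp - fp - fn
        return cls(tp=tp, tn=tn, fp=fp, fn=fn)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def score_type1_run(graph, neg_flagged: set, truth: pd.DataFrame, target_id: str):
    """Score positive- and negative-correlate recovery for one type-1 run.

    Parameters
    ----------
    graph : networkx.Graph
        Positive-correlation graph over all taxa.
    neg_flagged : set
        Taxa flagged as negatively correlated with the target.
    truth : pandas.DataFrame
        Ground-truth roles from :func:`smg.simulate.generate_type1`.
    target_id : str
        The target taxon; must be a graph vertex.

    Returns
    -------
    (positive, negative) : (ConfusionMetrics, ConfusionMetrics)
        Predicted positives are the non-target members of the target's
        connected component; predicted negatives are ``neg_flagged``.  Both
        are scored over all non-target taxa.
    """
    if target_id not in graph:
        raise ValueError(f"target {target_id!r} is not a vertex of the graph")
    component = next(c for c in connected_components(graph) if target_id in c)
    predicted_pos = component - {target_id}
    universe = set(truth.index) - {target_id}
    true_pos = set(truth.index[truth["role"] == "positive"])
    true_neg = set(truth.index[truth["role"] == "negative"])
    pos = ConfusionMetrics.from_sets(predicted_pos, true_pos, universe)
    neg = ConfusionMetrics.from_sets(set(neg_flagged) - {target_id}, true_neg, universe)
    return pos, neg


def evaluate_type1_replicate(spec: Type1Spec):
    """Generate one type-1 dataset and score SMG's recovery on it.

    Returns a dict with the spec, both metric sets and a ``perfect`` flag
    (all four rates equal 1, i.e. exact positive and negative grouping).
    """
    table, truth = generate_type1(spec)
    n = table.shape[1]
    graph = build_positive_graph(distance_matrix(table), n_samples=n)
    target_row = table.loc[spec.target_row_id].to_numpy()
    flagged = {
        taxon
        for taxon in table.index
        if taxon != spec.target_row_id
        and is_negative_correlation(target_row, table.loc[taxon].to_numpy())
    }
    pos, neg = score_type1_run(graph, flagged, truth, spec.target_row_id)
    perfect = (
        pos.fp == 0 and pos.fn == 0 and neg.fp == 0 and neg.fn == 0
    )
    return {"spec": spec, "positive": pos, "negative": neg, "perfect": perfect}


def _default_type1_specs(seed: int) -> list[Type1Spec]:
    """Five 50x10 and five 100x20 designs with derived seeds."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=10)
    shapes = [(50, 10)] * 5 + [(100, 20)] * 5
    return [
        Type1Spec(n_taxa=t, n_samples=s, seed=int(sd))
        for (t, s), sd in zip(shapes, seeds)
    ]


def run_type1_benchmark(n_replicates: int = 10, specs=None, seed: int = 0) -> dict:
    """Run the balanced compositional protocol (default: ten replicates).

    Returns a summary dict with per-replicate results, the number of
    replicates with perfect positive *and* negative grouping, and confusion
    counts pooled over replicates for both recovery tasks.
    """
    if specs is None:
        specs = _default_type1_specs(seed)[:n_replicates]
        if len(specs) < n_replicates:
            rng = np.random.default_rng(seed + 1)
            extra = n_replicates - len(specs)
            specs = specs + [
                Type1Spec(seed=int(s))
                for s in rng.integers(0, 2**31 - 1, size=extra)
            ]
    results = [evaluate_type1_replicate(sp) for sp in specs]
    pooled = {}
    for key in ("positive", "negative"):
        pooled[key] = ConfusionMetrics(
            tp=sum(r[key].tp for r in results),
            tn=sum(r[key].tn for r in results),
            fp=sum(r[key].fp for r in results),
            fn=sum(r[key].fn for r in results),
        )
    return {
        "replicates": results,
        "n_replicates": len(results),
        "n_perfect": sum(r["perfect"] for r in results),
        "pooled_positive": pooled["positive"],
        "pooled_negative": pooled["negative"],
    }


def run_type2_benchmark(
    da_fractions=(0.03, 0.05, 0.07, 0.10, 0.20),
    filter_p_map=None,
    n_replicates: int = 20,
    seed: int = 0,
    da_threshold_fraction: float = 0.05,
    spec_kwargs: dict | None = None,
) -> dict:
    """Run the two-group DA protocol across DA fractions.

    For each fraction, ``n_replicates`` datasets are generated with derived
    seeds, :func:`smg.daa.smg_daa` is run at the mapped filter level
    (default 0.975, but 0.955 at 20% DA) and the calls are scored against
    ground truth.

    Returns
    -------
    dict
        Per-fraction per-replicate metrics plus mean accuracy / sensitivity /
        specificity.
    """
    if filter_p_map is None:
        filter_p_map = DEFAULT_FILTER_MAP
    spec_kwargs = dict(spec_kwargs or {})
    rng = np.random.default_rng(seed)
    out = {"per_fraction": {}, "n_replicates": n_replicates}
    for frac in da_fractions:
        filter_p = filter_p_map.get(round(float(frac), 6), 0.975)
        reps = []
        for _ in range(n_replicates):
            spec = Type2Spec(
                da_fraction=float(frac),
                seed=int(rng.integers(0, 2**31 - 1)),
                **spec_kwargs,
            )
            t1, t2, truth = generate_type2(spec)
            report = smg_daa(
                t1, t2, filter_p=filter_p, da_threshold_fraction=da_threshold_fraction
            )
            metrics = ConfusionMetrics.from_sets(
                set(report.da_taxa),
                set(truth.index[truth["is_da"]]),
                set(truth.index),
            )
            reps.append({"spec": spec, "report": report, "metrics": metrics})
        accs = [r["metrics"].accuracy for r in reps]
        sens = [r["metrics"].sensitivity for r in reps]
        specificities = [r["metrics"].specificity for r in reps]
        out["per_fraction"][float(frac)] = {
            "filter_p": filter_p,
            "replicates": reps,
            "mean_accuracy": float(np.mean(accs)),
            "mean_sensitivity": float(np.nanmean(sens)),
            "mean_specificity": float(np.nanmean(specificities)),
        }
    return out
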