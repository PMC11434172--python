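"""Synthetic abundance tables with known correlation / DA ground truth.

Two generators cover the two study designs every other module is tested on:

* **Type 1 — balanced compositional matrices.**  Relative-abundance tables
  (columns sum to 1) containing a designated *target* row ``g``, rows exactly
  proportional to ``g`` (positive correlates, one per coefficient), rows
  exactly proportional to ``1 - g`` (negative correlates) and random filler
  rows.  Because min-max scaling removes positive affine factors, every
  positive row has slope distance exactly 0 to the target and every negative
  row has distance exactly 0 to the target's negation — the ground truth is
  recoverable by construction.

* **Type 2 — two-group zero-inflated count tables.**  Dirichlet-multinomial
  counts over a heavy-tailed (log-normal) baseline composition; a controlled
  fraction of taxa, drawn half from the top and half from the bottom quartile
  of baseline abundance, is differentially abundant with balanced direction
  (half up-, half down-shifted by a fold change in group 2).  Zero inflation
  emerges from sampling depth and rare taxa rather than from an explicit
  zero process.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Type1Spec", "Type2Spec", "generate_type1", "generate_type2"]

#: Coefficients used in the balanced compositional design: a sub-unit range
#: plus the doubling series 2, 4, 8, 16.
DEFAULT_COEFFICIENTS = (0.1, 0.2, 0.4, 0.8, 1.0, 2.0, 4.0, 8.0, 16.0)


@dataclass(frozen=True)
class Type1Spec:
    """Design of one balanced compositional matrix.

    Parameters
    ----------
    n_taxa, n_samples : int
        Matrix shape (taxa x samples); the study uses 50x10 and 100x20.
    target_row_id : str
        Identifier of the target-of-interest row (default ``"G19"``; rows are
        named ``G1..G{n_taxa}``).
    pos_coefficients, neg_coefficients : tuple of float
        Positive multipliers for the correlated rows (``c * g`` and
        ``c * neg_scale * (1 - g)`` respectively).
    target_band : (float, float)
        Range the target's relative abundances are drawn from; kept low so
        every designated row fits inside a unit column total even at
        coefficient 16.
    neg_scale : float
        Magnitude scale applied to negative rows; proportionality to
        ``1 - g`` (which is what defines negative correlation) is unaffected.
    seed : int
        Seed for the generator's private random stream.
    """

    n_taxa: int = 50
    n_samples: int = 10
    target_row_id: str = "G19"
    pos_coefficients: tuple = DEFAULT_COEFFICIENTS
    neg_coefficients: tuple = DEFAULT_COEFFICIENTS
    target_band: tuple = (0.002, 0.012)
    neg_scale: float = 0.01
    seed: int = 0

    def __post_init__(self):
        n_designated = len(self.pos_coefficients) + len(self.neg_coefficients) + 1
        if self.n_taxa <= n_designated:
            raise ValueError(
                f"n_taxa={self.n_taxa} leaves no room for filler rows "
                f"({n_designated} designated rows)"
            )
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if any(c <= 0 for c in self.pos_coefficients + self.neg_coefficients):
            raise ValueError("all coefficients must be positive")
        lo, hi = self.target_band
        if not 0 < lo < hi < 1:
            raise ValueError(f"target_band must satisfy 0 < lo < hi < 1, got {self.target_band}")


@dataclass(frozen=True)
class Type2Spec:
    """Design of one two-group differential-abundance count experiment.

    Parameters
    ----------
    n_taxa : int
        Number of taxa (default 100).
    samples_per_group : int
        Samples in each of the two groups (default 5).
    da_fraction : float
        Fraction of taxa that are differentially abundant (e.g. 0.03..0.20).
    fold_change : float
        Multiplicative shift applied to DA taxa in group 2 (up-shifted taxa
        multiplied, down-shifted divided).
    depth : int
        Sequencing depth (reads per sample).
    baseline_sigma : float
        Log-normal sigma of the baseline mean abundances (heavy tail).
    dispersion : float
        Dirichlet concentration mass for per-sample compositional variation;
        smaller values give stronger overdispersion.
    seed : int
        Seed for the generator's private random stream.
    """

    n_taxa: int = 100
    samples_per_group: int = 5
    da_fraction: float = 0.05
    fold_change: float = 4.0
    depth: int = 10_000
    baseline_sigma: float = 2.5
    dispersion: float = 500.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.da_fraction <= 1.0:
            raise ValueError(f"da_fraction must be in [0, 1], got {self.da_fraction}")
        n_da = int(round(self.da_fraction * self.n_taxa))
        if self.da_fraction > 0 and n_da < 2:
            raise ValueError(
                "da_fraction too small: need >= 2 DA taxa for a balanced direction"
            )
        if self.samples_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if self.fold_change <= 1.0:
            raise ValueError(f"fold_change must exceed 1, got {self.fold_change}")
        if self.depth < 1 or self.n_taxa < 8:
            raise ValueError("degenerate design (depth < 1 or fewer than 8 taxa)")

    @property
    def n_da(self) -> int:
        return int(round(self.da_fraction * self.n_taxa))


def _coefficient_label(c: float) -> str:
    """Readable coefficient tag: 0.1 -> '0.1', 8.0 -> '8'."""
    return f"{c:g}"


def generate_type1(spec: Type1Spec):
    """Generate one balanced compositional matrix with correlation truth.

    Returns
    -------
    (table, truth) : (pandas.DataFrame, pandas.DataFrame)
        ``table`` is taxa x samples with every column summing to 1.
        ``truth`` is indexed by taxon with columns ``role`` (one of
        ``target``/``positive``/``negative``/``random``) and ``coefficient``
        (NaN for filler rows).

    Raises
    ------
    ValueError
        If the designated rows cannot fit a unit column total (coefficients
        too large for the target band / negative scale).
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_taxa, spec.n_samples
    taxa = [f"G{i + 1}" for i in range(n)]
    if spec.target_row_id not in taxa:
        raise ValueError(
            f"target_row_id {spec.target_row_id!r} outside G1..G{n}"
        )

    lo, hi = spec.target_band
    # non-constant target with a guaranteed spread (min-max scaling needs it)
    g = rng.uniform(lo, hi, size=k)
    while np.ptp(g) < (hi - lo) * 0.2:  # pragma: no cover - vanishing probability
        g = rng.uniform(lo, hi, size=k)

    rows = {spec.target_row_id: g}
    roles = {spec.target_row_id: ("target", 1.0)}
    designated_ids = [spec.target_row_id]
    filler_ids = [t for t in taxa if t != spec.target_row_id]

    def take_filler_slot() -> str:
        return filler_ids.pop(rng.integers(len(filler_ids)))

    for c in spec.pos_coefficients:
        tid = take_filler_slot()
        rows[tid] = c * g
        roles[tid] = ("positive", c)
        designated_ids.append(tid)
    for c in spec.neg_coefficients:
        tid = take_filler_slot()
        rows[tid] = c * spec.neg_scale * (1.0 - g)
        roles[tid] = ("negative", c)
        designated_ids.append(tid)

    designated = np.vstack([rows[t] for t in designated_ids])
    col_mass = designated.sum(axis=0)
    residual = 1.0 - col_mass
    if (residual < 0.05).any():
        raise ValueError(
            "infeasible mass budget: designated rows use "
            f"{col_mass.max():.3f} of a unit column; lower the coefficients, "
            "target_band or neg_scale"
        )

    # filler rows share each column's residual mass via independent Dirichlet
    # weights, so their profiles are random and uncorrelated with the target
    weights = rng.dirichlet(np.ones(len(filler_ids)), size=k).T  # filler x samples
    for i, tid in enumerate(filler_ids):
        rows[tid] = residual * weights[i]
        roles[tid] = ("random", np.nan)

    table = pd.DataFrame(
        np.vstack([rows[t] for t in taxa]),
        index=pd.Index(taxa, name="taxon"),
        columns=[f"S{j + 1}" for j in range(k)],
    )
    truth = pd.DataFrame(
        {
            "role": [roles[t][0] for t in taxa],
            "coefficient": [roles[t][1] for t in taxa],
        },
        index=table.index,
    )
    return table, truth


def generate_type2(spec: Type2Spec):
    """Generate a two-group count experiment with DA ground truth.

    Baseline mean abundances are log-normal; DA taxa are drawn half from the
    top and half from the bottom quartile of the baseline means, and the
    direction of change is balanced (half up, half down by ``fold_change`` in
    group 2; odd counts give the extra taxon to the up direction).  Counts
    are Dirichlet-multinomial per sample at the configured depth.

    Returns
    -------
    (table1, table2, truth)
        Two taxa x samples count tables (one per group) and a truth frame
        indexed by taxon with columns ``is_da`` (bool), ``direction``
        (+1 up in group 2, -1 down, 0 null) and ``quartile``
        (``top``/``bottom``/``middle`` of the baseline abundance).
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_taxa, spec.samples_per_group
    taxa = pd.Index([f"OTU{i + 1}" for i in range(n)], name="taxon")

    base = rng.lognormal(mean=0.0, sigma=spec.baseline_sigma, size=n)
    order = np.argsort(-base, kind="stable")  # rank 0 = most abundant
    q = n // 4
    top_pool = order[:q]
    bottom_pool = order[-q:]

    n_da = spec.n_da
    direction = np.zeros(n, dtype=int)
    quartile = np.full(n, "middle", dtype=object)
    quartile[top_pool] = "top"
    quartile[bottom_pool] = "bottom"
    if n_da > 0:
        n_top = (n_da + 1) // 2  # odd counts: extra DA taxon from the top pool
        n_bottom = n_da - n_top
        chosen = np.concatenate(
            [
                rng.choice(top_pool, size=n_top, replace=False),
                rng.choice(bottom_pool, size=n_bottom, replace=False),
            ]
        )
        n_up = (n_da + 1) // 2  # balanced direction; odd counts favour up
        signs = np.array([1] * n_up + [-1] * (n_da - n_up))
        direction[chosen] = rng.permutation(signs)

    mean1 = base / base.sum()
    shifted = base * np.power(spec.fold_change, direction.astype(float))
    mean2 = shifted / shifted.sum()

    def sample_counts(mean: np.ndarray) -> np.ndarray:
        cols = []
        alpha = np.maximum(mean * spec.dispersion, 1e-12)
        for _ in range(k):
            p = rng.dirichlet(alpha)
            cols.append(rng.multinomial(spec.depth, p))
        return np.column_stack(cols)

    table1 = pd.DataFrame(
        sample_counts(mean1), index=taxa, columns=[f"A{j + 1}" for j in range(k)]
    )
    table2 = pd.DataFrame(
        sample_counts(mean2), index=taxa, columns=[f"B{j + 1}" for j in range(k)]
    )
    truth = pd.DataFrame(
        {
            "is_da": direction != 0,
            "direction": direction,
            "quartile": quartile,
            "baseline_mean": mean1,
        },
        index=taxa,
    )
    return table1, table2, truth
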