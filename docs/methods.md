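# Methods

## Model and assumptions

SMG treats each taxon's abundance profile across `n` samples as a shape, not
a magnitude.  Min–max scaling maps every profile to `[0, 1]` (a constant
profile, including an all-zero taxon, maps to the zero vector), and the
slope-based distance sums `|(α_j − α_i) − (β_j − β_i)|` over **all ordered**
sample pairs `(i, j)`.  The ordered-pair convention is load-bearing: it makes
the distance between the indicative profiles `O = (0,...,0)` and
`P = (1, 0, ..., 0)` exactly `2(n − 1)`, and half that value, `n − 1`, is the
positive-correlation threshold.  The comparison is strict (`d < n − 1`) and
performed in plain IEEE arithmetic; borderline values are not nudged by an
epsilon.  The distance is a pseudometric: symmetric, zero on identical (or
positively affine-related) profiles, and triangle-inequality-consistent; it
is invariant under `A → cA + k` for `c > 0`, which is why fold changes alone
do not move it (see "Known limitations").  Zeros need no special handling:
the distance is defined for any profile, which is the method's main appeal
for zero-inflated compositional tables.

Negative correlation is positive correlation with the negated profile:
`d(scaled(−A), scaled(B)) < n − 1`.  For non-constant `A`,
`scaled(−A) = 1 − scaled(A)`, and the relation is symmetric in `A` and `B`.

Clusters are connected components of the positive-correlation graph.
Between-condition change is the symmetric difference of the two conditions'
graphs on a common taxon set; its edge count is the scalar magnitude of
change, and a taxon's degree in the difference graph counts the correlations
it gained or lost.

## Differential abundance pipeline

`smg_daa(table1, table2, filter_p, da_threshold_fraction)`:

1. **Comparison filter with proportional zeroing** at level `filter_p`
   (default 0.975).  Taxa are ranked by row total; the smallest prefix whose
   cumulative share reaches `filter_p` of the grand total is kept and every
   other row is set to zero (rows are never dropped, so both conditions keep
   identical taxon sets).  By default totals are computed on the pooled
   (column-concatenated) pair of tables; `filter_scope="per-condition"`
   ranks each condition by its own totals instead.  With pooled scope the
   zeroed rows form identical zero-distance cliques in both graphs and
   cancel exactly in the symmetric difference; with per-condition scope a
   taxon whose retention status differs between conditions changes every
   edge it has into the zeroed clique.
2. Per-condition slope-distance matrices and positive graphs, each with its
   own threshold `n − 1` (conditions may have unequal sample counts).
3. Symmetric difference and per-taxon degrees.  A taxon is flagged as
   differentially abundant when its degree is at least
   `da_threshold_fraction` (default 5%) of the summed degrees (equivalently
   10% of the changed-edge count).  Normalizing by the summed degrees rather
   than the raw edge count is a design choice; the threshold is exposed so
   either convention is reachable.
4. With no single `filter_p`, a sweep over 95–100% in 0.5% steps is run and
   the heuristic optimum is the grid point immediately preceding the largest
   relative drop in the number of DA calls — a ground-truth-free proxy for
   an accuracy-drop rule; with no drop the last grid point is used.

Tie-breaks and degeneracies: equal row totals are ranked by original row
order (stable sort); `p = 0` retains the single largest taxon (the empty
prefix never satisfies the minimality condition); an all-zero table cannot
be filtered; an empty difference graph yields zero changes and no calls.

## Synthetic data

### Balanced compositional matrices (type 1)

Each matrix (50×10 or 100×20) has columns summing to 1 and contains a
designated target row `g` (drawn uniformly in a low band, default
0.002–0.012), one row `c·g` per positive coefficient, one row
`c·s⁻·(1 − g)` per negative coefficient, and random filler rows.  The
default coefficient set is {0.1, 0.2, 0.4, 0.8, 1, 2, 4, 8, 16} for both
directions.  Negative rows carry a small magnitude scale `s⁻` (default
0.01): proportionality to `1 − g` — the property that makes the row exactly
negatively correlated with the target after scaling — is unaffected by the
scale, while without it the large coefficients could not fit inside a unit
column total.  Designated rows are laid down first; each column's residual
mass is then shared among filler rows by an independent Dirichlet draw, so
filler profiles are random and, with overwhelming probability, far from both
the target and its complement (random scaled profiles sit at distances
several times the `n − 1` threshold).  An infeasible mass budget (residual
below 5% of any column) raises an error rather than silently renormalizing,
because renormalizing would break the exact proportionality the design
guarantees.  Positive rows therefore have slope distance exactly 0 to the
target and negative rows exactly 0 to its negation, up to floating-point
rounding — the ground truth is recoverable by construction, which is what
the type-1 benchmark verifies (10/10 replicates with 100% sensitivity and
specificity for both directions).

### Two-group count tables (type 2)

Emulates semiparametric zero-inflated 16S count data: baseline mean
abundances are log-normal (σ = 2.5, a typical heavy-tailed rank-abundance
curve), per-sample compositions are Dirichlet-perturbed (concentration mass
500, i.e. coefficient-of-variation ≈ 45% for a 1%-abundance taxon), and
counts are multinomial at a fixed depth of 10,000 reads per sample.  Zero
inflation emerges from depth and rarity rather than from an explicit zero
process; at the defaults roughly a quarter of all cells are zeros, rising
above one half in the bottom abundance quartile.  A fraction of taxa
(3–20%) is differentially abundant: drawn half from the top and half from
the bottom quartile of baseline abundance (the extra taxon from the top
when the count is odd), with balanced direction — half up-shifted, half
down-shifted 4-fold in group 2 (the extra direction up).  The two groups
are sampled independently; with `da_fraction = 0` they are i.i.d.

What the generator does **not** emulate: real between-taxon correlation
structure (taxa are exchangeable given their means), varying library sizes,
and resampling of a reference dataset's empirical profiles.

## What passing tests do and do not show

The type-1 benchmark is exact by construction and fully reproducible; it
validates scaling, the distance, the threshold, graph construction and
negative-correlation calling end to end.

The type-2 benchmark is an honest stress test, and its accuracy under this
generator falls short of a perfect score: measured mean accuracy over 20
replicates is ≈ 0.91 at 3% DA (filter 0.975) and ≈ 0.78 at 20% DA (filter
0.955).  The mechanism is intrinsic to the statistic: because the slope
distance is invariant under positive scaling of a profile, a pure fold
change does not alter a taxon's scaled-profile distribution, so edge changes
arise only when a taxon's all-zero status or filter-retention status toggles
between conditions — and with independently resampled groups, those toggles
are driven as much by sampling noise in boundary taxa as by the injected
fold changes.  Attribution runs (removing overdispersion, flattening the
abundance tail, switching filter scope) move these numbers by less than
0.05, so the gap is structural to independent two-group resampling rather
than a parameter artifact; reproducing a perfect score would require the two
groups to share realized sampling noise, which would contradict the
generator's i.i.d. contract.  The qualitative filter dependence does
reproduce: sensitivity declines as the filter rises past its optimum and is
exactly zero with no filtering at all (`p = 1`), because unfiltered graphs
differ only by diffuse noise edges and no taxon reaches the calling
threshold.

## Numerical choices

* The double sum is evaluated per pair as `2 Σ_{i<j} |γ_(j) − γ_(i)|` with
  `γ = α − β` via sorting (`O(n log n)` per pair); a brute-force double-loop
  oracle pins the equivalence to 1e-9 in the tests.
* Filter minimality is defined on the cumulative sums as actually summed
  (largest-first); comparisons use those sums, not independently re-summed
  totals, so the rule is well-defined at `p = 1` despite float associativity.
* Graph edges are stored canonically (lexicographic endpoint order) for
  deterministic set operations and file output; components are reported
  sorted by smallest member.
* One integer seed drives each generator run through its own
  `numpy.random.default_rng` stream; benchmark replicates derive child seeds
  from a master stream, all below 2³¹.
* Benchmark problem sizes (10 type-1 replicates; 20 type-2 replicates per
  DA fraction) were chosen so the full suite runs in seconds while keeping
  the stochastic means stable to ~0.01.

## Known limitations

* Scale invariance makes the method blind to fold changes that alter
  neither zero patterns nor filter retention; its DA power therefore
  concentrates on taxa near the rarity boundary.
* All-zero (or zeroed) taxa are mutually at distance 0 and form a clique;
  single-condition network statistics should drop all-zero taxa first (the
  CLI's default), while comparison workflows keep them so vertex sets stay
  aligned.
* The `n − 1` threshold grows linearly in sample count while the maximum
  possible distance grows quadratically, so graphs become sparser as `n`
  rises; thresholds are always per-condition (`n` of that condition).
* Distance computation is `O(T² n log n)` for `T` taxa; tables in the
  hundreds of taxa are interactive, tables in the thousands are not (no
  sparse shortcut is attempted).
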