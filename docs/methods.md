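# Methods

## Model and estimator

All dependence measures are information-theoretic quantities evaluated under
a multivariate-Gaussian working model, in nats. For a variable set of
dimension *d* with sample covariance *C*, the differential entropy is
`H = ½ ln((2πe)^d |C|)`; the exponent is the dimension of the variable set,
which is the bookkeeping that makes the entropy combination

```
I(X;Y|Z) = H(X,Z) + H(Y,Z) − H(Z) − H(X,Y,Z)
```

collapse exactly to the determinant ratio
`½ ln(|C(X,Z)|·|C(Y,Z)| / (|C(Z)|·|C(X,Y,Z)|))` — the `(2πe)` factors cancel
because `(1+k) + (1+k) − k − (2+k) = 0` for a conditioning set of size *k*.
The empty-set determinant is defined as 1, so the unconditioned case is
plain mutual information and order-0 scoring is the MI special case of the
same estimator. For Gaussian data, first-order CMI equals
`−½ ln(1 − ρ²_{XY·Z})` with the partial correlation `ρ_{XY·Z}`; the test
suite uses that closed form, and the entropy-combination form, as
independent oracles against the determinant-ratio implementation.

Covariances use the unbiased (n−1) denominator. The choice cancels in every
determinant ratio at fixed sample size and only affects standalone
entropies. The joint submatrix for a pair is always assembled in
(min, max) index order so `I(X;Y|Z)` and `I(Y;X|Z)` are bit-identical.

## Numerical safeguards

* Determinants at or below `1e−12` are floored at that value and the event
  logged; a genome-scale screen must not abort on one collinear triple.
* MI/CMI values are clamped to ≥ 0; negative values beyond `−1e−10` (which
  indicate a real numerical problem, not round-off) are logged first.
* Zero-variance genes score MI = 0 with a warning rather than raising, for
  the same keep-running reason. `gaussian_entropy` itself, which has no
  meaningful degenerate value, raises instead.

## The pruning loop

Order 0 thresholds the all-pairs MI matrix (computed vectorised from the
correlation matrix). At order *k* each surviving edge with at least *k*
common neighbors is re-scored by the **maximum** CMI over all size-*k*
conditioning subsets of its common neighbors — size exactly *k*, not up to
*k*, so orders are nested and an edge with too few common neighbors passes
through unchanged. Retention is strict (`weight > cutoff`; ties removed).

Two semantics were open:

* **Batch vs sequential removal.** Classical path-consistency removes edges
  as it finds them, which makes the result depend on edge processing order.
  Here all common-neighbor sets are read from the adjacency snapshot taken
  at the order's start and removals apply at the order's end. This makes
  the algorithm a pure function of (data, config) and is what makes the
  parallel contract possible: pair tasks are split into contiguous chunks
  (sizes differing by at most one) across joblib workers, and the merged
  result is bit-identical for any worker count — asserted directly in the
  tests for workers ∈ {1, 4, 8}.
* **Per-order cutoff.** In auto mode the cutoff is recomputed at each order
  from the weight distribution as it stands when the order begins; a fixed
  cutoff or an explicit per-order list can be supplied instead.

Orders beyond 3 are allowed but warned against (the subset enumeration
grows combinatorially); the loop stops early when no edge has enough common
neighbors for the next order. Default `max_order` is 1 — in practice the
first conditioning order removes most indirect edges and higher orders add
little accuracy for sharply higher cost.

## Automatic threshold

Edge counts are scanned on a cutoff grid (default 0 → 1 in steps of 0.02,
51 points; rescaled to [0, max weight] with 51 points when any weight
exceeds 1, since MI in nats is unbounded above). The scan is fit by
least squares to `y = a·e^(−bx) + c` with bounds a > 0, b > 0, c ≥ 0
(`scipy.optimize.curve_fit`, tolerance 1e−8, ≤ 10,000 evaluations),
initialised from the scan itself: c₀ = final count, a₀ = first count − c₀,
b₀ from a log-linear regression of the floored excess counts. The additive
floor *c* matters at genome scale, where scans plateau well above zero on
background correlation. Counts are fit on the raw scale: the tail carries
the plateau information and log-scale fitting would overweight it.

The returned cutoff is the x-coordinate where the tangent line to the
fitted curve at the first grid point crosses the tangent at the last grid
point — the inflection of the decay — clamped into the grid. It is
invariant under scaling counts by a constant and under adding a constant
(both leave the tangent-crossing x unchanged), and as the end tangent
flattens (x_end → ∞) it approaches the closed form `x_start + 1/b`.
When the fit is degenerate (flat scan, optimiser failure, parallel
tangents) a deterministic fallback returns the grid point farthest from the
chord joining the scan's endpoints, computed on axes normalised to [0, 1];
the pipeline therefore always produces a cutoff. With very few genes
(e.g. the 3-gene chain fixture: three pairs) the decay curve is essentially
unresolved and the automatic cutoff is unreliable — it is designed for
scans over hundreds of pairs or more.

## Evaluation

Gold standards are symmetrised to unordered pairs (the inferred networks
are undirected), the evaluation universe is every unordered non-self pair
over the gold gene list, and pairs never scored count as score 0. ROC and
PR curves treat tied scores as a single threshold step and both areas are
trapezoidal integrals over the raw curve points, without interpolation
refinement — documented because AUPR conventions differ and this choice
makes comparisons reproducible. AUROC is checked against the Mann–Whitney
rank statistic in the tests. The "true threshold" used for threshold-quality
scoring is the smallest grid cutoff maximising accuracy against the gold
standard (a pure argmax, re-running inference per grid point), and the
offset of an automatic cutoff is `|true − predicted| / (grid range) × 100%`,
with < 5 / 10 / 20 % labelled stringent / standard / moderate.

## Synthetic benchmark

The generator samples a random DAG (random topological order; each forward
pair an edge with probability `avg_degree/(n_genes − 1)`, so the expected
edge count is `n·avg_degree/2`) and simulates expression from the linear
structural-equation model the estimator assumes exactly: roots are standard
normal, every other gene is the weighted sum of its parents plus
`N(0, noise_sd²)` noise, in topological order. Defaults: edge weights
±[0.5, 1.5] (no near-zero effects that would make recovery ill-posed),
noise sd 0.5, giving e.g. a single-edge parent–child correlation of
`1/√1.25 ≈ 0.894`. The chain fixture is the minimal indirect motif — hub Z
with children X and Y — whose population covariance
`[[1.25, 1, 1], [1, 1.25, 1], [1, 1, 1]]` gives MI(X,Y) = 0.5108 nats but
CMI(X,Y|Z) = 0 exactly, so every expected value is hand-computable. A
chain-motif builder (independent serial A→B→C triples) provides the
chain-rich regime where order-1 pruning demonstrably beats order-0 ranking.

Because the generator matches the estimator's Gaussian assumption exactly
and noise is additive and independent, passing these benchmarks shows the
machinery is correct, not that the method attains the same accuracy on real
expression data — real data bring nonlinearity, non-Gaussian noise, hidden
confounders and far fewer samples per gene. Desk-scale problem sizes were
chosen for the shipped tests and acceptance script (3–50 genes, 300–1000
samples, 10–20 replicate seeds); they are large enough that the population
signal dominates sampling noise with margin.

## Files, CLI and reproducibility

Formats are UTF-8 TSV with `#`-comments: expression (genes × conditions,
or DREAM-style samples-in-rows via `--orientation`), DREAM three-column
gold standards, and two outputs per run — an interaction file (every pair's
final weight) and a relation file (retained edges as 1-rows; explicit
zeros behind `--emit-zeros`, since an all-pairs 0/1 file is impractical at
genome scale). Pairs are written lexically and rows sorted, so identical
networks yield byte-identical files; weights print with 6 decimals by
default, full precision on request. All writes go through a
temp-file-and-rename step, so failed runs leave no partial outputs. Every
CLI run writes a JSON manifest (resolved settings, input SHA-256 digests,
per-order cutoffs, version, wall time) sufficient to reproduce it.

## Known limitations

* Edges are undirected; orienting them needs interventions or time series.
* The Gaussian estimator sees only linear dependence; nonlinear regulation
  weakens both scoring and pruning.
* Conditioning sets come from current common neighbors only, so an indirect
  dependence mediated by a gene already pruned (or never connected) cannot
  be conditioned away.
* The automatic threshold assumes the scan actually decays; tiny networks
  fall back to the chord elbow, which is a heuristic.
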