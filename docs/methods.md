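# Methods

## Model

The contact matrix for one chromosome is treated as a matrix-variate
change-point problem.  Cells are assumed independent with a block-wise
constant mean: within the diagonal block of a TAD the mean is `μ_k`, and
in the rectangle coupling two neighbouring blocks it is lower.  The
reference parametric model is negative binomial, `x_ij ~ NB(μ_k, r)` with
a shared nuisance size `r` (variance `μ + μ²/r`), but the working statistic
is distribution-free: the generalized likelihood ratio for a single split
is asymptotically equivalent (as window size grows with the split fraction
held fixed) to a scan statistic `Z_m` built from two orthogonal
standardised contrasts — block 1 against the rectangle, and block 1 plus
rectangle against the whole window — scaled by the null cell variance
`σ₀²`.  The package therefore detects changes in mean for Gaussian,
Poisson, NB or normalised data alike; `GLR_NB,m` is provided alongside for
completeness and is cross-checked against `Z_m` in the tests (profile
correlation > 0.95 under the null).

Conventions: bins are 0-based; a change-point `τ` is the first bin of the
right-hand block; TAD intervals are half-open `[start, end)`; diagonal
cells belong to the triangular blocks, never to the rectangle.  Values are
stored as doubles, so normalised matrices are accepted; only the
upper-triangular non-zeros are kept, and region sums for every split of a
window come from cumulative row/column sums built in one pass.

## Null calibration

With the split location unknown, `Z̃ = max_{ξ < m ≤ n−ξ} Z_m` converges to
`g_δ = max_{δ < t < 1−δ} g_t`, the maximum of a quadratic functional of a
Gaussian random field `G` on the unit upper triangle, with `δ = ξ/n`.
`g_δ` has no closed form; it is tabulated by Monte Carlo: each draw fills
the `grid_n × grid_n` upper-triangular lattice with iid standard normals,
scales region sums by `1/grid_n` so `Var(G_S)` matches the area of `S`,
evaluates `g_t` on all grid values of `t` by cumulative sums, and records
the maximum over the admissible range.  Defaults: `δ = 0.01`,
`grid_n = 200`, `M = 20,000` draws, fixed seed; the table is cached per
process and regenerable from the CLI (`tadscan make-null`).

A single small-`δ` table serves all windows.  Restricting the maximum to a
narrower `t` range only shrinks `g`, so p-values for windows whose
effective `ξ/n` exceeds `δ` are conservative; the same argument makes the
finite-grid edge inflation conservative as well.  The max-statistic
p-value uses add-one continuity, `p = (1 + #{g ≥ Z̃}) / (1 + M)`, so its
floor is `1/(M+1) ≈ 5·10⁻⁵`; `α₀` must exceed this floor or every
candidate is rejected.  At a known location, `Z_m` is half the sum of two
squared independent standardised contrasts, so `2 Z_m` is referred to
chi-square with 2 df (verified against the simulated field null by KS
test).  Known-location p-values are floored at 1e−300 to keep Fisher logs
finite.

`σ₀²` is estimated as the unbiased variance of all cells (zeros included)
of the window under test — simple, consistent under the null, and
swappable via `TestConfig.sigma0_sq`.  Constant windows are floored at
1e−8 and flagged degenerate.

## Detection pipeline

1. **Binary segmentation.**  The window's `Z_m` profile is maximised over
   the admissible range `s + ξ < m ≤ e − ξ` (ties to the smallest `m`);
   the argmax becomes a candidate and the two sub-windows recurse until a
   window has no admissible split (size ≤ 2ξ).  No testing happens here.
2. **Pruning.**  Candidates are re-tested in reverse discovery order on
   the window delimited by their currently-surviving neighbours (or the
   matrix ends); a candidate whose max-statistic p-value exceeds `α₀`
   (default 1e−3) is removed, widening its neighbours' windows.  A
   surviving candidate is *re-estimated* at the argmax of its re-run scan.
   Re-tests scan the symmetric range `[s + ξ, e − ξ]`: both delimiters are
   fixed boundaries here, and the symmetric range guarantees any position
   at least `ξ` from both can be reached.  Two further safeguards handle
   artefacts of sequential re-testing: survivors closer than `2ξ` bins are
   re-scanned jointly and collapsed onto the joint-window argmax when it
   falls strictly between them (always when their gap violates `ξ`), and
   the sweep then iterates to a fixed point against the settled
   delimiters.  These steps were designed for the random-initialisation
   protocol, where the initial split may land within `ξ` of a true
   boundary and otherwise shadows it permanently; they leave clean
   ordinary runs untouched.
3. **Boundary p-values.**  Each survivor gets a known-location chi-square
   p-value from testing its own position on the window spanned by its
   flanking boundaries.
4. **Bottom-up merging.**  Starting from the leaf blocks, each round ranks
   the current inter-block boundary p-values in descending order and
   greedily merges non-conflicting adjacent pairs with `p > α₁` (default
   1e−5; each block joins at most one merge per round, conflicts go to the
   larger p, ties to the left).  The merged boundary's layer label is one
   more than the deepest layer interior to the merging blocks, so nested
   merges produce increasing layers; p-values of boundaries flanking new
   blocks are recomputed on the new geometry, and iteration stops when no
   boundary qualifies.  Remaining blocks are roots of order 1; children
   carry order parent + 1.  Raising `α₁` towards `α₀` monotonically
   reduces merging (flatter output).

Pruning uses the max-statistic null (the location was estimated); the
merge step and cross-sample tests use the fixed-location chi-square null
(the location is given).  `TestConfig.null_mode` forces either reference
everywhere.

## Synthetic data

The generators reproduce the study conditions used to validate the
detector; all are exactly reproducible under a seed and emit the true
change-points.

* **gaussian** — `n = 500`, `K = 31` change-points drawn uniformly over
  layouts with every block ≥ 5 bins, block means `μ_k ~ Gamma(shape 4,
  scale 18)` (mean 72); block cells `N(μ_k, σ²)` and background cells
  `max{N(0, σ²), 0}` with `σ² = 72 + 72²·ν`.
* **poisson-nb** — same layout; block cells NB with mean `μ_k` and
  variance `μ_k + ν μ_k²` (size `1/ν`, success probability
  `1/(1 + ν μ_k)`; exactly Poisson at `ν = 0`), background cells a 50/50
  mixture of a point mass at zero and an NB with the smallest block mean.
  `√ν` is the biological coefficient of variation; the benchmark grid is
  `√ν ∈ {0, 0.05, 0.10, 0.15}`.
* **nested** — outer blocks recursively subdivided (2–3 levels), each
  level multiplying the block mean by `sub_mean_ratio` (default 2), NB
  noise, per-level truth labels (level 1 = coarsest).  This is a
  structure-alike fixture for hierarchy scoring, not a calibrated model of
  any published benchmark; hierarchy tests that need *weak* inner
  boundaries set `sub_mean_ratio` near 1 explicitly.

What these generators do not emulate: genomic distance decay within and
between domains, unmappable (all-zero) bins, translocations, and
resolution-dependent sparsity patterns of real Hi-C libraries.  Passing
benchmarks therefore demonstrate correct recovery under block-constant
means with realistic count noise, not performance on arbitrary real data,
where the distance-decay trend inflates `σ₀²` and makes the tests more
conservative.

## Evaluation

TPR and FDR use greedy one-to-one matching by ascending distance within a
bin tolerance — exact matching (`tol = 0`) for the clean simulation
benchmarks, 2 bins for real-data-style comparisons.  `K̂ − K` averages the
signed boundary-count error over matrices.  Hierarchies are cut at each
order into flat partitions and compared with the Fowlkes–Mallows index
`B = T/√(PQ)` from the contingency table (`B = 0` when `T = 0`); the
permutation control shuffles the detected label vector across bins
(cluster sizes preserved, contiguity destroyed), estimating the agreement
expected between unrelated clusterings — permuting contiguous blocks
instead barely changes an interval partition and was rejected.

## Benchmark problem sizes

The acceptance benchmark runs 100 replicates per scenario (two families ×
four noise levels, n = 500, K = 31) with `ξ = 3`, `α₀ = 1e−3`,
`α₁ = 1e−5` and the default null table, pooling TPR/FDR per scenario.
The unit suite uses a reduced table (grid 100, M = 2,000) where only
pipeline mechanics are under test, and the default table for all
operating-characteristic checks.

## Known limitations

* Every bin belongs to a leaf TAD; there is no "gap" state between
  domains, and matrix normalisation is out of scope.
* The single shared null table is conservative for windows with
  `ξ/n > δ`; users scanning very small windows at stringent `α₀` should
  regenerate a table at a matching `δ`.
* `α₀` below the Monte-Carlo floor `1/(M+1)` rejects everything; increase
  `M` rather than `α₀` for more stringent screens.
* The NB nuisance `r` is estimated by method of moments and only feeds the
  optional `GLR_NB` path, not default detection.
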