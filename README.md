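# tadscan

Hierarchical detection of topologically associating domains (TADs) in Hi-C
contact matrices by matrix-variate change-point testing.

## The problem

A Hi-C experiment on one chromosome yields a symmetric matrix
`X = (x_ij) ∈ R^{n×n}` of contact counts between `n` fixed-width genomic
bins.  TADs appear as diagonal blocks of enriched contacts; the bins where
the block structure changes are the TAD boundaries, and boundaries of
nested sub-domains are weaker than the boundaries of the domains that
contain them.  `tadscan` finds the boundaries, attaches a p-value to each,
organises them into a nested hierarchy, and compares boundary sets across
samples — for anyone studying chromatin architecture from binned contact
maps (raw counts or KR/ICE-normalised values alike).

## The statistic

For change-points `τ_a < τ_b < τ_c`, write `A1` and `A2` for the two
triangular diagonal blocks they delimit, `R` for the rectangle between the
blocks, and `A = A1 ∪ A2 ∪ R`.  Under a negative-binomial model
`x_ij ~ NB(μ_k, r)` with block-wise means, the log generalized likelihood
ratio `GLR_NB,m` for "one change-point at `m`" against "no change-point"
is asymptotically equivalent to the distribution-free scan statistic

    Z_m = 1/(2σ₀²) · [ (S_A1 − w₁·S_{A1∪R})² / (|A1|(1−w₁))
                     + (S_{A1∪R} − w₂·S_A)²  / (|A1∪R|(1−w₂)) ]

where `S_·` are region sums, `w₁ = |A1|/|A1∪R|`, `w₂ = |A1∪R|/|A|`, and
`σ₀²` is the null cell variance — so detection does not depend on the count
distribution.  With the location unknown the test statistic is
`Z̃ = max_{ξ < m ≤ n−ξ} Z_m` (`ξ` = minimum TAD size, default
`ceil(100 kb / resolution)` bins).  `Z̃` converges to the maximum `g_δ` of a
quadratic functional of a Gaussian random field on the unit upper triangle;
`tadscan` tabulates that law by Monte Carlo and converts `Z̃` to a p-value
from the table.  At a *known* location, `2 Z_m` is asymptotically
chi-square with 2 df.

Detection proceeds by top-down binary segmentation (split at the argmax,
recurse), pruning of candidates at threshold `α₀` in reverse discovery
order, and bottom-up merging of blocks whose shared boundary p-value
exceeds `α₁` (default 1e−5), which yields layer labels for boundaries and
order labels for TADs (root = order 1).  Boundary sets from two samples
are compared by Fisher's method: `χ²₄ = −2 ln p₁ − 2 ln p₂` referred to
chi-square with 4 df.

## Worked example

Simulate a 500×500 count matrix with 31 change-points (negative-binomial
blocks, BCV 0.10), fit the model, and score against the generator truth:

```python
from tadscan import TADModel
from tadscan.simulate import SimScenario, gen_sim4
from tadscan.evaluate import tpr_fdr

cm, truth = gen_sim4(SimScenario(family="poisson-nb", n=500, K=31,
                                 bcv=0.10, seed=42))
res = TADModel(cm).fit()
print(res.summary())
tpr, fdr = tpr_fdr(res.taus, truth.taus, tol=0)
print(f"TPR={tpr:.3f}  FDR={fdr:.3f}")
```

Output (abridged):

```
Hierarchical TAD detection
==========================
chrom: sim   bins: 500   resolution: 1 bp   nnz: 65888
xi (min TAD size): 3 bins   alpha0: 0.001   alpha1: 1e-05
boundaries: 31   TAD nodes: 32   max order: 1

chrom  bin  pos  p_detect    p_boundary  layer
  sim   34   34   0.00005 9.292061e-115      0
  sim   39   39   0.00005  2.621236e-13      0
  ...
TPR=1.000  FDR=0.000
```

All 31 boundaries are recovered at their exact bins; `p_detect` is the
Monte-Carlo max-statistic p-value from pruning (here the table floor
1/(M+1) with M = 20,000 draws) and `p_boundary` the known-location
chi-square p-value used for merging and cross-sample comparison.  The same
pipeline is available from the shell:

```sh
tadscan simulate --family poisson-nb --bcv 0.10 --seed 42 --out-prefix sim
tadscan detect --input sim.list.txt --format list --positions bin \
        --resolution 1 --out-prefix fit
tadscan evaluate --pred fit.boundaries.tsv --truth sim.truth.tsv --tol 0
tadscan compare --a fit.boundaries.tsv --b other.boundaries.tsv --out cmp.tsv
```

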