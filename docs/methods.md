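# Methods

## Model and pipeline

The package estimates Gaussian graphical models (GGMs) over the 12
ACL-RSI items. In a GGM, zeros of the precision matrix Θ encode
conditional independence, and the displayed edge weights are partial
correlations w_ij = −θ_ij/√(θ_ii θ_jj). Estimation is a three-stage
pipeline applied identically to the whole cohort and to the
returned/not-returned subgroups, and re-run in full inside every
bootstrap replicate and permutation:

1. **Nonparanormal transform.** Each item's marginal is mapped to
   approximate standard normality through Φ⁻¹ of a truncated, scaled
   empirical CDF: ranks (average for ties) are divided by n+1 and
   clipped to [δ_n, 1−δ_n] with δ_n = 1/(4 n^{1/4} √(π ln n)), then
   columns are centred and scaled to unit sample variance. The map is
   monotone, so all rank-based dependence is preserved — except that
   the δ_n clipping ties the most extreme observations in each column,
   which perturbs Spearman correlations at roughly the 1e-4 level. This
   truncated-ECDF variant is the canonical one in the sparse-GGM
   literature; no alternative Gaussianization families are offered.
   Correlations of the transformed data are plain Pearson. A polychoric
   or otherwise latent-scale correlation would be a defensible
   alternative for 0–100 rating items and could move edge weights in
   the second decimal; Pearson-on-transformed was fixed because it is
   deterministic, fast, and the default in the ecosystem this analysis
   style comes from.

2. **Graphical LASSO with EBIC selection.** The ℓ1-penalized
   log-likelihood (diagonal unpenalized) is maximized by an ADMM
   scheme: the Θ-update is a closed-form eigenvalue shrinkage, the
   consensus copy is soft-thresholded off the diagonal (producing exact
   zeros), with over-relaxation 1.6, penalty parameter ρ = 0.3, and
   convergence declared when both max-norm residuals fall below 1e-7
   (iteration cap 10⁴; non-convergence raises). The p = 2 case is
   solved in closed form (soft-threshold of the off-diagonal
   covariance). Solutions agree with a brute-force numerical maximizer
   to ~1e-7 on small problems, comfortably inside the 1e-4 oracle
   tolerance used in tests; a KKT-residual check applies to every
   fitted network. λ is selected by minimizing
   EBIC = −2L + E ln n + 4γE ln p over a logarithmic path of 100 values
   from λ_max = max |S_ij| down to λ_max/100, with warm starts; ties
   prefer the larger λ (sparser model). γ defaults to 0.5, the
   conventional value. Entries below 1e-10 count as zero when counting
   edges E. Edge counts along a λ path are not perfectly monotone for
   the graphical lasso — isolated single-edge inversions deep in the
   path are expected and tolerated.

3. **Centrality.** Strength is the sum of absolute incident weights.
   Closeness and Betweenness use shortest paths with edge length
   1/|w| (stronger association = shorter distance); closeness is
   1/Σd(v,·) and is 0 when any node is unreachable; betweenness splits
   tied geodesics equally (Brandes convention). Tables carry raw values
   plus a min–max rescaling to [0, 1] for presentation; when all nodes
   tie, the rescaled value is 0 for every node. Group comparisons
   always operate on raw Strength.

## Resampling

- **Edge accuracy**: nonparametric bootstrap (rows resampled with
  replacement), percentile 2.5/97.5 intervals, B = 1000 by default.
- **Centrality stability**: case-dropping subset bootstrap over the
  grid {0.05, …, 0.75}; per proportion π, ⌊(1−π)n⌋ rows are kept and
  the Pearson correlation between replicate and original Strength
  vectors recorded. The CS-coefficient is the largest π such that every
  proportion up to π has ≥ 95% of replicate correlations ≥ 0.7.
  Replicates whose networks are empty have constant Strength vectors;
  their correlation is recorded as 0 (no evidence of a preserved
  ordering).
- **Group comparison (NCT)**: two-tailed absolute-difference statistics
  for every edge and every node's Strength, with the null built by
  re-assigning pooled participants to pseudo-groups of the original
  sizes and re-estimating both networks, λ re-selected each time, 1000
  permutations by default. p-values use the add-one estimator
  (1 + #{≥ observed})/(1 + M), are never 0, and are reported
  unadjusted for multiple comparisons (flagged as exploratory). An
  exhaustive-enumeration mode provides exact p-values for tiny groups.
  Transformation happens inside each pseudo-group, consistent with the
  main pipeline; transforming once before permuting would be the other
  defensible choice.

All resampling draws substreams from a single master seed
(`SeedSequence.spawn`), so results are reproducible and independent of
execution order; failed replicates (e.g. a resampled constant column)
are redrawn up to a 2B total-attempt cap.

**Interpretation caveat.** Bootstrap percentile intervals quantify the
sampling variability of the *penalized* estimate. Because the LASSO
shrinks toward zero, they are not calibrated intervals for the
unpenalized partial correlation: in simulations with a planted edge of
0.4 at n = 500, intervals covered the planted value only ~2/3 of the
time while tracking the finite-sample sampling distribution almost
perfectly. Tests therefore check calibration against the sampling
distribution, not coverage of the planted value.

## Synthetic cohort

The generator draws a latent multivariate normal whose precision matrix
has unit diagonal and off-diagonals −P (P the planted partial
correlations), maps each column through a Gaussian quantile with the
group/item mean and SD on the 0–100 scale, clips to [0, 100] and rounds
to integers. Defaults encode the study conditions: 115 returned / 326
not returned; per-group marginal means and SDs on the observed item
scale; strongest edge Q7–Q9 = 0.48 and second Q4–Q8 = 0.37; ten weaker
edges in [0.08, 0.18] clustered on Q12 so that Q12 carries the top
Strength in the larger group while Q7 leads in the returned group; and
three edges (Q2–Q7, Q5–Q8, Q3–Q12) planted stronger in the returned
group as the comparison's true alternative.

Every remaining pair receives a weak background partial correlation of
0.04. All 12 items reflect a single construct, so real item pairs are
never exactly conditionally independent; without this positive manifold
the EBIC selection returns implausibly sparse networks (~3 edges at the
subgroup sizes), nothing like the dense networks with lightly shrunk
strong edges seen on real rating-scale data. With it, the whole-cohort
fit at n = 441 has ~55 edges and estimates the planted 0.48 edge at
≈ 0.50. The implied precision matrices are verified positive definite
(smallest eigenvalue ≈ 0.11); if a custom specification is not, the
off-diagonals are shrunk uniformly and the factor recorded.

What the generator does **not** emulate: item-response-theory
measurement structure, floor/ceiling-induced heteroscedasticity beyond
simple clipping, longitudinal change, and the whole-cohort marginal
means printed in the source study (its whole-cohort column is not the
count-weighted average of its subgroup columns, so a two-group mixture
cannot match it; ours equals the mixture by construction). Clipping and
rounding attenuate planted correlations slightly — the planted 0.48
edge converges to ≈ 0.47 at n = 10⁵ — which the ±0.03 recovery
tolerance absorbs. Passing tests on this cohort demonstrate that the
machinery recovers known structure under realistic marginals; they do
not certify behavior under measurement models the generator omits.

## Problem sizes in tests and the acceptance script

Default replicate counts (B = 1000 everywhere, 1000 permutations) are
what an applied analysis should use. The test suite and
`scripts/acceptance.py` scale sizes so a full run completes in minutes
on one CPU: acceptance uses B = 200 for the edge bootstrap, 40
replicates per drop proportion, 200 permutations, a 50-point λ path
inside resampling loops (100 for the headline fits), and n = 10⁵ for
the large-sample recovery check; the type-I-error simulation uses 4
items, groups of 200, 200 permutations and 100 seeds. These counts are
stated in the code where they are used.

## Known limitations

- Networks are undirected partial-correlation structures; nothing here
  distinguishes common causes from mediators or effects.
- EBIC with γ = 0.5 is conservative: under sparse truth at n ≲ 400 it
  prunes weak true edges aggressively (sensitivity grows with n; the
  support-recovery test documents ≥ 0.9 sensitivity/specificity at
  n = 2000 for planted partials ≥ 0.2).
- The NCT has low power at these group sizes for edge-level differences
  of ~0.2 on the partial-correlation scale; planted differences are
  detected reliably only for large effects or larger groups.
- The CS-coefficient depends on the grid resolution (0.05 steps) and on
  B; small B makes it noisy at the qualification boundary.
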