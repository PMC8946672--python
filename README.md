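# rsinet

Network analysis of psychological readiness to return to sport after
anterior cruciate ligament (ACL) reconstruction.

The ACL-RSI scale measures psychological readiness with 12 items
(Q1–Q12), each scored 0–100, covering emotions, confidence in
performance, and risk appraisal. Rather than reducing the scale to a
total score, this package models the items as a network: nodes are
items, and edges are **regularized partial correlations** — associations
between two items adjusted for all other items. The structure of that
network, and how it differs between athletes who did and did not return
to pre-injury sport, points at which beliefs are most central to
readiness and are therefore candidate treatment targets.

## Model

Item scores are mapped to approximate normality with a nonparanormal
(rank-based Gaussian copula) transform, then a sparse Gaussian graphical
model is estimated by the graphical LASSO: the precision matrix Θ
maximizes

    log det Θ − tr(SΘ) − λ Σ_{i≠j} |θ_ij|

where S is the item correlation matrix. Edge weights are partial
correlations w_ij = −θ_ij / √(θ_ii θ_jj). The penalty λ is chosen by
minimizing the Extended Bayesian Information Criterion,
EBIC = −2L + E·ln n + 4γE·ln p (γ = 0.5), over a 100-point logarithmic
λ path. On top of the fitted networks the package computes:

- **Centrality** — Strength (sum of absolute incident weights; the
  primary index), Closeness and Betweenness (shortest paths with edge
  length 1/|w|).
- **Accuracy** — nonparametric bootstrap percentile intervals for every
  edge weight, re-running the whole pipeline per replicate.
- **Stability** — case-dropping subset bootstrap of Strength and the
  CS-coefficient: the largest share of participants that can be dropped
  while subsample Strength still correlates ≥ 0.7 with the full-sample
  Strength in 95% of replicates.
- **Group comparison** — a two-tailed permutation test (NCT) of every
  edge and every node's Strength between returners and non-returners,
  re-estimating both networks in each of the label permutations.

A synthetic-cohort generator with a known sparse partial-correlation
structure (two groups, 115 returned / 326 not returned, bounded 0–100
item marginals) provides ground truth for every stage.

## Worked example

```python
from rsinet import (
    make_spec_from_study_defaults, generate, concat, fit_network, strength,
)

spec = make_spec_from_study_defaults(seed=1)
returned, not_returned = generate(spec)
whole = concat([returned, not_returned])

model = fit_network(whole.items, node_labels=whole.item_labels)
print(f"lambda = {model.lam:.4f}, edges = {model.edge_count}")
print(f"Q7-Q9 partial correlation = {model.W[6, 8]:.3f}")
s = strength(model.W)
top = max(range(12), key=lambda i: s[i])
print(f"top Strength node: {model.node_labels[top]} ({s[top]:.2f})")
```

prints

```
lambda = 0.0284, edges = 55
Q7-Q9 partial correlation = 0.500
top Strength node: Q12 (1.07)
```

The strongest edge is between fear of re-injury (Q7) and fear of
accidental injury (Q9) — the generator plants it at 0.48 and the
pipeline recovers it almost unshrunk — and the most central item is
feeling relaxed about sport (Q12), whose many moderate associations sum
to the largest Strength.

The numbered drivers under `analysis/` run the full study sequence on
the synthetic cohort: `01_simulate_cohort.py` writes the cohort CSV,
then `02_descriptives.py`, `03_fit_networks.py`, `04_centrality.py`,
`05_bootstrap_stability.py` and `06_compare_groups.py` each write their
tables under `results/`.

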