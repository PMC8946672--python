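"""Bootstrap accuracy of edge weights and case-dropping stability of centrality.

Two resampling schemes, both re-running the full estimation pipeline
(nonparanormal transform -> correlation -> EBIC-tuned graphical LASSO) on
each replicate:

* nonparametric bootstrap (rows resampled with replacement) for percentile
  confidence intervals of every edge weight;
* case-dropping subset bootstrap: a proportion pi of participants is
  dropped, the network re-estimated, and node Strength re-computed; the
  correlation of each replicate's Strength vector with the original
  quantifies how stable the centrality ordering is under data loss. The
  CS-coefficient is the largest pi at which, with 95% probability, that
  correlation still reaches 0.7.

Replicates are driven by independent substreams spawned from one master
seed, so results are reproducible and independent of execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import strength
from .cohort import CohortTable
from .network import NetworkModel, fit_network

#: Default case-dropping grid: 5% to 75% in 5% steps (75% is the
#: conventional ceiling of the stability framework).
DEFAULT_DROP_GRID: tuple[float, ...] = tuple(
    round(0.05 * k, 2) for k in range(1, 16)
)


def _upper_pairs(labels) -> list[tuple[str, str]]:
    p = len(labels)
    return [(labels[i], labels[j]) for i in range(p) for j in range(i + 1, p)]


def _pipeline_kwargs(kw: dict) -> dict:
    allowed = {"gamma", "n_lambda", "lambda_min_ratio"}
    return {k: v for k, v in kw.items() if k in allowed}


@dataclass
class EdgeBootstrapResult:
    """Per-edge bootstrap distribution summary."""

    edges: list[tuple[str, str]]
    sample: np.ndarray          # observed edge weights (upper triangle)
    boot_weights: np.ndarray    # B x n_edges replicate weights
    B: int
    seed: int
    ci_level: float = 0.95
    model: NetworkModel | None = field(default=None, repr=False)

    @property
    def boot_mean(self) -> np.ndarray:
        return self.boot_weights.mean(axis=0)

    @property
    def ci(self) -> tuple[np.ndarray, np.ndarray]:
        a = (1.0 - self.ci_level) / 2.0
        lo = np.quantile(self.boot_weights, a, axis=0)
        hi = np.quantile(self.boot_weights, 1.0 - a, axis=0)
        return lo, hi

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.ci
        return pd.DataFrame(
            {
                "node_i": [e[0] for e in self.edges],
                "node_j": [e[1] for e in self.edges],
                "estimate": self.sample,
                "boot_mean": self.boot_mean,
                "ci_low": lo,
                "ci_high": hi,
            }
        )

    def edge_interval(self, a: str, b: str) -> tuple[float, float, float]:
        """(estimate, ci_low, ci_high) for the edge between labels a and b."""
        lo, hi = self.ci
        for k, (i, j) in enumerate(self.edges):
            if {i, j} == {a, b}:
                return float(self.sample[k]), float(lo[k]), float(hi[k])
        raise KeyError(f"edge {a}-{b} not found")


def _resample_until_valid(fit_one, rng_streams, B: int, what: str):
    """Run fit_one(rng) until B successes, redrawing failures.

    The total attempt budget is 2B; exceeding it raises, since systematic
    failure means the data cannot support the resampling scheme.
    """
    out = []
    attempts = 0
    stream_iter = iter(rng_streams)
    while len(out) < B:
        if attempts >= 2 * B:
            raise RuntimeError(
                f"{what}: more than {2 * B} attempts needed for {B} replicates"
            )
        attempts += 1
        rng = np.random.default_rng(next(stream_iter))
        try:
            out.append(fit_one(rng))
        except (ValueError, RuntimeError) as err:
            warnings.warn(f"{what}: replicate failed ({err}); redrawn", stacklevel=2)
    return out


def bootstrap_edges(
    cohort: CohortTable,
    B: int = 1000,
    seed: int = 0,
    **pipeline_kwargs,
) -> EdgeBootstrapResult:
    """Nonparametric bootstrap of all edge weights.

    Each replicate resamples n rows with replacement and re-runs the full
    pipeline (its own nonparanormal transform, correlation matrix and EBIC
    lambda selection). Reports per-edge bootstrap means and percentile 95%
    intervals. Replicates whose estimation fails (e.g. a resampled constant
    column) are redrawn, up to 2B total attempts.
    """
    if B < 100:
        warnings.warn(f"B={B} < 100 is too small for interval reporting",
                      stacklevel=2)
    elif B < 1000:
        warnings.warn(f"B={B} < 1000: intervals will be noisy", stacklevel=2)
    kw = _pipeline_kwargs(pipeline_kwargs)
    labels = cohort.item_labels
    model = fit_network(cohort.items, node_labels=labels, **kw)
    iu = np.triu_indices(cohort.p, k=1)
    sample_w = model.W[iu]

    streams = np.random.SeedSequence(seed).spawn(2 * B)

    def one(rng: np.random.Generator) -> np.ndarray:
        idx = rng.integers(0, cohort.n, size=cohort.n)
        m = fit_network(cohort.items[idx], node_labels=labels, **kw)
        return m.W[iu]

    boot = np.vstack(_resample_until_valid(one, streams, B, "edge bootstrap"))
    return EdgeBootstrapResult(
        edges=_upper_pairs(labels),
        sample=sample_w,
        boot_weights=boot,
        B=B,
        seed=seed,
        model=model,
    )


@dataclass
class CaseDropResult:
    """Strength correlations under increasing case-dropping proportions."""

    drop_proportions: tuple[float, ...]
    correlations: dict[float, np.ndarray]  # pi -> replicate correlations
    seed: int
    correlation_threshold: float = 0.7
    probability_level: float = 0.95
    original_strength: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pi in self.drop_proportions:
            for r in self.correlations[pi]:
                rows.append({"drop_proportion": pi, "correlation": r})
        return pd.DataFrame(rows)


def case_drop_bootstrap(
    cohort: CohortTable,
    proportions=DEFAULT_DROP_GRID,
    B_per_proportion: int = 1000,
    seed: int = 0,
    **pipeline_kwargs,
) -> CaseDropResult:
    """Case-dropping subset bootstrap of node Strength.

    For each drop proportion pi, repeatedly subsample floor((1-pi) n) rows
    without replacement, re-estimate the network, and record the Pearson
    correlation between the replicate's node-Strength vector and the
    original network's. A replicate with a degenerate (constant) Strength
    vector contributes a correlation of 0, since it carries no evidence of
    a preserved ordering.
    """
    proportions = tuple(float(x) for x in proportions)
    for pi in proportions:
        if not 0.0 < pi < 1.0:
            raise ValueError(f"drop proportion {pi} outside (0, 1)")
        if (1.0 - pi) * cohort.n < cohort.p + 5:
            raise ValueError(
                f"drop proportion {pi} leaves fewer than p + 5 = "
                f"{cohort.p + 5} participants"
            )
    kw = _pipeline_kwargs(pipeline_kwargs)
    labels = cohort.item_labels
    model = fit_network(cohort.items, node_labels=labels, **kw)
    s0 = strength(model.W)

    root = np.random.SeedSequence(seed)
    per_pi = root.spawn(len(proportions))
    correlations: dict[float, np.ndarray] = {}
    for pi, ss in zip(proportions, per_pi):
        m = int(np.floor((1.0 - pi) * cohort.n))

        def one(rng: np.random.Generator) -> float:
            idx = rng.choice(cohort.n, size=m, replace=False)
            mod = fit_network(cohort.items[idx], node_labels=labels, **kw)
            s = strength(mod.W)
            if s.std() == 0 or s0.std() == 0:
                return 0.0
            return float(np.corrcoef(s, s0)[0, 1])

        streams = ss.spawn(2 * B_per_proportion)
        vals = _resample_until_valid(
            one, streams, B_per_proportion, f"case-drop pi={pi}"
        )
        correlations[pi] = np.asarray(vals)
    return CaseDropResult(
        drop_proportions=proportions,
        correlations=correlations,
        seed=seed,
        original_strength=s0,
    )


def cs_coefficient(result: CaseDropResult) -> float:
    """Correlation-stability coefficient.

    The largest drop proportion pi such that at every proportion up to and
    including pi, at least 95% of replicate correlations reach the 0.7
    threshold (monotone qualification from the bottom of the grid);
    0 if even the smallest proportion fails.
    """
    cs = 0.0
    for pi in sorted(result.drop_proportions):
        r = np.abs(result.correlations[pi])
        ok = (r >= result.correlation_threshold).mean() >= result.probability_level
        if ok:
            cs = pi
        else:
            break
    return cs
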