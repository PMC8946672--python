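"""Permutation network comparison test (NCT) between two participant groups.

Each group's network is estimated with the full pipeline (its own
nonparanormal transform, correlation matrix and EBIC-selected penalty).
The two-tailed test statistic for an edge is the absolute difference of its
weights between groups; for a node it is the absolute difference of
Strength centrality. The null distribution comes from repeatedly permuting
the pooled participants into pseudo-groups of the original sizes and
re-estimating both networks, so it reflects the entire estimation pipeline
including penalty re-selection. p-values use the add-one permutation
estimator p = (1 + #{permuted >= observed}) / (1 + M), which can never be
exactly zero.

Per the exploratory design, p-values are reported unadjusted for multiple
comparisons and flagged as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import strength
from .cohort import CohortTable
from .network import NetworkModel, fit_network


@dataclass
class NCTResult:
    """Observed between-group differences and permutation p-values."""

    node_labels: tuple[str, ...]
    edge_pairs: list[tuple[str, str]]
    edge_diff: np.ndarray       # observed |w_A - w_B| per upper-triangle edge
    edge_p: np.ndarray
    strength_diff: np.ndarray   # observed |s_A - s_B| per node
    strength_p: np.ndarray
    global_strength_diff: float
    global_strength_p: float
    structure_diff: float       # omnibus max-edge-difference statistic
    structure_p: float
    n_permutations: int
    seed: int
    alpha: float = 0.05
    adjusted: bool = False
    model_A: NetworkModel | None = field(default=None, repr=False)
    model_B: NetworkModel | None = field(default=None, repr=False)

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_i": [e[0] for e in self.edge_pairs],
                "node_j": [e[1] for e in self.edge_pairs],
                "abs_diff": self.edge_diff,
                "p_value": self.edge_p,
            }
        )

    def strength_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": list(self.node_labels),
                "abs_diff": self.strength_diff,
                "p_value": self.strength_p,
            }
        )

    def edge_test(self, a: str, b: str) -> tuple[float, float]:
        """(observed |difference|, p-value) for the edge between a and b."""
        for k, (i, j) in enumerate(self.edge_pairs):
            if {i, j} == {a, b}:
                return float(self.edge_diff[k]), float(self.edge_p[k])
        raise KeyError(f"edge {a}-{b} not found")

    def strength_test(self, node: str) -> tuple[float, float]:
        k = self.node_labels.index(node)
        return float(self.strength_diff[k]), float(self.strength_p[k])


def _stats_for(items_A, items_B, labels, iu, kw):
    mA = fit_network(items_A, node_labels=labels, **kw)
    mB = fit_network(items_B, node_labels=labels, **kw)
    edge = np.abs(mA.W[iu] - mB.W[iu])
    st = np.abs(strength(mA.W) - strength(mB.W))
    gs = abs(np.abs(mA.W[iu]).sum() - np.abs(mB.W[iu]).sum())
    return mA, mB, edge, st, gs, edge.max() if edge.size else 0.0


def nct(
    cohort_A: CohortTable,
    cohort_B: CohortTable,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    **pipeline_kwargs,
) -> NCTResult:
    """Two-group permutation network comparison test.

    Tests every edge weight and every node's Strength with two-tailed
    absolute-difference statistics; also reports the omnibus
    structure-invariance statistic (maximum edge difference) and the global
    strength difference as extras. All statistics share one permutation
    draw set. Reproducible from ``seed``; degenerate permuted replicates
    are redrawn with a 2M total-attempt cap.
    """
    if cohort_A.item_labels != cohort_B.item_labels:
        raise ValueError("groups must share the same item set")
    p = cohort_A.p
    for name, c in (("A", cohort_A), ("B", cohort_B)):
        if c.n < 3:
            raise ValueError(f"group {name} has n={c.n} < 3")
        if c.n < p + 5:
            warnings.warn(
                f"group {name} has n={c.n} < p + 5 = {p + 5}; estimates "
                "will be unstable", stacklevel=2,
            )

    kw = {k: v for k, v in pipeline_kwargs.items()
          if k in {"gamma", "n_lambda", "lambda_min_ratio"}}
    labels = cohort_A.item_labels
    iu = np.triu_indices(p, k=1)

    mA, mB, obs_edge, obs_str, obs_gs, obs_struct = _stats_for(
        cohort_A.items, cohort_B.items, labels, iu, kw
    )

    pooled = np.vstack([cohort_A.items, cohort_B.items])
    nA, n_tot = cohort_A.n, pooled.shape[0]

    ge_edge = np.zeros_like(obs_edge)
    ge_str = np.zeros_like(obs_str)
    ge_gs = 0
    ge_struct = 0
    streams = iter(np.random.SeedSequence(seed).spawn(2 * n_permutations))
    done = attempts = 0
    while done < n_permutations:
        if attempts >= 2 * n_permutations:
            raise RuntimeError(
                f"NCT: more than {2 * n_permutations} permutation attempts needed"
            )
        attempts += 1
        rng = np.random.default_rng(next(streams))
        perm = rng.permutation(n_tot)
        try:
            _, _, e, s, gs, struct = _stats_for(
                pooled[perm[:nA]], pooled[perm[nA:]], labels, iu, kw
            )
        except (ValueError, RuntimeError) as err:
            warnings.warn(f"NCT: permutation replicate failed ({err}); redrawn",
                          stacklevel=2)
            continue
        ge_edge += e >= obs_edge
        ge_str += s >= obs_str
        ge_gs += gs >= obs_gs
        ge_struct += struct >= obs_struct
        done += 1

    M = n_permutations
    return NCTResult(
        node_labels=tuple(labels),
        edge_pairs=[(labels[i], labels[j]) for i, j in zip(*iu)],
        edge_diff=obs_edge,
        edge_p=(1.0 + ge_edge) / (1.0 + M),
        strength_diff=obs_str,
        strength_p=(1.0 + ge_str) / (1.0 + M),
        global_strength_diff=float(obs_gs),
        global_strength_p=(1.0 + ge_gs) / (1.0 + M),
        structure_diff=float(obs_struct),
        structure_p=(1.0 + ge_struct) / (1.0 + M),
        n_permutations=M,
        seed=seed,
        alpha=alpha,
        model_A=mA,
        model_B=mB,
    )


def nct_exhaustive(
    cohort_A: CohortTable,
    cohort_B: CohortTable,
    max_assignments: int = 200_000,
    **pipeline_kwargs,
) -> NCTResult:
    """Exact permutation NCT by exhaustive enumeration of group assignments.

    Enumerates every C(n_A + n_B, n_A) way of splitting the pooled rows
    into groups of the original sizes; the exact p-value is the proportion
    of assignments whose statistic is at least the observed one (the
    identity assignment is included, so p > 0). Only feasible for tiny
    groups; guarded by ``max_assignments``.
    """
    from itertools import combinations
    from math import comb

    if cohort_A.item_labels != cohort_B.item_labels:
        raise ValueError("groups must share the same item set")
    kw = {k: v for k, v in pipeline_kwargs.items()
          if k in {"gamma", "n_lambda", "lambda_min_ratio"}}
    labels = cohort_A.item_labels
    p = cohort_A.p
    iu = np.triu_indices(p, k=1)
    pooled = np.vstack([cohort_A.items, cohort_B.items])
    nA, n_tot = cohort_A.n, pooled.shape[0]
    n_assign = comb(n_tot, nA)
    if n_assign > max_assignments:
        raise ValueError(
            f"{n_assign} assignments exceed the exhaustive cap {max_assignments}"
        )

    mA, mB, obs_edge, obs_str, obs_gs, obs_struct = _stats_for(
        cohort_A.items, cohort_B.items, labels, iu, kw
    )
    ge_edge = np.zeros_like(obs_edge)
    ge_str = np.zeros_like(obs_str)
    ge_gs = ge_struct = 0
    all_idx = np.arange(n_tot)
    for pick in combinations(range(n_tot), nA):
        a = np.array(pick)
        b = np.setdiff1d(all_idx, a, assume_unique=True)
        _, _, e, s, gs, struct = _stats_for(pooled[a], pooled[b], labels, iu, kw)
        ge_edge += e >= obs_edge - 1e-12
        ge_str += s >= obs_str - 1e-12
        ge_gs += gs >= obs_gs - 1e-12
        ge_struct += struct >= obs_struct - 1e-12

    return NCTResult(
        node_labels=tuple(labels),
        edge_pairs=[(labels[i], labels[j]) for i, j in zip(*iu)],
        edge_diff=obs_edge,
        edge_p=ge_edge / n_assign,
        strength_diff=obs_str,
        strength_p=ge_str / n_assign,
        global_strength_diff=float(obs_gs),
        global_strength_p=ge_gs / n_assign,
        structure_diff=float(obs_struct),
        structure_p=ge_struct / n_assign,
        n_permutations=n_assign,
        seed=-1,
        model_A=mA,
        model_B=mB,
    )


def report_significant(result: NCTResult, alpha: float = 0.05) -> pd.DataFrame:
    """Statistics with unadjusted p < alpha, flagged as exploratory.

    Returns a frame with columns ``statistic, abs_diff, p_value, adjusted``
    where ``statistic`` is e.g. ``edge Q2-Q7`` or ``strength Q8``; the
    ``adjusted`` column is always False (no multiple-comparison correction,
    by design).
    """
    rows = []
    for (a, b), d, pv in zip(result.edge_pairs, result.edge_diff, result.edge_p):
        if pv < alpha:
            rows.append({"statistic": f"edge {a}-{b}", "abs_diff": d, "p_value": pv})
    for node, d, pv in zip(result.node_labels, result.strength_diff,
                           result.strength_p):
        if pv < alpha:
            rows.append({"statistic": f"strength {node}", "abs_diff": d,
                         "p_value": pv})
    out = pd.DataFrame(rows, columns=["statistic", "abs_diff", "p_value"])
    out["adjusted"] = False
    return out
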