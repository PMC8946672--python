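"""Synthetic two-group ACL-RSI cohorts with known sparse network structure.

The generator draws a latent multivariate normal whose precision matrix has
unit diagonal and off-diagonals equal to minus the planted partial
correlations, maps each item through a Gaussian quantile with per-group
per-item mean/SD on the 0-100 scale, clips to [0, 100] and rounds to
integers. Clipping reproduces the floor/ceiling effects typical of 0-100
rating scales (and slightly attenuates the planted correlations; recovery
tolerances downstream account for this).

The default specification mirrors the study conditions this package
targets: group sizes 115 (returned to pre-injury sport) and 326 (did not),
marginal means/SDs per group on the observed item scale, a strongest planted
edge Q7-Q9 = 0.48 and second Q4-Q8 = 0.37, a set of weaker edges in
[0.05, 0.2] concentrated around Q12 (so Q12 carries the highest Strength in
the larger group), and three edges (Q2-Q7, Q5-Q8, Q3-Q12) planted stronger
in the returned group to give the two-group comparison a true alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import ITEM_LABELS, CohortTable, concat

#: Per-item (mean, SD) on the 0-100 scale: returned group.
RETURNED_MARGINALS = {
    "Q1": (89.30, 14.80), "Q2": (74.44, 24.53), "Q3": (70.10, 29.69),
    "Q4": (83.94, 20.29), "Q5": (79.84, 24.24), "Q6": (60.63, 34.87),
    "Q7": (64.54, 30.84), "Q8": (83.46, 20.06), "Q9": (65.30, 30.09),
    "Q10": (81.81, 24.69), "Q11": (85.91, 18.85), "Q12": (80.07, 22.08),
}

#: Per-item (mean, SD): not-returned group.
NOT_RETURNED_MARGINALS = {
    "Q1": (71.74, 26.36), "Q2": (59.82, 25.49), "Q3": (47.92, 28.53),
    "Q4": (63.77, 26.73), "Q5": (54.86, 29.66), "Q6": (39.87, 30.68),
    "Q7": (42.57, 28.11), "Q8": (65.42, 24.86), "Q9": (43.55, 27.77),
    "Q10": (56.58, 33.31), "Q11": (63.25, 27.63), "Q12": (55.06, 27.81),
}

#: Planted partial correlations common to both groups, keyed by 1-based
#: item numbers. Two strong edges plus weaker edges clustered on Q12.
COMMON_EDGES = {
    (7, 9): 0.48, (4, 8): 0.37,
    (6, 12): 0.18, (10, 12): 0.18, (11, 12): 0.15, (5, 12): 0.15,
    (9, 12): 0.12, (1, 11): 0.18, (4, 5): 0.15, (2, 10): 0.15,
    (3, 7): 0.12, (6, 7): 0.08,
}

#: Edges that differ between groups (returned, not-returned): the
#: between-group comparison's true alternative hypotheses.
GROUP_EDGES = {
    (2, 7): (0.30, 0.05),
    (5, 8): (0.22, 0.05),
    (3, 12): (0.15, 0.06),
}

#: Weak partial correlation planted on every pair not listed above.
#: All 12 items reflect one construct (readiness), so real item pairs are
#: never conditionally independent — they show a positive manifold of small
#: partial correlations. This background reproduces the observed regime of
#: dense estimated networks with lightly shrunk strong edges; without it the
#: EBIC selection is far sparser than anything seen on real rating scales.
BACKGROUND_PARTIAL = 0.04


def _partial_matrix(p: int, edges: dict[tuple[int, int], float]) -> np.ndarray:
    P = np.zeros((p, p))
    for (i, j), w in edges.items():
        P[i - 1, j - 1] = P[j - 1, i - 1] = w
    return P


@dataclass
class SyntheticSpec:
    """Ground-truth specification for a two-group synthetic cohort.

    ``P_A``/``P_B`` are the planted partial-correlation matrices (group A =
    returned, group B = not returned); the implied precision matrices (unit
    diagonal, off-diagonals -P) must be positive definite — if not, the
    off-diagonals are uniformly shrunk and the factor recorded in
    ``shrink_factor``.
    """

    p: int
    n_A: int
    n_B: int
    P_A: np.ndarray
    P_B: np.ndarray
    means_A: np.ndarray
    sds_A: np.ndarray
    means_B: np.ndarray
    sds_B: np.ndarray
    seed: int
    item_labels: tuple[str, ...] = field(default=ITEM_LABELS)
    shrink_factor: float = 1.0
    round_scores: bool = True

    def __post_init__(self) -> None:
        for name in ("P_A", "P_B", "means_A", "sds_A", "means_B", "sds_B"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for g in ("A", "B"):
            n = getattr(self, f"n_{g}")
            if n < self.p + 5:
                raise ValueError(f"group {g} size {n} < p + 5")
            P = getattr(self, f"P_{g}")
            if P.shape != (self.p, self.p) or not np.allclose(P, P.T):
                raise ValueError(f"P_{g} must be symmetric {self.p} x {self.p}")
            if np.abs(np.diag(P)).max() > 0:
                raise ValueError(f"P_{g} must have a zero diagonal")
        # repair positive definiteness by uniform off-diagonal shrinkage
        factor = 1.0
        for _ in range(60):
            ok = all(
                np.linalg.eigvalsh(self._precision(g, factor)).min() > 1e-6
                for g in ("A", "B")
            )
            if ok:
                break
            factor *= 0.95
        else:
            raise ValueError("could not repair positive definiteness")
        if factor != 1.0:
            self.P_A = self.P_A * factor
            self.P_B = self.P_B * factor
        self.shrink_factor = factor

    def _precision(self, group: str, factor: float = 1.0) -> np.ndarray:
        P = getattr(self, f"P_{group}") * factor
        return np.eye(self.p) - P + np.diag(np.diag(P))

    def precision(self, group: str) -> np.ndarray:
        """Implied precision matrix (unit diagonal, off-diagonals -P)."""
        return self._precision(group)

    def latent_correlation(self, group: str) -> np.ndarray:
        """Correlation matrix of the latent normal implied by the precision."""
        Sigma = np.linalg.inv(self.precision(group))
        d = 1.0 / np.sqrt(np.diag(Sigma))
        return Sigma * np.outer(d, d)


def make_spec_from_study_defaults(seed: int = 0) -> SyntheticSpec:
    """The default two-group specification (sizes 115 / 326, see module doc)."""
    p = len(ITEM_LABELS)
    edges_A = dict(COMMON_EDGES)
    edges_B = dict(COMMON_EDGES)
    for pair, (wa, wb) in GROUP_EDGES.items():
        edges_A[pair] = wa
        edges_B[pair] = wb
    for i in range(1, p + 1):
        for j in range(i + 1, p + 1):
            edges_A.setdefault((i, j), BACKGROUND_PARTIAL)
            edges_B.setdefault((i, j), BACKGROUND_PARTIAL)
    mA = np.array([RETURNED_MARGINALS[q][0] for q in ITEM_LABELS])
    sA = np.array([RETURNED_MARGINALS[q][1] for q in ITEM_LABELS])
    mB = np.array([NOT_RETURNED_MARGINALS[q][0] for q in ITEM_LABELS])
    sB = np.array([NOT_RETURNED_MARGINALS[q][1] for q in ITEM_LABELS])
    return SyntheticSpec(
        p=p, n_A=115, n_B=326,
        P_A=_partial_matrix(p, edges_A), P_B=_partial_matrix(p, edges_B),
        means_A=mA, sds_A=sA, means_B=mB, sds_B=sB,
        seed=seed,
    )


def _draw_group(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    group: str,
    n: int,
    returned: bool,
    id_prefix: str,
) -> CohortTable:
    R = spec.latent_correlation(group)
    L = np.linalg.cholesky(R)
    z = rng.standard_normal((n, spec.p)) @ L.T
    means = getattr(spec, f"means_{group}")
    sds = getattr(spec, f"sds_{group}")
    x = means + sds * z
    x = np.clip(x, 0.0, 100.0)
    if spec.round_scores:
        x = np.round(x)
    ids = np.array([f"{id_prefix}{i:04d}" for i in range(n)], dtype=object)
    return CohortTable(
        items=x,
        returned=np.full(n, returned),
        participant_id=ids,
        item_labels=spec.item_labels,
    )


def generate(spec: SyntheticSpec) -> tuple[CohortTable, CohortTable]:
    """Draw (returned, not-returned) cohorts from the spec; deterministic
    in ``spec.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    cohort_A = _draw_group(rng, spec, "A", spec.n_A, True, "R")
    cohort_B = _draw_group(rng, spec, "B", spec.n_B, False, "N")
    return cohort_A, cohort_B


def generate_combined(spec: SyntheticSpec) -> CohortTable:
    """Both groups stacked into one whole-cohort table (returned first)."""
    a, b = generate(spec)
    return concat([a, b])
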