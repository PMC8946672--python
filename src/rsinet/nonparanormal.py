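"""Nonparanormal (Gaussian copula) marginal transformation.

Bounded 0-100 questionnaire items are skewed and have ceiling effects, so
their joint distribution is far from multivariate normal. The nonparanormal
transform replaces each item's marginal with standard-normal quantiles of a
truncated empirical CDF, preserving ranks (and therefore all rank-based
dependence) while making Gaussian graphical model estimation applicable.

The truncation constant delta_n = 1 / (4 n^{1/4} sqrt(pi ln n)) bounds the
ECDF away from 0 and 1 so that the normal quantile stays finite; this is the
"shrunken ECDF" estimator standard in the sparse-graphical-model literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class GaussianizedMatrix:
    """Column-wise rank-to-normal transformed score matrix.

    Attributes
    ----------
    values : ndarray, shape (n, p)
        Transformed scores; each column has (approximately) zero mean and
        unit sample variance.
    source_ranks : ndarray, shape (n, p)
        Average ranks of the raw scores per column, kept for audit.
    truncation : float
        The truncation constant delta_n applied to the scaled ECDF.
    """

    values: np.ndarray
    source_ranks: np.ndarray
    truncation: float

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def truncation_constant(n: int) -> float:
    """delta_n = 1 / (4 n^{1/4} sqrt(pi ln n))."""
    return 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))


def npn_transform(X: np.ndarray, item_labels=None) -> GaussianizedMatrix:
    """Map each column to approximate standard-normal scores by rank.

    Per column: average ranks -> ECDF scaled by n/(n+1) -> clipped to
    [delta_n, 1 - delta_n] -> standard normal quantile -> centred and
    rescaled to unit sample variance. Ties (average ranks) map to equal
    transformed values, and the map is monotone in the raw score.

    Raises
    ------
    ValueError
        If a column is constant (the transform is undefined) or the input
        contains missing values.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected an n x p matrix")
    n, p = X.shape
    if np.isnan(X).any():
        raise ValueError("missing values are not allowed in the transform")
    if n < 10:
        warnings.warn(
            f"nonparanormal transform with n={n} < 10 is unreliable",
            stacklevel=2,
        )

    const = np.where(X.max(axis=0) == X.min(axis=0))[0]
    if const.size:
        j = int(const[0])
        label = item_labels[j] if item_labels is not None else f"column {j}"
        raise ValueError(f"constant column: {label} (zero variance)")

    delta = truncation_constant(n)
    ranks = stats.rankdata(X, method="average", axis=0)
    u = np.clip(ranks / (n + 1.0), delta, 1.0 - delta)
    z = stats.norm.ppf(u)
    z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=1)
    return GaussianizedMatrix(values=z, source_ranks=ranks, truncation=delta)
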