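"""Epsilon-thresholded IF granules and their cardinalities.

The granule of sample i under a relation R is the IF set over all samples
obtained by zeroing relation values below a cut ``epsilon``; both the mu and
the nu component are thresholded independently at the same epsilon (the nu
cut can be disabled with ``threshold_nu=False``).  With a crisp relation and
``epsilon = 0`` granules are exactly the classical equivalence classes.

Cardinality of an IF granule is not uniquely defined; two modes are
provided:

* ``sigma_mu`` (default): the sigma-count ``sum_j mu_i(x_j)``, which
  reproduces the crisp limits (log2 n for the universal relation, 0 for the
  identity) exactly;
* ``mean_pi_adjusted``: ``sum_j (1 + mu - nu)/2`` over the support
  ``mu_i(x_j) > 0``, which lets the non-membership temper the count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GranuleFamily",
    "epsilon_granules",
    "granule_cardinality",
    "intersect_families",
    "decision_granules",
]

SIGMA_MU = "sigma_mu"
MEAN_PI_ADJUSTED = "mean_pi_adjusted"
_MODES = (SIGMA_MU, MEAN_PI_ADJUSTED)


@dataclass
class GranuleFamily:
    """Per-sample IF granules; row i of ``mu``/``nu`` is the granule of x_i."""

    mu: np.ndarray
    nu: np.ndarray
    epsilon: float
    cardinality_mode: str = SIGMA_MU

    def __post_init__(self) -> None:
        if self.cardinality_mode not in _MODES:
            raise ValueError(f"unknown cardinality mode {self.cardinality_mode!r}")

    @property
    def n(self) -> int:
        return self.mu.shape[0]

    def cardinalities(self) -> np.ndarray:
        """Vector of granule cardinalities, each in [1, n]."""
        if self.cardinality_mode == SIGMA_MU:
            return self.mu.sum(axis=1)
        support = self.mu > 0.0
        contrib = np.where(support, (1.0 + self.mu - self.nu) / 2.0, 0.0)
        return contrib.sum(axis=1)


def epsilon_granules(
    rel,
    epsilon: float,
    mode: str = SIGMA_MU,
    *,
    threshold_nu: bool = True,
) -> GranuleFamily:
    """Threshold a relation into a granule family.

    Values strictly below ``epsilon`` are zeroed; values at or above it are
    kept unchanged.  Since the relation diagonal is (1, 0), every sample
    keeps full self-membership for any ``epsilon <= 1``.
    """
    if not (0.0 <= epsilon <= 1.0):
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    mu = np.where(rel.mu >= epsilon, rel.mu, 0.0)
    nu = np.where(rel.nu >= epsilon, rel.nu, 0.0) if threshold_nu else rel.nu.copy()
    return GranuleFamily(mu=mu, nu=nu, epsilon=epsilon, cardinality_mode=mode)


def granule_cardinality(family: GranuleFamily, i: int) -> float:
    if not (0 <= i < family.n):
        raise IndexError(f"sample index {i} out of range for n={family.n}")
    return float(family.cardinalities()[i])


def _check_compatible(A: GranuleFamily, B: GranuleFamily) -> None:
    if A.n != B.n:
        raise ValueError(f"granule families differ in size: {A.n} vs {B.n}")
    if A.epsilon != B.epsilon:
        raise ValueError(
            f"granule families differ in epsilon: {A.epsilon} vs {B.epsilon}"
        )
    if A.cardinality_mode != B.cardinality_mode:
        raise ValueError("granule families differ in cardinality mode")


def intersect_families(A: GranuleFamily, B: GranuleFamily) -> GranuleFamily:
    """Per-sample intersection: min on mu, max on nu."""
    _check_compatible(A, B)
    return GranuleFamily(
        mu=np.minimum(A.mu, B.mu),
        nu=np.maximum(A.nu, B.nu),
        epsilon=A.epsilon,
        cardinality_mode=A.cardinality_mode,
    )


def decision_granules(
    labels,
    epsilon: float = 0.0,
    mode: str = SIGMA_MU,
) -> GranuleFamily:
    """Crisp granules of the decision classes: granule of x_i = its class.

    ``epsilon`` only tags the family for compatibility with conditional
    granules built at the same cut; crisp 0/1 values survive any epsilon <= 1.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    mu = (labels[:, None] == labels[None, :]).astype(float)
    return GranuleFamily(mu=mu, nu=1.0 - mu, epsilon=epsilon, cardinality_mode=mode)
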