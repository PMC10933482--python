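"""Rough entropies, mutual information and attribute significance on IF granules.

Two interchangeable conventions are exposed, related by an exact identity:

* ``granularity``: ``ET(B) = (1/n) sum_i log2 |[x_i]_B|`` — large for coarse
  granulation (all samples alike gives ``log2 n``), zero when every granule
  is a singleton.  Joint entropy uses granule intersections; mutual
  information is ``I(A;B) = ET(A) + ET(B) - ET(A,B)``.
* ``information``: the Shannon-style form ``H(B) = log2 n - ET(B)``
  (equivalently ``-(1/n) sum log2(|[x_i]|/n)``); all derived quantities are
  the corresponding complements, so ``I_information = log2 n -
  I_granularity``.

For feature ranking the information convention is the meaningful one: the
MI of a subset with the decision rises as the subset's granules become
consistent with the decision classes.  The granularity convention is kept
as the native form of the underlying algebra and is the one the monotonicity
propositions are stated in.

Attribute significance ``Omega(Y, P, D) = I(P u {Y}; D) - I(P; D)`` is the
MI gain of adding Y to the subset P, the greedy selection score; with
``P = {}`` it is ``I({Y}; D)``.
"""

from __future__ import annotations

import math

import numpy as np

from .granules import (
    SIGMA_MU,
    GranuleFamily,
    decision_granules,
    epsilon_granules,
    intersect_families,
)
from .ifis import IFInformationSystem
from .relation import subset_relation, universal_relation

__all__ = [
    "rough_entropy",
    "joint_entropy",
    "conditional_entropy",
    "mutual_information",
    "decision_mutual_information",
    "subset_decision_mi",
    "significance",
]

GRANULARITY = "granularity"
INFORMATION = "information"
_CONVENTIONS = (GRANULARITY, INFORMATION)


def _check_convention(convention: str) -> None:
    if convention not in _CONVENTIONS:
        raise ValueError(f"unknown entropy convention {convention!r}")


def rough_entropy(family: GranuleFamily, convention: str = GRANULARITY) -> float:
    _check_convention(convention)
    if family.n == 0:
        raise ValueError("empty granule family")
    et = float(np.mean(np.log2(family.cardinalities())))
    return et if convention == GRANULARITY else math.log2(family.n) - et


def joint_entropy(
    A: GranuleFamily, B: GranuleFamily, convention: str = GRANULARITY
) -> float:
    return rough_entropy(intersect_families(A, B), convention)


def conditional_entropy(
    target: GranuleFamily, given: GranuleFamily, convention: str = GRANULARITY
) -> float:
    """Chain-rule conditional entropy ``ET(target, given) - ET(given)``.

    In the granularity convention this is
    ``-(1/n) sum log2(|given_i| / |given_i ^ target_i|) <= 0``, zero exactly
    when the target granules refine nothing; the information convention
    returns the non-negative complementary form ``H(given,target) - H(given)``.
    """
    _check_convention(convention)
    cg = given.cardinalities()
    cj = intersect_families(given, target).cardinalities()
    et_cond = -float(np.mean(np.log2(cg / cj)))
    return et_cond if convention == GRANULARITY else -et_cond


def mutual_information(
    A: GranuleFamily, B: GranuleFamily, convention: str = GRANULARITY
) -> float:
    """``-(1/n) sum log2(|A_i ^ B_i| / (|A_i| |B_i|))`` (granularity)."""
    _check_convention(convention)
    ca = A.cardinalities()
    cb = B.cardinalities()
    cj = intersect_families(A, B).cardinalities()
    i_gran = -float(np.mean(np.log2(cj / (ca * cb))))
    return i_gran if convention == GRANULARITY else math.log2(A.n) - i_gran


def decision_mutual_information(
    cond: GranuleFamily, dec: GranuleFamily, convention: str = GRANULARITY
) -> float:
    """MI between a conditional granule family and the decision family."""
    return mutual_information(cond, dec, convention)


def subset_decision_mi(
    ifis: IFInformationSystem,
    subset,
    epsilon: float,
    convention: str = GRANULARITY,
    cardinality_mode: str = SIGMA_MU,
) -> float:
    """MI of an attribute subset with the decision; the empty subset uses the
    universal (all-similar) relation, so its information-convention MI is 0."""
    subset = tuple(subset)
    rel = universal_relation(ifis.n) if not subset else subset_relation(ifis, subset)
    fam = epsilon_granules(rel, epsilon, mode=cardinality_mode)
    dec = decision_granules(ifis.decision, epsilon=epsilon, mode=cardinality_mode)
    return decision_mutual_information(fam, dec, convention)


def significance(
    ifis: IFInformationSystem,
    Y: str,
    P,
    epsilon: float,
    convention: str = GRANULARITY,
    cardinality_mode: str = SIGMA_MU,
) -> float:
    """MI gain ``Omega(Y, P, D)`` of adding attribute Y to subset P.

    With empty P this is ``I({Y}; D)`` in either convention (for the
    information convention that coincides with the plain difference, since
    the empty subset carries zero information about D).
    """
    P = tuple(P)
    if Y in P:
        raise ValueError(f"candidate {Y!r} already in subset")
    ifis.attribute(Y)  # raises on unknown attribute
    if not P:
        return subset_decision_mi(ifis, (Y,), epsilon, convention, cardinality_mode)
    with_y = subset_decision_mi(ifis, P + (Y,), epsilon, convention, cardinality_mode)
    without = subset_decision_mi(ifis, P, epsilon, convention, cardinality_mode)
    return with_y - without
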