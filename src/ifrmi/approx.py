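"""IF rough lower/upper approximations and the dependency degree.

The operators are the standard inf-max / sup-min rough approximations with
the standard complement.  For a crisp class indicator ``X`` and a relation
``R`` with parts (mu, nu):

* lower: ``mu(x) = min_y max(nu_R(x,y), X(y))``,
  ``nu(x) = max_y min(mu_R(x,y), 1 - X(y))``
* upper: ``mu(x) = max_y min(mu_R(x,y), X(y))``,
  ``nu(x) = min_y max(nu_R(x,y), 1 - X(y))``

The dependency degree gamma averages, per sample, the best score-level
membership ``(mu + 1 - nu)/2`` in the lower approximation over all decision
classes; gamma = 1 iff every sample certainly belongs to its class's
positive region.  These quantities are reported alongside the MI trace and
never drive the greedy stopping rule.
"""

from __future__ import annotations

import numpy as np

from .relation import IFRelationMatrix

__all__ = ["lower_approximation", "upper_approximation", "dependency_degree"]


def _check_indicator(rel: IFRelationMatrix, indicator) -> np.ndarray:
    ind = np.asarray(indicator, dtype=float)
    if ind.shape != (rel.n,):
        raise ValueError(f"indicator length {ind.shape} does not match n={rel.n}")
    if not np.isin(ind, (0.0, 1.0)).all():
        raise ValueError("class indicator must be crisp (0/1)")
    return ind


def lower_approximation(rel: IFRelationMatrix, class_indicator):
    """Per-sample IF membership in the lower approximation of a crisp class.

    Returns (mu, nu) arrays of length n.
    """
    ind = _check_indicator(rel, class_indicator)
    mu = np.min(np.maximum(rel.nu, ind[None, :]), axis=1)
    nu = np.max(np.minimum(rel.mu, 1.0 - ind[None, :]), axis=1)
    return mu, nu


def upper_approximation(rel: IFRelationMatrix, class_indicator):
    """Dual of :func:`lower_approximation`; lower <= upper on mu always."""
    ind = _check_indicator(rel, class_indicator)
    mu = np.max(np.minimum(rel.mu, ind[None, :]), axis=1)
    nu = np.min(np.maximum(rel.nu, 1.0 - ind[None, :]), axis=1)
    return mu, nu


def dependency_degree(rel: IFRelationMatrix, labels) -> float:
    """Averaged certainty of class membership via lower approximations.

    ``gamma = (1/n) sum_x max_c (mu_lower_c(x) + 1 - nu_lower_c(x)) / 2``
    over decision classes c; in [0, 1], and 1 for the identity relation.
    """
    labels = np.asarray(labels)
    if labels.shape != (rel.n,):
        raise ValueError(f"label vector length {labels.shape} does not match n={rel.n}")
    scores = np.full(rel.n, -np.inf)
    for cls in np.unique(labels):
        mu, nu = lower_approximation(rel, (labels == cls).astype(float))
        scores = np.maximum(scores, (mu + 1.0 - nu) / 2.0)
    return float(np.mean(scores))
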