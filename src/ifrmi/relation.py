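"""Hybrid intuitionistic-fuzzy similarity relations over mixed attributes.

For a nominal attribute two samples are similar iff their codes are equal
(crisp 0/1 relation).  For a numeric attribute, similarity between samples
i and j is ``s(i,j) = 1 - |d_mu| * |d_nu|`` where ``d_mu``/``d_nu`` are the
differences of the fuzzified membership/non-membership grades, gated by an
adaptive radius: the pair counts as similar only when ``|d_mu| <= zeta_a``,
where ``zeta_a`` is the mean of ``|d_mu| * |d_nu|`` over all ordered sample
pairs of the attribute (a per-attribute spread measure; zero for a constant
attribute).  The non-membership part of every relation is the Sugeno
complement of the membership part, so the diagonal is (1, 0) and
``mu + nu <= 1`` holds cellwise.

Subset relations aggregate per-attribute matrices with the elementwise
minimum on mu and maximum on nu, so finer subsets yield finer relations
(monotonicity), which the entropy machinery relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ifis import NUMERIC, IFInformationSystem

__all__ = ["IFRelationMatrix", "AdaptiveRadius", "adaptive_radius",
           "attribute_relation", "subset_relation", "universal_relation"]

_GATE_TOL = 1e-12


@dataclass(frozen=True)
class AdaptiveRadius:
    attribute: str
    zeta: float


@dataclass
class IFRelationMatrix:
    """Pairwise IF similarity with mu- and nu-parts.

    Invariants (checked in :meth:`validate`): reflexive diagonal (1, 0),
    symmetric parts, and ``mu + nu <= 1`` per cell.
    """

    mu: np.ndarray
    nu: np.ndarray
    provenance: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.mu.shape[0]

    def validate(self, tol: float = 1e-9) -> "IFRelationMatrix":
        if self.mu.shape != self.nu.shape or self.mu.shape[0] != self.mu.shape[1]:
            raise ValueError("relation parts must be square and same-shaped")
        if not np.allclose(np.diag(self.mu), 1.0, atol=tol):
            raise ValueError("relation is not reflexive on mu")
        if not np.allclose(np.diag(self.nu), 0.0, atol=tol):
            raise ValueError("relation is not reflexive on nu")
        if not np.allclose(self.mu, self.mu.T, atol=tol):
            raise ValueError("mu part is not symmetric")
        if not np.allclose(self.nu, self.nu.T, atol=tol):
            raise ValueError("nu part is not symmetric")
        if np.any(self.mu + self.nu > 1.0 + tol):
            raise ValueError("mu + nu > 1 somewhere")
        return self


def _numeric_diffs(ifis: IFInformationSystem, attr: str):
    m = ifis.mu[attr]
    v = ifis.nu[attr]
    dmu = np.abs(m[:, None] - m[None, :])
    dnu = np.abs(v[:, None] - v[None, :])
    return dmu, dnu


def adaptive_radius(ifis: IFInformationSystem, attr: str) -> AdaptiveRadius:
    """Mean pairwise IF dissimilarity of a numeric attribute.

    ``zeta = (1/n^2) * sum_ij |d_mu(i,j)| * |d_nu(i,j)|`` over all ordered
    pairs including the diagonal; 0 for a constant attribute.
    """
    if not ifis.is_numeric(attr) or ifis.attribute(attr).role != "conditional":
        raise ValueError(f"attribute {attr!r} is not a numeric conditional attribute")
    dmu, dnu = _numeric_diffs(ifis, attr)
    return AdaptiveRadius(attribute=attr, zeta=float(np.mean(dmu * dnu)))


def attribute_relation(
    ifis: IFInformationSystem, attr: str, gate: str = "mu_only"
) -> IFRelationMatrix:
    """Relation matrix of a single conditional attribute.

    ``gate`` controls how the adaptive radius admits numeric pairs:
    ``"mu_only"`` (default) assigns ``s(i,j)`` whenever ``|d_mu| <= zeta``,
    else 0 — a total rule whose diagonal is (1, 0).  ``"as_printed"``
    additionally requires ``|d_nu| > zeta`` for similarity and
    ``|d_nu| <= zeta`` for dissimilarity, and raises on any pair covered by
    neither case (including the diagonal, whose differences are both zero).
    """
    schema = ifis.attribute(attr)
    if schema.role != "conditional":
        raise ValueError(f"attribute {attr!r} is not conditional")
    n = ifis.n
    if schema.kind == NUMERIC:
        dmu, dnu = _numeric_diffs(ifis, attr)
        zeta = adaptive_radius(ifis, attr).zeta
        sim = 1.0 - dmu * dnu
        if gate == "mu_only":
            mu = np.where(dmu <= zeta + _GATE_TOL, sim, 0.0)
        elif gate == "as_printed":
            case_sim = (dmu <= zeta + _GATE_TOL) & (dnu > zeta + _GATE_TOL)
            case_zero = (dmu > zeta + _GATE_TOL) & (dnu <= zeta + _GATE_TOL)
            uncovered = ~(case_sim | case_zero)
            if uncovered.any():
                i, j = np.argwhere(uncovered)[0]
                raise ValueError(
                    f"pair ({i}, {j}) of attribute {attr!r} is covered by no "
                    f"printed case (|d_mu|={dmu[i, j]:.6g}, "
                    f"|d_nu|={dnu[i, j]:.6g}, zeta={zeta:.6g})"
                )
            mu = np.where(case_sim, sim, 0.0)
        else:
            raise ValueError(f"unknown gate mode {gate!r}")
        np.fill_diagonal(mu, 1.0)
    else:
        codes = ifis.codes[attr]
        mu = (codes[:, None] == codes[None, :]).astype(float)
    mu = np.clip(mu, 0.0, 1.0)
    nu = (1.0 - mu) / (1.0 + ifis.lam * mu)
    assert mu.shape == (n, n)
    return IFRelationMatrix(mu=mu, nu=nu, provenance=(attr,))


def subset_relation(ifis: IFInformationSystem, subset, gate: str = "mu_only") -> IFRelationMatrix:
    """Aggregate relation of an attribute subset: min on mu, max on nu."""
    subset = tuple(subset)
    if not subset:
        raise ValueError("empty attribute subset")
    mats = [attribute_relation(ifis, a, gate=gate) for a in subset]
    mu = mats[0].mu.copy()
    nu = mats[0].nu.copy()
    for m in mats[1:]:
        np.minimum(mu, m.mu, out=mu)
        np.maximum(nu, m.nu, out=nu)
    return IFRelationMatrix(mu=mu, nu=nu, provenance=subset)


def universal_relation(n: int) -> IFRelationMatrix:
    """The all-similar relation induced by the empty attribute subset."""
    return IFRelationMatrix(
        mu=np.ones((n, n)), nu=np.zeros((n, n)), provenance=()
    )
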