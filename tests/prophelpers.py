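"""Shared machinery for the randomized entropy/relation proposition checks.

Generates small random IF information systems with nested attribute subsets
and asserts the monotonicity, chain-rule, symmetry and complement
identities of the granule entropy algebra on each instance.
"""

from __future__ import annotations

import math

import numpy as np

from ifrmi.entropy import (
    GRANULARITY,
    INFORMATION,
    conditional_entropy,
    joint_entropy,
    mutual_information,
    rough_entropy,
)
from ifrmi.granules import epsilon_granules
from ifrmi.relation import subset_relation
from ifrmi.synthdata import random_ifis

EPSILONS = (0.0, 0.3, 0.5, 0.8)
PROP_TOL = 1e-9
IDENTITY_TOL = 1e-12


def random_instance(seed: int):
    """One randomized system with nested subsets C1 subset of C2 and an
    arbitrary third subset, plus an epsilon from the standard grid."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 13))
    m = int(rng.integers(2, 6))
    ifis = random_ifis(seed=seed + 1, n=n, m=m)
    names = list(ifis.conditional_names)
    k2 = int(rng.integers(1, m + 1))
    c2 = tuple(rng.choice(names, size=k2, replace=False))
    k1 = int(rng.integers(1, k2 + 1))
    c1 = tuple(rng.choice(c2, size=k1, replace=False))
    k3 = int(rng.integers(1, m + 1))
    c3 = tuple(rng.choice(names, size=k3, replace=False))
    eps = EPSILONS[int(rng.integers(len(EPSILONS)))]
    return ifis, c1, c2, c3, eps


def check_propositions(seed: int) -> float:
    """Assert every proposition on one random instance.

    Returns the largest absolute violation observed (0 when all inequalities
    hold with slack), so callers can aggregate a worst-case number.
    """
    ifis, c1, c2, c3, eps = random_instance(seed)
    rel1 = subset_relation(ifis, c1)
    rel2 = subset_relation(ifis, c2)
    rel3 = subset_relation(ifis, c3)

    worst = 0.0

    def viol(x):  # positive means violated by x
        nonlocal worst
        worst = max(worst, x)
        assert x <= PROP_TOL
        return x

    # relation monotonicity under subset growth: C1 subset C2 => R1 >= R2
    viol(float(np.max(rel2.mu - rel1.mu)))
    viol(float(np.max(rel1.nu - rel2.nu)))

    g1 = epsilon_granules(rel1, eps)
    g2 = epsilon_granules(rel2, eps)
    g3 = epsilon_granules(rel3, eps)

    et1 = rough_entropy(g1)
    et2 = rough_entropy(g2)
    et3 = rough_entropy(g3)
    logn = math.log2(ifis.n)

    # entropy bounds and relation-monotone entropy (finer relation, lower ET)
    viol(-et1)
    viol(et1 - logn)
    viol(et2 - et1)  # ET(C1) >= ET(C2) for C1 subset C2

    # joint entropy: bounded by both marginals; equals the finer marginal
    # for nested subsets
    j13 = joint_entropy(g1, g3)
    viol(j13 - min(et1, et3))
    assert abs(joint_entropy(g1, g2) - et2) <= PROP_TOL

    # chain rule and its nested-subset degenerate case
    assert abs(conditional_entropy(g3, g1) - (j13 - et1)) <= PROP_TOL
    assert abs(conditional_entropy(g1, g2)) <= PROP_TOL  # C1 granules coarser

    # mutual information: symmetry, three-term identity, conditional forms
    i13 = mutual_information(g1, g3)
    assert abs(i13 - mutual_information(g3, g1)) <= PROP_TOL
    assert abs(i13 - (et1 + et3 - j13)) <= PROP_TOL
    assert abs(i13 - (et3 - conditional_entropy(g3, g1))) <= PROP_TOL
    assert abs(i13 - (et1 - conditional_entropy(g1, g3))) <= PROP_TOL

    return worst


def check_complement_identities(seed: int) -> float:
    """H = log2 n - ET and I_info = log2 n - I_gran, to 1e-12."""
    ifis, c1, _, c3, eps = random_instance(seed)
    g1 = epsilon_granules(subset_relation(ifis, c1), eps)
    g3 = epsilon_granules(subset_relation(ifis, c3), eps)
    logn = math.log2(ifis.n)
    errs = [
        abs(rough_entropy(g1, INFORMATION) - (logn - rough_entropy(g1, GRANULARITY))),
        abs(joint_entropy(g1, g3, INFORMATION)
            - (logn - joint_entropy(g1, g3, GRANULARITY))),
        abs(mutual_information(g1, g3, INFORMATION)
            - (logn - mutual_information(g1, g3, GRANULARITY))),
    ]
    worst = max(errs)
    assert worst <= IDENTITY_TOL
    return worst
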