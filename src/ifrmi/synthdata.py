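"""Seeded generators for mixed-type tables with planted structure.

The generator emulates the shape of screening datasets: a crisp class
label, a few informative numeric attributes drawn from class-shifted
Gaussians (unit within-class spread, means separated by ``effect``),
redundant attributes that are monotone (affine) transforms of informative
ones plus small noise, and class-independent noise attributes.  A fraction
of attributes is rendered nominal by tercile binning of the same draws, so
ground truth roles carry over to nominal columns.

It also provides the 3-sample worked fixture whose relation, granule,
entropy and MI values are small enough to verify by hand, plus a generator
of random IF information systems for property testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ifis import (
    CONDITIONAL,
    DECISION,
    NOMINAL,
    NUMERIC,
    AttributeSchema,
    IFInformationSystem,
    MixedDataset,
)

__all__ = ["SyntheticSpec", "generate_mixed", "worked_fixture", "random_ifis"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset; the seed is mandatory."""

    seed: int
    n: int = 200
    informative: int = 3
    redundant: int = 2
    noise: int = 10
    nominal_frac: float = 0.3
    classes: int = 2
    effect: float = 2.0
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.informative, self.redundant, self.noise) < 0:
            raise ValueError("attribute counts must be non-negative")
        if self.n < 2 * self.classes:
            raise ValueError("need n >= 2 * class count")
        if self.redundant > 0 and self.informative == 0:
            raise ValueError("redundant attributes require informative parents")
        if not (0.0 <= self.nominal_frac <= 1.0):
            raise ValueError("nominal_frac must be in [0, 1]")


def _tercile_bin(x: np.ndarray) -> np.ndarray:
    lo, hi = np.quantile(x, [1 / 3, 2 / 3])
    codes = np.where(x <= lo, "low", np.where(x <= hi, "mid", "high"))
    return codes


def generate_mixed(spec: SyntheticSpec) -> tuple[MixedDataset, dict[str, str]]:
    """Generate a dataset and the ground-truth role of every attribute.

    Returns ``(dataset, truth)`` with ``truth`` mapping each conditional
    attribute name to ``informative``/``redundant``/``noise``.  Fully
    reproducible from the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    base = np.repeat(np.arange(spec.classes), spec.n // spec.classes)
    labels = np.concatenate([base, rng.integers(spec.classes, size=spec.n - base.size)])
    labels = labels[rng.permutation(spec.n)]

    columns: dict[str, np.ndarray] = {}
    truth: dict[str, str] = {}
    schema: list[AttributeSchema] = []

    informative_cols: list[np.ndarray] = []
    for j in range(spec.informative):
        x = rng.normal(loc=spec.effect * labels, scale=1.0)
        informative_cols.append(x)
        columns[f"inf{j}"] = x
        truth[f"inf{j}"] = "informative"
    for j in range(spec.redundant):
        parent = informative_cols[j % spec.informative]
        slope = 0.5 + rng.random()  # positive => monotone
        x = slope * parent + rng.normal(scale=0.1 * spec.noise_scale, size=spec.n)
        columns[f"red{j}"] = x
        truth[f"red{j}"] = "redundant"
    for j in range(spec.noise):
        columns[f"noise{j}"] = rng.normal(scale=spec.noise_scale, size=spec.n)
        truth[f"noise{j}"] = "noise"

    frame = {}
    for name, values in columns.items():
        if rng.random() < spec.nominal_frac:
            frame[name] = _tercile_bin(values)
            schema.append(AttributeSchema(name, NOMINAL, CONDITIONAL))
        else:
            frame[name] = values
            schema.append(AttributeSchema(name, NUMERIC, CONDITIONAL))
    frame["class"] = np.array([f"c{int(c)}" for c in labels])
    schema.append(AttributeSchema("class", NOMINAL, DECISION))

    data = MixedDataset(frame=pd.DataFrame(frame), schema=tuple(schema))
    return data, truth


def worked_fixture() -> IFInformationSystem:
    """The 3-sample hand-checkable system used throughout the test suite.

    Numeric attribute ``a`` carries IF values (0.90, 0.05), (0.80, 0.10),
    (0.10, 0.80); nominal attribute ``b`` has codes (p, q, p); the decision
    is (A, A, B); lambda = 1.  Its adaptive radius is 2.19/9 and its eps=0.5
    granule cardinalities are (1.995, 1.995, 1).
    """
    schema = (
        AttributeSchema("a", NUMERIC, CONDITIONAL),
        AttributeSchema("b", NOMINAL, CONDITIONAL),
        AttributeSchema("d", NOMINAL, DECISION),
    )
    return IFInformationSystem(
        schema=schema,
        mu={"a": np.array([0.90, 0.80, 0.10])},
        nu={"a": np.array([0.05, 0.10, 0.80])},
        codes={"b": np.array([0, 1, 0])},
        decision=np.array(["A", "A", "B"]),
        lam=1.0,
    )


def random_ifis(
    seed: int,
    n: int = 8,
    m: int = 4,
    nominal_frac: float = 0.4,
    classes: int = 2,
    lam: float = 1.0,
) -> IFInformationSystem:
    """Random IF information system for property tests.

    Numeric attributes get mu ~ U(0,1) and nu ~ U(0, 1-mu); nominal
    attributes get uniform codes over up to 3 levels; the decision has the
    given number of classes.
    """
    rng = np.random.default_rng(seed)
    schema = []
    mu, nu, codes = {}, {}, {}
    for j in range(m):
        name = f"a{j}"
        if rng.random() < nominal_frac:
            schema.append(AttributeSchema(name, NOMINAL, CONDITIONAL))
            codes[name] = rng.integers(0, 3, size=n)
        else:
            schema.append(AttributeSchema(name, NUMERIC, CONDITIONAL))
            m_col = rng.random(n)
            mu[name] = m_col
            nu[name] = rng.random(n) * (1.0 - m_col)
    schema.append(AttributeSchema("d", NOMINAL, DECISION))
    decision = np.array([f"c{int(c)}" for c in rng.integers(0, classes, size=n)])
    return IFInformationSystem(
        schema=tuple(schema), mu=mu, nu=nu, codes=codes, decision=decision, lam=lam
    )
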