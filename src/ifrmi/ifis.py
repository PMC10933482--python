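"""Mixed-type tables and their intuitionistic-fuzzy information systems.

An intuitionistic fuzzy (IF) set assigns each element a membership grade mu
and a non-membership grade nu with ``mu + nu <= 1``; the slack
``pi = 1 - mu - nu`` is the hesitancy grade.  An IF information system (IFIS)
is a table of samples whose numeric conditional attributes have been mapped
to IF values, together with crisp nominal attributes and a crisp decision
attribute.

Numeric columns are fuzzified with min-max normalisation for the membership
and a Sugeno-class complement ``nu = (1 - mu) / (1 + lambda * mu)`` for the
non-membership.  Nominal attributes are never fuzzified: they enter the
similarity relation crisply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._arff import read_arff

__all__ = [
    "IFValue",
    "AttributeSchema",
    "MixedDataset",
    "IFInformationSystem",
    "load_table",
    "load_schema_sidecar",
    "intuitionistic_fuzzify",
    "validate_ifis",
]

_TOL = 1e-12

NOMINAL = "nominal"
NUMERIC = "numeric"
CONDITIONAL = "conditional"
DECISION = "decision"


@dataclass(frozen=True)
class IFValue:
    """A (membership, non-membership) pair.

    Construction does not validate so that deliberately broken values can be
    fed to :func:`validate_ifis`; call :meth:`violations` or
    :meth:`validate` to check the IF constraints.
    """

    mu: float
    nu: float

    @property
    def pi(self) -> float:
        """Hesitancy grade ``1 - mu - nu``."""
        return 1.0 - self.mu - self.nu

    def violations(self) -> list[str]:
        out = []
        if not (0.0 <= self.mu <= 1.0):
            out.append(f"mu = {self.mu} outside [0, 1]")
        if not (0.0 <= self.nu <= 1.0):
            out.append(f"nu = {self.nu} outside [0, 1]")
        if self.mu + self.nu > 1.0 + _TOL:
            out.append(f"mu + nu = {self.mu + self.nu} > 1")
        return out

    def validate(self) -> "IFValue":
        bad = self.violations()
        if bad:
            raise ValueError("invalid IF value: " + "; ".join(bad))
        return self


@dataclass(frozen=True)
class AttributeSchema:
    """Name, kind (nominal/numeric) and role (conditional/decision) of a column."""

    name: str
    kind: str
    role: str = CONDITIONAL

    def __post_init__(self) -> None:
        if self.kind not in (NOMINAL, NUMERIC):
            raise ValueError(f"unknown kind {self.kind!r} for attribute {self.name!r}")
        if self.role not in (CONDITIONAL, DECISION):
            raise ValueError(f"unknown role {self.role!r} for attribute {self.name!r}")


def _check_schema(attributes: Sequence[AttributeSchema]) -> tuple[AttributeSchema, ...]:
    attrs = tuple(attributes)
    decisions = [a for a in attrs if a.role == DECISION]
    if len(decisions) != 1:
        raise ValueError(
            f"exactly one decision attribute required, found {len(decisions)}"
        )
    names = [a.name for a in attrs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate attribute names in schema")
    return attrs


@dataclass
class MixedDataset:
    """A validated mixed nominal/numeric table with one crisp decision column.

    ``frame`` holds raw values: numeric columns as floats, nominal columns
    (and the decision) as strings/objects.  Column order follows ``schema``.
    """

    frame: pd.DataFrame
    schema: tuple[AttributeSchema, ...]

    def __post_init__(self) -> None:
        self.schema = _check_schema(self.schema)
        missing = [a.name for a in self.schema if a.name not in self.frame.columns]
        if missing:
            raise ValueError(f"schema attributes absent from table: {missing}")
        self.frame = self.frame[[a.name for a in self.schema]].reset_index(drop=True)
        for a in self.schema:
            col = self.frame[a.name]
            if col.isna().any():
                row = int(col.isna().idxmax())
                raise ValueError(f"missing value at row {row}, column {a.name!r}")
            if a.kind == NUMERIC and a.role == CONDITIONAL:
                vals = pd.to_numeric(col, errors="coerce")
                if vals.isna().any():
                    row = int(vals.isna().idxmax())
                    raise ValueError(
                        f"non-numeric token {col.iloc[row]!r} at row {row}, "
                        f"column {a.name!r}"
                    )
                if not np.isfinite(vals.to_numpy(dtype=float)).all():
                    raise ValueError(f"non-finite value in numeric column {a.name!r}")
                self.frame[a.name] = vals.astype(float)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def decision_name(self) -> str:
        return next(a.name for a in self.schema if a.role == DECISION)

    @property
    def conditional_attributes(self) -> tuple[AttributeSchema, ...]:
        return tuple(a for a in self.schema if a.role == CONDITIONAL)

    def decision_labels(self) -> np.ndarray:
        return self.frame[self.decision_name].astype(str).to_numpy()


@dataclass
class IFInformationSystem:
    """The quadruple (samples, conditional attributes, IF values, decision).

    Numeric conditional attributes carry per-sample (mu, nu) arrays; nominal
    conditional attributes carry integer codes assigned in first-appearance
    order; the decision is a crisp label vector.  ``lam`` is the positive
    parameter of the Sugeno complement used throughout (fuzzification and
    relation non-memberships).
    """

    schema: tuple[AttributeSchema, ...]
    mu: dict[str, np.ndarray]
    nu: dict[str, np.ndarray]
    codes: dict[str, np.ndarray]
    decision: np.ndarray  # original labels (strings)
    lam: float = 1.0

    def __post_init__(self) -> None:
        self.schema = _check_schema(self.schema)
        if self.lam <= 0:
            raise ValueError(f"lambda must be positive, got {self.lam}")
        self.decision = np.asarray(self.decision)
        if self.decision.size == 0:
            raise ValueError("empty decision vector")

    @property
    def n(self) -> int:
        return int(self.decision.size)

    @property
    def conditional_attributes(self) -> tuple[AttributeSchema, ...]:
        return tuple(a for a in self.schema if a.role == CONDITIONAL)

    @property
    def conditional_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.conditional_attributes)

    def attribute(self, name: str) -> AttributeSchema:
        for a in self.schema:
            if a.name == name:
                return a
        raise KeyError(f"unknown attribute {name!r}")

    def is_numeric(self, name: str) -> bool:
        return self.attribute(name).kind == NUMERIC


def load_schema_sidecar(path: str | Path) -> tuple[AttributeSchema, ...]:
    """Read a schema sidecar (YAML or JSON mapping column -> {kind, role})."""
    import json

    import yaml

    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"schema sidecar {path} must map column names to specs")
    out = []
    for name, entry in raw.items():
        out.append(
            AttributeSchema(
                name=str(name),
                kind=str(entry["kind"]),
                role=str(entry.get("role", CONDITIONAL)),
            )
        )
    return tuple(out)


def load_table(
    path: str | Path,
    schema: Sequence[AttributeSchema] | str | Path | None = None,
    *,
    impute: bool = False,
) -> MixedDataset:
    """Load a CSV (with schema sidecar) or ARFF file into a :class:`MixedDataset`.

    For CSV, ``schema`` is either a sequence of :class:`AttributeSchema` or
    the path of a sidecar file; every schema name must appear in the header.
    For ARFF, attribute kinds come from the declarations and ``schema`` must
    be omitted; a ``class`` attribute (else the last one) is the decision.

    With ``impute=True`` missing numeric cells take the column mean and
    missing nominal cells the column mode; by default any missing cell is an
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))

    if path.suffix.lower() == ".arff":
        if schema is not None:
            raise ValueError("ARFF files carry their own schema")
        frame, attrs = read_arff(path)
    else:
        if schema is None:
            raise ValueError("CSV loading requires a schema or sidecar path")
        if isinstance(schema, (str, Path)):
            attrs = load_schema_sidecar(schema)
        else:
            attrs = tuple(schema)
        frame = pd.read_csv(path, dtype=object, keep_default_na=False)
        frame = frame.replace({"": np.nan, "?": np.nan})
        unmatched = [a.name for a in attrs if a.name not in frame.columns]
        if unmatched:
            raise ValueError(f"schema attributes absent from header: {unmatched}")

    attrs = _check_schema(attrs)
    frame = frame[[a.name for a in attrs]]
    for a in attrs:
        if a.kind == NUMERIC and a.role == CONDITIONAL:
            frame[a.name] = pd.to_numeric(frame[a.name], errors="raise")
    if impute:
        for a in attrs:
            col = frame[a.name]
            if not col.isna().any():
                continue
            if a.kind == NUMERIC and a.role == CONDITIONAL:
                frame[a.name] = col.fillna(col.mean())
            else:
                frame[a.name] = col.fillna(col.mode().iloc[0])
    return MixedDataset(frame=frame, schema=attrs)


def _sugeno_complement(mu: np.ndarray, lam: float) -> np.ndarray:
    return (1.0 - mu) / (1.0 + lam * mu)


def intuitionistic_fuzzify(data: MixedDataset, lam: float = 1.0) -> IFInformationSystem:
    """Convert a mixed table into an IF information system.

    Each numeric conditional column is min-max normalised into the membership
    mu and complemented into ``nu = (1 - mu) / (1 + lam * mu)``.  A constant
    column maps to ``mu = 0.5`` everywhere (zero range carries no
    discriminating information).  Nominal columns and the decision pass
    through as first-appearance integer codes / raw labels.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    mu: dict[str, np.ndarray] = {}
    nu: dict[str, np.ndarray] = {}
    codes: dict[str, np.ndarray] = {}
    for a in data.conditional_attributes:
        col = data.frame[a.name]
        if a.kind == NUMERIC:
            x = col.to_numpy(dtype=float)
            if not np.isfinite(x).all():
                raise ValueError(f"non-finite value in numeric column {a.name!r}")
            lo, hi = x.min(), x.max()
            if hi - lo < _TOL:
                m = np.full(x.shape, 0.5)
            else:
                m = (x - lo) / (hi - lo)
            mu[a.name] = m
            nu[a.name] = _sugeno_complement(m, lam)
        else:
            codes[a.name] = pd.factorize(col.astype(str))[0].astype(np.int64)
    return IFInformationSystem(
        schema=data.schema,
        mu=mu,
        nu=nu,
        codes=codes,
        decision=data.decision_labels(),
        lam=lam,
    )


def validate_ifis(ifis: IFInformationSystem) -> list[tuple[int, str, str]]:
    """Report every violated IF-value invariant as (row, attribute, message).

    The report is empty iff the system is valid.
    """
    report: list[tuple[int, str, str]] = []
    for name in ifis.mu:
        m, v = ifis.mu[name], ifis.nu[name]
        for i in range(len(m)):
            for msg in IFValue(float(m[i]), float(v[i])).violations():
                report.append((i, name, msg))
    return report
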