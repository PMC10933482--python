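"""Minimal dense-ARFF reader.

Supports ``@relation``, ``@attribute name {a,b,...}`` (nominal),
``@attribute name numeric|real|integer`` and a dense ``@data`` section with
``%`` comments and ``?`` for missing.  Sparse rows, dates and strings are
out of scope.  A ``class`` attribute (case-insensitive), else the last
attribute, is taken as the decision.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

_ATTR_RE = re.compile(r"@attribute\s+('[^']+'|\"[^\"]+\"|\S+)\s+(.+)", re.IGNORECASE)


def _unquote(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == token[-1] and token[0] in "'\"":
        return token[1:-1]
    return token


def read_arff(path: str | Path):
    """Parse an ARFF file; returns (DataFrame, tuple of AttributeSchema)."""
    from .ifis import CONDITIONAL, DECISION, NOMINAL, NUMERIC, AttributeSchema

    names: list[str] = []
    kinds: list[str] = []
    rows: list[list[str]] = []
    in_data = False
    for raw in Path(path).read_text().splitlines():
        line = raw.split("%", 1)[0].strip()
        if not line:
            continue
        if in_data:
            if line.startswith("{"):
                raise ValueError("sparse ARFF data is not supported")
            rows.append([_unquote(t) for t in line.split(",")])
            continue
        low = line.lower()
        if low.startswith("@relation"):
            continue
        if low.startswith("@attribute"):
            m = _ATTR_RE.match(line)
            if m is None:
                raise ValueError(f"malformed attribute line: {raw!r}")
            names.append(_unquote(m.group(1)))
            decl = m.group(2).strip()
            if decl.startswith("{"):
                kinds.append(NOMINAL)
            elif decl.lower() in ("numeric", "real", "integer"):
                kinds.append(NUMERIC)
            else:
                raise ValueError(f"unsupported attribute type {decl!r}")
        elif low.startswith("@data"):
            in_data = True
    if not names:
        raise ValueError("ARFF file declares no attributes")
    bad = [r for r in rows if len(r) != len(names)]
    if bad:
        raise ValueError(f"data row with {len(bad[0])} fields, expected {len(names)}")

    frame = pd.DataFrame(rows, columns=names, dtype=object)
    frame = frame.replace({"?": np.nan})

    lowered = [n.lower() for n in names]
    dec_idx = lowered.index("class") if "class" in lowered else len(names) - 1
    schema = tuple(
        AttributeSchema(
            name=n,
            kind=NOMINAL if i == dec_idx else kinds[i],
            role=DECISION if i == dec_idx else CONDITIONAL,
        )
        for i, (n, _) in enumerate(zip(names, kinds))
    )
    return frame, schema
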