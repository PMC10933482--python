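"""Classification metrics and evaluation protocols for reduced datasets.

Binary metrics follow the screening-literature conventions: sensitivity,
specificity and accuracy as percentages; Matthews correlation coefficient on
its native [-1, 1] scale (0 with a logged warning when a marginal vanishes);
AUC as the rank statistic P(score+ > score-) with ties counting one half,
which equals trapezoidal ROC integration.

Protocols are stratified and seeded: k-fold cross validation or a single
percentage split.  Class balancing is a seeded SMOTE: synthetic minority
samples are interpolated between a minority sample and one of its k nearest
minority neighbours (Euclidean distance on min-max-normalised numerics;
nominal values copied from the seed sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors

from .ifis import CONDITIONAL, NUMERIC, MixedDataset

__all__ = [
    "ConfusionCounts",
    "MetricsRecord",
    "confusion_counts",
    "classification_metrics",
    "auc_score",
    "smote_balance",
    "evaluate_protocol",
    "sklearn_adapter",
    "knn_adapter",
    "oracle_adapter",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TRP: int
    TRN: int
    FLP: int
    FLN: int

    @property
    def total(self) -> int:
        return self.TRP + self.TRN + self.FLP + self.FLN


@dataclass
class MetricsRecord:
    Sn: float
    Sp: float
    Ac: float
    MCC: float
    AUC: float = float("nan")


def confusion_counts(truth, predicted, positive) -> ConfusionCounts:
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction lengths differ")
    alphabet = set(np.unique(truth)) | set(np.unique(predicted))
    if positive not in alphabet:
        raise ValueError(f"positive label {positive!r} absent from labels")
    if len(alphabet) > 2:
        raise ValueError(f"binary metrics require 2 classes, got {sorted(map(str, alphabet))}")
    t = truth == positive
    p = predicted == positive
    return ConfusionCounts(
        TRP=int(np.sum(t & p)),
        TRN=int(np.sum(~t & ~p)),
        FLP=int(np.sum(~t & p)),
        FLN=int(np.sum(t & ~p)),
    )


def classification_metrics(c: ConfusionCounts) -> MetricsRecord:
    """Sn/Sp/Ac as percentages, MCC on [-1, 1]; AUC left NaN (score-based)."""
    if c.total == 0:
        raise ValueError("no evaluated samples")
    sn = 100.0 * c.TRP / (c.TRP + c.FLN) if (c.TRP + c.FLN) else 0.0
    sp = 100.0 * c.TRN / (c.TRN + c.FLP) if (c.TRN + c.FLP) else 0.0
    ac = 100.0 * (c.TRP + c.TRN) / c.total
    denom = (
        (c.TRP + c.FLP) * (c.TRP + c.FLN) * (c.TRN + c.FLN) * (c.TRN + c.FLP)
    )
    if denom == 0:
        logger.warning("MCC denominator factor is zero; reporting MCC = 0")
        mcc = 0.0
    else:
        mcc = (c.TRP * c.TRN - c.FLN * c.FLP) / np.sqrt(denom)
    return MetricsRecord(Sn=sn, Sp=sp, Ac=ac, MCC=float(mcc))


def auc_score(scores, truth, positive) -> float:
    """Rank-based AUC: probability a random positive outscores a random
    negative, ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth lengths differ")
    pos = truth == positive
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def smote_balance(data: MixedDataset, k: int = 5, seed: int = 0) -> MixedDataset:
    """Oversample the minority class to parity by neighbour interpolation.

    Numeric values of a synthetic sample lie on the segment between a
    minority seed sample and one of its k nearest minority neighbours;
    nominal values are copied from the seed sample.  Returns the input
    unchanged when classes are already balanced.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = data.decision_labels()
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"SMOTE balancing needs 2 classes, got {len(classes)}")
    if counts[0] == counts[1]:
        return data
    minority = classes[np.argmin(counts)]
    deficit = int(abs(counts[0] - counts[1]))
    min_idx = np.flatnonzero(labels == minority)
    if len(min_idx) < 2:
        raise ValueError("minority class must have at least 2 samples")
    if k > len(min_idx) - 1:
        logger.warning("k=%d exceeds minority size - 1; clamping to %d",
                       k, len(min_idx) - 1)
        k = len(min_idx) - 1

    numeric = [a.name for a in data.conditional_attributes if a.kind == NUMERIC]
    X = data.frame.loc[min_idx, numeric].to_numpy(dtype=float)
    span = X.max(axis=0) - X.min(axis=0) if len(numeric) else np.array([])
    span = np.where(span > 0, span, 1.0)
    Xn = (X - X.min(axis=0)) / span if len(numeric) else X
    if len(numeric):
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xn)
        neigh = nn.kneighbors(Xn, return_distance=False)[:, 1:]
    else:
        # no numeric attributes: any other minority sample is a neighbour
        neigh = np.array([
            [j for j in range(len(min_idx)) if j != i][:k]
            for i in range(len(min_idx))
        ])

    rng = np.random.default_rng(seed)
    new_rows = []
    for _ in range(deficit):
        i = int(rng.integers(len(min_idx)))
        j = int(neigh[i, int(rng.integers(neigh.shape[1]))])
        u = float(rng.random())
        row = data.frame.iloc[min_idx[i]].copy()
        for col_pos, name in enumerate(numeric):
            row[name] = X[i, col_pos] + u * (X[j, col_pos] - X[i, col_pos])
        new_rows.append(row)
    frame = pd.concat(
        [data.frame, pd.DataFrame(new_rows)], ignore_index=True
    )
    return MixedDataset(frame=frame, schema=data.schema)


def sklearn_adapter(estimator_factory, encode="ordinal"):
    """Wrap a scikit-learn estimator factory into a protocol adapter.

    The adapter signature is ``adapter(X_train, y_train, X_test, y_test) ->
    (predictions, scores-or-None)``; ``y_test`` exists only so diagnostic
    adapters (see :func:`oracle_adapter`) are expressible and is ignored
    here.
    """

    def adapter(X_train, y_train, X_test, y_test):
        est = estimator_factory()
        est.fit(X_train, y_train)
        pred = est.predict(X_test)
        scores = None
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(X_test)
            pos_col = list(est.classes_).index(sorted(est.classes_)[-1])
            scores = proba[:, pos_col]
        return pred, scores

    return adapter


def knn_adapter(k: int = 3):
    from sklearn.neighbors import KNeighborsClassifier

    return sklearn_adapter(lambda: KNeighborsClassifier(n_neighbors=k))


def oracle_adapter(X_train, y_train, X_test, y_test):
    """Diagnostic adapter that echoes the true test labels (Ac = 100)."""
    return np.asarray(y_test), None


def _encode_features(data: MixedDataset, attrs) -> np.ndarray:
    cols = []
    for name in attrs:
        schema = next(a for a in data.schema if a.name == name)
        col = data.frame[name]
        if schema.kind == NUMERIC:
            cols.append(col.to_numpy(dtype=float))
        else:
            cols.append(pd.factorize(col.astype(str))[0].astype(float))
    return np.column_stack(cols)


def evaluate_protocol(
    data: MixedDataset,
    reduct,
    protocol: dict,
    adapter,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate a classifier on the reduct columns under a seeded protocol.

    ``protocol`` is ``{"kfold": k}`` (stratified k-fold CV) or
    ``{"split": train_percent}`` (single stratified split).  Returns one row
    per fold plus a ``mean`` row (with the accuracy standard deviation in
    ``Ac_std``).  Nominal features enter as first-appearance ordinal codes.
    """
    reduct = tuple(reduct)
    if not reduct:
        raise ValueError("empty reduct")
    cond = {a.name for a in data.conditional_attributes}
    unknown = [a for a in reduct if a not in cond]
    if unknown:
        raise ValueError(f"reduct attributes not in dataset: {unknown}")

    X = _encode_features(data, reduct)
    y = data.decision_labels()
    positive = sorted(np.unique(y))[-1]

    if "kfold" in protocol:
        k = int(protocol["kfold"])
        _, counts = np.unique(y, return_counts=True)
        if k > counts.min():
            raise ValueError(f"fold count {k} exceeds smallest class size {counts.min()}")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(splitter.split(X, y))
    elif "split" in protocol:
        train_pct = float(protocol["split"])
        idx = np.arange(len(y))
        tr, te = train_test_split(
            idx, train_size=train_pct / 100.0, stratify=y, random_state=seed
        )
        splits = [(tr, te)]
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    rows = []
    for fold, (tr, te) in enumerate(splits):
        pred, scores = adapter(X[tr], y[tr], X[te], y[te])
        c = confusion_counts(y[te], pred, positive)
        rec = classification_metrics(c)
        auc = (
            auc_score(scores, y[te], positive) if scores is not None else float("nan")
        )
        rows.append(
            {"fold": fold, "Sn": rec.Sn, "Sp": rec.Sp, "Ac": rec.Ac,
             "MCC": rec.MCC, "AUC": auc}
        )
    table = pd.DataFrame(rows)
    mean = table[["Sn", "Sp", "Ac", "MCC", "AUC"]].mean()
    summary = {"fold": "mean", **mean.to_dict(), "Ac_std": table["Ac"].std(ddof=0)}
    return pd.concat([table, pd.DataFrame([summary])], ignore_index=True)
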