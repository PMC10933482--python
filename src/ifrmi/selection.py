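"""Greedy reduct search driven by IF rough mutual information.

Forward selection starts from the empty subset and at each step adds the
attribute with the largest significance (MI gain with the decision),
breaking ties by position in the schema.  It stops when the best gain drops
to ``delta`` or below, when the subset's MI reaches the full attribute set's
MI up to ``delta``, or when every attribute has been selected.  The full
per-step trace (candidate scores, chosen attribute, MI of the running
subset, dependency degree) is recorded, and an exhaustive oracle that
recomputes every candidate from scratch is provided for verification.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .approx import dependency_degree
from .entropy import INFORMATION, significance, subset_decision_mi
from .granules import SIGMA_MU
from .ifis import IFInformationSystem
from .relation import subset_relation

__all__ = ["StepRecord", "Reduct", "fsifmi_select", "greedy_step_oracle",
           "sweep_epsilon"]

logger = logging.getLogger(__name__)

GAIN_BELOW_DELTA = "gain_below_delta"
REACHED_FULL_MI = "reached_full_MI"
EXHAUSTED = "exhausted"


@dataclass
class StepRecord:
    candidate_scores: dict[str, float]
    chosen: str
    omega: float
    mi_subset: float
    gamma: float


@dataclass
class Reduct:
    """Ordered selected attributes with the per-step significance trace."""

    selected: tuple[str, ...]
    steps: list[StepRecord]
    epsilon: float
    delta: float
    convention: str
    cardinality_mode: str
    full_mi: float
    stop_reason: str

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "epsilon": self.epsilon,
            "delta": self.delta,
            "convention": self.convention,
            "cardinality_mode": self.cardinality_mode,
            "full_mi": self.full_mi,
            "stop_reason": self.stop_reason,
            "steps": [
                {
                    "chosen": s.chosen,
                    "omega": s.omega,
                    "mi_subset": s.mi_subset,
                    "gamma": s.gamma,
                    "candidate_scores": {
                        k: s.candidate_scores[k] for k in sorted(s.candidate_scores)
                    },
                }
                for s in self.steps
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _argmax_with_index_tiebreak(
    scores: dict[str, float], order: tuple[str, ...]
) -> str:
    """Maximiser of ``scores``; ties go to the earliest attribute in ``order``."""
    best = None
    best_score = -np.inf
    for name in order:
        if name in scores and scores[name] > best_score:
            best, best_score = name, scores[name]
    assert best is not None
    return best


def fsifmi_select(
    ifis: IFInformationSystem,
    epsilon: float = 0.5,
    delta: float = 1e-3,
    convention: str = INFORMATION,
    cardinality_mode: str = SIGMA_MU,
) -> Reduct:
    """Significance-driven forward greedy reduct search.

    Deterministic for fixed inputs.  The dependency degree of the running
    subset is recorded per step for reporting only.
    """
    if not (0.0 <= epsilon <= 1.0):
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    if delta < 0:
        raise ValueError(f"delta must be non-negative, got {delta}")
    order = ifis.conditional_names
    if not order:
        raise ValueError("no conditional attributes to select from")

    def mi(subset) -> float:
        return subset_decision_mi(ifis, subset, epsilon, convention, cardinality_mode)

    full_mi = mi(order)
    selected: list[str] = []
    steps: list[StepRecord] = []
    stop_reason = EXHAUSTED

    while True:
        remaining = [a for a in order if a not in selected]
        if not remaining:
            stop_reason = EXHAUSTED
            break
        scores = {
            y: significance(ifis, y, tuple(selected), epsilon, convention,
                            cardinality_mode)
            for y in remaining
        }
        best = _argmax_with_index_tiebreak(scores, order)
        # gain condition takes precedence: an exhausted-gain stop is reported
        # as such even when the subset has also reached the full-set MI
        if scores[best] <= delta:
            stop_reason = GAIN_BELOW_DELTA
            if not selected:
                warnings.warn(
                    "no attribute exceeds the significance threshold; "
                    "reduct is empty", stacklevel=2,
                )
            break
        if selected and mi(tuple(selected)) >= full_mi - delta:
            stop_reason = REACHED_FULL_MI
            break
        selected.append(best)
        current_mi = mi(tuple(selected))
        gamma = dependency_degree(
            subset_relation(ifis, tuple(selected)), ifis.decision
        )
        steps.append(
            StepRecord(
                candidate_scores=scores,
                chosen=best,
                omega=scores[best],
                mi_subset=current_mi,
                gamma=gamma,
            )
        )

    return Reduct(
        selected=tuple(selected),
        steps=steps,
        epsilon=epsilon,
        delta=delta,
        convention=convention,
        cardinality_mode=cardinality_mode,
        full_mi=full_mi,
        stop_reason=stop_reason,
    )


def greedy_step_oracle(
    ifis: IFInformationSystem,
    red,
    epsilon: float,
    convention: str = INFORMATION,
    cardinality_mode: str = SIGMA_MU,
) -> tuple[str, float]:
    """Exhaustively recompute the next greedy choice from scratch.

    Evaluates the significance of every remaining attribute through the full
    relation/granule/MI pipeline (no reuse) and returns the maximiser with
    the same schema-order tie-break as :func:`fsifmi_select`.
    """
    red = tuple(red)
    order = ifis.conditional_names
    if not set(red) < set(order):
        raise ValueError("red must be a strict subset of the conditional attributes")
    scores = {
        y: significance(ifis, y, red, epsilon, convention, cardinality_mode)
        for y in order if y not in red
    }
    best = _argmax_with_index_tiebreak(scores, order)
    return best, scores[best]


def sweep_epsilon(
    ifis: IFInformationSystem,
    grid,
    evaluator,
    seed: int | None = None,
    delta: float = 1e-3,
    convention: str = INFORMATION,
):
    """Run the reduct search per epsilon and keep the best-scoring one.

    ``evaluator(reduct, seed) -> float`` scores each reduct (e.g. a
    cross-validated accuracy); ties go to the smaller epsilon.  Returns
    ``(best_epsilon, best_reduct, table)`` where the table has one row per
    grid value: (epsilon, score, reduct_size, selected).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty epsilon grid")
    rows = []
    best_eps, best_reduct, best_score = None, None, -np.inf
    for eps in sorted(grid):
        reduct = fsifmi_select(ifis, epsilon=eps, delta=delta, convention=convention)
        try:
            score = float(evaluator(reduct, seed))
        except Exception as exc:
            raise RuntimeError(f"evaluator failed at epsilon={eps}") from exc
        rows.append(
            {"epsilon": eps, "score": score, "reduct_size": len(reduct.selected),
             "selected": list(reduct.selected)}
        )
        if score > best_score:
            best_eps, best_reduct, best_score = eps, reduct, score
    return best_eps, best_reduct, rows
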