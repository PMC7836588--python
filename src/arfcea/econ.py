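"""Incremental cost-effectiveness metrics: NMB, ICER with dominance
handling, and the cost-effectiveness acceptability curve."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .decision_model import Strategy
from .psa import PSAResult

__all__ = [
    "nmb",
    "IncrementalResult",
    "incremental_icer",
    "CEACPoint",
    "ceac",
    "ceac_frame",
    "default_lambda_grid",
]


def nmb(qaly, cost, lam):
    """Net monetary benefit: ``qaly * lam - cost`` (lam >= 0)."""
    if np.any(np.asarray(lam) < 0):
        raise ValueError("willingness-to-pay threshold must be non-negative")
    return qaly * lam - cost


@dataclass(frozen=True)
class IncrementalResult:
    """ICER of the more effective strategy vs the next most effective.

    ``icer`` is None when no finite ratio is reported: either the more
    effective strategy is also cheaper (``dominant`` is set) or the mean
    QALYs are exactly equal (``undefined`` is True).
    """

    ordering: tuple[Strategy, ...]  # ascending mean QALYs
    icer: float | None
    dominant: Strategy | None
    undefined: bool
    direction_label: str
    incremental_cost: float
    incremental_qaly: float


def incremental_icer(
    mean_cost: Mapping[Strategy, float], mean_qaly: Mapping[Strategy, float]
) -> IncrementalResult:
    """Compare the two strategies' mean outcomes.

    The ICER numerator/denominator run from the less effective to the more
    effective strategy; with equal effectiveness or when the more
    effective strategy is cheaper no finite ICER exists.
    """
    strategies = list(mean_qaly)
    if len(strategies) != 2 or set(mean_cost) != set(mean_qaly):
        raise ValueError("expected mean outcomes for exactly the two strategies")
    ordering = tuple(sorted(strategies, key=lambda s: (mean_qaly[s], -mean_cost[s])))
    less, more = ordering
    d_cost = mean_cost[more] - mean_cost[less]
    d_qaly = mean_qaly[more] - mean_qaly[less]
    label = f"{Strategy(more).value} vs {Strategy(less).value}"
    if d_qaly == 0.0:
        cheaper = min(strategies, key=lambda s: mean_cost[s])
        return IncrementalResult(ordering, None, cheaper, True, label, d_cost, d_qaly)
    if d_cost <= 0.0:
        # more effective and no more expensive: simple dominance
        return IncrementalResult(ordering, None, more, False, label, d_cost, d_qaly)
    return IncrementalResult(ordering, d_cost / d_qaly, None, False, label, d_cost, d_qaly)


@dataclass(frozen=True)
class CEACPoint:
    """Probability each strategy is most cost-effective at one threshold."""

    lam: float
    probability: dict[Strategy, float]


def default_lambda_grid() -> np.ndarray:
    """£0 to £50,000 per QALY in £500 steps."""
    return np.arange(0, 50_001, 500, dtype=float)


def _winners(psa: PSAResult, lam: float) -> np.ndarray:
    """Index of the winning strategy per iteration; NMB ties go to the
    cheaper strategy (and then to column order)."""
    benefit = nmb(psa.qaly, psa.cost, lam)
    best = benefit.max(axis=1, keepdims=True)
    tied = benefit >= best
    cost_if_tied = np.where(tied, psa.cost, np.inf)
    return np.argmin(cost_if_tied, axis=1)


def ceac(psa: PSAResult, lambda_grid: Sequence[float]) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve over a threshold grid."""
    if psa.n_iterations == 0 or len(lambda_grid) == 0:
        raise ValueError("need a non-empty PSA result and threshold grid")
    points = []
    k = len(psa.strategies)
    for lam in lambda_grid:
        counts = np.bincount(_winners(psa, float(lam)), minlength=k)
        probs = counts / psa.n_iterations
        points.append(
            CEACPoint(float(lam), {s: float(probs[j]) for j, s in enumerate(psa.strategies)})
        )
    return points


def ceac_frame(points: Sequence[CEACPoint]) -> pd.DataFrame:
    """Long-format CEAC table: lambda, strategy, probability."""
    rows = [
        {"lambda": pt.lam, "strategy": s.value, "probability": p}
        for pt in points
        for s, p in pt.probability.items()
    ]
    return pd.DataFrame(rows)
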