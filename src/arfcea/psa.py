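"""Probabilistic sensitivity analysis: Monte Carlo propagation of the
parameter distributions through the decision tree."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision_model import STRATEGIES, Strategy, arm_outcome
from .parameters import ParameterSet, sample_draws

__all__ = ["PSAResult", "PSASummary", "run_psa", "summarize", "export_ce_plane", "psa_frame"]


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration outcomes of every strategy on common parameter draws.

    ``cost`` and ``qaly`` are (n_iterations, n_strategies) arrays with
    columns ordered as ``strategies``; both strategies within a row were
    evaluated on the same draw.
    """

    n_iterations: int
    seed: int
    scenario_label: str
    strategies: tuple[Strategy, ...]
    cost: np.ndarray
    qaly: np.ndarray

    def __post_init__(self) -> None:
        if self.cost.shape != (self.n_iterations, len(self.strategies)):
            raise ValueError("cost matrix shape does not match metadata")
        if self.qaly.shape != self.cost.shape:
            raise ValueError("qaly matrix shape does not match cost matrix")

    def column(self, strategy: Strategy) -> int:
        return self.strategies.index(Strategy(strategy))


@dataclass(frozen=True)
class PSASummary:
    """Arithmetic means over iterations plus the incremental comparison.

    The incremental direction is (more-effective-on-average strategy)
    minus (less-effective), mirroring the comparison to the next most
    effective alternative.
    """

    mean_cost: dict[Strategy, float]
    mean_qaly: dict[Strategy, float]
    more_effective: Strategy
    less_effective: Strategy
    incremental_cost: float
    incremental_qaly: float

    @property
    def direction_label(self) -> str:
        return f"{self.more_effective.value} vs {self.less_effective.value}"


def run_psa(
    params: ParameterSet,
    n_iterations: int = 10_000,
    seed: int = 0,
) -> PSAResult:
    """Run the Monte Carlo PSA.

    Each iteration takes one random draw from every parameter
    distribution and evaluates both strategies on that same draw.
    Deterministic given ``(params, n_iterations, seed)``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x50A)))
    draws = sample_draws(params, n_iterations, rng)
    cost = np.empty((n_iterations, len(STRATEGIES)))
    qaly = np.empty_like(cost)
    for j, strategy in enumerate(STRATEGIES):
        outcome = arm_outcome(draws, strategy)
        cost[:, j] = outcome.cost
        qaly[:, j] = outcome.qaly
    return PSAResult(
        n_iterations=n_iterations,
        seed=seed,
        scenario_label=params.scenario_name,
        strategies=STRATEGIES,
        cost=cost,
        qaly=qaly,
    )


def summarize(psa: PSAResult) -> PSASummary:
    """Mean costs/QALYs per strategy and the incremental comparison."""
    if psa.n_iterations == 0:
        raise ValueError("cannot summarise an empty PSA result")
    mean_cost = {s: float(psa.cost[:, j].mean()) for j, s in enumerate(psa.strategies)}
    mean_qaly = {s: float(psa.qaly[:, j].mean()) for j, s in enumerate(psa.strategies)}
    ranked = sorted(psa.strategies, key=lambda s: mean_qaly[s])
    less, more = ranked[0], ranked[-1]
    return PSASummary(
        mean_cost=mean_cost,
        mean_qaly=mean_qaly,
        more_effective=more,
        less_effective=less,
        incremental_cost=mean_cost[more] - mean_cost[less],
        incremental_qaly=mean_qaly[more] - mean_qaly[less],
    )


def export_ce_plane(psa: PSAResult, comparator: Strategy) -> pd.DataFrame:
    """Per-iteration incremental cost and QALYs relative to ``comparator``.

    For the two-strategy model the result has one row per iteration with
    columns ``iteration, d_cost, d_qaly`` (other strategy minus
    comparator).
    """
    j_cmp = psa.column(comparator)
    j_other = [j for j in range(len(psa.strategies)) if j != j_cmp]
    d_cost = psa.cost[:, j_other].sum(axis=1) - len(j_other) * psa.cost[:, j_cmp]
    d_qaly = psa.qaly[:, j_other].sum(axis=1) - len(j_other) * psa.qaly[:, j_cmp]
    return pd.DataFrame(
        {"iteration": np.arange(psa.n_iterations), "d_cost": d_cost, "d_qaly": d_qaly}
    )


def psa_frame(psa: PSAResult) -> pd.DataFrame:
    """Long-format table: iteration, strategy, cost, qaly."""
    frames = []
    for j, strategy in enumerate(psa.strategies):
        frames.append(
            pd.DataFrame(
                {
                    "iteration": np.arange(psa.n_iterations),
                    "strategy": strategy.value,
                    "cost": psa.cost[:, j],
                    "qaly": psa.qaly[:, j],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
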