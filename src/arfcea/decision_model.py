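"""Decision-tree evaluation: expected lifetime cost and QALYs per strategy.

Two strategies are compared for a cohort presenting with acute respiratory
failure: standard oxygen therapy and prehospital CPAP.  The comparator arm
uses the baseline 30-day death and intubation risks directly; the CPAP arm
obtains its risks by applying log odds ratios to the baseline odds.
Outcomes are cohort expectations over the tree, not per-patient
simulations: every patient incurs the hospitalisation cost, intubation
adds critical-care cost with probability ``p_intubation``, and survivors
accrue annual care costs and QALYs over their (already discounted) life
expectancy.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .parameters import ParameterDraw

__all__ = ["Strategy", "STRATEGIES", "StrategyOutcome", "apply_log_or", "arm_outcome", "evaluate_strategies"]


class Strategy(str, enum.Enum):
    STANDARD_CARE = "standard_care"
    PREHOSPITAL_CPAP = "prehospital_cpap"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


STRATEGIES = (Strategy.STANDARD_CARE, Strategy.PREHOSPITAL_CPAP)


@dataclass(frozen=True)
class StrategyOutcome:
    """Expected outcome of one strategy under one parameter draw.

    Fields may be scalars or aligned numpy arrays (vectorised draws).
    """

    cost: object
    qaly: object
    p_death: object
    p_intubation: object


def apply_log_or(p0, log_or):
    """Shift a baseline probability by a log odds ratio.

    Returns ``expit(logit(p0) + log_or)``, strictly increasing in both
    arguments and always inside (0, 1).  ``p0`` must lie strictly between
    0 and 1 (the odds are undefined at the endpoints).
    """
    p0 = np.asarray(p0, dtype=float)
    log_or = np.asarray(log_or, dtype=float)
    if np.any((p0 <= 0.0) | (p0 >= 1.0)):
        raise ValueError("baseline probability must lie strictly in (0, 1)")
    if not np.all(np.isfinite(log_or)):
        raise ValueError("log odds ratio must be finite")
    out = expit(logit(p0) + log_or)
    return float(out) if out.ndim == 0 else out


def arm_outcome(draw: ParameterDraw, strategy: Strategy) -> StrategyOutcome:
    """Evaluate the tree for one strategy under one (possibly vector) draw."""
    strategy = Strategy(strategy)
    if strategy is Strategy.STANDARD_CARE:
        p_death = np.asarray(draw.p_death0, dtype=float)
        p_int = np.asarray(draw.p_int0, dtype=float)
        intervention_cost = 0.0
    else:
        p_death = apply_log_or(draw.p_death0, draw.logor_death)
        p_int = apply_log_or(draw.p_int0, draw.logor_int)
        intervention_cost = draw.c_cpap
    survive = 1.0 - p_death
    cost = (
        intervention_cost
        + draw.c_hosp
        + p_int * draw.c_int
        + survive * draw.c_annual * draw.life_years
    )
    qaly = survive * draw.life_years * draw.utility
    squeeze = np.ndim(cost) == 0 or (np.ndim(draw.c_hosp) == 0 and np.ndim(p_death) == 0)
    if squeeze:
        return StrategyOutcome(float(cost), float(qaly), float(p_death), float(p_int))
    return StrategyOutcome(np.asarray(cost), np.asarray(qaly), np.asarray(p_death), np.asarray(p_int))


def evaluate_strategies(draw: ParameterDraw) -> dict[Strategy, StrategyOutcome]:
    """Evaluate both strategies on the same draw (common random numbers)."""
    return {s: arm_outcome(draw, s) for s in STRATEGIES}
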