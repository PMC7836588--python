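"""Value-of-information analysis.

Per-person EVPI is computed directly from PSA output as
``mean(max-strategy NMB) - max(mean-strategy NMB)``.  EVPPI for a subset
of parameters uses the nested two-level Monte Carlo estimator: the outer
loop fixes the subset, the inner loop integrates out the remaining
parameters.  Population figures multiply per-person values by the
incident population accrued over the technology lifespan, optionally
discounting future annual cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .decision_model import STRATEGIES, arm_outcome
from .econ import nmb
from .parameters import PARAMETER_NAMES, ParameterDraw, ParameterSet
from .psa import PSAResult, run_psa

__all__ = [
    "PopulationAssumptions",
    "VOIResult",
    "effective_population",
    "evpi_per_person",
    "evppi_2level",
    "run_voi",
    "voi_frame",
]


@dataclass(frozen=True)
class PopulationAssumptions:
    """Incident population over which perfect information has value."""

    annual_incidence: float = 11_000.0
    technology_lifespan: int = 5
    discount_rate: float = 0.035
    discount_future_cohorts: bool = True

    def __post_init__(self) -> None:
        if self.annual_incidence <= 0 or self.technology_lifespan <= 0:
            raise ValueError("incidence and lifespan must be positive")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError("discount rate must lie in [0, 1)")


def effective_population(assumptions: PopulationAssumptions) -> float:
    """Patients affected over the technology lifespan.

    The first cohort is not discounted; cohort ``t`` (t = 0..lifespan-1)
    carries weight ``(1 + rate)^-t`` when discounting is enabled.
    """
    a = assumptions
    if not a.discount_future_cohorts:
        return a.annual_incidence * a.technology_lifespan
    t = np.arange(a.technology_lifespan)
    return float(a.annual_incidence * np.sum((1.0 + a.discount_rate) ** -t))


def evpi_per_person(psa: PSAResult, lam: float) -> float:
    """Expected value of perfect information per patient at threshold lam."""
    if psa.n_iterations == 0:
        raise ValueError("empty PSA result")
    benefit = nmb(psa.qaly, psa.cost, lam)
    # mean-of-max >= max-of-means in exact arithmetic; clamp float error
    return max(0.0, float(benefit.max(axis=1).mean() - benefit.mean(axis=0).max()))


def _nested_draws(
    params: ParameterSet,
    subset: Sequence[str],
    n_outer: int,
    n_inner: int,
    rng: np.random.Generator,
) -> ParameterDraw:
    """(n_outer*n_inner,) draws where subset values repeat across inner."""
    subset = list(subset)
    values = {}
    for name, spec in params.specs().items():
        if name in subset:
            outer = np.asarray(spec.sample(rng, n_outer), dtype=float)
            values[name] = np.repeat(outer, n_inner)
        else:
            values[name] = np.asarray(spec.sample(rng, n_outer * n_inner), dtype=float)
    from .parameters import _truncate  # shared truncation rules

    return ParameterDraw(**{k: _truncate(k, v) for k, v in values.items()})


def evppi_2level(
    params: ParameterSet,
    subset: Sequence[str],
    lam: float,
    n_outer: int = 1000,
    n_inner: int = 1000,
    seed: int = 0,
) -> float:
    """Two-level Monte Carlo EVPPI for a subset of parameters, per person.

    Outer iterations draw the subset; for each, the inner loop redraws
    the complementary parameters and averages each strategy's NMB.  The
    estimate is the mean over outer draws of the best inner-mean NMB,
    minus the best overall-mean NMB; non-negative up to Monte Carlo
    error.  When the subset covers every parameter the inner loop is
    degenerate and the estimator reduces to per-person EVPI.
    """
    subset = tuple(dict.fromkeys(subset))
    if not subset:
        raise ValueError("subset must name at least one parameter")
    unknown = sorted(set(subset) - set(PARAMETER_NAMES))
    if unknown:
        raise ValueError(f"unknown parameter name(s) in subset: {', '.join(unknown)}")
    if n_outer < 100 or n_inner < 100:
        raise ValueError("n_outer and n_inner must each be >= 100")
    if set(subset) == set(PARAMETER_NAMES):
        n_inner = 1  # nothing left to integrate out
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xEF1)))
    draws = _nested_draws(params, subset, n_outer, n_inner, rng)
    benefit = np.empty((n_outer * n_inner, len(STRATEGIES)))
    for j, strategy in enumerate(STRATEGIES):
        outcome = arm_outcome(draws, strategy)
        benefit[:, j] = nmb(outcome.qaly, outcome.cost, lam)
    per_outer = benefit.reshape(n_outer, n_inner, -1).mean(axis=1)
    # mean-of-max >= max-of-means in exact arithmetic; clamp float error
    return max(0.0, float(per_outer.max(axis=1).mean() - per_outer.mean(axis=0).max()))


@dataclass(frozen=True)
class VOIResult:
    """Per-person and population value-of-information at one threshold."""

    lam: float
    evpi_per_person: float
    effective_population: float
    population_evpi: float
    evppi_per_person: dict[str, float] = field(default_factory=dict)
    population_evppi: dict[str, float] = field(default_factory=dict)


def run_voi(
    params: ParameterSet,
    lam: float = 20_000.0,
    subsets: Mapping[str, Sequence[str]] | None = None,
    assumptions: PopulationAssumptions | None = None,
    n_psa: int = 100_000,
    n_outer: int = 1000,
    n_inner: int = 1000,
    seed: int = 0,
    psa: PSAResult | None = None,
) -> VOIResult:
    """EVPI plus EVPPI for each named parameter subset.

    ``subsets`` maps a label to the parameter names it contains; the
    default analyses each effectiveness parameter on its own.  An
    existing ``psa`` result may be supplied to avoid re-running the PSA.
    """
    if assumptions is None:
        assumptions = PopulationAssumptions()
    if subsets is None:
        subsets = {"logor_death": ("logor_death",), "logor_int": ("logor_int",)}
    if psa is None:
        psa = run_psa(params, n_iterations=n_psa, seed=seed)
    pop = effective_population(assumptions)
    evpi = evpi_per_person(psa, lam)
    evppi = {
        label: evppi_2level(params, names, lam, n_outer, n_inner, seed + i)
        for i, (label, names) in enumerate(subsets.items())
    }
    return VOIResult(
        lam=float(lam),
        evpi_per_person=evpi,
        effective_population=pop,
        population_evpi=evpi * pop,
        evppi_per_person=evppi,
        population_evppi={k: v * pop for k, v in evppi.items()},
    )


def voi_frame(result: VOIResult) -> pd.DataFrame:
    """Tabular export: EVPI row followed by one row per EVPPI subset."""
    rows = [
        {
            "lambda": result.lam,
            "quantity": "evpi",
            "subset": "",
            "per_person": result.evpi_per_person,
            "effective_population": result.effective_population,
            "population": result.population_evpi,
        }
    ]
    for label, value in result.evppi_per_person.items():
        rows.append(
            {
                "lambda": result.lam,
                "quantity": "evppi",
                "subset": label,
                "per_person": value,
                "effective_population": result.effective_population,
                "population": result.population_evppi[label],
            }
        )
    return pd.DataFrame(rows)
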