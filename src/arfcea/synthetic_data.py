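"""Synthetic two-arm trial generator and trial-to-distribution builders.

Emulates the data-generating process the analysis assumes: binomial
30-day mortality and intubation outcomes in a control and an
intervention arm, with the intervention risks obtained by applying a log
odds ratio to the control risks.  The builders convert observed counts
back into the beta baselines and Woolf log-odds-ratio normals the model
samples from, enabling end-to-end tests with no external data.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .decision_model import apply_log_or
from .parameters import DistributionSpec, ParameterSet, builtin_acute_parameters
from .psa import run_psa, summarize

__all__ = [
    "ArmCounts",
    "TrialCounts",
    "simulate_trial",
    "distributions_from_trial",
    "parameter_set_from_trial",
    "recovery_experiment",
    "trial_to_csv",
    "trial_from_csv",
]


@dataclass(frozen=True)
class ArmCounts:
    """Event counts for one trial arm; the two endpoints may have
    different complete-case denominators."""

    n_mortality_assessed: int
    deaths: int
    n_intubation_assessed: int
    intubations: int

    def __post_init__(self) -> None:
        for n, k in (
            (self.n_mortality_assessed, self.deaths),
            (self.n_intubation_assessed, self.intubations),
        ):
            if n < 0 or k < 0 or k > n:
                raise ValueError(f"invalid arm counts: {self!r}")


@dataclass(frozen=True)
class TrialCounts:
    control: ArmCounts
    intervention: ArmCounts


def simulate_trial(
    n_mortality: int,
    n_intubation: int,
    p_death_control: float,
    or_death: float,
    p_int_control: float,
    or_int: float,
    seed: int = 0,
) -> TrialCounts:
    """Simulate one two-arm trial with binomial endpoint counts.

    Intervention-arm probabilities are ``apply_log_or(p, ln OR)``; the
    same per-endpoint denominator is used in both arms.
    """
    if not (0 < p_death_control < 1 and 0 < p_int_control < 1):
        raise ValueError("control probabilities must lie in (0, 1)")
    if or_death <= 0 or or_int <= 0:
        raise ValueError("odds ratios must be positive")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x7121)))
    p_death_iv = apply_log_or(p_death_control, math.log(or_death))
    p_int_iv = apply_log_or(p_int_control, math.log(or_int))
    control = ArmCounts(
        n_mortality, int(rng.binomial(n_mortality, p_death_control)),
        n_intubation, int(rng.binomial(n_intubation, p_int_control)),
    )
    intervention = ArmCounts(
        n_mortality, int(rng.binomial(n_mortality, p_death_iv)),
        n_intubation, int(rng.binomial(n_intubation, p_int_iv)),
    )
    return TrialCounts(control, intervention)


def _log_or_spec(
    name: str, events_c: int, n_c: int, events_i: int, n_i: int, continuity_correction: bool
) -> DistributionSpec:
    a, b = events_i, n_i - events_i  # intervention events / non-events
    c, d = events_c, n_c - events_c
    if min(a, b, c, d) == 0:
        if not continuity_correction:
            raise ValueError(
                f"{name}: zero cell in the 2x2 table; pass "
                "continuity_correction=True to add 0.5 to every cell"
            )
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    log_or = math.log((a / b) / (c / d))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)  # Woolf standard error
    return DistributionSpec(name, "normal", (log_or, se))


def distributions_from_trial(
    counts: TrialCounts, continuity_correction: bool = False
) -> tuple[dict[str, DistributionSpec], dict[str, DistributionSpec]]:
    """Build the model's effectiveness distributions from trial counts.

    Baselines are Beta(events, non-events) from the control arm; the log
    odds ratios are Normal(sample log-OR, Woolf SE) from the 2x2 tables.
    Zero cells raise unless ``continuity_correction`` adds 0.5 everywhere.
    """
    c, i = counts.control, counts.intervention
    if c.deaths in (0, c.n_mortality_assessed) or c.intubations in (0, c.n_intubation_assessed):
        if not continuity_correction:
            raise ValueError(
                "control arm has a zero cell; a Beta(events, non-events) "
                "baseline needs both counts positive (or continuity_correction=True)"
            )
    cc = 0.5 if continuity_correction else 0.0

    def beta(name: str, events: float, n: float) -> DistributionSpec:
        return DistributionSpec(name, "beta", (events + cc, n - events + cc))

    baselines = {
        "p_death0": beta("p_death0", c.deaths, c.n_mortality_assessed),
        "p_int0": beta("p_int0", c.intubations, c.n_intubation_assessed),
    }
    log_ors = {
        "logor_death": _log_or_spec(
            "logor_death", c.deaths, c.n_mortality_assessed,
            i.deaths, i.n_mortality_assessed, continuity_correction,
        ),
        "logor_int": _log_or_spec(
            "logor_int", c.intubations, c.n_intubation_assessed,
            i.intubations, i.n_intubation_assessed, continuity_correction,
        ),
    }
    return baselines, log_ors


def parameter_set_from_trial(
    counts: TrialCounts,
    template: ParameterSet | None = None,
    continuity_correction: bool = False,
) -> ParameterSet:
    """Replace a template's baseline and effectiveness specs with ones
    rebuilt from trial counts (costs/utility/life expectancy unchanged)."""
    if template is None:
        template = builtin_acute_parameters()
    baselines, log_ors = distributions_from_trial(counts, continuity_correction)
    return replace(template, scenario_name="synthetic", **baselines, **log_ors)


def recovery_experiment(
    p_death_control: float,
    or_death: float,
    p_int_control: float,
    or_int: float,
    n_mortality: int = 35,
    n_intubation: int = 29,
    n_replicates: int = 100,
    n_psa: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Parameter-recovery harness: simulate, rebuild, re-analyse.

    Each replicate simulates a trial, rebuilds the effectiveness
    distributions (with continuity correction, since small trials often
    produce zero cells), runs a reduced PSA, and records the recovered
    means plus whether the 95% Wald interval covers the true log-OR.
    Returns one row per replicate; biases are column means minus truth.
    """
    if n_replicates < 100:
        raise ValueError("n_replicates must be >= 100")
    true_logor_death = math.log(or_death)
    true_logor_int = math.log(or_int)
    rows = []
    for r in range(n_replicates):
        counts = simulate_trial(
            n_mortality, n_intubation, p_death_control, or_death,
            p_int_control, or_int, seed=seed * n_replicates + r,
        )
        params = parameter_set_from_trial(counts, continuity_correction=True)
        mu_d, se_d = params.logor_death.params
        mu_i, se_i = params.logor_int.params
        summary = summarize(run_psa(params, n_iterations=n_psa, seed=r))
        rows.append(
            {
                "replicate": r,
                "p_death0_hat": params.p_death0.mean(),
                "logor_death_hat": mu_d,
                "logor_int_hat": mu_i,
                "covered_death": abs(mu_d - true_logor_death) <= 1.96 * se_d,
                "covered_int": abs(mu_i - true_logor_int) <= 1.96 * se_i,
                "ci_width_death": 2 * 1.96 * se_d,
                "incremental_qaly": summary.incremental_qaly,
                "incremental_cost": summary.incremental_cost,
            }
        )
    return pd.DataFrame(rows)


def trial_to_csv(counts: TrialCounts) -> str:
    """Serialise trial counts as a small CSV (one row per arm)."""
    rows = []
    for arm, ac in (("control", counts.control), ("intervention", counts.intervention)):
        rows.append(
            {
                "arm": arm,
                "n_mortality_assessed": ac.n_mortality_assessed,
                "deaths": ac.deaths,
                "n_intubation_assessed": ac.n_intubation_assessed,
                "intubations": ac.intubations,
            }
        )
    return pd.DataFrame(rows).to_csv(index=False)


def trial_from_csv(text: str) -> TrialCounts:
    """Inverse of :func:`trial_to_csv`."""
    df = pd.read_csv(io.StringIO(text)).set_index("arm")
    def arm(name: str) -> ArmCounts:
        row = df.loc[name]
        return ArmCounts(
            int(row["n_mortality_assessed"]), int(row["deaths"]),
            int(row["n_intubation_assessed"]), int(row["intubations"]),
        )
    return TrialCounts(arm("control"), arm("intervention"))
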