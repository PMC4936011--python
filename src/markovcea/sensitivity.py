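"""Deterministic and probabilistic sensitivity analysis.

One-way DSA re-runs the model with a single parameter moved to a scenario
value and records the shift in the ICER; the scenario set mirrors the
standard practice for this model family (discount-rate grid, entry-state
variants, horizon variants, cohort-size variant, ±20 % on every utility and
cost).  PSA draws every uncertain parameter from an assigned distribution —
beta for probabilities and utilities, gamma for costs, method-of-moments
with SD equal to a fixed fraction of the mean — evaluates both strategies on
the same drawn parameter set (common random parameters) and summarizes the
(ΔC, ΔE) cloud as a cost-effectiveness acceptability curve (CEAC).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from .cea import classify_quadrant, compute_icer
from .engine import evaluate_strategy
from .model_config import ModelSpec, validate_model_spec

__all__ = [
    "DSAScenario",
    "DSAResult",
    "TornadoEntry",
    "PSAResult",
    "CEACPoint",
    "standard_dsa_scenarios",
    "apply_scenario",
    "run_dsa",
    "tornado_table",
    "sample_psa_draw",
    "run_psa",
    "compute_ceac",
]

#: Default relative standard deviation for PSA distributions (and the span of
#: the ±20 % DSA scenarios).
DEFAULT_SD_FRACTION = 0.20


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DSAScenario:
    """A single one-way scenario: one parameter moved to one value.

    ``parameter_path`` addresses the spec field being varied using a dotted
    path (``discount.annual_rate``, ``states[moderate].utility``,
    ``states[turp].event_cost``, ``states[severe].annual_state_cost_by_strategy``,
    ``cohort.horizon_cycles``, ``cohort.cohort_size``,
    ``cohort.initial_distribution``).  ``group`` collects the scenarios that
    vary the same underlying parameter (e.g. the low/high pair of a ±20 %
    band, or the whole discount-rate grid) into one tornado bar.
    """

    label: str
    group: str
    parameter_path: str
    baseline_value: object
    scenario_value: object


@dataclass(frozen=True)
class DSAResult:
    scenario: DSAScenario
    icer: float
    deviation: float  # icer − baseline_icer
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass(frozen=True)
class TornadoEntry:
    """One tornado bar: the ICER span a parameter group produces."""

    group: str
    icer_low: float
    icer_high: float
    baseline_icer: float

    @property
    def max_abs_deviation(self) -> float:
        return max(
            abs(self.icer_low - self.baseline_icer),
            abs(self.icer_high - self.baseline_icer),
        )


def _apply_path(data: dict, path: str, value: object) -> None:
    # dotted path; `states[name]` segments address the state list by name
    parts = path.split(".")
    node: object = data
    for seg in parts[:-1]:
        if "[" in seg:
            base, key = seg[:-1].split("[", 1)
            child = node[base]  # type: ignore[index]
            if isinstance(child, list):
                node = next(item for item in child if item["name"] == key)
            else:
                node = child[key]
        else:
            node = node[seg]  # type: ignore[index]
    node[parts[-1]] = value  # type: ignore[index]


def apply_scenario(spec: ModelSpec, scenario: DSAScenario) -> ModelSpec:
    """Return a copy of ``spec`` with the scenario's parameter applied."""
    data = spec.model_dump()
    _apply_path(data, scenario.parameter_path, copy.deepcopy(scenario.scenario_value))
    return ModelSpec.model_validate(data)


def standard_dsa_scenarios(
    spec: ModelSpec, span: float = DEFAULT_SD_FRACTION
) -> list[DSAScenario]:
    """The standard one-way scenario set for a model spec.

    Emits: discount rate over {0.01, …, 0.06}; entry in the moderate and in
    the severe state; horizon 5 and 15 cycles; a ~570,000-person cohort
    variant; every non-death-state utility at ±``span`` (capped at 1, the
    utility upper bound); every nonzero cost (annual, per state, both
    strategies scaled jointly; and per-episode) at ±``span``.
    """
    scenarios: list[DSAScenario] = []

    base_rate = spec.discount.annual_rate
    for rate in (0.01, 0.02, 0.03, 0.04, 0.05, 0.06):
        scenarios.append(
            DSAScenario(
                label=f"discount rate {rate:.2f}",
                group="discount_rate",
                parameter_path="discount.annual_rate",
                baseline_value=base_rate,
                scenario_value=rate,
            )
        )

    base_dist = dict(spec.cohort.initial_distribution)
    for state in ("moderate", "severe"):
        if state in spec.state_names():
            scenarios.append(
                DSAScenario(
                    label=f"entry at {state}",
                    group="entry_state",
                    parameter_path="cohort.initial_distribution",
                    baseline_value=base_dist,
                    scenario_value={state: 1.0},
                )
            )

    for horizon in (5, 15):
        scenarios.append(
            DSAScenario(
                label=f"horizon {horizon} cycles",
                group="horizon",
                parameter_path="cohort.horizon_cycles",
                baseline_value=spec.cohort.horizon_cycles,
                scenario_value=horizon,
            )
        )

    scenarios.append(
        DSAScenario(
            label="cohort 570,000",
            group="cohort_size",
            parameter_path="cohort.cohort_size",
            baseline_value=spec.cohort.cohort_size,
            scenario_value=570_000,
        )
    )

    for state in spec.states:
        if state.is_death:
            continue
        for sign, tag in ((1 + span, "+"), ((1 - span), "-")):
            value = min(state.utility * sign, 1.0)  # utility cannot exceed 1
            scenarios.append(
                DSAScenario(
                    label=f"utility[{state.name}] {tag}{span:.0%}",
                    group=f"utility[{state.name}]",
                    parameter_path=f"states[{state.name}].utility",
                    baseline_value=state.utility,
                    scenario_value=value,
                )
            )

    for state in spec.states:
        if state.annual_state_cost_by_strategy and any(
            c > 0 for c in state.annual_state_cost_by_strategy.values()
        ):
            for factor, tag in ((1 + span, "+"), (1 - span, "-")):
                scenarios.append(
                    DSAScenario(
                        label=f"annual cost[{state.name}] {tag}{span:.0%}",
                        group=f"annual_cost[{state.name}]",
                        parameter_path=f"states[{state.name}].annual_state_cost_by_strategy",
                        baseline_value=dict(state.annual_state_cost_by_strategy),
                        scenario_value={
                            k: v * factor
                            for k, v in state.annual_state_cost_by_strategy.items()
                        },
                    )
                )
        if state.event_cost > 0:
            for factor, tag in ((1 + span, "+"), (1 - span, "-")):
                scenarios.append(
                    DSAScenario(
                        label=f"event cost[{state.name}] {tag}{span:.0%}",
                        group=f"event_cost[{state.name}]",
                        parameter_path=f"states[{state.name}].event_cost",
                        baseline_value=state.event_cost,
                        scenario_value=state.event_cost * factor,
                    )
                )

    return scenarios


def run_dsa(
    spec: ModelSpec,
    scenarios: list[DSAScenario],
    intervention: str | None = None,
    comparator: str | None = None,
) -> tuple[float, list[DSAResult]]:
    """Recompute the ICER under each scenario.

    Returns ``(baseline_icer, results)``.  A scenario that yields an invalid
    spec is recorded as a failed entry (``error`` set) and the run continues.
    Fully deterministic.
    """
    if comparator is None:
        comparator = spec.strategies[0]
    if intervention is None:
        intervention = spec.strategies[1] if len(spec.strategies) > 1 else spec.strategies[0]

    def icer_of(s: ModelSpec) -> float:
        res = compute_icer(
            evaluate_strategy(s, intervention), evaluate_strategy(s, comparator)
        )
        return res.icer

    baseline_icer = icer_of(spec)
    results: list[DSAResult] = []
    for scenario in scenarios:
        try:
            varied = apply_scenario(spec, scenario)
        except Exception as exc:  # scenario not applicable to this spec
            results.append(
                DSAResult(scenario=scenario, icer=math.nan, deviation=math.nan, error=str(exc))
            )
            continue
        report = validate_model_spec(varied)
        if not report.ok:
            results.append(
                DSAResult(
                    scenario=scenario,
                    icer=math.nan,
                    deviation=math.nan,
                    error="; ".join(str(f) for f in report.findings),
                )
            )
            continue
        icer = icer_of(varied)
        results.append(
            DSAResult(scenario=scenario, icer=icer, deviation=icer - baseline_icer)
        )
    return baseline_icer, results


def tornado_table(baseline_icer: float, results: list[DSAResult]) -> list[TornadoEntry]:
    """Aggregate per-scenario ICERs into tornado bars, widest first.

    A zero-width baseline entry is always included (and sorts last among
    entries with any spread).
    """
    groups: dict[str, list[float]] = {}
    for r in results:
        if r.ok:
            groups.setdefault(r.scenario.group, []).append(r.icer)
    entries = [
        TornadoEntry(
            group=group,
            icer_low=min(icers),
            icer_high=max(icers),
            baseline_icer=baseline_icer,
        )
        for group, icers in groups.items()
    ]
    entries.append(
        TornadoEntry(
            group="baseline",
            icer_low=baseline_icer,
            icer_high=baseline_icer,
            baseline_icer=baseline_icer,
        )
    )
    entries.sort(key=lambda e: e.max_abs_deviation, reverse=True)
    return entries


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


def _beta_draw(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Beta draw with the given mean and SD (method of moments).

    Degenerate baselines (mean at or outside {0, 1}) and infeasible moment
    pairs (SD too large for the mean) are held at the baseline value.
    """
    if not 0.0 < mean < 1.0 or sd <= 0.0:
        return mean
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    if nu <= 0.0:
        return mean
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def _gamma_draw(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Gamma draw with the given mean and SD; zero means are held fixed."""
    if mean <= 0.0 or sd <= 0.0:
        return mean
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return float(rng.gamma(shape, scale))


def sample_psa_draw(
    spec: ModelSpec,
    rng: np.random.Generator,
    sd_fraction: float = DEFAULT_SD_FRACTION,
    renormalize: bool = True,
) -> ModelSpec:
    """One PSA draw: a perturbed copy of ``spec``.

    Probabilities and utilities are drawn from beta distributions, costs from
    gamma distributions, each with mean equal to the baseline value and SD
    equal to ``sd_fraction`` × mean.  Transition parameters that share a
    (from, to, baseline) triple across strategies receive the *same* draw
    (common random parameters), so strategy-shared quantities such as the
    background death rate do not add spurious between-strategy noise.  Drawn
    exit rows whose sum exceeds 1 are scaled back proportionally
    (``renormalize=True``, default); with ``renormalize=False`` the row is
    redrawn.  ``sd_fraction=0`` reproduces the baseline spec exactly.
    """
    if sd_fraction == 0.0:
        return spec.model_copy(deep=True)
    data = spec.model_dump()

    for state in data["states"]:
        if state["is_death"]:
            continue
        u = state["utility"]
        if 0.0 < u < 1.0:
            state["utility"] = _beta_draw(rng, u, sd_fraction * u)
        for strat, c in state["annual_state_cost_by_strategy"].items():
            state["annual_state_cost_by_strategy"][strat] = _gamma_draw(
                rng, c, sd_fraction * c
            )
        state["event_cost"] = _gamma_draw(rng, state["event_cost"], sd_fraction * state["event_cost"])

    shared: dict[tuple[str, str, float], float] = {}
    for t in data["transitions"]:
        p = t["annual_probability"]
        key = (t["from_state"], t["to_state"], p)
        if key not in shared:
            shared[key] = _beta_draw(rng, p, sd_fraction * p)
        t["annual_probability"] = shared[key]

    # keep each (strategy, from_state) exit row feasible
    def oversized_rows() -> dict[tuple[str, str], float]:
        sums: dict[tuple[str, str], float] = {}
        for t in data["transitions"]:
            if t["from_state"] == t["to_state"]:
                continue
            k = (t["strategy"], t["from_state"])
            sums[k] = sums.get(k, 0.0) + t["annual_probability"]
        return {k: s for k, s in sums.items() if s > 1.0}

    if not renormalize:  # reject-and-redraw (bounded; falls back to scaling)
        for _ in range(100):
            bad = oversized_rows()
            if not bad:
                break
            for t in data["transitions"]:
                k = (t["strategy"], t["from_state"])
                if k in bad and t["from_state"] != t["to_state"]:
                    p0 = spec.transition(t["strategy"], t["from_state"], t["to_state"])
                    t["annual_probability"] = _beta_draw(rng, p0, sd_fraction * p0)
    bad = oversized_rows()
    if bad:
        for t in data["transitions"]:
            k = (t["strategy"], t["from_state"])
            if k in bad and t["from_state"] != t["to_state"]:
                t["annual_probability"] /= bad[k]

    return ModelSpec.model_validate(data)


@dataclass(frozen=True)
class PSAResult:
    """Monte-Carlo (ΔC, ΔE) draws for one strategy pair."""

    intervention: str
    comparator: str
    n_draws: int
    seed: int
    draws: np.ndarray  # shape (n_draws, 2): columns ΔC, ΔE
    quadrants: list[str] = field(default_factory=list)

    @property
    def delta_costs(self) -> np.ndarray:
        return self.draws[:, 0]

    @property
    def delta_effects(self) -> np.ndarray:
        return self.draws[:, 1]

    def quadrant_fractions(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for q in self.quadrants:
            out[q] = out.get(q, 0.0) + 1.0 / self.n_draws
        return out


def run_psa(
    spec: ModelSpec,
    n: int,
    seed: int,
    intervention: str | None = None,
    comparator: str | None = None,
    sd_fraction: float = DEFAULT_SD_FRACTION,
) -> PSAResult:
    """Probabilistic sensitivity analysis with ``n`` seeded draws.

    Both strategies are evaluated on the same drawn parameter set per draw;
    identical seeds give bitwise-identical results.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if comparator is None:
        comparator = spec.strategies[0]
    if intervention is None:
        intervention = spec.strategies[1] if len(spec.strategies) > 1 else spec.strategies[0]
    rng = np.random.default_rng(seed)
    draws = np.empty((n, 2))
    quadrants: list[str] = []
    for i in range(n):
        drawn = sample_psa_draw(spec, rng, sd_fraction=sd_fraction)
        out_i = evaluate_strategy(drawn, intervention)
        out_c = evaluate_strategy(drawn, comparator)
        dc = out_i.total_discounted_cost - out_c.total_discounted_cost
        de = out_i.total_discounted_qalys - out_c.total_discounted_qalys
        draws[i] = (dc, de)
        quadrants.append(classify_quadrant(dc, de))
    return PSAResult(
        intervention=intervention,
        comparator=comparator,
        n_draws=n,
        seed=seed,
        draws=draws,
        quadrants=quadrants,
    )


@dataclass(frozen=True)
class CEACPoint:
    """Probability the intervention is cost-effective at one WTP value."""

    wtp: float
    probability_cost_effective: float


def compute_ceac(psa: PSAResult, wtp_grid: list[float]) -> list[CEACPoint]:
    """Acceptability curve: at each λ, the fraction of draws with λ·ΔE − ΔC > 0."""
    if len(wtp_grid) == 0:
        raise ValueError("wtp_grid must be nonempty")
    if any(w < 0 for w in wtp_grid):
        raise ValueError("wtp_grid values must be >= 0")
    if psa.n_draws == 0:
        raise ValueError("PSA result has no draws")
    dc, de = psa.delta_costs, psa.delta_effects
    return [
        CEACPoint(
            wtp=float(w),
            probability_cost_effective=float(np.mean(w * de - dc > 0)),
        )
        for w in wtp_grid
    ]
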