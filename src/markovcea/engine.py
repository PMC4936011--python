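"""Markov cohort engine: transition matrices, trace iteration, outcome accrual.

The cohort is closed: every cycle, occupancy is redistributed by the
strategy's transition matrix, so the row-stochastic invariant guarantees
conservation of persons (including the absorbing death state).  Rewards
(costs and QALYs) accrue at cycle end — occupancy after the t-th transition
earns cycle-t rewards — with no half-cycle correction by default; an averaged
(half-cycle) occupancy option is available.

Event states (those with a per-episode ``event_cost``, e.g. AUR and TURP in
the bundled BPH model) are charged per *entry* rather than per occupancy
year; an explicit self-loop transition on such a state (repeat TURP) is
counted as a repeat episode each cycle and re-incurs the episode cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_config import ModelSpec, require_valid

__all__ = [
    "TransitionMatrix",
    "CohortTrace",
    "StrategyOutcome",
    "ModelError",
    "build_transition_matrix",
    "run_cohort",
    "discount_weight",
    "accumulate_outcomes",
    "evaluate_strategy",
    "trace_to_frame",
    "outcome_to_frame",
]

_ROW_TOL = 1e-12


class ModelError(ValueError):
    """The spec cannot be turned into a coherent Markov process."""


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic annual transition matrix for one strategy.

    ``probabilities[i, j]`` is the annual probability of moving from
    ``state_order[i]`` to ``state_order[j]``.  ``repeat_event_rates`` holds
    the explicit self-loop probabilities (per-cycle repeat-episode rates) by
    state name; they are not part of the matrix since staying probabilities
    are always the complement of the declared exits.
    """

    strategy: str
    state_order: tuple[str, ...]
    probabilities: np.ndarray
    repeat_event_rates: dict[str, float] = field(default_factory=dict)

    def index(self, state: str) -> int:
        return self.state_order.index(state)


def build_transition_matrix(spec: ModelSpec, strategy: str) -> TransitionMatrix:
    """Assemble the annual transition matrix for ``strategy``.

    Off-diagonal entries come from the declared transitions; the diagonal is
    the complement of the declared exits (a negative staying probability
    raises :class:`ModelError` naming the state); the death row is absorbing.
    """
    require_valid(spec)
    if strategy not in spec.strategies:
        raise ModelError(f"unknown strategy {strategy!r}")
    names = tuple(spec.state_names())
    n = len(names)
    idx = {name: i for i, name in enumerate(names)}
    mat = np.zeros((n, n))
    repeats: dict[str, float] = {}
    for t in spec.transitions:
        if t.strategy != strategy:
            continue
        if t.from_state == t.to_state:
            repeats[t.from_state] = t.annual_probability
            continue
        mat[idx[t.from_state], idx[t.to_state]] = t.annual_probability
    for s in spec.states:
        i = idx[s.name]
        if s.is_death:
            mat[i, :] = 0.0
            mat[i, i] = 1.0
            continue
        exits = mat[i, :].sum()
        stay = 1.0 - exits
        if stay < -_ROW_TOL:
            raise ModelError(
                f"state {s.name!r} under strategy {strategy!r}: "
                f"exit probabilities sum to {exits:.6g} > 1"
            )
        mat[i, i] = max(stay, 0.0)
    return TransitionMatrix(
        strategy=strategy,
        state_order=names,
        probabilities=mat,
        repeat_event_rates=repeats,
    )


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy per cycle for one strategy, in persons.

    ``occupancy`` has shape (horizon + 1, n_states); row 0 is the entry
    distribution.  ``event_counts_per_cycle`` maps event name (``"<state>
    _entries"`` / ``"<state>_repeats"``) to a length-(horizon + 1) array of
    persons experiencing the event during the transition into each cycle
    (index 0 is always 0).
    """

    strategy: str
    state_order: tuple[str, ...]
    occupancy: np.ndarray
    event_counts_per_cycle: dict[str, np.ndarray]
    cohort_size: float

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def state_occupancy(self, state: str) -> np.ndarray:
        return self.occupancy[:, self.state_order.index(state)]

    def total_events(self, event: str) -> float:
        return float(self.event_counts_per_cycle[event].sum())


def run_cohort(
    spec: ModelSpec,
    strategy: str,
    horizon: int | None = None,
    initial: dict[str, float] | None = None,
) -> CohortTrace:
    """Iterate the cohort over ``horizon`` annual cycles.

    ``occupancy[0] = cohort_size × initial``; ``occupancy[t] =
    occupancy[t−1] · matrix``.  Entries into each event-cost state and
    repeat-episode flows (self-loop rate × previous occupancy) are recorded
    per cycle.
    """
    matrix = build_transition_matrix(spec, strategy)
    names = matrix.state_order
    horizon = spec.cohort.horizon_cycles if horizon is None else int(horizon)
    if horizon < 1:
        raise ModelError(f"horizon must be >= 1, got {horizon}")
    dist = spec.cohort.initial_distribution if initial is None else initial
    total_p = sum(dist.values())
    if abs(total_p - 1.0) > 1e-9 or any(p < 0 for p in dist.values()):
        raise ModelError("initial distribution must be nonnegative and sum to 1")
    cohort = spec.cohort.effective_cohort_size()
    start = np.zeros(len(names))
    for name, p in dist.items():
        start[names.index(name)] = cohort * p

    occ = np.empty((horizon + 1, len(names)))
    occ[0] = start
    P = matrix.probabilities
    for t in range(1, horizon + 1):
        occ[t] = occ[t - 1] @ P

    events: dict[str, np.ndarray] = {}
    event_states = [s.name for s in spec.states if s.event_cost > 0]
    for name in event_states:
        j = names.index(name)
        inflow = np.zeros(horizon + 1)
        col = P[:, j].copy()
        col[j] = 0.0  # entries only: exclude those already in the state
        for t in range(1, horizon + 1):
            inflow[t] = occ[t - 1] @ col
        events[f"{name}_entries"] = inflow
    for name, rate in matrix.repeat_event_rates.items():
        j = names.index(name)
        repeats = np.zeros(horizon + 1)
        repeats[1:] = rate * occ[:-1, j]
        events[f"{name}_repeats"] = repeats

    return CohortTrace(
        strategy=strategy,
        state_order=names,
        occupancy=occ,
        event_counts_per_cycle=events,
        cohort_size=cohort,
    )


def discount_weight(rate: float, cycle_index: int, convention: str = "first-cycle-undiscounted") -> float:
    """Discount weight ``(1 + rate)^(−cycle_index)``.

    ``cycle_index`` is the discounting exponent: under the
    first-cycle-undiscounted convention the rewards of cycle 1 carry index 0.
    The ``convention`` argument only matters to callers mapping cycle numbers
    to indices; the weight itself is the plain power.
    """
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    if cycle_index < 0:
        raise ValueError(f"cycle_index must be >= 0, got {cycle_index}")
    return float((1.0 + rate) ** (-cycle_index))


def _cycle_exponent(cycle: int, convention: str) -> int:
    if convention == "first-cycle-undiscounted":
        return cycle - 1
    if convention == "first-cycle-discounted":
        return cycle
    raise ValueError(f"unknown discount convention {convention!r}")


@dataclass(frozen=True)
class StrategyOutcome:
    """Aggregate discounted/undiscounted totals for one strategy."""

    strategy: str
    total_discounted_cost: float
    total_discounted_qalys: float
    total_undiscounted_cost: float
    total_undiscounted_qalys: float
    event_totals: dict[str, float]

    @property
    def turp_count(self) -> float:
        """TURP procedures: first entries plus repeat episodes."""
        return self.event_totals.get("turp_entries", 0.0) + self.event_totals.get(
            "turp_repeats", 0.0
        )

    @property
    def aur_count(self) -> float:
        return self.event_totals.get("aur_entries", 0.0)


def accumulate_outcomes(
    trace: CohortTrace,
    spec: ModelSpec,
    strategy: str | None = None,
    half_cycle_correction: bool = False,
) -> StrategyOutcome:
    """Accrue per-cycle costs and QALYs from a trace and discount them.

    For each cycle ``t ≥ 1``::

        cost_t = Σ_states occupancy[t] × annual_cost[state, strategy]
                 + Σ_events events[t] × event_cost
        qaly_t = Σ_states occupancy[t] × utility × cycle_length

    With ``half_cycle_correction`` the state occupancy used for accrual is
    the average of cycle t−1 and t.  Totals apply the discount weight of the
    cycle's index under the spec's convention.
    """
    strategy = trace.strategy if strategy is None else strategy
    names = trace.state_order
    horizon = trace.n_cycles
    cycle_len = spec.cohort.cycle_length_years
    utilities = np.array([spec.state(n).utility for n in names])
    costs = np.array(
        [spec.state(n).annual_state_cost_by_strategy.get(strategy, 0.0) for n in names]
    )
    event_costs = {
        f"{s.name}_{kind}": s.event_cost
        for s in spec.states
        for kind in ("entries", "repeats")
        if s.event_cost > 0
    }

    occ = trace.occupancy
    if half_cycle_correction:
        accrual = 0.5 * (occ[:-1] + occ[1:])
    else:
        accrual = occ[1:]

    rate = spec.discount.annual_rate
    convention = spec.discount.convention
    disc_cost = disc_qaly = undisc_cost = undisc_qaly = 0.0
    for t in range(1, horizon + 1):
        row = accrual[t - 1]
        cost_t = float(row @ costs) * cycle_len
        for ev, counts in trace.event_counts_per_cycle.items():
            cost_t += counts[t] * event_costs.get(ev, 0.0)
        qaly_t = float(row @ utilities) * cycle_len
        w = discount_weight(rate, _cycle_exponent(t, convention))
        disc_cost += w * cost_t
        disc_qaly += w * qaly_t
        undisc_cost += cost_t
        undisc_qaly += qaly_t

    totals = {ev: float(c.sum()) for ev, c in trace.event_counts_per_cycle.items()}
    return StrategyOutcome(
        strategy=strategy,
        total_discounted_cost=disc_cost,
        total_discounted_qalys=disc_qaly,
        total_undiscounted_cost=undisc_cost,
        total_undiscounted_qalys=undisc_qaly,
        event_totals=totals,
    )


def evaluate_strategy(
    spec: ModelSpec,
    strategy: str,
    horizon: int | None = None,
    initial: dict[str, float] | None = None,
    half_cycle_correction: bool = False,
) -> StrategyOutcome:
    """Run the cohort and accumulate outcomes in one step."""
    trace = run_cohort(spec, strategy, horizon=horizon, initial=initial)
    return accumulate_outcomes(
        trace, spec, strategy, half_cycle_correction=half_cycle_correction
    )


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------


def trace_to_frame(trace: CohortTrace) -> pd.DataFrame:
    """Long-format trace: one row per (cycle, state) with occupancy."""
    records = [
        {
            "strategy": trace.strategy,
            "cycle": t,
            "state": name,
            "occupancy": trace.occupancy[t, j],
        }
        for t in range(trace.occupancy.shape[0])
        for j, name in enumerate(trace.state_order)
    ]
    return pd.DataFrame.from_records(records)


def outcome_to_frame(outcome: StrategyOutcome) -> pd.DataFrame:
    """One-row summary frame for a strategy outcome."""
    row = {
        "strategy": outcome.strategy,
        "total_discounted_cost": outcome.total_discounted_cost,
        "total_discounted_qalys": outcome.total_discounted_qalys,
        "total_undiscounted_cost": outcome.total_undiscounted_cost,
        "total_undiscounted_qalys": outcome.total_undiscounted_qalys,
        "turp_count": outcome.turp_count,
        "aur_count": outcome.aur_count,
    }
    return pd.DataFrame([row])
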