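"""Random and degenerate model specifications for property testing.

These generators make no attempt at clinical realism — they exist so that
the engine's structural guarantees (cohort conservation, matrix-power
equivalence, discount monotonicity, cohort linearity, round-tripping) can be
exercised over a wide space of valid models without any external input.
Transition rows are generated directly as normalized weight vectors and then
decomposed into off-diagonal entries, so invalid exit sums cannot arise by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_config import (
    CohortSettings,
    DiscountSettings,
    HealthStateDef,
    ModelSpec,
    TransitionEntry,
)

__all__ = ["GeneratorSettings", "generate_random_model", "degenerate_fixtures"]


@dataclass(frozen=True)
class GeneratorSettings:
    """Controls for :func:`generate_random_model`.

    ``n_states`` includes the death state (so must be ≥ 2); ``cost_scale``
    sets the magnitude of drawn annual costs in US$.
    """

    n_states: int = 5
    n_strategies: int = 2
    seed: int = 0
    cost_scale: float = 1000.0
    horizon_cycles: int = 10
    cohort_size: float = 10_000.0
    discount_rate: float = 0.05
    event_state_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2 (at least one alive + death)")
        if self.n_strategies < 1:
            raise ValueError("n_strategies must be >= 1")


def generate_random_model(settings: GeneratorSettings) -> ModelSpec:
    """Draw a random valid model spec, deterministic under a fixed seed.

    Utilities are uniform in [0, 1]; per-state annual costs are uniform in
    [0, cost_scale]; a random subset of alive states carries a per-episode
    event cost; each alive state's transition row is a normalized Dirichlet-
    like weight vector whose off-diagonal mass becomes the declared exits.
    """
    rng = np.random.default_rng(settings.seed)
    n = settings.n_states
    names = [f"s{i}" for i in range(n - 1)] + ["death"]
    strategies = [f"strategy{j}" for j in range(settings.n_strategies)]

    states = []
    for i, name in enumerate(names):
        if name == "death":
            states.append(HealthStateDef(name=name, is_death=True))
            continue
        event_cost = (
            float(rng.uniform(0, settings.cost_scale))
            if rng.random() < settings.event_state_fraction
            else 0.0
        )
        states.append(
            HealthStateDef(
                name=name,
                utility=float(rng.uniform(0, 1)),
                annual_state_cost_by_strategy={
                    s: float(rng.uniform(0, settings.cost_scale)) for s in strategies
                },
                event_cost=event_cost,
            )
        )

    transitions: list[TransitionEntry] = []
    for strategy in strategies:
        for i, name in enumerate(names):
            if name == "death":
                continue
            weights = rng.random(n)
            row = weights / weights.sum()
            for j, to in enumerate(names):
                if j == i or row[j] == 0.0:
                    continue  # staying probability is implied
                transitions.append(
                    TransitionEntry(
                        strategy=strategy,
                        from_state=name,
                        to_state=to,
                        annual_probability=float(row[j]),
                    )
                )

    init_weights = rng.random(n - 1)
    init = init_weights / init_weights.sum()
    # renormalize in float to keep the sum at exactly 1.0
    initial = {names[i]: float(p) for i, p in enumerate(init)}
    drift = 1.0 - sum(initial.values())
    first = names[0]
    initial[first] += drift

    return ModelSpec(
        states=states,
        strategies=strategies,
        transitions=transitions,
        discount=DiscountSettings(annual_rate=settings.discount_rate),
        cohort=CohortSettings(
            cohort_size=settings.cohort_size,
            initial_distribution=initial,
            horizon_cycles=settings.horizon_cycles,
        ),
    )


def _two_state(
    name: str,
    p_exit: float,
    utility: float = 1.0,
    cost: float = 0.0,
    horizon: int = 5,
) -> ModelSpec:
    states = [
        HealthStateDef(
            name="alive",
            utility=utility,
            annual_state_cost_by_strategy={"only": cost},
        ),
        HealthStateDef(name="death", is_death=True),
    ]
    transitions = (
        [
            TransitionEntry(
                strategy="only",
                from_state="alive",
                to_state="death",
                annual_probability=p_exit,
            )
        ]
        if p_exit > 0
        else []
    )
    return ModelSpec(
        states=states,
        strategies=["only"],
        transitions=transitions,
        discount=DiscountSettings(annual_rate=0.0),
        cohort=CohortSettings(
            cohort_size=100.0,
            initial_distribution={"alive": 1.0},
            horizon_cycles=horizon,
        ),
    )


def degenerate_fixtures() -> dict[str, ModelSpec]:
    """Named edge-case models.

    ``zero_cost``: all costs zero.  ``all_utility_one``: every alive state at
    full health.  ``immediate_death``: the whole cohort dies in cycle 1.
    ``identity_transition``: no declared exits, occupancy constant.
    ``single_strategy``: minimal one-strategy survival chain.
    """
    zero_cost = _two_state("zero_cost", p_exit=0.3, utility=0.8)

    all_one = generate_random_model(GeneratorSettings(n_states=4, seed=7))
    data = all_one.model_dump()
    for s in data["states"]:
        if not s["is_death"]:
            s["utility"] = 1.0
    all_one = ModelSpec.model_validate(data)

    return {
        "zero_cost": zero_cost,
        "all_utility_one": all_one,
        "immediate_death": _two_state("immediate_death", p_exit=1.0),
        "identity_transition": _two_state("identity", p_exit=0.0, cost=50.0),
        "single_strategy": _two_state("single", p_exit=0.1, utility=0.9, cost=10.0),
    }
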