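"""Incremental cost-effectiveness comparison of two strategies.

The ICER is the incremental cost divided by the incremental effect,
ΔC / ΔE.  A negative ratio is ambiguous on its own (it arises from both
dominance and dominated configurations), so every result carries an explicit
status and results are classified on the cost-effectiveness plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .engine import StrategyOutcome

__all__ = [
    "CEAResult",
    "compute_icer",
    "compute_nmb",
    "classify_quadrant",
]


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of ``intervention`` against ``comparator``.

    ``icer`` is ``nan`` when ΔE = 0 (undefined ratio).  ``status`` is one of
    ``dominant`` (cheaper and/or more effective with no downside),
    ``dominated`` (the mirror image), ``trade-off-NE`` (more costly, more
    effective), ``trade-off-SW`` (cheaper, less effective) or ``equivalent``.
    """

    intervention: str
    comparator: str
    delta_cost: float
    delta_effect: float
    icer: float
    status: str

    @property
    def icer_defined(self) -> bool:
        return not math.isnan(self.icer)

    def formatted_icer(self) -> str:
        """Display form: 2 decimal places, dominance flagged."""
        if not self.icer_defined:
            return f"undefined ({self.status})"
        if self.status in ("dominant", "dominated"):
            return f"{self.icer:.2f} ({self.status})"
        return f"{self.icer:.2f}"


def _status(delta_cost: float, delta_effect: float) -> str:
    if delta_cost == 0 and delta_effect == 0:
        return "equivalent"
    if delta_cost <= 0 and delta_effect >= 0:
        return "dominant"
    if delta_cost >= 0 and delta_effect <= 0:
        return "dominated"
    if delta_cost > 0 and delta_effect > 0:
        return "trade-off-NE"
    return "trade-off-SW"


def compute_icer(
    intervention: StrategyOutcome | tuple[float, float],
    comparator: StrategyOutcome | tuple[float, float],
) -> CEAResult:
    """ICER of ``intervention`` versus ``comparator``.

    Accepts :class:`StrategyOutcome` objects or plain ``(cost, qalys)``
    pairs (useful for arithmetic over published summary tables).
    """

    def unpack(x) -> tuple[str, float, float]:
        if isinstance(x, StrategyOutcome):
            return x.strategy, x.total_discounted_cost, x.total_discounted_qalys
        cost, effect = x
        return "?", float(cost), float(effect)

    name_i, cost_i, eff_i = unpack(intervention)
    name_c, cost_c, eff_c = unpack(comparator)
    delta_cost = cost_i - cost_c
    delta_effect = eff_i - eff_c
    icer = delta_cost / delta_effect if delta_effect != 0 else math.nan
    return CEAResult(
        intervention=name_i,
        comparator=name_c,
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=icer,
        status=_status(delta_cost, delta_effect),
    )


def compute_nmb(outcome: StrategyOutcome | tuple[float, float], wtp: float) -> float:
    """Net monetary benefit: ``wtp × QALYs − cost``."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be >= 0, got {wtp}")
    if isinstance(outcome, StrategyOutcome):
        cost, qalys = outcome.total_discounted_cost, outcome.total_discounted_qalys
    else:
        cost, qalys = outcome
    return wtp * qalys - cost


def classify_quadrant(delta_cost: float, delta_effect: float) -> str:
    """Cost-effectiveness-plane quadrant of a (ΔC, ΔE) point.

    ``NE``/``NW``/``SE``/``SW`` for strict quadrants; boundary cases are
    labelled ``origin``, ``cost-axis`` (ΔE = 0) or ``effect-axis`` (ΔC = 0).
    """
    if delta_cost == 0 and delta_effect == 0:
        return "origin"
    if delta_effect == 0:
        return "cost-axis"
    if delta_cost == 0:
        return "effect-axis"
    ns = "N" if delta_cost > 0 else "S"
    ew = "E" if delta_effect > 0 else "W"
    return ns + ew
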