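"""Incremental cost-effectiveness: deltas, ICERs and net monetary benefit.

ICERs are only reported as ratios in the north-east quadrant of the
cost-effectiveness plane (positive incremental cost and effect).  Negative
ratios are not order-preserving, so other quadrants carry a dominance
category instead: ``dominant`` (cheaper and more effective), ``dominated``
(costlier and less effective), or ``undefined`` (zero incremental effect).
"""

from __future__ import annotations

from dataclasses import dataclass

from .costs import CostBreakdown
from .effects import EFFECT_MEASURES, EffectSet
from .exceptions import ModelError

__all__ = ["IncrementalResult", "incremental", "net_monetary_benefit", "PERSPECTIVES"]

PERSPECTIVES = ("societal", "provider", "user")


def _delta_cost(i: CostBreakdown, c: CostBreakdown, perspective: str) -> float:
    if perspective == "societal":
        return i.societal - c.societal
    if perspective == "provider":
        return i.provider_net - c.provider_net
    if perspective == "user":
        return i.user_total - c.user_total
    raise ModelError(f"unknown perspective {perspective!r}")


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental cost and effects of intervention vs control.

    ``icers[m]`` is ``delta_cost / delta_effects[m]`` when both deltas are
    positive, else ``None`` with the reason in ``category[m]``.
    """

    perspective: str
    delta_cost: float
    delta_effects: dict[str, float]
    icers: dict[str, float | None]
    category: dict[str, str]

    def icer(self, measure: str) -> float | None:
        return self.icers[measure]


def incremental(
    intervention: tuple[CostBreakdown, EffectSet],
    control: tuple[CostBreakdown, EffectSet],
    perspective: str = "societal",
) -> IncrementalResult:
    """Incremental result between two arms evaluated under one scenario."""
    (cost_i, eff_i), (cost_c, eff_c) = intervention, control
    d_cost = _delta_cost(cost_i, cost_c, perspective)
    d_eff = {
        m: eff_i.as_dict()[m] - eff_c.as_dict()[m] for m in EFFECT_MEASURES
    }
    icers: dict[str, float | None] = {}
    category: dict[str, str] = {}
    for m, de in d_eff.items():
        if de > 0:
            if d_cost >= 0:
                icers[m] = d_cost / de
                category[m] = "icer"
            else:
                icers[m] = None
                category[m] = "dominant"
        elif de == 0:
            icers[m] = None
            category[m] = "undefined"
        else:
            icers[m] = None
            category[m] = "dominated" if d_cost >= 0 else "trade-off"
    return IncrementalResult(perspective, d_cost, d_eff, icers, category)


def net_monetary_benefit(
    result: IncrementalResult, threshold: float, measure: str = "dalys_averted"
) -> float:
    """``threshold * delta_effect - delta_cost``; positive iff cost-effective."""
    if measure not in result.delta_effects:
        raise ModelError(f"unknown effect measure {measure!r}")
    return threshold * result.delta_effects[measure] - result.delta_cost
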