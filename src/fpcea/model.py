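"""End-to-end decision model: parameter values -> incremental results.

A :class:`DecisionModel` wires the pieces together once — it calibrates the
effects chain from the anchored arm totals and solves the additive cost
offsets at base-case parameter values — and then evaluates any realized
parameter vector (base case, one-way substitution, or a Monte Carlo draw)
through service mixes, costs and effects to an incremental result.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cea import IncrementalResult, incremental
from .costs import (
    CostAssumptions,
    CostBreakdown,
    CostOffsets,
    apply_fee_scenario,
    apply_offsets,
    arm_cost,
    calibrate_offsets,
    service_mix_from_values,
)
from .effects import EffectCoefficients, EffectSet, calibrate_chain, effects_from_services, load_anchors
from .params import ParameterSet, load_parameters

__all__ = ["DecisionModel", "ArmOutcome"]

ARMS = ("intervention", "control")


@dataclass(frozen=True)
class ArmOutcome:
    cost: CostBreakdown
    effects: EffectSet


class DecisionModel:
    """Calibrated cost-effectiveness model for the two trial arms.

    Parameters
    ----------
    params
        Parameter registry (packaged defaults if omitted).
    assumptions
        Micro-costing assumptions (packaged defaults if omitted).
    anchors
        Anchored arm totals for calibration (packaged defaults if omitted).
    coefficients
        Pre-computed effect coefficients; when omitted they are calibrated
        from the anchors at base-case service mixes.
    calibrated
        When True (default) the cost model is anchored to the reported arm
        totals with additive base-case residuals; when False the raw
        mechanistic costs are used.
    """

    def __init__(
        self,
        params: ParameterSet | None = None,
        assumptions: CostAssumptions | None = None,
        anchors: dict | None = None,
        coefficients: EffectCoefficients | None = None,
        calibrated: bool = True,
    ) -> None:
        self.params = params or load_parameters()
        self.assumptions = assumptions or CostAssumptions()
        self.anchors = anchors or load_anchors()
        base = self.params.base_values()
        self.coefficients: EffectCoefficients = coefficients or calibrate_chain(
            {arm: service_mix_from_values(base, arm) for arm in ARMS},
            self.anchors,
        )
        self.offsets: dict[str, CostOffsets] = {}
        for arm in ARMS:
            if calibrated:
                raw = arm_cost(
                    service_mix_from_values(base, arm),
                    base,
                    self.assumptions,
                    arm,
                    self.params.overhead_proportion,
                )
                ca = self.anchors["costs"][arm]
                self.offsets[arm] = calibrate_offsets(
                    raw, ca["provider_net"], ca["user_total"], ca["user_total_no_fee"]
                )
            else:
                self.offsets[arm] = CostOffsets()

    # -- evaluation --------------------------------------------------------

    def arm_outcome(
        self,
        arm: str,
        values: dict[str, float] | None = None,
        fee_fraction: float = 1.0,
        overhead: float | None = None,
    ) -> ArmOutcome:
        """Costs and effects for one arm at the given parameter values."""
        values = values if values is not None else self.params.base_values()
        overhead = overhead if overhead is not None else self.params.overhead_proportion
        mix = service_mix_from_values(values, arm)
        cost = arm_cost(mix, values, self.assumptions, arm, overhead)
        cost = apply_offsets(cost, self.offsets[arm])
        cost = apply_fee_scenario(cost, fee_fraction)
        return ArmOutcome(cost, effects_from_services(mix, self.coefficients))

    def evaluate(
        self,
        values: dict[str, float] | None = None,
        perspective: str = "societal",
        fee_fraction: float = 1.0,
        overhead: float | None = None,
    ) -> IncrementalResult:
        """Incremental result at the given parameter values and scenario."""
        outcomes = {
            arm: self.arm_outcome(arm, values, fee_fraction, overhead) for arm in ARMS
        }
        return incremental(
            (outcomes["intervention"].cost, outcomes["intervention"].effects),
            (outcomes["control"].cost, outcomes["control"].effects),
            perspective,
        )

    def base_case(
        self, perspective: str = "societal", fee_fraction: float = 1.0
    ) -> IncrementalResult:
        """Incremental result at the deterministic point estimates."""
        return self.evaluate(perspective=perspective, fee_fraction=fee_fraction)
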