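"""Cost model: provider/user/societal components, fee scenarios, offsets."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpcea.costs import (
    CostBreakdown,
    ServiceMix,
    apply_fee_scenario,
    apply_offsets,
    arm_cost,
    calibrate_offsets,
    load_assumptions,
    provider_cost,
    service_mix_from_values,
    user_cost,
)
from fpcea.exceptions import ModelError
from tests.conftest import TABLE_COSTS

ZERO_MIX = ServiceMix(0, 0, 0, 0, 0)


class TestProviderCost:
    def test_intervention_delivery_subtotal_per_participant(self, params, assumptions):
        base = params.base_values()
        subtotal = sum(
            base[f"cost.delivery.{k}"]
            for k in ("voice_airtime", "call_airtime", "computer", "phone")
        )
        assert subtotal == pytest.approx(4.49)
        # remove counsellor time to isolate the airtime/equipment component
        a = dataclasses.replace(assumptions, counsellor_minutes_per_participant=0.0)
        cost = provider_cost(ZERO_MIX, base, a, arm="intervention")
        assert cost.provider_gross == pytest.approx(4490.0)

    def test_zero_services_zero_cost(self, params, assumptions):
        base = params.base_values()
        cost = provider_cost(ZERO_MIX, base, assumptions, arm="control")
        assert cost.provider_gross == 0.0
        assert cost.fee_income == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ModelError):
            ServiceMix(-1, 0, 0, 0, 0)

    @pytest.mark.parametrize("arm", ["intervention", "control"])
    def test_raw_provider_net_within_5pct_of_reported(self, params, assumptions, arm):
        base = params.base_values()
        mix = service_mix_from_values(base, arm)
        cost = arm_cost(mix, base, assumptions, arm, params.overhead_proportion)
        want = TABLE_COSTS["provider"][arm]
        assert cost.provider_net == pytest.approx(want, rel=0.05)

    def test_overhead_loads_personnel_linearly(self, params, assumptions):
        base = params.base_values()
        mix = service_mix_from_values(base, "control")
        c0 = provider_cost(mix, base, assumptions, "control", overhead=0.0)
        c2 = provider_cost(mix, base, assumptions, "control", overhead=0.2)
        c4 = provider_cost(mix, base, assumptions, "control", overhead=0.4)
        assert c4.provider_gross - c2.provider_gross == pytest.approx(
            c2.provider_gross - c0.provider_gross, rel=1e-9
        )


class TestUserCost:
    def test_single_full_distance_round_trip(self, params, assumptions):
        base = params.base_values()
        # one repeat abortion: a full-distance trip at 38.2 km x 0.22 US$/km
        mix = ServiceMix(0, 0, 0, 0, 1)
        cost = user_cost(mix, base, assumptions, "control")
        assert cost.user_transport == pytest.approx(38.2 * 0.22)

    def test_abortion_household_indirect_cost(self, params, assumptions):
        base = params.base_values()
        cost = user_cost(ServiceMix(0, 0, 0, 0, 1), base, assumptions, "control")
        time_cost = (
            (assumptions.minutes["repeat_abortion"] + 38.2 / 30.0 * 60.0)
            * 6.9
            / (8 * 60.0)
        )
        assert cost.user_indirect == pytest.approx(5.07 + time_cost)

    def test_other_clinic_trips_save_a_third_of_distance(self, params):
        base = params.base_values()
        mix = ServiceMix(0, 0, 100, 0, 0)
        all_study = dataclasses.replace(load_assumptions(), other_clinic_share=0.0)
        all_other = dataclasses.replace(load_assumptions(), other_clinic_share=1.0)
        t_study = user_cost(mix, base, all_study, "control").user_transport
        t_other = user_cost(mix, base, all_other, "control").user_transport
        assert t_other == pytest.approx(t_study * 2.0 / 3.0)

    @pytest.mark.parametrize("arm", ["intervention", "control"])
    def test_raw_user_total_within_5pct_of_reported(self, params, assumptions, arm):
        base = params.base_values()
        mix = service_mix_from_values(base, arm)
        cost = user_cost(mix, base, assumptions, arm)
        assert cost.user_total == pytest.approx(TABLE_COSTS["user"][arm], rel=0.05)


class TestLinearity:
    def test_costs_scale_linearly_in_service_counts(self, params, assumptions):
        base = params.base_values()
        mix = service_mix_from_values(base, "control")
        double = ServiceMix(**{k: 2 * v for k, v in mix.as_dict().items()})
        c1 = arm_cost(mix, base, assumptions, "control", 0.2)
        c2 = arm_cost(double, base, assumptions, "control", 0.2)
        assert c2.societal == pytest.approx(2 * c1.societal, rel=1e-12)
        assert c2.user_fees == pytest.approx(2 * c1.user_fees, rel=1e-12)


@pytest.fixture(scope="module")
def breakdown(params, assumptions):
    base = params.base_values()
    mix = service_mix_from_values(base, "control")
    return arm_cost(mix, base, assumptions, "control", 0.2)


class TestFeeScenario:
    def test_full_fees_is_identity(self, breakdown):
        assert apply_fee_scenario(breakdown, 1.0) == breakdown

    def test_zero_fees_moves_cost_to_provider(self, breakdown):
        free = apply_fee_scenario(breakdown, 0.0)
        assert free.user_fees == 0.0
        assert free.provider_net == pytest.approx(
            breakdown.provider_net + breakdown.user_fees
        )

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(f=st.floats(0.0, 1.0))
    def test_societal_total_invariant_for_any_fraction(self, breakdown, f):
        assert apply_fee_scenario(breakdown, f).societal == pytest.approx(
            breakdown.societal, rel=1e-12
        )

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(f=st.floats(0.0, 1.0), g=st.floats(0.0, 1.0))
    def test_user_total_monotone_in_fee_fraction(self, breakdown, f, g):
        lo, hi = sorted((f, g))
        a, b = apply_fee_scenario(breakdown, lo), apply_fee_scenario(breakdown, hi)
        assert a.user_total <= b.user_total + 1e-9
        assert a.provider_net >= b.provider_net - 1e-9

    def test_out_of_range_fraction_rejected(self, breakdown):
        with pytest.raises(ModelError):
            apply_fee_scenario(breakdown, 1.2)


class TestOffsets:
    def test_offsets_reproduce_anchored_totals_exactly(self, params, assumptions, anchors):
        base = params.base_values()
        for arm in ("intervention", "control"):
            raw = arm_cost(
                service_mix_from_values(base, arm), base, assumptions, arm, 0.2
            )
            ca = anchors["costs"][arm]
            adjusted = apply_offsets(
                raw,
                calibrate_offsets(
                    raw, ca["provider_net"], ca["user_total"], ca["user_total_no_fee"]
                ),
            )
            assert adjusted.provider_net == pytest.approx(ca["provider_net"], abs=1e-6)
            assert adjusted.user_total == pytest.approx(ca["user_total"], abs=1e-6)
            assert adjusted.user_fees == pytest.approx(
                ca["user_total"] - ca["user_total_no_fee"], abs=1e-6
            )

    def test_transfer_identity_survives_offsets(self):
        raw = CostBreakdown(100.0, 30.0, 30.0, 10.0, 5.0)
        adj = apply_offsets(raw, calibrate_offsets(raw, 80.0, 50.0, 20.0))
        assert adj.societal == pytest.approx(adj.provider_net + adj.user_total)
        assert adj.fee_income == adj.user_fees
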