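"""Provider, user and societal costs per 1000 clients per arm.

The accounting identity running through this module is the fee transfer:
user fees are income to the provider, so

    provider net  = provider gross - fee income
    user total    = fees + transport + indirect
    societal      = provider net + user total
                  = provider gross + transport + indirect

which makes the societal total invariant to any user-fee scenario.

Provider gross cost is commodities for every service, clinical personnel
time (valued at the midwife wage, with a proportional overhead loading) for
clinic-delivered services, and — in the intervention arm — per-participant
intervention delivery costs (voice-message and call airtime, computer and
phone shares, counsellor time).  User costs are fees (clinic or pharmacy
prices), motorbike transport for dedicated clinic trips (reduced by one
third of the distance when a different clinic is visited), and the value of
clinical plus travel time at the gross daily income, applied to all
attendees regardless of employment, plus a per-event household indirect
cost for repeat abortions.

Because per-service minutes, attendance and resupply splits are assumptions
rather than published data, a set of per-arm additive
:class:`CostOffsets` can anchor the computed breakdown to externally
reported totals; the offsets are solved once at base-case parameter values
and held fixed during sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import yaml

from .exceptions import ModelError, SchemaError

__all__ = [
    "ServiceMix",
    "CostAssumptions",
    "CostBreakdown",
    "CostOffsets",
    "service_mix_from_values",
    "provider_cost",
    "user_cost",
    "arm_cost",
    "apply_fee_scenario",
    "apply_offsets",
    "calibrate_offsets",
    "load_assumptions",
]


@dataclass(frozen=True)
class ServiceMix:
    """Annual services per 1000 clients: pill cycles, injectable doses,
    implant and IUD insertions, repeat abortions."""

    ocp_cycles: float
    injectable_doses: float
    implant_insertions: float
    iud_insertions: float
    repeat_abortions: float

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if not math.isfinite(v) or v < 0:
                raise ModelError(f"service count {name} must be finite and >= 0, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {
            "ocp_cycles": self.ocp_cycles,
            "injectable_doses": self.injectable_doses,
            "implant_insertions": self.implant_insertions,
            "iud_insertions": self.iud_insertions,
            "repeat_abortions": self.repeat_abortions,
        }


def service_mix_from_values(values: dict[str, float], arm: str) -> ServiceMix:
    """Build a :class:`ServiceMix` from a parameter-value mapping."""
    return ServiceMix(
        ocp_cycles=values[f"svc.{arm}.ocp"],
        injectable_doses=values[f"svc.{arm}.injectable"],
        implant_insertions=values[f"svc.{arm}.implant"],
        iud_insertions=values[f"svc.{arm}.iud"],
        repeat_abortions=values[f"svc.{arm}.repeat_abortion"],
    )


@dataclass(frozen=True)
class CostAssumptions:
    """Micro-costing assumptions; see the packaged defaults for semantics."""

    clinic_share: float = 0.40
    abortion_medical_share: float = 0.80
    removals_per_insertion: float = 0.10
    separate_visit_proportion: float = 0.42
    other_clinic_share: float = 0.50
    larc_followup_visits: float = 1.20
    minutes: dict | None = None
    counsellor_minutes_per_participant: float = 55.0
    hotline_minutes_per_participant: float = 0.0
    travel_speed_kmh: float = 30.0
    workday_hours: float = 8.0
    participants_per_1000: float = 1000.0

    def __post_init__(self) -> None:
        if self.minutes is None:
            object.__setattr__(self, "minutes", dict(_DEFAULT_MINUTES))
        for name in (
            "clinic_share",
            "abortion_medical_share",
            "separate_visit_proportion",
            "other_clinic_share",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SchemaError(f"{name} must lie in [0, 1], got {v}")
        if any(m < 0 for m in self.minutes.values()):
            raise SchemaError("per-service minutes must be >= 0")
        if self.travel_speed_kmh <= 0 or self.workday_hours <= 0:
            raise SchemaError("travel speed and workday length must be positive")


_DEFAULT_MINUTES = {
    "ocp_cycle": 10.0,
    "injectable_dose": 25.0,
    "implant_insertion": 40.0,
    "iud_insertion": 40.0,
    "larc_removal": 30.0,
    "repeat_abortion": 180.0,
    "larc_followup": 15.0,
}


def load_assumptions(path: str | Path | None = None) -> CostAssumptions:
    """Load cost assumptions from YAML (packaged defaults if ``path`` is None)."""
    p = (
        Path(path)
        if path is not None
        else Path(resources.files("fpcea.data") / "cost_assumptions.yaml")
    )
    if not p.exists():
        raise SchemaError(f"assumptions file not found: {p}")
    doc = yaml.safe_load(p.read_text()) or {}
    known = {f.name for f in CostAssumptions.__dataclass_fields__.values()}
    unknown = set(doc) - known
    if unknown:
        raise SchemaError(f"unknown assumption keys: {', '.join(sorted(unknown))}")
    return CostAssumptions(**doc)


@dataclass(frozen=True)
class CostBreakdown:
    """Cost components in US$ per 1000 clients.

    ``fee_income`` (income to the provider) equals ``user_fees`` in this
    model: every fee is a transfer from users to the provider sector.
    """

    provider_gross: float = 0.0
    fee_income: float = 0.0
    user_fees: float = 0.0
    user_transport: float = 0.0
    user_indirect: float = 0.0

    @property
    def provider_net(self) -> float:
        return self.provider_gross - self.fee_income

    @property
    def user_total(self) -> float:
        return self.user_fees + self.user_transport + self.user_indirect

    @property
    def societal(self) -> float:
        return self.provider_net + self.user_total

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown(
            self.provider_gross + other.provider_gross,
            self.fee_income + other.fee_income,
            self.user_fees + other.user_fees,
            self.user_transport + other.user_transport,
            self.user_indirect + other.user_indirect,
        )


# ---------------------------------------------------------------------------
# shared service-level quantities


def _removals(mix: ServiceMix, a: CostAssumptions) -> tuple[float, float]:
    return (
        a.removals_per_insertion * mix.implant_insertions,
        a.removals_per_insertion * mix.iud_insertions,
    )


def _user_fees(mix: ServiceMix, v: dict[str, float], a: CostAssumptions) -> float:
    impl_rem, iud_rem = _removals(mix, a)
    c, m = a.clinic_share, a.abortion_medical_share
    return (
        mix.ocp_cycles * (c * v["fee.ocp_clinic"] + (1 - c) * v["fee.ocp_pharmacy"])
        + mix.injectable_doses
        * (c * v["fee.injectable_clinic"] + (1 - c) * v["fee.injectable_pharmacy"])
        + mix.implant_insertions * v["fee.implant_insertion"]
        + mix.iud_insertions * v["fee.iud_insertion"]
        + impl_rem * v["fee.implant_removal"]
        + iud_rem * v["fee.iud_removal"]
        + mix.repeat_abortions
        * (m * v["fee.abortion_medical"] + (1 - m) * v["fee.abortion_surgical"])
    )


# ---------------------------------------------------------------------------
# provider perspective


def provider_cost(
    mix: ServiceMix,
    values: dict[str, float],
    assumptions: CostAssumptions | None = None,
    arm: str = "control",
    overhead: float = 0.20,
) -> CostBreakdown:
    """Provider gross cost and fee income for one arm.

    Commodities are costed for every service (pharmacy supplies included at
    clinic commodity prices); clinical personnel time covers only
    clinic-delivered services; intervention delivery costs apply to the
    intervention arm only.  The overhead proportion loads all personnel
    costs.
    """
    a = assumptions or CostAssumptions()
    v = values
    impl_rem, iud_rem = _removals(mix, a)
    c, m = a.clinic_share, a.abortion_medical_share

    commodities = (
        mix.ocp_cycles * v["cost.commodity.ocp_cycle"]
        + mix.injectable_doses * v["cost.commodity.injectable_dose"]
        + mix.implant_insertions * v["cost.commodity.implant_device"]
        + mix.iud_insertions * v["cost.commodity.iud_device"]
        + (impl_rem + iud_rem) * v["cost.commodity.larc_removal"]
        + mix.repeat_abortions
        * (m * v["cost.commodity.medical_abortion"] + (1 - m) * v["cost.commodity.surgical_abortion"])
    )

    mins = a.minutes
    clinic_minutes = (
        c * mix.ocp_cycles * mins["ocp_cycle"]
        + c * mix.injectable_doses * mins["injectable_dose"]
        + mix.implant_insertions * mins["implant_insertion"]
        + mix.iud_insertions * mins["iud_insertion"]
        + (impl_rem + iud_rem) * mins["larc_removal"]
        + mix.repeat_abortions * mins["repeat_abortion"]
    )
    personnel = clinic_minutes / 60.0 * v["cost.personnel.midwife_hourly"] * (1.0 + overhead)

    delivery = 0.0
    if arm == "intervention":
        per_participant = (
            v["cost.delivery.voice_airtime"]
            + v["cost.delivery.call_airtime"]
            + v["cost.delivery.computer"]
            + v["cost.delivery.phone"]
        )
        counsellor = (
            a.counsellor_minutes_per_participant
            / 60.0
            * v["cost.personnel.counsellor_hourly"]
            * (1.0 + overhead)
        )
        delivery = a.participants_per_1000 * (per_participant + counsellor)

    return CostBreakdown(
        provider_gross=commodities + personnel + delivery,
        fee_income=_user_fees(mix, v, a),
    )


# ---------------------------------------------------------------------------
# user perspective


def user_cost(
    mix: ServiceMix,
    values: dict[str, float],
    assumptions: CostAssumptions | None = None,
    arm: str = "control",
) -> CostBreakdown:
    """User fees, transport and indirect (time) costs for one arm.

    Dedicated clinic trips are generated by the separate-visit share of
    resupply and insertion services, by removals and follow-up checks, and
    by every repeat abortion.  Pharmacy resupply is treated as costless
    beyond the fee itself.
    """
    a = assumptions or CostAssumptions()
    v = values
    impl_rem, iud_rem = _removals(mix, a)
    p, c = a.separate_visit_proportion, a.clinic_share
    mins = a.minutes

    transport_full = v["user.roundtrip_km"] * v["user.motorbike_per_km"]
    # contraceptive visits mix study-clinic and reduced-distance other-clinic trips
    reduction = a.other_clinic_share / 3.0
    transport_clinic = transport_full * (1.0 - reduction)
    travel_minutes = v["user.roundtrip_km"] / a.travel_speed_kmh * 60.0
    value_per_min = v["user.daily_income"] / (a.workday_hours * 60.0)

    # (count, clinical minutes, transport rate) per trip type
    trips = [
        (p * c * mix.ocp_cycles, mins["ocp_cycle"], transport_clinic),
        (p * c * mix.injectable_doses, mins["injectable_dose"], transport_clinic),
        (p * mix.implant_insertions, mins["implant_insertion"], transport_clinic),
        (p * mix.iud_insertions, mins["iud_insertion"], transport_clinic),
        (impl_rem + iud_rem, mins["larc_removal"], transport_clinic),
        (
            a.larc_followup_visits * (mix.implant_insertions + mix.iud_insertions),
            mins["larc_followup"],
            transport_clinic,
        ),
        (mix.repeat_abortions, mins["repeat_abortion"], transport_full),
    ]
    transport = sum(n * rate for n, _, rate in trips)
    indirect = sum(n * (clin + travel_minutes) * value_per_min for n, clin, _ in trips)
    indirect += mix.repeat_abortions * v["user.abortion_household_indirect"]

    phone = (
        a.hotline_minutes_per_participant
        * a.participants_per_1000
        * v["user.hotline_airtime_per_min"]
        if arm == "intervention"
        else 0.0
    )

    return CostBreakdown(
        user_fees=_user_fees(mix, v, a),
        user_transport=transport,
        user_indirect=indirect + phone,
    )


def arm_cost(
    mix: ServiceMix,
    values: dict[str, float],
    assumptions: CostAssumptions | None = None,
    arm: str = "control",
    overhead: float = 0.20,
) -> CostBreakdown:
    """Full cost breakdown (provider + user components) for one arm."""
    return provider_cost(mix, values, assumptions, arm, overhead) + user_cost(
        mix, values, assumptions, arm
    )


# ---------------------------------------------------------------------------
# fee scenarios and calibration offsets


def apply_fee_scenario(base: CostBreakdown, fee_fraction: float) -> CostBreakdown:
    """Scale user fees (and the matching provider fee income) by ``fee_fraction``.

    Transport, indirect and provider gross costs are untouched, so the
    societal total is invariant: removing fees shifts cost from users to
    the provider.
    """
    if not 0.0 <= fee_fraction <= 1.0:
        raise ModelError(f"fee fraction must lie in [0, 1], got {fee_fraction}")
    return replace(
        base,
        fee_income=base.fee_income * fee_fraction,
        user_fees=base.user_fees * fee_fraction,
    )


@dataclass(frozen=True)
class CostOffsets:
    """Additive per-arm calibration residuals (US$ per 1000 clients)."""

    fees: float = 0.0
    provider_gross: float = 0.0
    user_nonfee: float = 0.0


def apply_offsets(base: CostBreakdown, offsets: CostOffsets) -> CostBreakdown:
    """Anchor a computed breakdown with additive calibration residuals.

    The non-fee user residual is folded into the indirect component; the
    fee residual moves fees and fee income together, preserving the
    transfer identity.
    """
    return CostBreakdown(
        provider_gross=base.provider_gross + offsets.provider_gross,
        fee_income=base.fee_income + offsets.fees,
        user_fees=base.user_fees + offsets.fees,
        user_transport=base.user_transport,
        user_indirect=base.user_indirect + offsets.user_nonfee,
    )


def calibrate_offsets(
    raw: CostBreakdown,
    provider_net: float,
    user_total: float,
    user_total_no_fee: float,
) -> CostOffsets:
    """Solve the residuals that reproduce anchored arm totals exactly.

    ``user_total_no_fee`` (the user total with fees removed) identifies the
    fee component of the anchored totals; the remaining two residuals then
    follow from the provider-net and user-total identities.
    """
    anchored_fees = user_total - user_total_no_fee
    d_fees = anchored_fees - raw.user_fees
    return CostOffsets(
        fees=d_fees,
        provider_gross=(provider_net + anchored_fees) - raw.provider_gross,
        user_nonfee=user_total_no_fee - (raw.user_transport + raw.user_indirect),
    )
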