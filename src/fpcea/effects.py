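"""Health effects of contraceptive service provision.

Services are first converted to couple-years of protection (CYPs) with the
standard per-method factors: 15 pill cycles or 4 injectable doses per CYP,
and 3.2 / 4.6 CYPs per implant / IUD insertion (consistent with a 4-year
implant and 10-year IUD service lifespan).  Abortion services contribute no
effects.

Downstream effects use a two-class surrogate of the Impact2-style
conversion: short-acting and long-acting CYPs avert unintended pregnancies
at different per-CYP rates (a single pooled rate cannot reproduce both
trial arms, because lifespan discounting of fertility makes a long-acting
CYP more protective).  The two rates are solved exactly from the two arms'
anchored pregnancies averted; abortions averted are a fixed fraction of
pregnancies averted (57%, the share of unintended pregnancies ending in
abortion in Asia); DALYs and under-5 deaths averted are pooled ratios per
pregnancy averted.  Maternal deaths averted are zero in both arms, so the
chain carries an identically zero maternal component.

No discounting is applied to effects; all arithmetic is kept at full
precision, with rounding deferred to the reporting layer.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .costs import ServiceMix
from .exceptions import CalibrationError, ModelError

__all__ = [
    "EffectCoefficients",
    "EffectSet",
    "cyp_from_services",
    "cyp_split",
    "calibrate_chain",
    "effects_from_services",
    "load_anchors",
    "load_coefficients",
    "save_coefficients",
]

EFFECT_MEASURES = (
    "cyps",
    "pregnancies_averted",
    "abortions_averted",
    "under5_deaths_averted",
    "maternal_deaths_averted",
    "dalys_averted",
)


def load_anchors(path: str | Path | None = None) -> dict:
    """Anchored arm-level totals used to calibrate the effects chain."""
    p = (
        Path(path)
        if path is not None
        else Path(resources.files("fpcea.data") / "anchors.yaml")
    )
    return yaml.safe_load(p.read_text())


@dataclass(frozen=True)
class EffectCoefficients:
    """Per-method CYP factors and the calibrated effect-conversion rates."""

    cycles_per_cyp: float = 15.0
    doses_per_cyp: float = 4.0
    cyp_per_implant: float = 3.2
    cyp_per_iud: float = 4.6
    preg_per_cyp_short: float = 0.0
    preg_per_cyp_long: float = 0.0
    abortion_fraction: float = 0.57
    dalys_per_pregnancy: float = 0.0
    under5_per_pregnancy: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.abortion_fraction <= 1.0:
            raise ModelError("abortion fraction must lie in [0, 1]")
        for f in (
            self.cycles_per_cyp,
            self.doses_per_cyp,
            self.cyp_per_implant,
            self.cyp_per_iud,
        ):
            if f <= 0:
                raise ModelError("CYP factors must be positive")
        for r in (
            self.preg_per_cyp_short,
            self.preg_per_cyp_long,
            self.dalys_per_pregnancy,
            self.under5_per_pregnancy,
        ):
            if r < 0:
                raise ModelError("effect-conversion rates must be >= 0")


@dataclass(frozen=True)
class EffectSet:
    """Health effects per 1000 clients per year."""

    cyps: float
    pregnancies_averted: float
    abortions_averted: float
    under5_deaths_averted: float
    maternal_deaths_averted: float
    dalys_averted: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in EFFECT_MEASURES}


def cyp_split(mix: ServiceMix, coeff: EffectCoefficients) -> tuple[float, float]:
    """(short-acting, long-acting) CYPs from a service mix."""
    short = (
        mix.ocp_cycles / coeff.cycles_per_cyp
        + mix.injectable_doses / coeff.doses_per_cyp
    )
    long = (
        mix.implant_insertions * coeff.cyp_per_implant
        + mix.iud_insertions * coeff.cyp_per_iud
    )
    return short, long


def cyp_from_services(mix: ServiceMix, coeff: EffectCoefficients | None = None) -> float:
    """Total couple-years of protection; abortion services contribute none."""
    coeff = coeff or EffectCoefficients()
    return sum(cyp_split(mix, coeff))


def calibrate_chain(
    mixes: dict[str, ServiceMix],
    anchors: dict | None = None,
    coeff: EffectCoefficients | None = None,
) -> EffectCoefficients:
    """Solve the pregnancy/DALY conversion rates from two anchored arms.

    The 2x2 linear system ``[CYP_short, CYP_long] @ [r_s, r_l] = pregnancies``
    across the two arms identifies the short-/long-acting rates; DALYs and
    under-5 deaths per pregnancy averted are pooled ratios.

    Raises
    ------
    CalibrationError
        If the two arms have (near-)identical short/long CYP shares, which
        makes the system singular.
    """
    anchors = anchors or load_anchors()
    coeff = coeff or EffectCoefficients()
    arms = ("intervention", "control")
    A = np.array([cyp_split(mixes[arm], coeff) for arm in arms])
    preg = np.array([anchors["effects"]["pregnancies_averted"][arm] for arm in arms])

    # singular when both arms share the same short/long mix direction
    norms = np.linalg.norm(A, axis=1)
    if np.any(norms == 0) or abs(np.linalg.det(A)) < 1e-10 * norms.prod():
        raise CalibrationError(
            "arms have identical short/long CYP shares; pregnancy rates "
            "per CYP class are not identifiable"
        )
    r_s, r_l = np.linalg.solve(A, preg)
    if r_s < 0 or r_l < 0:
        raise CalibrationError("calibrated pregnancies-per-CYP are negative")

    total_preg = preg.sum()
    dalys = sum(anchors["effects"]["dalys_averted"][arm] for arm in arms)
    u5 = sum(anchors["effects"]["under5_deaths_averted"][arm] for arm in arms)
    return EffectCoefficients(
        cycles_per_cyp=coeff.cycles_per_cyp,
        doses_per_cyp=coeff.doses_per_cyp,
        cyp_per_implant=coeff.cyp_per_implant,
        cyp_per_iud=coeff.cyp_per_iud,
        preg_per_cyp_short=float(r_s),
        preg_per_cyp_long=float(r_l),
        abortion_fraction=float(anchors.get("abortion_fraction", 0.57)),
        dalys_per_pregnancy=float(dalys / total_preg),
        under5_per_pregnancy=float(u5 / total_preg),
    )


def save_coefficients(coeff: EffectCoefficients, path: str | Path) -> None:
    """Write calibrated effect coefficients to YAML."""
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(coeff), sort_keys=False))


def load_coefficients(path: str | Path) -> EffectCoefficients:
    """Read effect coefficients from YAML."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(EffectCoefficients)}
    unknown = set(doc) - known
    if unknown:
        raise ModelError(f"unknown coefficient keys: {', '.join(sorted(unknown))}")
    return EffectCoefficients(**doc)


def effects_from_services(mix: ServiceMix, coeff: EffectCoefficients) -> EffectSet:
    """Full effect chain for one arm's service mix."""
    short, long = cyp_split(mix, coeff)
    preg = coeff.preg_per_cyp_short * short + coeff.preg_per_cyp_long * long
    out = EffectSet(
        cyps=short + long,
        pregnancies_averted=preg,
        abortions_averted=coeff.abortion_fraction * preg,
        under5_deaths_averted=coeff.under5_per_pregnancy * preg,
        maternal_deaths_averted=0.0,
        dalys_averted=coeff.dalys_per_pregnancy * preg,
    )
    if not all(math.isfinite(v) for v in out.as_dict().values()):
        raise ModelError("non-finite effect computed")
    return out
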