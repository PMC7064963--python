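"""Deterministic and probabilistic sensitivity analysis.

* :func:`tornado` — one-way substitution of each parameter's deterministic
  range bounds (all others held at base), re-running the full pipeline and
  reporting the resulting ICER swing per parameter, sorted by width.  The
  overhead proportion, a structural constant, is included via its own
  deterministic range.
* :func:`run_psa` — Monte Carlo simulation: every uncertain parameter is
  drawn independently from its calibrated distribution (a single RNG
  stream, fixed declaration order, hence bit-reproducible under a seed)
  and the incremental cost and effects recomputed per iteration.
  Uncertainty internal to the effects-conversion surrogate is not sampled.
* :func:`ceac` — probability of cost-effectiveness as a function of the
  threshold, by the net-monetary-benefit rule ``lambda*dE - dC > 0``;
  iterations with non-positive incremental effects are retained and simply
  counted by the same rule.
* :func:`ce_plane` — per-iteration (dE, dC) scatter plus the threshold
  rays bounding the cost-effectiveness region.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ModelError
from .model import DecisionModel

__all__ = [
    "TornadoEntry",
    "tornado",
    "run_psa",
    "ceac",
    "ceac_crossing",
    "ce_plane",
    "default_threshold_grid",
]

#: PSA output column per effect measure
_MEASURE_COLUMNS = {
    "cyps": "delta_cyps",
    "pregnancies_averted": "delta_pregnancies",
    "abortions_averted": "delta_abortions",
    "dalys_averted": "delta_dalys",
}


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity of the ICER to a single parameter."""

    name: str
    icer_at_lo: float
    icer_at_hi: float

    @property
    def width(self) -> float:
        return abs(self.icer_at_hi - self.icer_at_lo)

    @property
    def low(self) -> float:
        return min(self.icer_at_lo, self.icer_at_hi)

    @property
    def high(self) -> float:
        return max(self.icer_at_lo, self.icer_at_hi)


def tornado(
    model: DecisionModel,
    measure: str = "dalys_averted",
    perspective: str = "societal",
) -> list[TornadoEntry]:
    """One-way DSA over every parameter range plus the overhead proportion."""
    base = model.params.base_values()
    entries = []
    for name, spec in model.params.specs.items():
        icers = []
        for bound in (spec.lo, spec.hi):
            values = dict(base)
            values[name] = bound
            icers.append(model.evaluate(values, perspective).icers[measure])
        if any(x is None for x in icers):
            raise ModelError(f"ICER undefined at a bound of {name}")
        entries.append(TornadoEntry(name, icers[0], icers[1]))
    o_lo, o_hi = model.params.overhead_range
    entries.append(
        TornadoEntry(
            "structural.overhead_proportion",
            model.evaluate(base, perspective, overhead=o_lo).icers[measure],
            model.evaluate(base, perspective, overhead=o_hi).icers[measure],
        )
    )
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.name for e in entries],
            "icer_at_lo": [e.icer_at_lo for e in entries],
            "icer_at_hi": [e.icer_at_hi for e in entries],
            "width": [e.width for e in entries],
        }
    )


def run_psa(
    model: DecisionModel,
    iterations: int | None = None,
    seed: int | None = None,
    perspective: str = "societal",
) -> pd.DataFrame:
    """Monte Carlo PSA; one row per iteration.

    Columns: ``iteration``, ``delta_cost``, one ``delta_*`` per effect
    measure, and ``digest`` (an 8-byte hash of the sampled parameter
    vector, for reproducibility audits).
    """
    iterations = iterations if iterations is not None else model.params.psa_iterations
    if iterations <= 0:
        raise ModelError("iterations must be positive")
    seed = seed if seed is not None else model.params.seed
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(iterations):
        values = model.params.sample_values(rng)
        res = model.evaluate(values, perspective)
        vec = np.array(list(values.values()))
        digest = hashlib.blake2b(vec.tobytes(), digest_size=8).hexdigest()
        rows.append(
            {
                "iteration": it,
                "delta_cost": res.delta_cost,
                **{
                    col: res.delta_effects[m]
                    for m, col in _MEASURE_COLUMNS.items()
                },
                "digest": digest,
            }
        )
    return pd.DataFrame(rows)


def default_threshold_grid(upper: float = 300.0, step: float = 1.0) -> np.ndarray:
    """Threshold grid for CEACs: 0 to ``upper`` US$ per effect unit."""
    return np.arange(0.0, upper + step / 2, step)


def _effect_column(measure: str) -> str:
    try:
        return _MEASURE_COLUMNS[measure]
    except KeyError:
        raise ModelError(f"unknown effect measure {measure!r}") from None


def ceac(
    results: pd.DataFrame,
    thresholds: np.ndarray | None = None,
    measure: str = "dalys_averted",
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve from PSA output."""
    if len(results) == 0:
        raise ModelError("empty PSA results")
    thresholds = (
        np.asarray(thresholds, dtype=float)
        if thresholds is not None
        else default_threshold_grid()
    )
    de = results[_effect_column(measure)].to_numpy()
    dc = results["delta_cost"].to_numpy()
    nmb = thresholds[:, None] * de[None, :] - dc[None, :]
    return pd.DataFrame(
        {"threshold": thresholds, "probability": (nmb > 0).mean(axis=1)}
    )


def ceac_crossing(
    curve: pd.DataFrame, probability: float = 0.5
) -> float:
    """Smallest gridded threshold at which the CEAC reaches ``probability``."""
    hit = curve.loc[curve["probability"] >= probability, "threshold"]
    if hit.empty:
        raise ModelError(
            f"CEAC never reaches probability {probability} on the given grid"
        )
    return float(hit.iloc[0])


def ce_plane(
    results: pd.DataFrame,
    measure: str = "dalys_averted",
    thresholds: tuple[float, float] = (58.0, 176.0),
) -> dict:
    """Cost-effectiveness plane: scatter, threshold rays and summary shares.

    Returns a dict with ``points`` (DataFrame of dE, dC), ``rays`` (slopes
    of the lower/upper threshold lines through the origin),
    ``fraction_below_upper`` (NMB > 0 at the upper threshold) and
    ``fraction_within`` (between the two rays).
    """
    if len(results) == 0:
        raise ModelError("empty PSA results")
    lo, hi = thresholds
    de = results[_effect_column(measure)].to_numpy()
    dc = results["delta_cost"].to_numpy()
    below_upper = hi * de - dc > 0
    above_lower = lo * de - dc <= 0
    return {
        "points": pd.DataFrame({"delta_effect": de, "delta_cost": dc}),
        "rays": {"lower": lo, "upper": hi},
        "fraction_below_upper": float(below_upper.mean()),
        "fraction_within": float((below_upper & above_lower).mean()),
    }
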