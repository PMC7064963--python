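"""Synthetic two-arm trial cohort with monthly contraceptive-use records.

The generator emulates the individual-level structure behind the service
provision model: 500 participants per arm enrolled at a postabortion
visit, 66% retained through 12 months of follow-up, each retained
participant possibly initiating one contraceptive method in month 1.
Short-acting methods (pill, injectable) run for a dispersion-controlled
duration ``1 + Binomial(11, q)`` months; long-acting methods (implant,
IUD), once entered, persist to the end of follow-up unless a switching
rule generates an explicit discontinuation.  Repeat abortions occur as a
single annual Bernoulli event with a uniform month.

Aggregation converts person-month states to annual services per 1000
retained participants: one pill cycle per month of use, one injectable
dose per started 3-month interval of continuous use, one insertion per
implant/IUD episode start, one event per repeat abortion.

Method initiation is allocated proportionally (largest-remainder counts
over a shuffled roster) rather than by iid per-participant draws, so the
aggregate method mix tracks the configured shares with finite-sample
noise coming only from retention and durations.  ``allocation="multinomial"``
restores iid draws.  :func:`calibrate_cohort_config` solves the duration
parameters so the expected aggregate rates hit given targets exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .costs import ServiceMix
from .exceptions import ModelError, SchemaError

__all__ = [
    "METHODS",
    "STATES",
    "CohortConfig",
    "ParticipantRecord",
    "Cohort",
    "generate_cohort",
    "aggregate_services",
    "calibrate_cohort_config",
]

METHODS = ("ocp", "injectable", "implant", "iud")
STATES = ("none",) + METHODS  # state codes 0..4
_LONG_ACTING = {"implant", "iud"}
_CODE = {name: i for i, name in enumerate(STATES)}
ARMS = ("intervention", "control")
N_MONTHS = 12


@dataclass(frozen=True)
class CohortConfig:
    """Behavioral parameters of the synthetic cohort.

    ``initiation[arm][method]`` are month-1 initiation shares (summing to
    at most 1 per arm); ``duration_q[arm][method]`` the binomial duration
    parameter for short-acting methods; ``switching[method][method']`` the
    probability of starting ``method'`` when an episode of ``method`` ends
    before month 12 (row sums at most 1, remainder discontinues).
    """

    n_per_arm: int = 500
    retention: float = 0.66
    initiation: dict = field(default_factory=dict)
    duration_q: dict = field(default_factory=dict)
    switching: dict = field(default_factory=dict)
    repeat_abortion_prob: dict = field(default_factory=dict)
    allocation: str = "proportional"
    seed: int = 2020

    def __post_init__(self) -> None:
        if self.n_per_arm < 0:
            raise SchemaError("n_per_arm must be >= 0")
        if not 0.0 <= self.retention <= 1.0:
            raise SchemaError("retention must lie in [0, 1]")
        if self.allocation not in ("proportional", "multinomial"):
            raise SchemaError(f"unknown allocation {self.allocation!r}")
        for arm, probs in self.initiation.items():
            bad = [m for m, p in probs.items() if not 0.0 <= p <= 1.0]
            if bad:
                raise SchemaError(f"{arm}: initiation probabilities outside [0,1]: {bad}")
            if sum(probs.values()) > 1.0 + 1e-9:
                raise SchemaError(f"{arm}: initiation shares sum to more than 1")
        for m, row in self.switching.items():
            if sum(row.values()) > 1.0 + 1e-9:
                raise SchemaError(f"switching row {m!r} sums to more than 1")
        for arm, p in self.repeat_abortion_prob.items():
            if not 0.0 <= p <= 1.0:
                raise SchemaError(f"{arm}: repeat-abortion probability outside [0,1]")


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: arm, retention flag, 12 monthly method states and
    an optional repeat-abortion month (1-based)."""

    id: str
    arm: str
    retained: bool
    states: tuple[str, ...]
    repeat_abortion_month: int | None = None


class Cohort:
    """Columnar container for generated participants."""

    def __init__(
        self,
        arm: np.ndarray,
        retained: np.ndarray,
        states: np.ndarray,
        abortion_month: np.ndarray,
    ) -> None:
        self.arm = np.asarray(arm)
        self.retained = np.asarray(retained, dtype=bool)
        self.states = np.asarray(states, dtype=np.int8)
        self.abortion_month = np.asarray(abortion_month, dtype=np.int16)
        n = len(self.arm)
        if not (len(self.retained) == self.states.shape[0] == len(self.abortion_month) == n):
            raise ModelError("cohort arrays have inconsistent lengths")
        if n and self.states.shape[1] != N_MONTHS:
            raise ModelError(f"states must have {N_MONTHS} monthly columns")

    def __len__(self) -> int:
        return len(self.arm)

    @property
    def records(self) -> list[ParticipantRecord]:
        out = []
        for i in range(len(self)):
            month = int(self.abortion_month[i])
            out.append(
                ParticipantRecord(
                    id=f"P{i:04d}",
                    arm=str(self.arm[i]),
                    retained=bool(self.retained[i]),
                    states=tuple(STATES[s] for s in self.states[i]),
                    repeat_abortion_month=month if month > 0 else None,
                )
            )
        return out

    def subset(self, index: np.ndarray) -> "Cohort":
        return Cohort(
            self.arm[index], self.retained[index], self.states[index], self.abortion_month[index]
        )

    def to_frame(self) -> pd.DataFrame:
        """Long person-month table: id, arm, retained, month, state, event."""
        n = len(self)
        months = np.tile(np.arange(1, N_MONTHS + 1), n)
        ids = np.repeat([f"P{i:04d}" for i in range(n)], N_MONTHS)
        return pd.DataFrame(
            {
                "id": ids,
                "arm": np.repeat(self.arm, N_MONTHS),
                "retained": np.repeat(self.retained, N_MONTHS),
                "month": months,
                "state": [STATES[s] for s in self.states.ravel()],
                "event": np.where(
                    np.repeat(self.abortion_month, N_MONTHS) == months,
                    "repeat_abortion",
                    "",
                ),
            }
        )

    def to_csv(self, path: str | Path | io.IOBase) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Cohort":
        frame = frame.sort_values(["id", "month"])
        ids = frame["id"].unique()
        n = len(ids)
        states = (
            frame["state"].map(_CODE).to_numpy().reshape(n, N_MONTHS).astype(np.int8)
        )
        per = frame.groupby("id", sort=True)
        arm = per["arm"].first().to_numpy()
        retained = per["retained"].first().to_numpy(dtype=bool)
        ab = frame.loc[frame["event"] == "repeat_abortion", ["id", "month"]]
        month_map = dict(zip(ab["id"], ab["month"]))
        abortion_month = np.array([month_map.get(i, 0) for i in ids], dtype=np.int16)
        return cls(arm, retained, states, abortion_month)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))

    @classmethod
    def concat(cls, cohorts: Iterable["Cohort"]) -> "Cohort":
        cohorts = list(cohorts)
        return cls(
            np.concatenate([c.arm for c in cohorts]),
            np.concatenate([c.retained for c in cohorts]),
            np.vstack([c.states for c in cohorts]) if cohorts else np.empty((0, N_MONTHS)),
            np.concatenate([c.abortion_month for c in cohorts]),
        )


# ---------------------------------------------------------------------------
# generation


def _allocate(rng, indices: np.ndarray, probs: dict[str, float], mode: str) -> dict[str, np.ndarray]:
    """Assign method initiators among retained participants."""
    r = len(indices)
    order = rng.permutation(indices)
    if mode == "multinomial":
        names = list(probs) + ["none"]
        p = np.array([probs[m] for m in probs] + [1.0 - sum(probs.values())])
        p = np.clip(p, 0.0, None)
        draws = rng.choice(len(names), size=r, p=p / p.sum())
        return {m: order[draws == i] for i, m in enumerate(names) if m != "none"}
    # largest-remainder proportional allocation
    exact = {m: p * r for m, p in probs.items()}
    counts = {m: int(np.floor(x)) for m, x in exact.items()}
    short = int(round(sum(exact.values()))) - sum(counts.values())
    if short > 0:
        remainders = sorted(exact, key=lambda m: exact[m] - counts[m], reverse=True)
        for m in remainders[:short]:
            counts[m] += 1
    out, start = {}, 0
    for m, k in counts.items():
        out[m] = order[start : start + k]
        start += k
    return out


def _durations(rng, method: str, q: float, n: int) -> np.ndarray:
    if method in _LONG_ACTING:
        return np.full(n, N_MONTHS, dtype=np.int64)
    return 1 + rng.binomial(N_MONTHS - 1, q, size=n)


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate both arms; reproducible for a given config and seed."""
    config = config or calibrate_cohort_config()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    parts = []
    for arm in ARMS:
        n = config.n_per_arm
        states = np.zeros((n, N_MONTHS), dtype=np.int8)
        retained = rng.random(n) < config.retention
        abortion_month = np.zeros(n, dtype=np.int16)
        if n and retained.any():
            ridx = np.flatnonzero(retained)
            probs = config.initiation.get(arm, {})
            qs = config.duration_q.get(arm, {})
            assigned = _allocate(rng, ridx, probs, config.allocation)
            # episode loop: (participant index, method, start month)
            active: list[tuple[np.ndarray, str, np.ndarray]] = [
                (idx, m, np.zeros(len(idx), dtype=np.int64))
                for m, idx in assigned.items()
                if len(idx)
            ]
            guard = 0
            while active and guard < 4 * N_MONTHS:
                guard += 1
                idx, m, start = active.pop()
                dur = _durations(rng, m, qs.get(m, 0.0), len(idx))
                end = np.minimum(start + dur, N_MONTHS)
                for i, s, e in zip(idx, start, end):
                    states[i, s:e] = _CODE[m]
                row = config.switching.get(m, {})
                ends_early = end < N_MONTHS
                if row and ends_early.any():
                    sw_idx = idx[ends_early]
                    sw_start = end[ends_early]
                    names = list(row)
                    p = np.array([row[x] for x in names] + [1.0 - sum(row.values())])
                    draw = rng.choice(len(names) + 1, size=len(sw_idx), p=np.clip(p, 0, None) / np.clip(p, 0, None).sum())
                    for j, nxt in enumerate(names):
                        sel = draw == j
                        if sel.any():
                            active.append((sw_idx[sel], nxt, sw_start[sel]))
            p_ab = config.repeat_abortion_prob.get(arm, 0.0)
            has_ab = ridx[rng.random(len(ridx)) < p_ab]
            abortion_month[has_ab] = rng.integers(1, N_MONTHS + 1, size=len(has_ab))
        parts.append(Cohort(np.full(n, arm, dtype=object), retained, states, abortion_month))
    return Cohort.concat(parts)


# ---------------------------------------------------------------------------
# aggregation


def _run_starts(states: np.ndarray, code: int) -> int:
    """Number of maximal runs of ``code`` across rows."""
    is_m = states == code
    starts = is_m.copy()
    starts[:, 1:] &= ~is_m[:, :-1]
    return int(starts.sum())


def _injectable_doses(states: np.ndarray) -> int:
    """One dose per started 3-month block of continuous injectable use."""
    run = np.zeros(states.shape[0], dtype=np.int64)
    doses = 0
    for j in range(states.shape[1]):
        on = states[:, j] == _CODE["injectable"]
        run = np.where(on, run + 1, 0)
        doses += int(np.sum(on & ((run - 1) % 3 == 0)))
    return doses


def aggregate_services(cohort: Cohort) -> dict[str, ServiceMix]:
    """Annual services per 1000 retained participants, per arm.

    Aggregation is additive: pooling two cohorts and aggregating equals
    the retained-count-weighted combination of their aggregates.
    """
    if len(cohort) == 0:
        raise ModelError("cannot aggregate an empty cohort")
    out = {}
    for arm in np.unique(cohort.arm):
        sel = (cohort.arm == arm) & cohort.retained
        r = int(sel.sum())
        if r == 0:
            raise ModelError(f"arm {arm!r} has no retained participants")
        states = cohort.states[sel]
        scale = 1000.0 / r
        out[str(arm)] = ServiceMix(
            ocp_cycles=float((states == _CODE["ocp"]).sum()) * scale,
            injectable_doses=_injectable_doses(states) * scale,
            implant_insertions=_run_starts(states, _CODE["implant"]) * scale,
            iud_insertions=_run_starts(states, _CODE["iud"]) * scale,
            repeat_abortions=float((cohort.abortion_month[sel] > 0).sum()) * scale,
        )
    return out


# ---------------------------------------------------------------------------
# calibration to target service rates


#: default month-1 initiation shares; chosen as a plausible postabortion
#: method mix, with the duration parameters absorbing the rate targets
_DEFAULT_SHARES = {
    "intervention": {"ocp": 0.45, "injectable": 0.22, "implant": None, "iud": None},
    "control": {"ocp": 0.62, "injectable": 0.18, "implant": None, "iud": None},
}

_DEFAULT_TARGETS = {
    "intervention": {"ocp": 2172.0, "injectable": 558.0, "implant": 172.0, "iud": 112.0, "repeat_abortion": 47.0},
    "control": {"ocp": 3308.0, "injectable": 325.0, "implant": 75.0, "iud": 63.0, "repeat_abortion": 69.0},
}


def _expected_doses(q: float) -> float:
    """E[ceil((1 + Binomial(11, q)) / 3)]."""
    k = np.arange(N_MONTHS)
    pmf = stats.binom.pmf(k, N_MONTHS - 1, q)
    return float(np.sum(pmf * np.ceil((1 + k) / 3.0)))


def calibrate_cohort_config(
    targets: dict[str, dict[str, float]] | None = None,
    shares: dict[str, dict[str, float]] | None = None,
    n_per_arm: int = 500,
    retention: float = 0.66,
    seed: int = 2020,
) -> CohortConfig:
    """Solve initiation shares and duration parameters for target rates.

    ``targets[arm][service]`` are annual services per 1000 retained
    participants.  Implant/IUD initiation shares equal the insertion rate
    per participant; pill and injectable shares are fixed (defaults above)
    and their duration parameters solved so the expected cycle/dose counts
    match the targets exactly.
    """
    targets = targets or _DEFAULT_TARGETS
    shares = shares or _DEFAULT_SHARES
    initiation, duration_q, abortion = {}, {}, {}
    for arm, t in targets.items():
        s_ocp = shares[arm]["ocp"]
        s_inj = shares[arm]["injectable"]
        mean_cycles = t["ocp"] / 1000.0 / s_ocp
        q_ocp = (mean_cycles - 1.0) / (N_MONTHS - 1)
        if not 0.0 <= q_ocp <= 1.0:
            raise ModelError(f"{arm}: pill target {t['ocp']} unreachable at share {s_ocp}")
        mean_doses = t["injectable"] / 1000.0 / s_inj
        if not 1.0 <= mean_doses <= 4.0:
            raise ModelError(
                f"{arm}: injectable target {t['injectable']} unreachable at share {s_inj}"
            )
        lo, hi = 0.0, 1.0
        for _ in range(80):
            mid = (lo + hi) / 2.0
            if _expected_doses(mid) < mean_doses:
                lo = mid
            else:
                hi = mid
        q_inj = (lo + hi) / 2.0
        initiation[arm] = {
            "ocp": s_ocp,
            "injectable": s_inj,
            "implant": t["implant"] / 1000.0,
            "iud": t["iud"] / 1000.0,
        }
        if sum(initiation[arm].values()) > 1.0:
            raise ModelError(f"{arm}: initiation shares exceed 1")
        duration_q[arm] = {"ocp": q_ocp, "injectable": q_inj}
        abortion[arm] = t["repeat_abortion"] / 1000.0
    return CohortConfig(
        n_per_arm=n_per_arm,
        retention=retention,
        initiation=initiation,
        duration_q=duration_q,
        repeat_abortion_prob=abortion,
        seed=seed,
    )
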