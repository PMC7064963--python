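"""Parameter registry: typed parameter records with uncertainty specs.

The packaged default file transcribes the trial's service-provision rates
(annual services per 1000 clients per arm) and unit costs, each with a
deterministic range read as the 95% interval of its probability family.
A :class:`ParameterSet` keeps the records in declaration order; sampling
always walks that order from a single RNG stream, which makes the Monte
Carlo analysis bit-reproducible for a given seed.
"""

from __future__ import annotations

import hashlib
from collections import OrderedDict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .distributions import (
    CalibratedDistribution,
    DistributionSpec,
    calibrate_distribution,
)
from .exceptions import SchemaError

__all__ = ["ParameterSet", "load_parameters", "default_parameter_path", "EXPECTED_PARAMETERS"]

_ARMS = ("intervention", "control")
_SERVICES = ("ocp", "injectable", "implant", "iud", "repeat_abortion")

#: every row the packaged schema requires, exactly once
EXPECTED_PARAMETERS: tuple[str, ...] = tuple(
    [f"svc.{arm}.{svc}" for arm in _ARMS for svc in _SERVICES]
    + [
        "cost.delivery.voice_airtime",
        "cost.delivery.call_airtime",
        "cost.delivery.computer",
        "cost.delivery.phone",
        "cost.commodity.ocp_cycle",
        "cost.commodity.iud_device",
        "cost.commodity.medical_abortion",
        "cost.commodity.surgical_abortion",
        "cost.commodity.injectable_dose",
        "cost.commodity.implant_device",
        "cost.commodity.larc_removal",
        "cost.personnel.midwife_hourly",
        "cost.personnel.counsellor_hourly",
        "fee.iud_insertion",
        "fee.implant_insertion",
        "fee.injectable_clinic",
        "fee.injectable_pharmacy",
        "fee.ocp_clinic",
        "fee.ocp_pharmacy",
        "fee.iud_removal",
        "fee.implant_removal",
        "fee.abortion_surgical",
        "fee.abortion_medical",
        "user.hotline_airtime_per_min",
        "user.motorbike_per_km",
        "user.roundtrip_km",
        "user.gni_per_capita",
        "user.daily_income",
        "user.abortion_household_indirect",
    ]
)


def default_parameter_path() -> Path:
    """Path of the packaged default parameter file."""
    return Path(resources.files("fpcea.data") / "parameters.yaml")


@dataclass
class ParameterSet:
    """All model parameters plus structural constants.

    Attributes
    ----------
    specs
        Ordered mapping name -> :class:`DistributionSpec`; the order is the
        sampling order.
    seed, psa_iterations, threshold_range
        Run configuration defaults.
    overhead_proportion, overhead_range
        Proportion added to personnel costs for overheads, with its
        deterministic range (used by the tornado, never sampled).
    distance_reduction_other_clinic
        Fraction of the home-clinic distance saved when a different clinic
        is visited.
    """

    specs: "OrderedDict[str, DistributionSpec]"
    seed: int = 2020
    psa_iterations: int = 1000
    threshold_range: tuple[float, float] = (58.0, 176.0)
    overhead_proportion: float = 0.20
    overhead_range: tuple[float, float] = (0.10, 0.30)
    distance_reduction_other_clinic: float = 1.0 / 3.0
    _calibrated: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = [n for n in EXPECTED_PARAMETERS if n not in self.specs]
        if missing:
            raise SchemaError(f"missing parameter rows: {', '.join(missing)}")
        extra = [n for n in self.specs if n not in EXPECTED_PARAMETERS]
        if extra:
            raise SchemaError(f"unknown parameter rows: {', '.join(extra)}")
        for name, spec in self.specs.items():
            if (name.startswith(("cost.", "fee.", "user."))) and spec.lo < 0:
                raise SchemaError(f"{name}: monetary value must be non-negative")
            if name.startswith("svc.") and spec.lo < 0:
                raise SchemaError(f"{name}: service count must be non-negative")
        if not 0.0 <= self.overhead_proportion <= 1.0:
            raise SchemaError("overhead_proportion must lie in [0, 1]")
        if not self.threshold_range[0] < self.threshold_range[1]:
            raise SchemaError("threshold_range must satisfy lo < hi")
        if self.psa_iterations < 1:
            raise SchemaError("psa_iterations must be >= 1")

    # -- access helpers ---------------------------------------------------

    def __getitem__(self, name: str) -> DistributionSpec:
        return self.specs[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.specs)

    def base_values(self) -> dict[str, float]:
        """Deterministic point estimates, in declaration order."""
        return {name: spec.base for name, spec in self.specs.items()}

    def calibrated(self, name: str) -> CalibratedDistribution:
        """Calibrated distribution for one parameter (cached)."""
        if name not in self._calibrated:
            self._calibrated[name] = calibrate_distribution(self.specs[name])
        return self._calibrated[name]

    def sample_values(self, rng: np.random.Generator) -> dict[str, float]:
        """One joint draw: every parameter sampled independently, in order."""
        return {
            name: float(self.calibrated(name).sample(rng))
            for name in self.specs
        }

    def service_rates(self, arm: str, values: dict[str, float] | None = None) -> dict[str, float]:
        """Annual service counts per 1000 clients for one arm."""
        if arm not in _ARMS:
            raise SchemaError(f"unknown arm {arm!r}")
        values = values if values is not None else self.base_values()
        return {svc: values[f"svc.{arm}.{svc}"] for svc in _SERVICES}

    def digest(self) -> str:
        """Short content hash of all parameter rows and structural constants."""
        h = hashlib.blake2b(digest_size=8)
        for name, spec in self.specs.items():
            h.update(
                f"{name}:{spec.base}:{spec.lo}:{spec.hi}:{spec.family}:{spec.scale};".encode()
            )
        h.update(
            f"{self.overhead_proportion}:{self.threshold_range}:"
            f"{self.distance_reduction_other_clinic}".encode()
        )
        return h.hexdigest()

    # -- (de)serialization -------------------------------------------------

    def to_mapping(self) -> dict:
        rows = []
        for name, spec in self.specs.items():
            row = {
                "name": name,
                "base": spec.base,
                "lo": spec.lo,
                "hi": spec.hi,
                "family": spec.family,
                "units": spec.units,
            }
            if spec.scale != 1.0:
                row["scale"] = spec.scale
            rows.append(row)
        return {
            "meta": {
                "seed": self.seed,
                "psa_iterations": self.psa_iterations,
                "threshold_range": list(self.threshold_range),
                "overhead_proportion": self.overhead_proportion,
                "overhead_range": list(self.overhead_range),
                "distance_reduction_other_clinic": self.distance_reduction_other_clinic,
            },
            "parameters": rows,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_mapping(), sort_keys=False))

    @classmethod
    def from_mapping(cls, doc: dict) -> "ParameterSet":
        if not isinstance(doc, dict) or "parameters" not in doc:
            raise SchemaError("parameter file must contain a 'parameters' list")
        meta = doc.get("meta", {})
        specs: "OrderedDict[str, DistributionSpec]" = OrderedDict()
        for row in doc["parameters"]:
            try:
                name = row["name"]
            except (TypeError, KeyError) as exc:
                raise SchemaError(f"parameter row without a name: {row!r}") from exc
            if name in specs:
                raise SchemaError(f"{name}: duplicated parameter row")
            try:
                specs[name] = DistributionSpec(
                    name=name,
                    base=float(row["base"]),
                    lo=float(row["lo"]),
                    hi=float(row["hi"]),
                    family=row["family"],
                    units=row.get("units", ""),
                    scale=float(row.get("scale", 1.0)),
                )
            except KeyError as exc:
                raise SchemaError(f"{name}: missing field {exc}") from exc
        return cls(
            specs=specs,
            seed=int(meta.get("seed", 2020)),
            psa_iterations=int(meta.get("psa_iterations", 1000)),
            threshold_range=tuple(meta.get("threshold_range", (58.0, 176.0))),
            overhead_proportion=float(meta.get("overhead_proportion", 0.20)),
            overhead_range=tuple(meta.get("overhead_range", (0.10, 0.30))),
            distance_reduction_other_clinic=float(
                meta.get("distance_reduction_other_clinic", 1.0 / 3.0)
            ),
        )


def load_parameters(path: str | Path | None = None) -> ParameterSet:
    """Load and validate a parameter file (packaged defaults if ``path`` is None)."""
    p = Path(path) if path is not None else default_parameter_path()
    if not p.exists():
        raise SchemaError(f"parameter file not found: {p}")
    try:
        doc = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise SchemaError(f"could not parse {p}: {exc}") from exc
    return ParameterSet.from_mapping(doc)
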