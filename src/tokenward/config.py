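"""Domain vocabulary and scenario configuration for the bed-allocation market.

The simulated hospital is a set of inpatient wards, each staffed for a single
illness (its *specialty*).  Admitting a patient raises the ward's nursing
*workload* by an amount that depends on the patient's severity and on whether
the patient's illness matches the ward's specialty; a mismatched admission
carries a surcharge because the ward's staff are not trained for that illness.
Every quantity here is dimensionless: workload is measured in workload points,
prices in tokens.

The shipped defaults reproduce the reference scenario: 3 wards of 40 beds,
3 illnesses x 3 severities, matched increments 1.0 / 1.25 / 1.5 and
mismatched increments 1.5 / 1.8 / 2.25 (mild / moderate / severe).  Note the
printed mismatched-moderate value is 1.8, not the 1.875 that an exact +50%
surcharge on 1.25 would give; 1.8 is kept as the default and an exact-surcharge
variant is bundled alongside it (``data/surcharge_exact.yaml``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = [
    "ConfigurationError",
    "WorkloadWeightTable",
    "WardSpec",
    "PolicySpec",
    "ScenarioConfig",
    "Patient",
    "PriceList",
    "workload_increment",
    "validate_config",
    "default_scenario",
    "DEFAULT_ILLNESSES",
    "DEFAULT_SEVERITIES",
    "DEFAULT_MATCHED_WEIGHTS",
    "DEFAULT_MISMATCHED_WEIGHTS",
]

DEFAULT_ILLNESSES = ("gastric ulcer", "pneumonia", "heart failure")
DEFAULT_SEVERITIES = ("mild", "moderate", "severe")
DEFAULT_MATCHED_WEIGHTS = {"mild": 1.0, "moderate": 1.25, "severe": 1.5}
DEFAULT_MISMATCHED_WEIGHTS = {"mild": 1.5, "moderate": 1.8, "severe": 2.25}


class ConfigurationError(ValueError):
    """A scenario configuration violated one or more invariants.

    The message aggregates every violation found, not just the first.
    """


class WorkloadWeightTable(BaseModel):
    """Per-severity workload increments, one row per specialty-match status.

    ``matched[s]`` is the increment when the patient's illness equals the
    ward's specialty; ``mismatched[s]`` applies otherwise and must dominate
    the matched row (the mismatch surcharge).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    matched: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_MATCHED_WEIGHTS))
    mismatched: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_MISMATCHED_WEIGHTS))


class WardSpec(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    id: str
    specialty: str
    capacity: int = 40


class PolicySpec(BaseModel):
    """Declarative pricing-policy choice for one ward.

    ``kind`` selects the policy family; ``params`` are passed to its
    constructor (see :mod:`tokenward.agents` for the families and their
    parameters).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    kind: Literal["constant", "workload_linear", "random", "replay", "interactive"] = "constant"
    params: dict[str, Any] = Field(default_factory=dict)


def _default_wards() -> list[WardSpec]:
    return [
        WardSpec(id="A", specialty="gastric ulcer"),
        WardSpec(id="B", specialty="pneumonia"),
        WardSpec(id="C", specialty="heart failure"),
    ]


class ScenarioConfig(BaseModel):
    """Complete parameterization of one simulated session.

    Defaults reproduce the reference scenario; every field can be overridden
    from a YAML/JSON file (see :func:`tokenward.io.load_scenario`).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    illnesses: tuple[str, ...] = DEFAULT_ILLNESSES
    severities: tuple[str, ...] = DEFAULT_SEVERITIES
    weights: WorkloadWeightTable = Field(default_factory=WorkloadWeightTable)
    wards: tuple[WardSpec, ...] = Field(default_factory=lambda: tuple(_default_wards()))
    arrivals_per_day: int = 7
    mean_los_days: float = 14.0
    n_days: int = 10
    multiplier_range: tuple[float, float] = (1.0, 2.0)
    #: nested illness -> severity -> probability; None means uniform over all
    #: (illness, severity) combinations.
    arrival_distribution: Optional[dict[str, dict[str, float]]] = None
    policies: dict[str, PolicySpec] = Field(default_factory=dict)
    seed: int = 0
    #: when to run the discharge draw within a day: after allocation (default)
    #: or before prices are set.
    discharge_timing: Literal["day_end", "day_start"] = "day_end"
    #: if True, each ward's view also carries the other wards' posted prices
    #: (the strict default hides them: only admitted-patient counts leak).
    reveal_other_prices: bool = False

    # -- derived helpers ---------------------------------------------------

    def patterns(self) -> list[tuple[str, str]]:
        """All (illness, severity) combinations, in catalog order."""
        return [(i, s) for i in self.illnesses for s in self.severities]

    def specialty_of(self, ward_id: str) -> str:
        for w in self.wards:
            if w.id == ward_id:
                return w.specialty
        raise ConfigurationError(f"unknown ward id: {ward_id!r}")

    def arrival_probabilities(self) -> list[tuple[tuple[str, str], float]]:
        """Arrival distribution as an ordered list of ((illness, severity), p)."""
        pats = self.patterns()
        if self.arrival_distribution is None:
            p = 1.0 / len(pats)
            return [(pat, p) for pat in pats]
        return [
            (pat, self.arrival_distribution.get(pat[0], {}).get(pat[1], 0.0))
            for pat in pats
        ]

    def policy_spec(self, ward_id: str) -> PolicySpec:
        return self.policies.get(ward_id, PolicySpec())

    def workload_increment(self, illness: str, severity: str, ward_specialty: str) -> float:
        if illness not in self.illnesses:
            raise ConfigurationError(f"unknown illness: {illness!r}")
        if ward_specialty not in self.illnesses:
            raise ConfigurationError(f"unknown specialty: {ward_specialty!r}")
        return workload_increment(illness, severity, ward_specialty, self.weights)


@dataclass
class Patient:
    """One admitted or waiting patient.

    ``assigned_ward`` and ``admit_day`` are set together on admission;
    ``discharge_day`` strictly exceeds ``admit_day`` (no zero-length stays).
    """

    id: str
    illness: str
    severity: str
    admit_day: Optional[int] = None
    assigned_ward: Optional[str] = None
    discharge_day: Optional[int] = None


@dataclass(frozen=True)
class PriceList:
    """One ward's posted prices for a day: (illness, severity) -> tokens."""

    prices: dict[tuple[str, str], float]
    effective_day: int = 0

    def price(self, illness: str, severity: str) -> float:
        try:
            return self.prices[(illness, severity)]
        except KeyError:
            raise ConfigurationError(
                f"price list has no entry for ({illness!r}, {severity!r})"
            ) from None

    def validate_complete(self, config: ScenarioConfig) -> None:
        missing = [p for p in config.patterns() if p not in self.prices]
        if missing:
            raise ConfigurationError(f"price list missing patterns: {missing}")
        bad = {k: v for k, v in self.prices.items() if not math.isfinite(v) or v < 0}
        if bad:
            raise ConfigurationError(f"non-finite or negative prices: {bad}")


def workload_increment(
    illness: str,
    severity: str,
    ward_specialty: str,
    weights: WorkloadWeightTable,
) -> float:
    """Workload points added when a ward admits one patient.

    Pure function: the matched row applies when the patient's illness equals
    the ward's specialty, the mismatched row otherwise.
    """
    row = weights.matched if illness == ward_specialty else weights.mismatched
    try:
        return row[severity]
    except KeyError:
        raise ConfigurationError(f"unknown severity: {severity!r}") from None


def _invariant_errors(cfg: ScenarioConfig) -> list[str]:
    errs: list[str] = []

    if not cfg.illnesses:
        errs.append("illnesses: catalog must be non-empty")
    if len(set(cfg.illnesses)) != len(cfg.illnesses):
        errs.append("illnesses: identifiers must be unique")
    if not cfg.severities:
        errs.append("severities: scale must be non-empty")
    if len(set(cfg.severities)) != len(cfg.severities):
        errs.append("severities: identifiers must be unique")

    for row_name in ("matched", "mismatched"):
        row = getattr(cfg.weights, row_name)
        missing = [s for s in cfg.severities if s not in row]
        if missing:
            errs.append(f"weights.{row_name}: missing severities {missing}")
            continue
        if any(row[s] <= 0 for s in cfg.severities):
            errs.append(f"weights.{row_name}: all weights must be > 0")
        ordered = [row[s] for s in cfg.severities]
        if any(a > b for a, b in zip(ordered, ordered[1:])):
            errs.append(f"weights.{row_name}: weights must be non-decreasing in severity")
    if all(s in cfg.weights.matched and s in cfg.weights.mismatched for s in cfg.severities):
        if any(cfg.weights.mismatched[s] < cfg.weights.matched[s] for s in cfg.severities):
            errs.append("weights: mismatched weight must be >= matched weight per severity")

    if not cfg.wards:
        errs.append("wards: at least one ward is required")
    ids = [w.id for w in cfg.wards]
    if len(set(ids)) != len(ids):
        errs.append("wards: ids must be unique")
    for w in cfg.wards:
        if w.capacity <= 0:
            errs.append(f"wards[{w.id}].capacity: must be a positive integer")
        if w.specialty not in cfg.illnesses:
            errs.append(f"wards[{w.id}].specialty: {w.specialty!r} not in illness catalog")

    if cfg.arrivals_per_day < 0:
        errs.append("arrivals_per_day: must be >= 0")
    if cfg.mean_los_days < 1:
        errs.append("mean_los_days: must be >= 1 (daily discharge probability <= 1)")
    if cfg.n_days < 0:
        errs.append("n_days: must be >= 0")

    lo, hi = cfg.multiplier_range
    if lo < 1.0:
        errs.append("multiplier_range: lower bound must be >= 1.0 (1.0 means no premium)")
    if hi < lo:
        errs.append("multiplier_range: upper bound must be >= lower bound")

    if cfg.arrival_distribution is not None:
        for ill, sev_map in cfg.arrival_distribution.items():
            if ill not in cfg.illnesses:
                errs.append(f"arrival_distribution: unknown illness {ill!r}")
            for sev, p in sev_map.items():
                if sev not in cfg.severities:
                    errs.append(f"arrival_distribution[{ill}]: unknown severity {sev!r}")
                if p < 0:
                    errs.append(f"arrival_distribution[{ill}][{sev}]: probability must be >= 0")
        total = sum(p for _, p in cfg.arrival_probabilities())
        if abs(total - 1.0) > 1e-9:
            errs.append(f"arrival_distribution: probabilities sum to {total!r}, expected 1")

    for ward_id in cfg.policies:
        if ward_id not in ids:
            errs.append(f"policies: unknown ward id {ward_id!r}")

    return errs


def validate_config(config: ScenarioConfig | dict[str, Any]) -> ScenarioConfig:
    """Validate a scenario, aggregating every violation into one error.

    Accepts either an already-constructed :class:`ScenarioConfig` or a raw
    mapping (as parsed from YAML/JSON); defaults are filled for absent fields.
    """
    if isinstance(config, dict):
        try:
            config = ScenarioConfig(**config)
        except ValidationError as exc:
            msgs = [
                f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
            ]
            raise ConfigurationError("invalid scenario:\n  " + "\n  ".join(msgs)) from exc
    errs = _invariant_errors(config)
    if errs:
        raise ConfigurationError("invalid scenario:\n  " + "\n  ".join(errs))
    return config


def default_scenario(**overrides: Any) -> ScenarioConfig:
    """The reference scenario, optionally with field overrides applied."""
    return validate_config(ScenarioConfig(**overrides))
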