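"""Stochastic processes driving ward occupancy: arrivals, admission, discharge.

Arrivals are i.i.d. draws of (illness, severity) from the configured arrival
distribution, a fixed number per day.  Discharge is a per-day Bernoulli trial
per occupant with probability ``1 / mean_los_days``, which makes the length of
stay geometric (support starting at 1 day, mean ``mean_los_days``): the single
stated rate pins down exactly one memoryless discrete-time process.  Patients
admitted on a given day are ineligible for that day's discharge draw, so no
stay has zero length.

All randomness flows through :class:`RandomStream`, which carves a seed into
independent named substreams (arrivals, discharge, multiplier, tiebreak,
policy).  Consuming more draws from one substream never perturbs another, so
e.g. raising ``arrivals_per_day`` leaves the discharge trajectory of existing
patients untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import Patient, ScenarioConfig, WorkloadWeightTable, workload_increment

__all__ = [
    "RandomStream",
    "ArrivalBatch",
    "OccupancyRecord",
    "WardState",
    "HospitalState",
    "CapacityError",
    "generate_arrivals",
    "apply_admission",
    "discharge_step",
    "sample_lengths_of_stay",
]

_STREAM_NAMES = ("arrivals", "discharge", "multiplier", "tiebreak", "policy")


class RandomStream:
    """Named, independent random substreams derived from one seed.

    Each substream is a :class:`numpy.random.Generator` seeded from a distinct
    spawn key of the master :class:`numpy.random.SeedSequence`, so identical
    (seed, config) pairs reproduce identical event logs bit for bit.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)
        self._gens = {
            name: np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(i,)))
            for i, name in enumerate(_STREAM_NAMES)
        }

    def get(self, name: str) -> np.random.Generator:
        try:
            return self._gens[name]
        except KeyError:
            raise KeyError(f"unknown substream {name!r}; expected one of {_STREAM_NAMES}") from None

    @property
    def arrivals(self) -> np.random.Generator:
        return self._gens["arrivals"]

    @property
    def discharge(self) -> np.random.Generator:
        return self._gens["discharge"]

    @property
    def multiplier(self) -> np.random.Generator:
        return self._gens["multiplier"]

    @property
    def tiebreak(self) -> np.random.Generator:
        return self._gens["tiebreak"]

    @property
    def policy(self) -> np.random.Generator:
        return self._gens["policy"]


@dataclass(frozen=True)
class ArrivalBatch:
    """One day's newly appeared patients, in allocation order."""

    day: int
    patients: tuple[Patient, ...]


class CapacityError(RuntimeError):
    """Raised on an admission request to a ward with no vacant bed."""


@dataclass
class OccupancyRecord:
    """A patient currently occupying a bed, with the workload increment and
    price recorded at admission so discharge can reverse them exactly."""

    patient: Patient
    increment: float
    price_paid: float = 0.0


@dataclass
class WardState:
    """Mutable runtime state of one ward."""

    id: str
    specialty: str
    capacity: int
    occupants: dict[str, OccupancyRecord] = field(default_factory=dict)
    workload: float = 0.0
    balance: float = 0.0

    @property
    def occupancy(self) -> int:
        return len(self.occupants)

    @property
    def vacancies(self) -> int:
        return self.capacity - len(self.occupants)

    def recomputed_workload(self) -> float:
        """Workload summed afresh from occupant records (drift check)."""
        return sum(rec.increment for rec in self.occupants.values())


@dataclass
class HospitalState:
    """All wards plus the cumulative patient registry."""

    wards: dict[str, WardState]
    patients: dict[str, Patient] = field(default_factory=dict)
    total_admitted: int = 0
    total_discharged: int = 0

    @classmethod
    def empty(cls, config: ScenarioConfig) -> "HospitalState":
        return cls(
            wards={
                w.id: WardState(id=w.id, specialty=w.specialty, capacity=w.capacity)
                for w in config.wards
            }
        )

    @property
    def occupancy(self) -> int:
        return sum(w.occupancy for w in self.wards.values())


def generate_arrivals(day: int, config: ScenarioConfig, rng: RandomStream) -> ArrivalBatch:
    """Draw the day's patients i.i.d. from the arrival distribution."""
    if day < 0:
        raise ValueError("day must be >= 0")
    probs = config.arrival_probabilities()
    patterns = [p for p, _ in probs]
    weights = np.array([w for _, w in probs], dtype=float)
    idx = rng.arrivals.choice(len(patterns), size=config.arrivals_per_day, p=weights)
    patients = tuple(
        Patient(id=f"d{day}p{i}", illness=patterns[j][0], severity=patterns[j][1])
        for i, j in enumerate(idx)
    )
    return ArrivalBatch(day=day, patients=patients)


def apply_admission(
    ward: WardState,
    patient: Patient,
    day: int,
    weights: WorkloadWeightTable,
    price_paid: float = 0.0,
) -> float:
    """Admit ``patient`` to ``ward``, returning the workload increment applied.

    The increment is stored with the occupancy record so that the later
    discharge reverses exactly what admission added, even if the weight table
    were edited in between.
    """
    if ward.vacancies < 1:
        raise CapacityError(f"ward {ward.id} is full ({ward.capacity} beds)")
    if patient.assigned_ward is not None:
        raise ValueError(f"patient {patient.id} is already assigned")
    inc = workload_increment(patient.illness, patient.severity, ward.specialty, weights)
    patient.admit_day = day
    patient.assigned_ward = ward.id
    ward.occupants[patient.id] = OccupancyRecord(patient=patient, increment=inc, price_paid=price_paid)
    ward.workload += inc
    return inc


@dataclass(frozen=True)
class DischargeEvent:
    patient_id: str
    ward_id: str
    day: int
    increment: float


def discharge_step(
    state: HospitalState,
    day: int,
    config: ScenarioConfig,
    rng: RandomStream,
) -> list[DischargeEvent]:
    """Run the day's independent Bernoulli discharge draws.

    Every occupant admitted strictly before ``day`` leaves with probability
    ``1 / mean_los_days``; the ward's workload drops by that patient's stored
    increment.  Iteration order is ward order then admission order, fixed so a
    given seed replays identically.
    """
    p = 1.0 / config.mean_los_days
    events: list[DischargeEvent] = []
    for ward in state.wards.values():
        eligible = [rec for rec in ward.occupants.values() if rec.patient.admit_day < day]
        if not eligible:
            continue
        draws = rng.discharge.random(len(eligible))
        for rec, u in zip(eligible, draws):
            if u < p:
                pat = rec.patient
                pat.discharge_day = day
                del ward.occupants[pat.id]
                ward.workload -= rec.increment
                state.total_discharged += 1
                events.append(DischargeEvent(pat.id, ward.id, day, rec.increment))
    return events


def sample_lengths_of_stay(
    n: int,
    config: ScenarioConfig,
    rng: RandomStream,
    max_days: int | None = None,
) -> np.ndarray:
    """Simulate ``n`` complete stays through the admission/discharge machinery.

    All patients are admitted on day 0 to a single ward sized to hold them,
    then the daily discharge process runs until the ward empties.  Returns the
    array of realized lengths of stay in days.
    """
    ill = config.illnesses[0]
    sev = config.severities[0]
    ward = WardState(id="los", specialty=ill, capacity=n)
    state = HospitalState(wards={"los": ward})
    for i in range(n):
        pat = Patient(id=f"los{i}", illness=ill, severity=sev)
        apply_admission(ward, pat, day=0, weights=config.weights)
        state.patients[pat.id] = pat
    state.total_admitted = n
    limit = max_days if max_days is not None else 1000 * int(config.mean_los_days)
    day = 1
    los: list[int] = []
    while ward.occupants and day <= limit:
        for ev in discharge_step(state, day, config, rng):
            los.append(ev.day)  # admit_day is 0, so discharge day == LOS
        day += 1
    if ward.occupants:
        raise RuntimeError(f"stays did not complete within {limit} days")
    return np.asarray(los, dtype=float)
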