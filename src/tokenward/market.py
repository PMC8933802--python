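"""Token ledger, admission settlement, and the day/session engine.

One simulated day runs in a fixed order: (1) every ward's pricing policy
posts its price list from the ward's own restricted view; (2) the day's
patients appear; (3) each patient in arrival order is allocated by the
physician rule, paying the chosen ward's posted price for that patient's
(illness, severity) pattern — or is rejected if no ward has a vacancy;
(4) the random discharge draw frees beds for subsequent days.  A session is
``n_days`` such days starting from an empty hospital.

The token economy is closed and pass-through: for every admission the
hospital issues exactly the agreed price to the physician, who hands it to
the ward, so total issuance always equals the sum of ward balances.  Every
event is appended to a typed, ordered :class:`EventLog` from which the final
state can be rebuilt exactly (replay equivalence), making each run fully
auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import pandas as pd

from .agents import PricingPolicy, SelectionOutcome, WardView, build_policy, select_ward
from .config import Patient, PriceList, ScenarioConfig, validate_config
from .dynamics import (
    HospitalState,
    RandomStream,
    apply_admission,
    discharge_step,
    generate_arrivals,
)

__all__ = [
    "Event",
    "EventLog",
    "TokenLedger",
    "SessionResult",
    "settle_admission",
    "run_day",
    "run_session",
    "replay_log",
    "token_allocator",
]

EVENT_KINDS = ("price_set", "arrival", "admission", "rejection", "discharge")


@dataclass(frozen=True)
class Event:
    day: int
    seq: int
    kind: str
    payload: dict

    def to_json(self) -> str:
        return json.dumps(
            {"day": self.day, "seq": self.seq, "kind": self.kind, "payload": self.payload},
            sort_keys=True,
        )


class EventLog:
    """Ordered, typed record of everything that happened in a session."""

    def __init__(self, events: Optional[list[Event]] = None):
        self.events: list[Event] = list(events) if events else []

    def append(self, day: int, kind: str, payload: dict) -> Event:
        if kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {kind!r}")
        ev = Event(day=day, seq=len(self.events), kind=kind, payload=payload)
        self.events.append(ev)
        return ev

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    def to_jsonl(self) -> str:
        return "".join(e.to_json() + "\n" for e in self.events)

    @classmethod
    def from_jsonl(cls, text: str) -> "EventLog":
        events = []
        for line in text.splitlines():
            if not line.strip():
                continue
            d = json.loads(line)
            events.append(Event(day=d["day"], seq=d["seq"], kind=d["kind"], payload=d["payload"]))
        return cls(events)

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-event table (payload fields flattened)."""
        rows = []
        for e in self.events:
            row = {"day": e.day, "seq": e.seq, "kind": e.kind}
            for k, v in e.payload.items():
                row[k] = json.dumps(v) if isinstance(v, (list, dict)) else v
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class TokenLedger:
    """Closed-economy token accounting: issuance equals the sum of balances."""

    ward_balances: dict[str, float] = field(default_factory=dict)
    hospital_issuance: float = 0.0

    def conservation_gap(self) -> float:
        return abs(self.hospital_issuance - sum(self.ward_balances.values()))


def settle_admission(ledger: TokenLedger, ward_id: str, price: float) -> TokenLedger:
    """Issue ``price`` tokens and transfer them to the admitting ward."""
    if price < 0:
        raise ValueError(f"price must be >= 0, got {price}")
    ledger.ward_balances[ward_id] = ledger.ward_balances.get(ward_id, 0.0) + price
    ledger.hospital_issuance += price
    return ledger


# Allocator signature shared by the token mechanism and baselines:
# (patient, prices, vacancies, specialties, rng) -> SelectionOutcome
Allocator = Callable[
    [Patient, Mapping[str, PriceList], Mapping[str, int], Mapping[str, str], RandomStream],
    SelectionOutcome,
]


def token_allocator(config: ScenarioConfig) -> Allocator:
    """The price-based physician rule, bound to the scenario's multiplier range."""

    def allocate(patient, prices, vacancies, specialties, rng):
        return select_ward(patient, prices, vacancies, specialties, config.multiplier_range, rng)

    return allocate


@dataclass
class SessionResult:
    """Everything produced by one session run."""

    config: ScenarioConfig
    state: HospitalState
    ledger: TokenLedger
    log: EventLog
    snapshots: pd.DataFrame
    rejections: int
    policies: dict[str, PricingPolicy]


class _Engine:
    def __init__(
        self,
        config: ScenarioConfig,
        policies: Optional[dict[str, PricingPolicy]] = None,
        allocator: Optional[Allocator] = None,
        charge_prices: bool = True,
    ):
        self.config = validate_config(config)
        self.rng = RandomStream(config.seed)
        self.state = HospitalState.empty(config)
        self.ledger = TokenLedger(ward_balances={w.id: 0.0 for w in config.wards})
        self.log = EventLog()
        self.policies = policies or {w.id: build_policy(config, w.id) for w in config.wards}
        self.allocator = allocator or token_allocator(config)
        self.charge_prices = charge_prices
        self.price_history: dict[str, list[PriceList]] = {w.id: [] for w in config.wards}
        self.current_prices: dict[str, PriceList] = {}
        self.snapshot_rows: list[dict] = []
        self.rejections = 0

    def _view_for(self, ward_id: str, day: int) -> WardView:
        ward = self.state.wards[ward_id]
        others = {
            w: s.occupancy for w, s in self.state.wards.items() if w != ward_id
        }
        others_prices = None
        if self.config.reveal_other_prices and self.current_prices:
            others_prices = {
                w: pl for w, pl in self.current_prices.items() if w != ward_id
            }
        return WardView(
            day=day,
            ward_id=ward_id,
            specialty=ward.specialty,
            capacity=ward.capacity,
            occupancy=ward.occupancy,
            workload=ward.workload,
            balance=ward.balance,
            others_census=others,
            price_history=tuple(self.price_history[ward_id]),
            others_prices=others_prices,
        )

    def _set_prices(self, day: int) -> None:
        for spec in self.config.wards:
            ward = self.state.wards[spec.id]
            view = self._view_for(spec.id, day)
            pl = self.policies[spec.id].set_prices(view, self.rng)
            pl.validate_complete(self.config)
            self.current_prices[spec.id] = pl
            self.price_history[spec.id].append(pl)
            self.log.append(
                day,
                "price_set",
                {
                    "ward": spec.id,
                    "prices": [[i, s, pl.prices[(i, s)]] for i, s in self.config.patterns()],
                    "workload": ward.workload,
                    "occupancy": ward.occupancy,
                    "balance": ward.balance,
                },
            )
            row = {
                "day": day,
                "ward": spec.id,
                "occupancy": ward.occupancy,
                "workload": ward.workload,
                "balance": ward.balance,
            }
            for i, s in self.config.patterns():
                row[f"price[{i}|{s}]"] = pl.prices[(i, s)]
            self.snapshot_rows.append(row)

    def _allocate(self, day: int) -> None:
        batch = generate_arrivals(day, self.config, self.rng)
        specialties = {w.id: w.specialty for w in self.config.wards}
        for patient in batch.patients:
            self.state.patients[patient.id] = patient
            self.log.append(
                day,
                "arrival",
                {"patient": patient.id, "illness": patient.illness, "severity": patient.severity},
            )
            vacancies = {w: s.vacancies for w, s in self.state.wards.items()}
            outcome = self.allocator(patient, self.current_prices, vacancies, specialties, self.rng)
            if outcome.ward_id is None:
                self.rejections += 1
                self.log.append(
                    day,
                    "rejection",
                    {"patient": patient.id, "illness": patient.illness, "severity": patient.severity},
                )
                continue
            ward = self.state.wards[outcome.ward_id]
            price = (
                self.current_prices[outcome.ward_id].price(patient.illness, patient.severity)
                if self.charge_prices
                else 0.0
            )
            inc = apply_admission(ward, patient, day, self.config.weights, price_paid=price)
            ward.balance += price
            settle_admission(self.ledger, outcome.ward_id, price)
            self.state.total_admitted += 1
            self.log.append(
                day,
                "admission",
                {
                    "patient": patient.id,
                    "illness": patient.illness,
                    "severity": patient.severity,
                    "ward": outcome.ward_id,
                    "price": price,
                    "multiplier": outcome.multiplier,
                    "reason": outcome.reason,
                    "increment": inc,
                },
            )

    def _discharge(self, day: int) -> None:
        for ev in discharge_step(self.state, day, self.config, self.rng):
            self.log.append(
                day,
                "discharge",
                {
                    "patient": ev.patient_id,
                    "ward": ev.ward_id,
                    "increment": ev.increment,
                    "admit_day": self.state.patients[ev.patient_id].admit_day,
                },
            )

    def run_day(self, day: int) -> None:
        if self.config.discharge_timing == "day_start":
            self._discharge(day)
        self._set_prices(day)
        self._allocate(day)
        if self.config.discharge_timing == "day_end":
            self._discharge(day)

    def result(self) -> SessionResult:
        return SessionResult(
            config=self.config,
            state=self.state,
            ledger=self.ledger,
            log=self.log,
            snapshots=pd.DataFrame(self.snapshot_rows),
            rejections=self.rejections,
            policies=self.policies,
        )


def run_day(
    engine_or_config,
    day: int,
    policies: Optional[dict[str, PricingPolicy]] = None,
) -> _Engine:
    """Run a single day; accepts an existing engine or builds one from config."""
    engine = (
        engine_or_config
        if isinstance(engine_or_config, _Engine)
        else _Engine(engine_or_config, policies=policies)
    )
    engine.run_day(day)
    return engine


def run_session(
    config: ScenarioConfig,
    policies: Optional[dict[str, PricingPolicy]] = None,
    allocator: Optional[Allocator] = None,
    charge_prices: bool = True,
    n_days: Optional[int] = None,
) -> SessionResult:
    """Run a full session of ``n_days`` consecutive days from an empty hospital.

    Deterministic given ``config.seed``: the same (config, seed) pair yields a
    byte-identical event log.
    """
    engine = _Engine(config, policies=policies, allocator=allocator, charge_prices=charge_prices)
    days = config.n_days if n_days is None else n_days
    for day in range(days):
        engine.run_day(day)
    return engine.result()


def replay_log(config: ScenarioConfig, log: EventLog) -> HospitalState:
    """Rebuild hospital state purely from the event log (no randomness).

    Admissions and discharges are applied with the increments and prices
    recorded in the log; the result must equal the state produced online.
    """
    state = HospitalState.empty(config)
    from .dynamics import OccupancyRecord

    for ev in log:
        p = ev.payload
        if ev.kind == "arrival":
            state.patients[p["patient"]] = Patient(
                id=p["patient"], illness=p["illness"], severity=p["severity"]
            )
        elif ev.kind == "admission":
            pat = state.patients[p["patient"]]
            pat.admit_day = ev.day
            pat.assigned_ward = p["ward"]
            ward = state.wards[p["ward"]]
            if ward.vacancies < 1:
                raise RuntimeError(f"replay: ward {ward.id} over capacity at event {ev.seq}")
            ward.occupants[pat.id] = OccupancyRecord(
                patient=pat, increment=p["increment"], price_paid=p["price"]
            )
            ward.workload += p["increment"]
            ward.balance += p["price"]
            state.total_admitted += 1
        elif ev.kind == "discharge":
            ward = state.wards[p["ward"]]
            pat = state.patients[p["patient"]]
            pat.discharge_day = ev.day
            del ward.occupants[p["patient"]]
            ward.workload -= p["increment"]
            state.total_discharged += 1
    return state
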