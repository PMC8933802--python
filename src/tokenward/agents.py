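"""The physician agent's ward-selection rule and ward pricing policies.

Ward selection
--------------
The emulated physician admits each patient to the cheapest vacant ward,
except that the ward specializing in the patient's illness may charge a
premium: for every admission decision a multiplier ``m ~ U(lo, hi)`` is
drawn (defaults [1.0, 2.0]; 1.0 means no premium tolerated) and the
specialty ward wins whenever its price is at most ``m`` times the cheapest
vacant ward's price.  Ties at the minimum price are broken uniformly at
random.  The closed-form specialty-selection probability at price ratio
``r = price_s / p_min`` is ``min(1, max(0, (hi - r) / (hi - lo)))``.

Information asymmetry
---------------------
Pricing policies stand in for the human ward managers.  They see only a
:class:`WardView`: the full state of their own ward but, of the other wards,
nothing beyond the number of admitted patients.  The view type itself carries
no field for another ward's workload, prices, or token balance, so the
constraint is structural rather than conventional.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .config import ConfigurationError, Patient, PriceList, ScenarioConfig
from .dynamics import RandomStream

__all__ = [
    "WardView",
    "SelectionOutcome",
    "select_ward",
    "specialty_selection_probability",
    "PricingPolicy",
    "ConstantPolicy",
    "WorkloadLinearPolicy",
    "RandomPolicy",
    "ReplayPolicy",
    "InteractivePolicy",
    "build_policy",
    "ScheduleError",
]


@dataclass(frozen=True)
class WardView:
    """What one ward's pricing policy is allowed to observe.

    ``others_census`` maps each other ward's id to its admitted-patient count
    only.  ``others_prices`` is populated solely when the scenario opts into
    relaxed asymmetry (``reveal_other_prices``); under the strict default it
    is None.
    """

    day: int
    ward_id: str
    specialty: str
    capacity: int
    occupancy: int
    workload: float
    balance: float
    others_census: Mapping[str, int]
    price_history: tuple[PriceList, ...] = ()
    others_prices: Optional[Mapping[str, PriceList]] = None


@dataclass(frozen=True)
class SelectionOutcome:
    """Result of one physician admission decision."""

    patient_id: str
    ward_id: Optional[str]
    lowest_price: Optional[float]
    specialty_price: Optional[float]
    multiplier: Optional[float]
    reason: str  # lowest_price | specialty_premium | no_vacancy


def specialty_selection_probability(
    price_ratio: float, multiplier_range: tuple[float, float]
) -> float:
    """P(specialty ward chosen) given price_s = ratio * p_min, both vacant."""
    lo, hi = multiplier_range
    if hi == lo:
        return 1.0 if price_ratio <= lo else 0.0
    return min(1.0, max(0.0, (hi - price_ratio) / (hi - lo)))


def select_ward(
    patient: Patient,
    prices: Mapping[str, PriceList],
    vacancies: Mapping[str, int],
    specialties: Mapping[str, str],
    multiplier_range: tuple[float, float],
    rng: RandomStream,
) -> SelectionOutcome:
    """Apply the physician's lowest-price-with-specialty-premium rule.

    The multiplier is drawn (from the dedicated substream) iff the specialty
    ward has a vacancy, and is recorded in the outcome exactly then.
    """
    candidates = [w for w, v in vacancies.items() if v >= 1]
    if not candidates:
        return SelectionOutcome(patient.id, None, None, None, None, "no_vacancy")

    def price_of(w: str) -> float:
        return prices[w].price(patient.illness, patient.severity)

    p_min = min(price_of(w) for w in candidates)
    specialty_ward = next(
        (w for w in candidates if specialties[w] == patient.illness), None
    )

    multiplier: Optional[float] = None
    specialty_price: Optional[float] = None
    if specialty_ward is not None:
        specialty_price = price_of(specialty_ward)
        lo, hi = multiplier_range
        multiplier = float(rng.multiplier.uniform(lo, hi))
        if specialty_price <= multiplier * p_min:
            reason = "lowest_price" if specialty_price == p_min else "specialty_premium"
            return SelectionOutcome(
                patient.id, specialty_ward, p_min, specialty_price, multiplier, reason
            )

    cheapest = [w for w in candidates if price_of(w) == p_min]
    if len(cheapest) == 1:
        chosen = cheapest[0]
    else:
        chosen = cheapest[int(rng.tiebreak.integers(len(cheapest)))]
    return SelectionOutcome(patient.id, chosen, p_min, specialty_price, multiplier, "lowest_price")


# ---------------------------------------------------------------------------
# Pricing policies


class ScheduleError(RuntimeError):
    """A replay schedule is missing a required (day, pattern) row."""


class PricingPolicy(abc.ABC):
    """Produces the ward's complete daily price list from its own view only."""

    def __init__(self, config: ScenarioConfig, ward_id: str):
        self.config = config
        self.ward_id = ward_id

    @abc.abstractmethod
    def set_prices(self, view: WardView, rng: RandomStream) -> PriceList: ...

    def _complete(self, day: int, price_fn) -> PriceList:
        prices = {}
        for pat in self.config.patterns():
            p = float(price_fn(pat))
            if p < 0:
                import warnings

                warnings.warn(
                    f"policy for ward {self.ward_id} computed negative price {p} "
                    f"for {pat}; clipping to 0",
                    stacklevel=3,
                )
                p = 0.0
            prices[pat] = p
        pl = PriceList(prices=prices, effective_day=day)
        pl.validate_complete(self.config)
        return pl


class ConstantPolicy(PricingPolicy):
    """Same price every day: a scalar base, or a per-pattern base map."""

    def __init__(self, config, ward_id, base: float | dict = 5.0):
        super().__init__(config, ward_id)
        self.base = base

    def _base_of(self, pattern: tuple[str, str]) -> float:
        if isinstance(self.base, dict):
            ill, sev = pattern
            if ill in self.base and isinstance(self.base[ill], dict):
                return float(self.base[ill][sev])
            return float(self.base[pattern])
        return float(self.base)

    def set_prices(self, view: WardView, rng: RandomStream) -> PriceList:
        return self._complete(view.day, self._base_of)


class WorkloadLinearPolicy(ConstantPolicy):
    """price = base + slope * own current workload, clipped at zero.

    The workload-responsive policy: with positive slope the posted price is a
    deterministic signal of the ward's otherwise-hidden workload.
    """

    def __init__(self, config, ward_id, base: float | dict = 5.0, slope: float = 0.5):
        super().__init__(config, ward_id, base=base)
        self.slope = float(slope)

    def set_prices(self, view: WardView, rng: RandomStream) -> PriceList:
        return self._complete(
            view.day, lambda pat: self._base_of(pat) + self.slope * view.workload
        )


class RandomPolicy(PricingPolicy):
    """Prices drawn U(low, high) per pattern per day, independent of workload.

    Serves as the no-signal null: price variation exists but carries no
    information about the ward's state.
    """

    def __init__(self, config, ward_id, low: float = 1.0, high: float = 10.0):
        super().__init__(config, ward_id)
        if high < low:
            raise ConfigurationError("random policy: high must be >= low")
        self.low, self.high = float(low), float(high)

    def set_prices(self, view: WardView, rng: RandomStream) -> PriceList:
        draws = rng.policy.uniform(self.low, self.high, size=len(self.config.patterns()))
        values = {pat: float(d) for pat, d in zip(self.config.patterns(), draws)}
        return self._complete(view.day, lambda pat: values[pat])


class ReplayPolicy(PricingPolicy):
    """Reads the day's prices from a recorded schedule.

    The schedule is a tidy table with columns day, ward, illness, severity,
    price — the same format in which interactive sessions are recorded, so a
    recorded human session replays bit-exactly.
    """

    def __init__(self, config, ward_id, schedule: pd.DataFrame | str):
        super().__init__(config, ward_id)
        if isinstance(schedule, str):
            schedule = pd.read_csv(schedule)
        required = {"day", "ward", "illness", "severity", "price"}
        if not required.issubset(schedule.columns):
            raise ScheduleError(
                f"schedule must have columns {sorted(required)}, got {list(schedule.columns)}"
            )
        self._table = {
            (int(r.day), str(r.ward), str(r.illness), str(r.severity)): float(r.price)
            for r in schedule.itertuples()
        }

    def set_prices(self, view: WardView, rng: RandomStream) -> PriceList:
        def lookup(pat):
            key = (view.day, self.ward_id, pat[0], pat[1])
            if key not in self._table:
                raise ScheduleError(
                    f"schedule has no price for ward {self.ward_id}, day {view.day}, "
                    f"pattern {pat}"
                )
            return self._table[key]

        return self._complete(view.day, lookup)


class InteractivePolicy(PricingPolicy):
    """Prompts a human on the terminal with the same information the game
    screens showed: own occupancy and workload, other wards' patient counts.

    Entered prices are appended to ``recorded`` so the session can be saved
    as a replayable schedule.
    """

    def __init__(self, config, ward_id, input_fn=input, output_fn=print):
        super().__init__(config, ward_id)
        self._input = input_fn
        self._print = output_fn
        self.recorded: list[dict] = []

    def set_prices(self, view: WardView, rng: RandomStream) -> PriceList:
        self._print(f"\n=== Day {view.day} — ward {view.ward_id} ({view.specialty}) ===")
        self._print(
            f"occupancy {view.occupancy}/{view.capacity}, workload {view.workload:.2f}, "
            f"balance {view.balance:.2f} tokens"
        )
        census = ", ".join(f"{w}: {n} patients" for w, n in sorted(view.others_census.items()))
        self._print(f"other wards — {census}")
        prices = {}
        for ill, sev in self.config.patterns():
            while True:
                raw = self._input(f"price for ({ill}, {sev}): ")
                try:
                    val = float(raw)
                    if val < 0:
                        raise ValueError
                    break
                except ValueError:
                    self._print("please enter a non-negative number")
            prices[(ill, sev)] = val
            self.recorded.append(
                {"day": view.day, "ward": self.ward_id, "illness": ill,
                 "severity": sev, "price": val}
            )
        return self._complete(view.day, lambda pat: prices[pat])


_POLICY_KINDS = {
    "constant": ConstantPolicy,
    "workload_linear": WorkloadLinearPolicy,
    "random": RandomPolicy,
    "replay": ReplayPolicy,
    "interactive": InteractivePolicy,
}


def build_policy(config: ScenarioConfig, ward_id: str) -> PricingPolicy:
    """Instantiate the configured pricing policy for one ward."""
    spec = config.policy_spec(ward_id)
    cls = _POLICY_KINDS[spec.kind]
    params = dict(spec.params)
    if spec.kind == "replay" and "schedule" in params and isinstance(params["schedule"], str):
        params["schedule"] = pd.read_csv(params["schedule"])
    return cls(config, ward_id, **params)
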