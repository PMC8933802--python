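"""Command-based allocation baseline and mechanism comparison.

The comparator models the command-style process in which a central allocation
manager assigns beds by fiat: the patient goes to the specialty ward whenever
it has a vacancy, otherwise to a vacant ward chosen by a fallback rule
(least occupied, or uniformly at random), and is rejected only when the whole
hospital is full.  Prices play no role — the allocator is price-blind by
construction.

The negotiation-style process (consensus between allocation and ward
managers) is deliberately not simulated: it has no mechanical specification
and inventing one would attribute behavior to humans the model knows nothing
about.  ``compare_mechanisms`` pairs the token market against the command
baseline on common seeds and reports workload balance, specialty matching,
and rejections per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional

import pandas as pd

from .agents import SelectionOutcome
from .config import Patient, ScenarioConfig
from .dynamics import RandomStream
from .market import SessionResult, run_session

__all__ = ["CommandAllocator", "command_select", "run_command_session", "compare_mechanisms"]


@dataclass(frozen=True)
class CommandAllocator:
    """Price-blind central allocator with a configurable fallback rule."""

    fallback: Literal["least_occupied", "random_vacant"] = "least_occupied"

    def __call__(self, patient, prices, vacancies, specialties, rng) -> SelectionOutcome:
        chosen = command_select(patient, vacancies, specialties, rng, self.fallback)
        if chosen is None:
            return SelectionOutcome(patient.id, None, None, None, None, "no_vacancy")
        reason = "specialty" if specialties[chosen] == patient.illness else "fallback"
        return SelectionOutcome(patient.id, chosen, None, None, None, reason)


def command_select(
    patient: Patient,
    vacancies: Mapping[str, int],
    specialties: Mapping[str, str],
    rng: RandomStream,
    fallback: str = "least_occupied",
    capacities: Optional[Mapping[str, int]] = None,
) -> Optional[str]:
    """Specialty ward if vacant; else the fallback rule over vacant wards.

    ``least_occupied`` needs occupancy, inferred as capacity - vacancy when
    ``capacities`` is given, else ranked by vacancy descending (equivalent for
    equal capacities).  Ties are broken uniformly from the tie-break substream.
    """
    vacant = [w for w, v in vacancies.items() if v >= 1]
    if not vacant:
        return None
    for w in vacant:
        if specialties[w] == patient.illness:
            return w
    if fallback == "random_vacant":
        return vacant[int(rng.tiebreak.integers(len(vacant)))]
    if capacities is not None:
        key = {w: capacities[w] - vacancies[w] for w in vacant}  # true occupancy
    else:
        key = {w: -vacancies[w] for w in vacant}
    best = min(key[w] for w in vacant)
    tied = [w for w in vacant if key[w] == best]
    if len(tied) == 1:
        return tied[0]
    return tied[int(rng.tiebreak.integers(len(tied)))]


def run_command_session(
    config: ScenarioConfig, fallback: str = "least_occupied"
) -> SessionResult:
    """A full session allocated by the command baseline.

    Pricing policies still run (their posted prices are recorded for
    comparability) but no tokens change hands and the allocator never reads
    the prices.
    """
    return run_session(
        config, allocator=CommandAllocator(fallback=fallback), charge_prices=False
    )


def _session_metrics(result: SessionResult) -> dict:
    snaps = result.snapshots
    admissions = result.log.of_kind("admission")
    matched = sum(
        1
        for e in admissions
        if result.config.specialty_of(e.payload["ward"]) == e.payload["illness"]
    )
    per_day_sd = (
        snaps.groupby("day")["workload"].std(ddof=0).mean() if len(snaps) else float("nan")
    )
    return {
        "mean_workload": snaps["workload"].mean() if len(snaps) else 0.0,
        "max_workload": snaps["workload"].max() if len(snaps) else 0.0,
        "workload_sd_across_wards": per_day_sd,
        "specialty_match_fraction": matched / len(admissions) if admissions else float("nan"),
        "n_admissions": len(admissions),
        "rejections": result.rejections,
    }


def compare_mechanisms(
    config: ScenarioConfig,
    n_replicates: int,
    base_seed: Optional[int] = None,
    fallback: str = "least_occupied",
) -> pd.DataFrame:
    """Run the token market and the command baseline on paired seeds.

    Each replicate r uses seed ``base_seed + r`` for both arms, so arrival
    sequences and all other draws are shared and differences are attributable
    to the mechanism alone.  Returns one row per (mechanism, replicate).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    base = config.seed if base_seed is None else int(base_seed)
    rows = []
    for r in range(n_replicates):
        cfg = config.model_copy(update={"seed": base + r})
        for mechanism, result in (
            ("token", run_session(cfg)),
            ("command", run_command_session(cfg, fallback=fallback)),
        ):
            row = {"mechanism": mechanism, "replicate": r, "seed": base + r}
            row.update(_session_metrics(result))
            rows.append(row)
    return pd.DataFrame(rows)
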