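"""Physician selection rule, specialty premium, and pricing policies."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import tokenward as tw
from tokenward.agents import (
    ConstantPolicy,
    RandomPolicy,
    ReplayPolicy,
    ScheduleError,
    WardView,
    WorkloadLinearPolicy,
    specialty_selection_probability,
)
from tokenward.config import Patient, PriceList


def _prices(cfg, per_ward: dict[str, float]) -> dict[str, PriceList]:
    return {
        w: PriceList({pat: v for pat in cfg.patterns()}) for w, v in per_ward.items()
    }


SPECIALTIES = {"A": "gastric ulcer", "B": "pneumonia", "C": "heart failure"}


def _patient(illness="gastric ulcer", severity="mild", pid="p"):
    return Patient(id=pid, illness=illness, severity=severity)


class TestSelectWard:
    def test_specialty_at_minimum_price_always_wins(self, cfg, rng):
        prices = _prices(cfg, {"A": 2.0, "B": 2.0, "C": 5.0})
        vac = {"A": 1, "B": 1, "C": 1}
        for i in range(200):
            o = tw.select_ward(_patient(pid=str(i)), prices, vac, SPECIALTIES, (1.0, 2.0), rng)
            assert o.ward_id == "A"
            assert o.reason == "lowest_price"  # price_s == p_min
            assert o.multiplier is not None  # drawn because specialty vacant

    def test_specialty_full_falls_back_to_cheapest(self, cfg, rng):
        prices = _prices(cfg, {"A": 1.0, "B": 5.0, "C": 7.0})
        vac = {"A": 0, "B": 1, "C": 1}
        o = tw.select_ward(_patient(), prices, vac, SPECIALTIES, (1.0, 2.0), rng)
        assert o.ward_id == "B" and o.reason == "lowest_price"
        assert o.multiplier is None and o.lowest_price == 5.0

    def test_no_vacancy_anywhere(self, cfg, rng):
        prices = _prices(cfg, {"A": 1.0, "B": 1.0, "C": 1.0})
        o = tw.select_ward(_patient(), prices, {"A": 0, "B": 0, "C": 0}, SPECIALTIES, (1.0, 2.0), rng)
        assert o.ward_id is None and o.reason == "no_vacancy"

    def test_premium_probability_half_at_ratio_1_5(self, cfg):
        """price_s = 1.5 p_min, m ~ U(1,2): specialty wins iff m >= 1.5, prob 0.5.

        10,000 replays land within 3 binomial SE (+-0.015) of the closed form,
        itself cross-checked against a brute-force Monte Carlo over m draws.
        """
        closed = specialty_selection_probability(1.5, (1.0, 2.0))
        assert closed == 0.5
        mc_oracle = (np.random.default_rng(0).uniform(1, 2, 200_000) >= 1.5).mean()
        assert abs(mc_oracle - closed) < 0.005

        prices = _prices(cfg, {"A": 3.0, "B": 2.0, "C": 2.0})
        vac = {"A": 1, "B": 1, "C": 1}
        rng = tw.RandomStream(202)
        n = 10_000
        hits = sum(
            tw.select_ward(_patient(pid=str(i)), prices, vac, SPECIALTIES, (1.0, 2.0), rng).ward_id == "A"
            for i in range(n)
        )
        assert abs(hits / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_premium_never_stretches_to_triple_price(self, cfg):
        prices = _prices(cfg, {"A": 6.0, "B": 2.0, "C": 2.0})
        vac = {"A": 1, "B": 1, "C": 1}
        rng = tw.RandomStream(303)
        for i in range(2000):
            o = tw.select_ward(_patient(pid=str(i)), prices, vac, SPECIALTIES, (1.0, 2.0), rng)
            assert o.ward_id != "A"

    def test_monotone_in_specialty_price_against_closed_form(self, cfg):
        """Empirical selection rate tracks min(1, max(0, (hi-r)/(hi-lo))) and
        decreases weakly along a grid of specialty prices."""
        rng = tw.RandomStream(44)
        vac = {"A": 1, "B": 1, "C": 1}
        n = 4000
        rates = []
        for ratio in [1.0, 1.25, 1.5, 1.75, 2.0, 2.5]:
            prices = _prices(cfg, {"A": 2.0 * ratio, "B": 2.0, "C": 2.0})
            hits = sum(
                tw.select_ward(_patient(pid=str(i)), prices, vac, SPECIALTIES, (1.0, 2.0), rng).ward_id == "A"
                for i in range(n)
            )
            rate = hits / n
            expected = specialty_selection_probability(ratio, (1.0, 2.0))
            assert abs(rate - expected) < 3 * np.sqrt(max(expected * (1 - expected), 1e-4) / n) + 0.01
            rates.append(rate)
        assert all(a >= b - 0.02 for a, b in zip(rates, rates[1:]))

    def test_tie_break_uniform_over_vacant_wards(self, cfg):
        """Equal prices, specialty full: chi-square can't reject uniformity."""
        prices = _prices(cfg, {"A": 2.0, "B": 2.0, "C": 2.0})
        vac = {"A": 0, "B": 1, "C": 1}
        rng = tw.RandomStream(55)
        n = 10_000
        counts = {"B": 0, "C": 0}
        for i in range(n):
            o = tw.select_ward(_patient(pid=str(i)), prices, vac, SPECIALTIES, (1.0, 2.0), rng)
            counts[o.ward_id] += 1
        _, pval = stats.chisquare(list(counts.values()))
        assert pval > 0.001

    def test_never_selects_a_full_ward(self, cfg):
        rng = tw.RandomStream(66)
        grid = np.random.default_rng(1)
        for i in range(300):
            vac = {w: int(grid.integers(0, 3)) for w in "ABC"}
            prices = _prices(cfg, {w: float(grid.uniform(0, 10)) for w in "ABC"})
            o = tw.select_ward(_patient(pid=str(i)), prices, vac, SPECIALTIES, (1.0, 2.0), rng)
            if o.ward_id is not None:
                assert vac[o.ward_id] >= 1
            else:
                assert all(v == 0 for v in vac.values())

    def test_missing_price_entry_is_configuration_error(self, cfg, rng):
        prices = {"A": PriceList({("pneumonia", "mild"): 1.0})}
        with pytest.raises(tw.ConfigurationError):
            tw.select_ward(_patient(), prices, {"A": 1}, {"A": "gastric ulcer"}, (1.0, 2.0), rng)


def _view(cfg, ward_id="B", workload=0.0, day=0):
    return WardView(
        day=day,
        ward_id=ward_id,
        specialty=cfg.specialty_of(ward_id),
        capacity=40,
        occupancy=0,
        workload=workload,
        balance=0.0,
        others_census={"A": 0, "C": 0},
    )


class TestPolicies:
    def test_constant_policy_prices_every_pattern(self, cfg, rng):
        pl = ConstantPolicy(cfg, "B", base=5.0).set_prices(_view(cfg), rng)
        assert set(pl.prices) == set(cfg.patterns())
        assert set(pl.prices.values()) == {5.0}

    def test_linear_with_zero_slope_reduces_to_constant(self, cfg, rng):
        v = _view(cfg, workload=12.0)
        flat = WorkloadLinearPolicy(cfg, "B", base=3.0, slope=0.0).set_prices(v, rng)
        const = ConstantPolicy(cfg, "B", base=3.0).set_prices(v, rng)
        assert flat.prices == const.prices

    def test_linear_price_formula(self, cfg, rng):
        pl = WorkloadLinearPolicy(cfg, "B", base=2.0, slope=0.5).set_prices(
            _view(cfg, workload=10.0), rng
        )
        assert set(pl.prices.values()) == {7.0}

    def test_negative_computed_price_clipped_to_zero_with_warning(self, cfg, rng):
        with pytest.warns(UserWarning, match="clipping"):
            pl = WorkloadLinearPolicy(cfg, "B", base=-5.0, slope=0.1).set_prices(
                _view(cfg, workload=1.0), rng
            )
        assert set(pl.prices.values()) == {0.0}

    def test_random_policy_within_bounds_and_seeded(self, cfg):
        pol = RandomPolicy(cfg, "B", low=1.0, high=4.0)
        pl1 = pol.set_prices(_view(cfg), tw.RandomStream(9))
        pl2 = RandomPolicy(cfg, "B", low=1.0, high=4.0).set_prices(_view(cfg), tw.RandomStream(9))
        assert pl1.prices == pl2.prices
        assert all(1.0 <= p <= 4.0 for p in pl1.prices.values())

    def test_replay_policy_reads_schedule_and_errors_on_gaps(self, cfg, rng):
        import pandas as pd

        rows = [
            {"day": 0, "ward": "B", "illness": i, "severity": s, "price": 2.5}
            for i, s in cfg.patterns()
        ]
        pol = ReplayPolicy(cfg, "B", pd.DataFrame(rows))
        assert set(pol.set_prices(_view(cfg), rng).prices.values()) == {2.5}
        with pytest.raises(ScheduleError):
            pol.set_prices(_view(cfg, day=1), rng)

    def test_ward_view_structurally_hides_other_wards_state(self, cfg):
        """The asymmetry is in the type: a view exposes no field that could
        carry another ward's workload, prices, or balance."""
        fields = {f.name for f in dataclasses.fields(WardView)}
        assert fields == {
            "day", "ward_id", "specialty", "capacity", "occupancy",
            "workload", "balance", "others_census", "price_history", "others_prices",
        }
        v = _view(cfg)
        assert v.others_prices is None  # strict default
        assert all(isinstance(n, int) for n in v.others_census.values())
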