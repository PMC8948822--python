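"""Per-100 kcal arithmetic, the NRF8.3 index and the FoP classifier."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nutrinova import (
    DEFAULT_REFERENCE_VALUES,
    FoPThresholds,
    classify_fop,
    compute_indicators,
    compute_nrf83,
    per_100kcal,
)
from nutrinova.errors import DomainError

from conftest import make_item

RV = DEFAULT_REFERENCE_VALUES
THR = FoPThresholds()


class TestPer100kcal:
    def test_basic_rescale(self):
        assert per_100kcal(200.0, 400.0) == pytest.approx(50.0)

    def test_energy_100_is_fixed_point(self):
        assert per_100kcal(3.14, 100.0) == pytest.approx(3.14)

    def test_zero_energy_is_domain_error(self):
        with pytest.raises(DomainError):
            per_100kcal(1.0, 0.0)


class TestNRF83:
    def test_zero_profile_scores_zero(self):
        assert compute_nrf83(make_item(), RV) == pytest.approx(0.0)

    def test_saturation_reaches_800(self):
        # Every qualifying nutrient at its full daily value per 100 kcal
        # (energy 100 kcal/100 g makes per-100 g == per-100 kcal).
        item = make_item(**{n: dv for n, dv in RV.qualifying.items()})
        assert compute_nrf83(item, RV) == pytest.approx(800.0)
        richer = make_item(**{n: 3 * dv for n, dv in RV.qualifying.items()})
        assert compute_nrf83(richer, RV) == pytest.approx(800.0)  # cap binds

    def test_hand_computed_profile(self):
        # protein at 50% DV, fibre at 25% DV, saturated fat at 10% MRV
        # per 100 kcal: 50 + 25 - 10 = 65.
        item = make_item(
            protein=0.5 * RV.qualifying["protein"],
            fibre=0.25 * RV.qualifying["fibre"],
            saturated_fat=0.1 * RV.limiting["saturated_fat"],
        )
        assert compute_nrf83(item, RV) == pytest.approx(65.0)

    def test_missing_nutrient_is_named(self):
        item = make_item()
        del item.nutrients["iron"]
        with pytest.raises(KeyError, match="iron"):
            compute_nrf83(item, RV)

    def test_zero_energy_is_domain_error(self):
        with pytest.raises(DomainError):
            compute_nrf83(make_item(energy=0.0), RV)

    def test_monotone_and_bounded_on_random_profiles(self):
        """Raising a qualifying nutrient below cap strictly raises the score;
        raising a limiting nutrient strictly lowers it; 800 bounds it."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            profile = {
                n: float(rng.uniform(0, 2 * dv))
                for n, dv in {**dict(RV.qualifying), **dict(RV.limiting)}.items()
            }
            energy = float(rng.uniform(20, 600))
            item = make_item(energy=energy, **profile)
            base = compute_nrf83(item, RV)
            assert base <= 800.0 + 1e-9

            q = str(rng.choice(list(RV.qualifying)))
            capped = 100.0 * per_100kcal(profile[q], energy) / RV.qualifying[q] >= 100
            bumped = make_item(energy=energy, **{**profile, q: profile[q] + 1.0})
            if capped:
                assert compute_nrf83(bumped, RV) >= base - 1e-9
            else:
                assert compute_nrf83(bumped, RV) > base

            l = str(rng.choice(list(RV.limiting)))
            worse = make_item(energy=energy, **{**profile, l: profile[l] + 1.0})
            assert compute_nrf83(worse, RV) < base

    def test_energy_scaling_divides_pre_cap_terms(self):
        """With no cap binding, scaling energy density by k divides the
        score by k (all terms are linear in 1/energy)."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            # small amounts at high energy keep every %DV below the cap
            profile = {
                n: float(rng.uniform(0, 0.05 * dv))
                for n, dv in {**dict(RV.qualifying), **dict(RV.limiting)}.items()
            }
            for k in (0.5, 2.0):
                a = compute_nrf83(make_item(energy=400.0, **profile), RV)
                b = compute_nrf83(make_item(energy=400.0 * k, **profile), RV)
                assert b == pytest.approx(a / k)


class TestFoPClassifier:
    @pytest.mark.parametrize("criterion", ["total_sugar", "total_fat",
                                           "saturated_fat", "salt"])
    @pytest.mark.parametrize("is_drink", [False, True])
    def test_boundary_is_inclusive(self, criterion, is_drink):
        table = THR.drink if is_drink else THR.food
        cutoff = table[criterion]
        at = make_item(is_drink=is_drink, **{criterion: cutoff})
        below = make_item(is_drink=is_drink, **{criterion: cutoff - 1e-9})
        assert classify_fop(at, THR) is True
        assert classify_fop(below, THR) is False

    def test_drink_below_all_thresholds_is_low(self):
        drink = make_item(is_drink=True, total_sugar=11.24)
        assert classify_fop(drink, THR) is False

    def test_salt_threshold_food_and_drink(self):
        salty = make_item(salt=1.5)
        assert classify_fop(salty, THR) is True
        as_drink = make_item(is_drink=True, salt=1.5)
        assert classify_fop(as_drink, THR) is True  # 0.75 threshold also exceeded

    def test_default_drink_thresholds_are_half_food(self):
        assert THR.drink_is_half_of_food

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        sugar=st.floats(0, 40), fat=st.floats(0, 40), sat=st.floats(0, 20),
        salt=st.floats(0, 5), bump=st.floats(0, 20),
        which=st.sampled_from(["total_sugar", "total_fat", "saturated_fat", "salt"]),
        is_drink=st.booleans(),
    )
    def test_monotone_never_flips_high_to_low(self, sugar, fat, sat, salt, bump,
                                              which, is_drink):
        base = make_item(is_drink=is_drink, total_sugar=sugar, total_fat=fat,
                         saturated_fat=sat, salt=salt)
        raised = make_item(is_drink=is_drink, **{
            **{"total_sugar": sugar, "total_fat": fat,
               "saturated_fat": sat, "salt": salt},
            which: {"total_sugar": sugar, "total_fat": fat,
                    "saturated_fat": sat, "salt": salt}[which] + bump,
        })
        if classify_fop(base, THR):
            assert classify_fop(raised, THR)


class TestComputeIndicators:
    def test_energy_100_fixed_point(self):
        item = make_item(energy=100.0, ghge=300.0, cost=0.48)
        (t,) = compute_indicators([item], RV, THR)
        assert t.ghge_100kcal == pytest.approx(300.0)
        assert t.cost_100kcal == pytest.approx(0.48)

    def test_zero_energy_item_is_dropped(self, caplog):
        items = [make_item(item_id="ok"), make_item(item_id="water", energy=0.0)]
        with caplog.at_level("INFO", logger="nutrinova.indicators"):
            triples = compute_indicators(items, RV, THR)
        assert [t.item_id for t in triples] == ["ok"]
        assert any("zero-energy" in r.message for r in caplog.records)

    def test_batch_preserves_order(self):
        items = [make_item(item_id=f"i{k}", energy=50.0 + k) for k in range(20)]
        triples = compute_indicators(items, RV, THR)
        assert [t.item_id for t in triples] == [it.item_id for it in items]
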