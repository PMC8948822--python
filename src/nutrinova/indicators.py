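"""Per-100 kcal indicators and the front-of-pack fat/salt/sugar classifier.

Three quantities are attached to every item, all on a 100-kcal basis so that
foods of very different energy density are comparable:

* NRF8.3 — nutrient-rich food index: the sum over 8 qualifying nutrients of
  percent daily value per 100 kcal (each capped, by default at 100%), minus
  the sum over 3 limiting nutrients of percent maximal reference value per
  100 kcal (uncapped). Higher is more nutrient-dense; the default maximum is
  800.
* GHGE per 100 kcal — g CO2-equivalents.
* Cost per 100 kcal — GBP.

The FoP classifier flags an item "high in fat, salt and/or sugar" when any
of total sugar, total fat, saturated fat or salt per 100 g is at or above the
UK front-of-pack threshold for its food/drink class (inclusive boundary).
"""

from __future__ import annotations

import logging
from typing import Sequence

from .config import FoPThresholds, ReferenceValues
from .databank import FoodItem, IndicatorTriple
from .errors import DomainError

log = logging.getLogger(__name__)


def per_100kcal(amount_per_100g: float, energy_kcal_100g: float) -> float:
    """Rescale a per-100 g amount to a per-100 kcal amount.

    Raises :class:`DomainError` for non-positive energy; zero-energy items
    must be excluded upstream.
    """
    if energy_kcal_100g <= 0:
        raise DomainError(
            f"per-100 kcal conversion requires energy > 0, got {energy_kcal_100g}"
        )
    return amount_per_100g * 100.0 / energy_kcal_100g


def compute_nrf83(item: FoodItem, rv: ReferenceValues) -> float:
    """NRF index of one item on a 100-kcal basis.

    score = sum_i min(cap, 100 * a_i / DV_i) - sum_j 100 * l_j / MRV_j
    with a_i, l_j the qualifying/limiting amounts per 100 kcal.
    """
    if item.energy_kcal_100g <= 0:
        raise DomainError(
            f"item {item.item_id!r}: NRF undefined at energy "
            f"{item.energy_kcal_100g} kcal/100 g"
        )
    score = 0.0
    for nutrient, dv in rv.qualifying.items():
        if nutrient not in item.nutrients:
            raise KeyError(
                f"item {item.item_id!r}: missing qualifying nutrient {nutrient!r}"
            )
        amount = per_100kcal(item.nutrients[nutrient], item.energy_kcal_100g)
        score += min(rv.cap_pct, 100.0 * amount / dv)
    for nutrient, mrv in rv.limiting.items():
        if nutrient not in item.nutrients:
            raise KeyError(
                f"item {item.item_id!r}: missing limiting nutrient {nutrient!r}"
            )
        amount = per_100kcal(item.nutrients[nutrient], item.energy_kcal_100g)
        score -= 100.0 * amount / mrv
    return score


def classify_fop(item: FoodItem, thr: FoPThresholds) -> bool:
    """True when the item is high in fat, salt and/or sugar (any criterion
    at or above its per-100 g threshold; drinks use the drink thresholds)."""
    table = thr.drink if item.is_drink else thr.food
    for nutrient, cutoff in table.items():
        if nutrient not in item.nutrients:
            raise KeyError(
                f"item {item.item_id!r}: missing FoP criterion nutrient {nutrient!r}"
            )
        if item.nutrients[nutrient] >= cutoff:
            return True
    return False


def compute_indicators(
    items: Sequence[FoodItem], rv: ReferenceValues, thr: FoPThresholds
) -> list[IndicatorTriple]:
    """Indicator triples for all items with positive energy, order preserved.

    Items with zero (or negative) energy cannot be expressed per 100 kcal;
    they are dropped and the count is logged.
    """
    triples: list[IndicatorTriple] = []
    n_zero_energy = 0
    for item in items:
        if item.energy_kcal_100g <= 0:
            n_zero_energy += 1
            continue
        triples.append(
            IndicatorTriple(
                item_id=item.item_id,
                nrf83=compute_nrf83(item, rv),
                ghge_100kcal=per_100kcal(item.ghge_g_100g, item.energy_kcal_100g),
                cost_100kcal=per_100kcal(item.cost_gbp_100g, item.energy_kcal_100g),
                high_fss=classify_fop(item, thr),
            )
        )
    if n_zero_energy:
        log.info("dropped %d zero-energy item(s) from indicator computation", n_zero_energy)
    return triples
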