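"""Analysis-set construction: exclusions and (group x NOVA x FSS) strata.

The stratified comparison keeps only NOVA categories 1, 3 and 4 and the four
food groups not dominated by a single NOVA category (fruit & vegetables,
starchy carbohydrates, proteins, dairy & alternatives, by default). Each
retained item lands in exactly one (group, NOVA) cell, in its FSS cell
("low" or "high") and in the pooled "all" FSS cell; an "all items"
pseudo-group unions the retained groups. The protein group additionally gets
a plant- vs animal-based split by sub-group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .config import AnalysisConfig
from .databank import FoodItem, IndicatorTriple
from .errors import ValidationError

#: Pseudo-group label for the union of retained food groups.
ALL_ITEMS = "all_items"
PLANT_PROTEIN = "plant_protein"
ANIMAL_PROTEIN = "animal_protein"

RETAINED_NOVAS = (1, 3, 4)
FSS_STRATA = ("all", "low", "high")

#: Exclusion reasons, in the order they are applied.
EXCLUSION_REASONS = (
    "irrelevant_category",
    "unlinked",
    "excluded_group",
    "nova2",
    "zero_energy",
)


@dataclass
class AnalysisSet:
    """Retained (item, triple) pairs, exclusion accounting, and strata."""

    retained: list[tuple[FoodItem, IndicatorTriple]]
    excluded: Counter
    strata: dict[tuple[str, str, int], list[str]] = field(default_factory=dict)

    @property
    def triples_by_id(self) -> dict[str, IndicatorTriple]:
        return {t.item_id: t for _, t in self.retained}

    @property
    def items_by_id(self) -> dict[str, FoodItem]:
        return {it.item_id: it for it, _ in self.retained}

    def group_labels(self) -> list[str]:
        return sorted({g for g, _, _ in self.strata})


def _add_to_strata(
    strata: dict[tuple[str, str, int], list[str]],
    group: str,
    item: FoodItem,
    triple: IndicatorTriple,
) -> None:
    fss = "high" if triple.high_fss else "low"
    for stratum in ("all", fss):
        strata.setdefault((group, stratum, item.nova), []).append(item.item_id)


def build_analysis_set(
    items: Sequence[FoodItem],
    triples: Sequence[IndicatorTriple],
    config: AnalysisConfig,
) -> AnalysisSet:
    """Apply the exclusion rules and build the strata.

    Rules, in order of precedence per item: pre-analysis labels
    (``irrelevant`` / ``unlinked`` in the food_group column), excluded food
    groups, NOVA 2, and zero-energy items (those with no indicator triple).
    """
    by_id = {t.item_id: t for t in triples}
    retained: list[tuple[FoodItem, IndicatorTriple]] = []
    excluded: Counter = Counter()
    strata: dict[tuple[str, str, int], list[str]] = {}
    for item in items:
        if item.food_group == "irrelevant":
            excluded["irrelevant_category"] += 1
            continue
        if item.food_group == "unlinked":
            excluded["unlinked"] += 1
            continue
        if item.food_group in config.excluded_groups:
            excluded["excluded_group"] += 1
            continue
        if item.nova == 2:
            excluded["nova2"] += 1
            continue
        triple = by_id.get(item.item_id)
        if triple is None:
            excluded["zero_energy"] += 1
            continue
        retained.append((item, triple))
        _add_to_strata(strata, item.food_group, item, triple)
        _add_to_strata(strata, ALL_ITEMS, item, triple)
    if not retained:
        raise ValidationError("analysis set is empty after exclusions")
    return AnalysisSet(retained=retained, excluded=excluded, strata=strata)


def split_protein_subgroups(
    analysis_set: AnalysisSet, config: AnalysisConfig
) -> AnalysisSet:
    """Add plant- vs animal-based protein pseudo-groups to the strata.

    Every retained protein item must map to exactly one side; an unknown
    sub-group label raises :class:`ValidationError` naming it.
    """
    plant = {s.lower() for s in config.plant_protein_subgroups}
    animal = {s.lower() for s in config.animal_protein_subgroups}
    strata = {k: list(v) for k, v in analysis_set.strata.items()}
    for item, triple in analysis_set.retained:
        if item.food_group != "protein":
            continue
        sub = item.sub_group.lower()
        if sub in plant:
            label = PLANT_PROTEIN
        elif sub in animal:
            label = ANIMAL_PROTEIN
        else:
            raise ValidationError(
                f"item {item.item_id!r}: unknown protein sub-group {item.sub_group!r}"
            )
        _add_to_strata(strata, label, item, triple)
    return AnalysisSet(
        retained=analysis_set.retained,
        excluded=analysis_set.excluded,
        strata=strata,
    )


def stratum_values(
    analysis_set: AnalysisSet,
    group: str,
    fss: str,
    nova: int,
    indicator: str,
) -> list[float]:
    """Indicator values for one stratum cell (may be empty)."""
    attr = {"nrf83": "nrf83", "ghge": "ghge_100kcal", "cost": "cost_100kcal"}[indicator]
    triples = analysis_set.triples_by_id
    ids = analysis_set.strata.get((group, fss, nova), [])
    return [getattr(triples[i], attr) for i in ids]


def exclusion_report(analysis_set: AnalysisSet) -> "Mapping[str, int]":
    """Reason -> count mapping covering every applied exclusion reason."""
    return {r: analysis_set.excluded.get(r, 0) for r in EXCLUSION_REASONS}
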