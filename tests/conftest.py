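from __future__ import annotations

import pytest

from nutrinova import AnalysisConfig, BootstrapSettings, FoodItem

#: Nutrients every test item carries (zero unless overridden).
_ALL_NUTRIENTS = (
    "protein",
    "fibre",
    "vitamin_a",
    "vitamin_c",
    "vitamin_e",
    "calcium",
    "iron",
    "potassium",
    "total_fat",
    "saturated_fat",
    "total_sugar",
    "sodium",
    "salt",
)


def make_item(
    item_id: str = "x1",
    name: str = "test item",
    food_group: str = "protein",
    sub_group: str = "meats",
    nova: int = 1,
    is_drink: bool = False,
    energy: float = 100.0,
    ghge: float = 100.0,
    cost: float = 0.5,
    **nutrients: float,
) -> FoodItem:
    """Item factory: full nutrient panel, zeros unless overridden."""
    nut = {n: 0.0 for n in _ALL_NUTRIENTS}
    nut.update(nutrients)
    return FoodItem(
        item_id=item_id,
        name=name,
        food_group=food_group,
        sub_group=sub_group,
        nova=nova,
        is_drink=is_drink,
        energy_kcal_100g=energy,
        nutrients=nut,
        ghge_g_100g=ghge,
        cost_gbp_100g=cost,
    )


@pytest.fixture
def item_factory():
    return make_item


@pytest.fixture
def config() -> AnalysisConfig:
    """Default analysis config with a small, fast bootstrap."""
    return AnalysisConfig(bootstrap=BootstrapSettings(B=200, seed=7))
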