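"""Compute the three per-100 kcal indicators for a single food item.

NRF8.3 sums the capped percent daily values of 8 qualifying nutrients and
subtracts the percent maximal reference values of 3 limiting nutrients, all
per 100 kcal; emissions and cost are simply rescaled from per-100 g to
per-100 kcal. The FoP flag applies the UK front-of-pack "high in" cut-offs.
"""

from nutrinova import AnalysisConfig, FoodItem, compute_indicators

cheddar = FoodItem(
    item_id="cheese-01",
    name="cheddar-style hard cheese",
    food_group="dairy",
    sub_group="cheese",
    nova=3,
    is_drink=False,
    energy_kcal_100g=416.0,
    nutrients={
        "protein": 25.4, "fibre": 0.0, "vitamin_a": 330.0, "vitamin_c": 0.0,
        "vitamin_e": 0.5, "calcium": 740.0, "iron": 0.3, "potassium": 76.0,
        "total_fat": 34.9, "saturated_fat": 21.7, "total_sugar": 0.1,
        "sodium": 700.0, "salt": 1.75,
    },
    ghge_g_100g=998.0,
    cost_gbp_100g=0.80,
)

cfg = AnalysisConfig()
(triple,) = compute_indicators([cheddar], cfg.reference_values, cfg.fop)

print(f"item: {cheddar.name} ({cheddar.energy_kcal_100g:.0f} kcal/100 g)")
print(f"  NRF8.3 per 100 kcal : {triple.nrf83:8.1f}")
print(f"  GHGE per 100 kcal   : {triple.ghge_100kcal:8.1f} g CO2e")
print(f"  cost per 100 kcal   : {triple.cost_100kcal:8.3f} GBP")
print(f"  high in fat/salt/sugar: {triple.high_fss}")
print(
    "\nThe NRF value nets dense protein and calcium against heavy saturated"
    "\nfat and sodium penalties; saturated fat (21.7 >= 5 g/100 g) and salt"
    "\n(1.75 >= 1.5 g/100 g) both trigger the FoP 'high' classification."
)
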