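"""Generate a small synthetic food databank and inspect its structure.

The generator emulates a UK-style nutrient databank: seven food groups with
realistic sub-groups, NOVA processing categories 1-4 in group-specific
proportions, and lognormal per-100 g energy, nutrient, emission and cost
values. The printed counts show the group/NOVA structure the downstream
analysis stratifies over.
"""

from nutrinova import default_config, generate_databank
from nutrinova.databank import items_to_frame

items, truth = generate_databank(default_config(n_items=1000, seed=42))
df = items_to_frame(items)

print(f"generated {len(df)} items, {df.columns.size} columns")
print("\nitems per food group x NOVA category:")
print(df.groupby(["food_group", "nova"]).size().unstack(fill_value=0))

# Ground truth: the population medians implied by the generating
# distributions, e.g. for minimally processed protein foods:
key = ("protein", 1, "low")
print(f"\ntrue per-100 kcal medians for {key}:")
for name, value in truth.medians[key].items():
    print(f"  {name}: {value:.3g}")
print("(these are what parameter-recovery tests compare estimates against)")
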