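"""Synthetic food-databank generator with known ground truth.

The real UK nutrient databank underlying this kind of analysis is restricted,
so the package ships a generator that emulates its structure: ~5,000 items
spread over seven food groups and their sub-groups, NOVA processing
categories 1–4 with group-specific proportions, and per-100 g energy,
nutrient, emission and cost values drawn from lognormal distributions.

Design points:

* Lognormal generative family — all indicators are positive and right-skewed
  (normality is firmly rejected on real food data), and the lognormal median
  is the closed form ``exp(location)``, which makes parameter-recovery tests
  exact.
* NOVA effects are multiplicative shifts on the per-100 g medians, so the
  per-100 kcal median of emissions or cost in a (group, NOVA) cell is
  exactly ``shifted ghge median / shifted energy median x 100`` (the ratio of
  independent lognormals is lognormal).
* High fat/salt/sugar status is NOT a label: a latent high-FSS mixture
  component boosts the drawn fat, saturated-fat, sugar and sodium medians,
  and the front-of-pack classifier is then run on the drawn composition, so
  FSS status emerges from the numbers.
* Stream order is fixed and field-major: the four categorical uniforms, then
  one standard-normal vector per value field in documented order. Appending
  a new field never perturbs earlier draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .config import FOOD_GROUPS, SALT_FROM_SODIUM, UNIT_TO_GRAMS, DEFAULT_NUTRIENT_UNITS
from .databank import FoodItem
from .errors import ConfigError

#: Value fields in draw order (after the categorical draws).
VALUE_FIELDS = (
    "energy_kcal_100g",
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
    "ghge_g_100g",
    "cost_gbp_100g",
)

NUTRIENT_FIELDS = VALUE_FIELDS[1:-2]

#: Item counts per food group in the emulated databank (total 4912).
DEFAULT_GROUP_COUNTS = {
    "fruit_veg": 800,
    "starchy": 1378,
    "protein": 1689,
    "dairy": 380,
    "drinks": 301,
    "oils_spreads": 86,
    "miscellaneous": 278,
}

#: Sub-group item counts within each group.
DEFAULT_SUBGROUP_COUNTS = {
    "fruit_veg": {
        "fruits": 193,
        "vegetables": 296,
        "juices and fruit canned in juice": 155,
        "prepared dishes based on vegetables": 156,
    },
    "starchy": {
        "cereals": 509,
        "potatoes": 163,
        "prepared dishes based on cereals": 706,
    },
    "protein": {
        "beans and pulses": 141,
        "seeds and nuts": 51,
        "oily fish": 103,
        "white fish or shellfish": 254,
        "meats": 500,
        "eggs": 53,
        "prepared dishes based on animal-based protein": 587,
    },
    "dairy": {
        "milk": 46,
        "alternative milks": 29,
        "cheese": 86,
        "yogurt": 59,
        "other dairy products and desserts": 160,
    },
    "drinks": {"soft drinks": 172, "coffee and tea": 37, "alcohol": 92},
    "oils_spreads": {"oils and spreads": 86},
    "miscellaneous": {"miscellaneous": 278},
}

#: NOVA category weights per group (normalised at construction).
DEFAULT_NOVA_WEIGHTS = {
    "fruit_veg": (46, 0, 35, 19),
    "starchy": (8, 0, 33, 59),
    "protein": (23, 0, 41, 36),
    "dairy": (14, 0, 28, 58),
    "drinks": (4, 1, 5, 95),
    "oils_spreads": (0, 95, 3, 2),
    "miscellaneous": (1, 4, 2, 93),
}

#: Baseline per-100 g medians by group, in the default declared units
#: (g for macronutrients/fibre/salt-relevant fields, mg for minerals and
#: sodium, ug for vitamin A; GHGE g CO2e; cost GBP).
DEFAULT_BASELINE_MEDIANS: dict[str, dict[str, float]] = {
    "fruit_veg": dict(
        energy_kcal_100g=60, protein=1.5, fibre=2.5, vitamin_a=100, vitamin_c=30,
        vitamin_e=1.0, calcium=30, iron=0.7, potassium=250, total_fat=0.8,
        saturated_fat=0.15, total_sugar=6.0, sodium=20, ghge_g_100g=150,
        cost_gbp_100g=0.30,
    ),
    "starchy": dict(
        energy_kcal_100g=250, protein=7.0, fibre=3.0, vitamin_a=5, vitamin_c=1.0,
        vitamin_e=0.5, calcium=50, iron=1.2, potassium=150, total_fat=3.0,
        saturated_fat=0.8, total_sugar=3.0, sodium=200, ghge_g_100g=120,
        cost_gbp_100g=0.15,
    ),
    "protein": dict(
        energy_kcal_100g=180, protein=18.0, fibre=1.5, vitamin_a=20, vitamin_c=1.0,
        vitamin_e=0.7, calcium=40, iron=1.5, potassium=300, total_fat=8.0,
        saturated_fat=2.5, total_sugar=1.0, sodium=300, ghge_g_100g=500,
        cost_gbp_100g=0.80,
    ),
    "dairy": dict(
        energy_kcal_100g=120, protein=5.0, fibre=0.2, vitamin_a=60, vitamin_c=1.0,
        vitamin_e=0.3, calcium=140, iron=0.2, potassium=180, total_fat=5.0,
        saturated_fat=3.0, total_sugar=6.0, sodium=120, ghge_g_100g=250,
        cost_gbp_100g=0.35,
    ),
    "drinks": dict(
        energy_kcal_100g=30, protein=0.3, fibre=0.1, vitamin_a=2, vitamin_c=5.0,
        vitamin_e=0.05, calcium=15, iron=0.1, potassium=60, total_fat=0.1,
        saturated_fat=0.05, total_sugar=5.0, sodium=15, ghge_g_100g=80,
        cost_gbp_100g=0.10,
    ),
    "oils_spreads": dict(
        energy_kcal_100g=700, protein=0.5, fibre=0.1, vitamin_a=400, vitamin_c=0.5,
        vitamin_e=5.0, calcium=15, iron=0.3, potassium=30, total_fat=75.0,
        saturated_fat=25.0, total_sugar=0.5, sodium=500, ghge_g_100g=400,
        cost_gbp_100g=0.60,
    ),
    "miscellaneous": dict(
        energy_kcal_100g=200, protein=2.0, fibre=1.0, vitamin_a=20, vitamin_c=2.0,
        vitamin_e=0.8, calcium=40, iron=0.8, potassium=200, total_fat=8.0,
        saturated_fat=2.0, total_sugar=15.0, sodium=800, ghge_g_100g=200,
        cost_gbp_100g=0.40,
    ),
}

#: Multiplicative median shifts by NOVA category (absent => 1). The defaults
#: reproduce the qualitative real-data pattern: higher energy density and
#: fat/salt/sugar but lower micronutrients for processed/ultra-processed
#: items, hence lower NRF8.3, GHGE and cost per 100 kcal.
DEFAULT_NOVA_EFFECTS: dict[str, dict[int, float]] = {
    "energy_kcal_100g": {3: 1.3, 4: 1.6},
    "fibre": {3: 0.85, 4: 0.7},
    "vitamin_a": {3: 0.8, 4: 0.65},
    "vitamin_c": {3: 0.8, 4: 0.65},
    "vitamin_e": {3: 0.8, 4: 0.65},
    "calcium": {3: 0.8, 4: 0.65},
    "iron": {3: 0.8, 4: 0.65},
    "potassium": {3: 0.8, 4: 0.65},
    "total_fat": {3: 1.15, 4: 1.25},
    "saturated_fat": {3: 1.2, 4: 1.35},
    "total_sugar": {3: 1.3, 4: 1.6},
    "sodium": {3: 1.3, 4: 1.5},
    "ghge_g_100g": {3: 0.95, 4: 0.9},
    "cost_gbp_100g": {3: 0.95, 4: 0.9},
}

#: Median boosts applied to the high-FSS mixture component.
DEFAULT_FSS_BOOST = {
    "total_fat": 3.5,
    "saturated_fat": 4.0,
    "total_sugar": 4.0,
    "sodium": 5.0,
}

#: Log-scale (sigma) per field.
DEFAULT_SIGMA = {f: 0.6 for f in NUTRIENT_FIELDS}
DEFAULT_SIGMA.update(
    {"energy_kcal_100g": 0.35, "ghge_g_100g": 0.5, "cost_gbp_100g": 0.5}
)


def _normalise(weights: Mapping, keys: Sequence) -> dict:
    total = float(sum(weights[k] for k in keys))
    if total <= 0:
        raise ConfigError("mixture weights must have a positive sum")
    return {k: weights[k] / total for k in keys}


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of a synthetic databank (including the seed)."""

    n_items: int = 4912
    seed: int = 0
    group_mix: Mapping[str, float] = field(
        default_factory=lambda: _normalise(DEFAULT_GROUP_COUNTS, FOOD_GROUPS)
    )
    subgroup_mix: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            g: _normalise(c, tuple(c)) for g, c in DEFAULT_SUBGROUP_COUNTS.items()
        }
    )
    nova_mix: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            g: tuple(np.asarray(w, float) / sum(w))
            for g, w in DEFAULT_NOVA_WEIGHTS.items()
        }
    )
    baseline_median: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            g: dict(v) for g, v in DEFAULT_BASELINE_MEDIANS.items()
        }
    )
    sigma: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMA))
    nova_effects: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {f: dict(e) for f, e in DEFAULT_NOVA_EFFECTS.items()}
    )
    fss_high_fraction: Mapping[str, float] = field(
        default_factory=lambda: {g: 0.25 for g in FOOD_GROUPS}
    )
    fss_boost: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FSS_BOOST)
    )

    def validate(self) -> None:
        if self.n_items < 1:
            raise ConfigError(f"n_items must be >= 1, got {self.n_items}")
        if abs(sum(self.group_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("group_mix proportions must sum to 1")
        for g, mix in self.subgroup_mix.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigError(f"subgroup_mix[{g!r}] must sum to 1")
        for g, mix in self.nova_mix.items():
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ConfigError(f"nova_mix[{g!r}] must sum to 1")
        for f, s in self.sigma.items():
            if s < 0:
                raise ConfigError(f"sigma[{f!r}] must be >= 0")
        for g, base in self.baseline_median.items():
            for f, v in base.items():
                if v <= 0:
                    raise ConfigError(f"baseline_median[{g!r}][{f!r}] must be > 0")
        for g, fr in self.fss_high_fraction.items():
            if not 0.0 <= fr <= 1.0:
                raise ConfigError(f"fss_high_fraction[{g!r}] must be in [0, 1]")


def default_config(
    n_items: int = 4912,
    seed: int = 0,
    nova_effects: Optional[Mapping[str, Mapping[int, float]]] = None,
    **overrides,
) -> SyntheticConfig:
    """Convenience constructor; ``nova_effects`` replaces the defaults
    field-by-field (pass ``{}`` for a null-effect configuration)."""
    kwargs: dict = dict(n_items=n_items, seed=seed, **overrides)
    if nova_effects is not None:
        kwargs["nova_effects"] = {f: dict(e) for f, e in nova_effects.items()}
    cfg = SyntheticConfig(**kwargs)
    cfg.validate()
    return cfg


@dataclass(frozen=True)
class GroundTruth:
    """Population medians implied by a :class:`SyntheticConfig`.

    Keyed by (group, nova, fss_component) where fss_component is "low",
    "high" (the generating mixture component) or "all". GHGE and cost per
    100 kcal are exact lognormal-ratio medians; NRF8.3 is the index evaluated
    at the median composition, an approximation (a sum of capped dependent
    ratios has no closed-form median). The "all" entry evaluates at the
    component-weighted mean of log-medians, also an approximation.
    """

    medians: Mapping[tuple[str, int, str], Mapping[str, float]]

    def to_json(self, path: str) -> None:
        payload = {
            f"{g}|{nova}|{fss}": dict(v) for (g, nova, fss), v in self.medians.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        medians = {}
        for key, v in payload.items():
            g, nova, fss = key.split("|")
            medians[(g, int(nova), fss)] = v
        return cls(medians=medians)


def _effect(config: SyntheticConfig, fld: str, nova: int) -> float:
    return config.nova_effects.get(fld, {}).get(nova, 1.0)


def true_field_median(
    config: SyntheticConfig, group: str, nova: int, fss: str, fld: str
) -> float:
    """Closed-form per-100 g median of one field in one generating cell."""
    mu = np.log(config.baseline_median[group][fld]) + np.log(
        _effect(config, fld, nova)
    )
    boost = config.fss_boost.get(fld, 1.0)
    if fss == "high":
        mu += np.log(boost)
    elif fss == "all":
        mu += config.fss_high_fraction[group] * np.log(boost)
    return float(np.exp(mu))


def true_medians(config: SyntheticConfig) -> GroundTruth:
    """Ground-truth per-100 kcal medians per (group, NOVA, FSS component)."""
    from .config import DEFAULT_REFERENCE_VALUES as rv  # default NRF8.3 table

    config.validate()
    medians: dict[tuple[str, int, str], dict[str, float]] = {}
    for group in config.group_mix:
        for nova in (1, 2, 3, 4):
            for fss in ("low", "high", "all"):
                e = true_field_median(config, group, nova, fss, "energy_kcal_100g")
                per100 = {
                    fld: true_field_median(config, group, nova, fss, fld) * 100.0 / e
                    for fld in VALUE_FIELDS
                    if fld != "energy_kcal_100g"
                }
                nrf = sum(
                    min(rv.cap_pct, 100.0 * per100[n] / dv)
                    for n, dv in rv.qualifying.items()
                ) - sum(100.0 * per100[n] / mrv for n, mrv in rv.limiting.items())
                medians[(group, nova, fss)] = {
                    "nrf83": float(nrf),
                    "ghge_100kcal": float(per100["ghge_g_100g"]),
                    "cost_100kcal": float(per100["cost_gbp_100g"]),
                }
    return GroundTruth(medians=medians)


def _pick(u: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Map uniforms to category indices through the cumulative distribution."""
    edges = np.cumsum(probs)
    edges[-1] = 1.0 + 1e-12  # guard against float round-off at the top
    return np.searchsorted(edges, u, side="right")


def generate_databank(config: SyntheticConfig) -> tuple[list[FoodItem], GroundTruth]:
    """Draw a synthetic databank; deterministic given the config (incl. seed).

    Draw order: group, sub-group, NOVA and FSS-component uniforms, then one
    standard-normal vector per value field in :data:`VALUE_FIELDS` order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_items

    groups = list(config.group_mix)
    g_idx = _pick(rng.random(n), np.array([config.group_mix[g] for g in groups]))
    group_arr = np.array(groups, dtype=object)[g_idx]

    u_sub = rng.random(n)
    sub_arr = np.empty(n, dtype=object)
    for gi, g in enumerate(groups):
        mask = g_idx == gi
        subs = list(config.subgroup_mix[g])
        probs = np.array([config.subgroup_mix[g][s] for s in subs])
        sub_arr[mask] = np.array(subs, dtype=object)[_pick(u_sub[mask], probs)]

    u_nova = rng.random(n)
    nova_arr = np.empty(n, dtype=int)
    for gi, g in enumerate(groups):
        mask = g_idx == gi
        nova_arr[mask] = 1 + _pick(u_nova[mask], np.asarray(config.nova_mix[g]))

    frac = np.array([config.fss_high_fraction[g] for g in groups])
    high_comp = rng.random(n) < frac[g_idx]

    values: dict[str, np.ndarray] = {}
    log_base = {
        g: {f: np.log(config.baseline_median[g][f]) for f in VALUE_FIELDS}
        for g in groups
    }
    for fld in VALUE_FIELDS:
        z = rng.standard_normal(n)
        mu = np.array([log_base[g][fld] for g in group_arr])
        eff = np.array([_effect(config, fld, nv) for nv in nova_arr])
        mu += np.log(eff)
        boost = config.fss_boost.get(fld, 1.0)
        if boost != 1.0:
            mu = mu + np.where(high_comp, np.log(boost), 0.0)
        values[fld] = np.exp(mu + config.sigma.get(fld, 0.0) * z)

    sodium_unit = DEFAULT_NUTRIENT_UNITS["sodium"]
    salt = SALT_FROM_SODIUM * values["sodium"] * UNIT_TO_GRAMS[sodium_unit]

    width = max(5, len(str(n)))
    items: list[FoodItem] = []
    for i in range(n):
        nutrients = {f: float(values[f][i]) for f in NUTRIENT_FIELDS}
        nutrients["salt"] = float(salt[i])
        items.append(
            FoodItem(
                item_id=f"SYN{i:0{width}d}",
                name=f"{sub_arr[i]} item {i:0{width}d}",
                food_group=str(group_arr[i]),
                sub_group=str(sub_arr[i]),
                nova=int(nova_arr[i]),
                is_drink=bool(group_arr[i] == "drinks"),
                energy_kcal_100g=float(values["energy_kcal_100g"][i]),
                nutrients=nutrients,
                ghge_g_100g=float(values["ghge_g_100g"][i]),
                cost_gbp_100g=float(values["cost_gbp_100g"][i]),
            )
        )
    return items, true_medians(config)
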