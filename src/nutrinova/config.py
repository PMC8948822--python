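"""Analysis configuration: NRF reference values, front-of-pack thresholds,
bootstrap settings, nutrient units and group-exclusion rules.

All amounts are per 100 g of food. Each nutrient has a declared unit
(``g``, ``mg`` or ``ug``); NRF daily values and maximal reference values are
expressed in the same unit as the nutrient column they refer to.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

from .errors import ConfigError

#: Eatwell-style food groups used throughout the package.
FOOD_GROUPS = (
    "fruit_veg",
    "starchy",
    "protein",
    "dairy",
    "drinks",
    "oils_spreads",
    "miscellaneous",
)

#: Special pre-analysis labels a databank row may carry instead of a food group.
SPECIAL_GROUPS = ("irrelevant", "unlinked")

#: Multiplicative factors to grams for the supported unit declarations.
UNIT_TO_GRAMS = {"g": 1.0, "mg": 1e-3, "ug": 1e-6}

#: UK convention: salt (g) = 2.5 x sodium (g).
SALT_FROM_SODIUM = 2.5


@dataclass(frozen=True)
class ReferenceValues:
    """Daily values (DV) for qualifying nutrients and maximal reference
    values (MRV) for limiting nutrients used by the NRF index.

    The default configuration is NRF8.3: eight qualifying nutrients capped at
    ``cap_pct`` percent of DV per 100 kcal, three limiting nutrients uncapped.
    Values are EU/UK adult reference intakes, in the unit each nutrient column
    is declared in.
    """

    qualifying: Mapping[str, float]
    limiting: Mapping[str, float]
    cap_pct: float = 100.0

    def validate(self) -> None:
        for name, v in {**dict(self.qualifying), **dict(self.limiting)}.items():
            if v <= 0:
                raise ConfigError(f"reference value for {name!r} must be > 0, got {v}")
        if self.cap_pct <= 0:
            raise ConfigError(f"cap_pct must be > 0, got {self.cap_pct}")

    @property
    def max_score(self) -> float:
        return self.cap_pct * len(self.qualifying)


DEFAULT_REFERENCE_VALUES = ReferenceValues(
    qualifying={
        "protein": 50.0,       # g
        "fibre": 30.0,         # g
        "vitamin_a": 800.0,    # ug RE
        "vitamin_c": 80.0,     # mg
        "vitamin_e": 12.0,     # mg
        "calcium": 800.0,      # mg
        "iron": 14.0,          # mg
        "potassium": 3500.0,   # mg
    },
    limiting={
        "saturated_fat": 20.0,  # g
        "total_sugar": 90.0,    # g
        "sodium": 2400.0,       # mg
    },
)

DEFAULT_NUTRIENT_UNITS = {
    "protein": "g",
    "fibre": "g",
    "vitamin_a": "ug",
    "vitamin_c": "mg",
    "vitamin_e": "mg",
    "calcium": "mg",
    "iron": "mg",
    "potassium": "mg",
    "total_fat": "g",
    "saturated_fat": "g",
    "total_sugar": "g",
    "sodium": "mg",
    "salt": "g",
}


@dataclass(frozen=True)
class FoPThresholds:
    """UK voluntary front-of-pack "high in" cut-offs, g per 100 g.

    A food (drink) is high in fat, salt and/or sugar when ANY criterion amount
    is at or above its threshold; the boundary is inclusive. The default drink
    thresholds are exactly half the food thresholds.
    """

    food: Mapping[str, float] = field(
        default_factory=lambda: {
            "total_sugar": 22.5,
            "total_fat": 17.5,
            "saturated_fat": 5.0,
            "salt": 1.5,
        }
    )
    drink: Mapping[str, float] = field(
        default_factory=lambda: {
            "total_sugar": 11.25,
            "total_fat": 8.75,
            "saturated_fat": 2.5,
            "salt": 0.75,
        }
    )

    def validate(self) -> None:
        if set(self.food) != set(self.drink):
            raise ConfigError("food and drink thresholds must name the same criteria")
        for m in (self.food, self.drink):
            for name, v in m.items():
                if v <= 0:
                    raise ConfigError(f"threshold for {name!r} must be > 0, got {v}")

    @property
    def drink_is_half_of_food(self) -> bool:
        return all(
            abs(self.drink[k] - self.food[k] / 2.0) < 1e-12 for k in self.food
        )


@dataclass(frozen=True)
class BootstrapSettings:
    """Resampling configuration: B replicates, two-sided level alpha, seed."""

    B: int = 10_000
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.B < 1:
            raise ConfigError(f"B must be >= 1, got {self.B}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")


#: Sub-groups of the protein food group mapped to plant- vs animal-based.
DEFAULT_PLANT_PROTEIN_SUBGROUPS = ("beans and pulses", "seeds and nuts")
DEFAULT_ANIMAL_PROTEIN_SUBGROUPS = (
    "oily fish",
    "white fish or shellfish",
    "meats",
    "eggs",
    "prepared dishes based on animal-based protein",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything a full run needs besides the databank itself."""

    reference_values: ReferenceValues = DEFAULT_REFERENCE_VALUES
    fop: FoPThresholds = field(default_factory=FoPThresholds)
    bootstrap: BootstrapSettings = field(default_factory=BootstrapSettings)
    nutrient_units: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_NUTRIENT_UNITS)
    )
    # Food groups dominated by a single NOVA category are excluded from the
    # stratified comparison; drinks and oils/spreads per the study design,
    # miscellaneous by the same single-category-dominance rationale.
    excluded_groups: tuple[str, ...] = ("drinks", "oils_spreads", "miscellaneous")
    plant_protein_subgroups: tuple[str, ...] = DEFAULT_PLANT_PROTEIN_SUBGROUPS
    animal_protein_subgroups: tuple[str, ...] = DEFAULT_ANIMAL_PROTEIN_SUBGROUPS
    delimiter: str = "\t"
    # Rendering precision for report tables, decimal places per indicator.
    precision: Mapping[str, int] = field(
        default_factory=lambda: {"nrf83": 0, "ghge": 0, "cost": 2}
    )
    # When True, composite-score medians are taken over all retained items
    # pooled rather than per food group.
    global_medians: bool = False

    def validate(self) -> None:
        self.reference_values.validate()
        self.fop.validate()
        self.bootstrap.validate()
        for n, u in self.nutrient_units.items():
            if u not in UNIT_TO_GRAMS:
                raise ConfigError(f"unknown unit {u!r} for nutrient {n!r}")
        for g in self.excluded_groups:
            if g not in FOOD_GROUPS:
                raise ConfigError(f"unknown food group in exclusion list: {g!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        """Stable sha256 of the canonical JSON form, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def load_config(path: str) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML (or JSON) file.

    Only keys present in the file override the defaults; nested mappings
    replace the corresponding default wholesale.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "reference_values" in raw:
        rv = raw["reference_values"]
        kwargs["reference_values"] = ReferenceValues(
            qualifying=dict(rv["qualifying"]),
            limiting=dict(rv["limiting"]),
            cap_pct=float(rv.get("cap_pct", 100.0)),
        )
    if "fop" in raw:
        kwargs["fop"] = FoPThresholds(
            food=dict(raw["fop"]["food"]), drink=dict(raw["fop"]["drink"])
        )
    if "bootstrap" in raw:
        b = raw["bootstrap"]
        kwargs["bootstrap"] = BootstrapSettings(
            B=int(b.get("B", 10_000)),
            alpha=float(b.get("alpha", 0.05)),
            seed=int(b.get("seed", 0)),
        )
    for key in ("nutrient_units", "precision"):
        if key in raw:
            kwargs[key] = dict(raw[key])
    for key in (
        "excluded_groups",
        "plant_protein_subgroups",
        "animal_protein_subgroups",
    ):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    for key in ("delimiter", "global_medians"):
        if key in raw:
            kwargs[key] = raw[key]
    cfg = AnalysisConfig(**kwargs)
    cfg.validate()
    return cfg


def save_config(cfg: AnalysisConfig, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
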