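"""Databank data model and I/O.

A databank is a delimited text table, one row per food or drink item, with
identity columns, group labels, a NOVA processing category, energy and
nutrient composition per 100 g, greenhouse-gas emissions (g CO2e per 100 g)
and cost (GBP per 100 g). Per-100 kcal quantities are never stored in input
files; they are always derived downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import (
    AnalysisConfig,
    FOOD_GROUPS,
    SALT_FROM_SODIUM,
    SPECIAL_GROUPS,
    UNIT_TO_GRAMS,
)
from .errors import SchemaError, ValidationError

#: Columns every databank file must carry besides the nutrient columns.
BASE_COLUMNS = (
    "item_id",
    "name",
    "food_group",
    "sub_group",
    "nova",
    "is_drink",
    "energy_kcal_100g",
    "ghge_g_100g",
    "cost_gbp_100g",
)

#: Nutrients that must be present on every item (salt/sodium reconciled on load).
REQUIRED_NUTRIENTS = ("total_fat", "saturated_fat", "total_sugar")

VALID_GROUPS = set(FOOD_GROUPS) | set(SPECIAL_GROUPS)


@dataclass
class FoodItem:
    """One databank row: identity, labels, and per-100 g composition."""

    item_id: str
    name: str
    food_group: str
    sub_group: str
    nova: int
    is_drink: bool
    energy_kcal_100g: float
    nutrients: dict[str, float]
    ghge_g_100g: float
    cost_gbp_100g: float


@dataclass(frozen=True)
class IndicatorTriple:
    """The three per-100 kcal indicators plus the FoP classification."""

    item_id: str
    nrf83: float
    ghge_100kcal: float
    cost_100kcal: float
    high_fss: bool


@dataclass
class StratumEstimate:
    """Bootstrapped summary for one (group, FSS stratum, NOVA, indicator) cell.

    ``diff_vs_nova1`` and its CI are None for the NOVA 1 reference cell and
    for cells where either arm is empty. ``significant`` is True exactly when
    the difference CI excludes zero.
    """

    food_group: str
    fss_stratum: str  # "all", "low" or "high"
    nova: int
    indicator: str  # "nrf83", "ghge" or "cost"
    n: int
    raw_median: Optional[float] = None
    boot_median: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    diff_vs_nova1: Optional[float] = None
    diff_ci_low: Optional[float] = None
    diff_ci_high: Optional[float] = None
    significant: bool = False


def validate_item(item: FoodItem) -> list[str]:
    """Return human-readable invariant violations for one item.

    Total: never raises, whatever the field contents; an empty list means the
    item satisfies every databank invariant.
    """
    out: list[str] = []
    try:
        if item.food_group not in VALID_GROUPS:
            out.append(f"food_group: unknown group {item.food_group!r}")
        if not (isinstance(item.nova, (int, np.integer)) and item.nova in (1, 2, 3, 4)):
            out.append(f"nova: must be an integer in 1..4, got {item.nova!r}")
        for fname in ("energy_kcal_100g", "ghge_g_100g", "cost_gbp_100g"):
            v = getattr(item, fname)
            if not np.isfinite(v) or v < 0:
                out.append(f"{fname}: must be a finite non-negative number, got {v!r}")
        nutrients = item.nutrients if isinstance(item.nutrients, dict) else {}
        if not isinstance(item.nutrients, dict):
            out.append("nutrients: must be a mapping")
        for n in REQUIRED_NUTRIENTS:
            if n not in nutrients:
                out.append(f"nutrients: missing required nutrient {n!r}")
        if "sodium" not in nutrients and "salt" not in nutrients:
            out.append("nutrients: needs at least one of 'sodium' or 'salt'")
        for n, v in nutrients.items():
            try:
                if not np.isfinite(v) or v < 0:
                    out.append(f"nutrients[{n}]: must be finite and >= 0, got {v!r}")
            except TypeError:
                out.append(f"nutrients[{n}]: not a number: {v!r}")
    except Exception as exc:  # pragma: no cover - totality guard
        out.append(f"item: malformed ({exc})")
    return out


def _sodium_grams(amount: float, unit: str) -> float:
    return amount * UNIT_TO_GRAMS[unit]


def reconcile_salt_sodium(
    nutrients: dict[str, float], config: AnalysisConfig, item_id: str = "?"
) -> dict[str, float]:
    """Ensure both ``salt`` (g) and ``sodium`` (declared unit) are present.

    salt = 2.5 x sodium expressed in grams. When both columns are given and
    disagree by more than 5%, a warning is emitted and the salt value wins
    (sodium is recomputed from it).
    """
    sodium_unit = config.nutrient_units.get("sodium", "mg")
    has_salt = "salt" in nutrients
    has_sodium = "sodium" in nutrients
    out = dict(nutrients)
    if has_salt and has_sodium:
        implied_salt = SALT_FROM_SODIUM * _sodium_grams(out["sodium"], sodium_unit)
        if out["salt"] > 0 and abs(out["salt"] - implied_salt) / out["salt"] > 0.05:
            warnings.warn(
                f"item {item_id}: salt ({out['salt']:.3g} g) and sodium imply "
                f"inconsistent values (sodium implies {implied_salt:.3g} g salt); "
                "keeping the salt column",
                stacklevel=2,
            )
            out["sodium"] = (out["salt"] / SALT_FROM_SODIUM) / UNIT_TO_GRAMS[sodium_unit]
    elif has_sodium:
        out["salt"] = SALT_FROM_SODIUM * _sodium_grams(out["sodium"], sodium_unit)
    elif has_salt:
        out["sodium"] = (out["salt"] / SALT_FROM_SODIUM) / UNIT_TO_GRAMS[sodium_unit]
    return out


def _detect_sep(path: str | Path, config: AnalysisConfig) -> str:
    p = str(path)
    if p.endswith(".csv"):
        return ","
    return config.delimiter


def load_databank(path: str | Path, config: AnalysisConfig) -> list[FoodItem]:
    """Read a databank file into validated :class:`FoodItem` rows.

    Raises :class:`SchemaError` naming the first missing required column and
    :class:`ValidationError` naming the offending row for invariant breaches.
    Row order is preserved.
    """
    df = pd.read_csv(path, sep=_detect_sep(path, config), dtype={"item_id": str})
    for col in BASE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"databank is missing required column {col!r}")
    nutrient_cols = [c for c in config.nutrient_units if c in df.columns]
    for n in REQUIRED_NUTRIENTS:
        if n not in nutrient_cols:
            raise SchemaError(f"databank is missing required nutrient column {n!r}")
    if "sodium" not in nutrient_cols and "salt" not in nutrient_cols:
        raise SchemaError("databank needs a 'sodium' or a 'salt' column")

    items: list[FoodItem] = []
    for _, row in df.iterrows():
        nutrients = {
            n: float(row[n]) for n in nutrient_cols if pd.notna(row[n])
        }
        nutrients = reconcile_salt_sodium(nutrients, config, str(row["item_id"]))
        item = FoodItem(
            item_id=str(row["item_id"]),
            name=str(row["name"]),
            food_group=str(row["food_group"]),
            sub_group=str(row["sub_group"]),
            nova=int(row["nova"]),
            is_drink=bool(row["is_drink"]),
            energy_kcal_100g=float(row["energy_kcal_100g"]),
            nutrients=nutrients,
            ghge_g_100g=float(row["ghge_g_100g"]),
            cost_gbp_100g=float(row["cost_gbp_100g"]),
        )
        problems = validate_item(item)
        if problems:
            raise ValidationError(
                f"item {item.item_id!r}: " + "; ".join(problems)
            )
        items.append(item)
    return items


def items_to_frame(items: Sequence[FoodItem]) -> pd.DataFrame:
    """Tabular view of a databank, nutrient columns in first-seen order."""
    nutrient_order: list[str] = []
    for it in items:
        for n in it.nutrients:
            if n not in nutrient_order:
                nutrient_order.append(n)
    rows = []
    for it in items:
        row: dict = {
            "item_id": it.item_id,
            "name": it.name,
            "food_group": it.food_group,
            "sub_group": it.sub_group,
            "nova": it.nova,
            "is_drink": it.is_drink,
            "energy_kcal_100g": it.energy_kcal_100g,
            "ghge_g_100g": it.ghge_g_100g,
            "cost_gbp_100g": it.cost_gbp_100g,
        }
        for n in nutrient_order:
            row[n] = it.nutrients.get(n, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def write_databank(
    items: Sequence[FoodItem], path: str | Path, config: AnalysisConfig
) -> None:
    """Write items as a delimited text file (inverse of :func:`load_databank`)."""
    df = items_to_frame(items)
    df.to_csv(path, sep=_detect_sep(path, config), index=False)


# --------------------------------------------------------------------------
# Report tables
# --------------------------------------------------------------------------

_INDICATOR_UNITS = {
    "nrf83": "NRF8.3 points/100 kcal",
    "ghge": "g CO2e/100 kcal",
    "cost": "GBP/100 kcal",
}


def _fmt(x: Optional[float], dp: int) -> str:
    if x is None:
        return "NA"
    return f"{x:.{dp}f}"


def _median_ci(est: StratumEstimate, dp: int) -> str:
    if est.n == 0 or est.boot_median is None:
        return "NA"
    return f"{_fmt(est.boot_median, dp)} [{_fmt(est.ci_low, dp)}, {_fmt(est.ci_high, dp)}]"


def _diff_ci(est: StratumEstimate, dp: int) -> str:
    if est.diff_vs_nova1 is None:
        return "NA"
    s = (
        f"{_fmt(est.diff_vs_nova1, dp)} "
        f"[{_fmt(est.diff_ci_low, dp)}, {_fmt(est.diff_ci_high, dp)}]"
    )
    return s + " *" if est.significant else s


def summary_frame(
    estimates: Sequence[StratumEstimate], indicator: str, precision: Mapping[str, int]
) -> pd.DataFrame:
    """One row per (group, FSS stratum); NOVA 1/3/4 medians, CIs, differences.

    Columns (10): food_group, fss_stratum, n_nova1, nova1_median_ci,
    n_nova3, nova3_median_ci, diff_nova3_ci, n_nova4, nova4_median_ci,
    diff_nova4_ci. Significant differences carry a trailing ``*``.
    """
    dp = precision.get(indicator, 2)
    cells: dict[tuple[str, str], dict[int, StratumEstimate]] = {}
    order: list[tuple[str, str]] = []
    for e in estimates:
        if e.indicator != indicator:
            continue
        key = (e.food_group, e.fss_stratum)
        if key not in cells:
            cells[key] = {}
            order.append(key)
        cells[key][e.nova] = e
    rows = []
    for group, fss in order:
        by_nova = cells[(group, fss)]
        row: dict = {"food_group": group, "fss_stratum": fss}
        for nova in (1, 3, 4):
            e = by_nova.get(
                nova,
                StratumEstimate(group, fss, nova, indicator, n=0),
            )
            row[f"n_nova{nova}"] = e.n
            row[f"nova{nova}_median_ci"] = _median_ci(e, dp)
            if nova != 1:
                row[f"diff_nova{nova}_ci"] = _diff_ci(e, dp)
        rows.append(row)
    cols = [
        "food_group",
        "fss_stratum",
        "n_nova1",
        "nova1_median_ci",
        "n_nova3",
        "nova3_median_ci",
        "diff_nova3_ci",
        "n_nova4",
        "nova4_median_ci",
        "diff_nova4_ci",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_summary_tables(
    estimates: Sequence[StratumEstimate],
    scores: Optional[Mapping[str, pd.DataFrame]],
    outdir: str | Path,
    config: Optional[AnalysisConfig] = None,
) -> list[Path]:
    """Write one TSV per indicator (plus score summaries when given).

    Returns the list of written paths. An empty estimate list is an error.
    """
    if not estimates:
        raise ValueError("no stratum estimates to write")
    config = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for indicator in ("nrf83", "ghge", "cost"):
        df = summary_frame(estimates, indicator, config.precision)
        if df.empty:
            continue
        path = outdir / f"stratum_{indicator}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
    if scores:
        for name, df in scores.items():
            path = outdir / f"score_{name}.tsv"
            df.to_csv(path, sep="\t", index=False)
            written.append(path)
    return written


def write_item_results(
    triples: Iterable[IndicatorTriple],
    records: Optional[Iterable] = None,
    path: str | Path = "item_indicators.tsv",
) -> Path:
    """Per-item TSV of indicator triples, joined with composite scores if given."""
    tri = pd.DataFrame(
        [
            {
                "item_id": t.item_id,
                "nrf83": t.nrf83,
                "ghge_100kcal": t.ghge_100kcal,
                "cost_100kcal": t.cost_100kcal,
                "high_fss": t.high_fss,
            }
            for t in triples
        ]
    )
    if records is not None:
        rec = pd.DataFrame(
            [
                {
                    "item_id": r.item_id,
                    "group_label": r.group_label,
                    "points_nrf": r.points_nrf,
                    "points_ghge": r.points_ghge,
                    "points_cost": r.points_cost,
                    "score": r.score,
                }
                for r in records
            ]
        )
        tri = tri.merge(rec, on="item_id", how="left")
    path = Path(path)
    tri.to_csv(path, sep="\t", index=False)
    return path
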