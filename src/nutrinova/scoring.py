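"""Masset-style 0–3 composite score and its distribution summaries.

Each retained item earns one point for greenhouse-gas emissions per 100 kcal
strictly under its food group's median, one point for cost strictly under
the group median, and one point for an NRF8.3 value strictly above the group
median. Ties at a median earn no point, so a group of identical items scores
0 throughout. Items scoring 3 are the most nutritious, lowest-emission,
cheapest options of their group.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .databank import FoodItem, IndicatorTriple
from .errors import DomainError
from .stratify import AnalysisSet

#: Label used when scoring against pooled (not per-group) medians.
GLOBAL = "__global__"


@dataclass(frozen=True)
class ScoreRecord:
    item_id: str
    group_label: str
    points_nrf: int
    points_ghge: int
    points_cost: int

    @property
    def score(self) -> int:
        return self.points_nrf + self.points_ghge + self.points_cost


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (so 11.45 -> 11.5, not banker's 11.4)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def group_medians(
    pairs: Sequence[tuple[FoodItem, IndicatorTriple]],
    global_medians: bool = False,
) -> dict[str, dict[str, float]]:
    """Plain medians of the three indicators per food group (FSS strata and
    NOVA categories pooled), or pooled over all items when ``global_medians``.
    """
    if not pairs:
        raise DomainError("group_medians requires a non-empty analysis set")
    buckets: dict[str, dict[str, list[float]]] = {}
    for item, triple in pairs:
        label = GLOBAL if global_medians else item.food_group
        b = buckets.setdefault(label, {"nrf83": [], "ghge": [], "cost": []})
        b["nrf83"].append(triple.nrf83)
        b["ghge"].append(triple.ghge_100kcal)
        b["cost"].append(triple.cost_100kcal)
    return {
        label: {k: float(np.median(v)) for k, v in vals.items()}
        for label, vals in buckets.items()
    }


def score_items(
    pairs: Sequence[tuple[FoodItem, IndicatorTriple]],
    medians: Mapping[str, Mapping[str, float]],
) -> list[ScoreRecord]:
    """Score every item against its group's medians (strict inequalities)."""
    records: list[ScoreRecord] = []
    pooled = GLOBAL in medians
    for item, triple in pairs:
        label = GLOBAL if pooled else item.food_group
        if label not in medians:
            raise DomainError(
                f"item {item.item_id!r}: no medians for group {label!r}"
            )
        m = medians[label]
        records.append(
            ScoreRecord(
                item_id=item.item_id,
                group_label=label,
                points_nrf=int(triple.nrf83 > m["nrf83"]),
                points_ghge=int(triple.ghge_100kcal < m["ghge"]),
                points_cost=int(triple.cost_100kcal < m["cost"]),
            )
        )
    return records


def score_distribution(
    records: Sequence[ScoreRecord],
    analysis_set: Optional[AnalysisSet] = None,
    triples: Optional[Sequence[IndicatorTriple]] = None,
) -> dict[str, pd.DataFrame]:
    """Distribution summaries of the composite score.

    Returns three frames:

    * ``summary`` — per FSS stratum: item count, count scoring 3, and the
      percentage of maximum scorers (1 decimal, half-up).
    * ``by_nova`` — among each stratum's maximum scorers, the percentage in
      each NOVA category.
    * ``by_group`` — likewise by food group.

    FSS status and NOVA/group labels come from ``analysis_set`` (or, for the
    FSS split alone, a plain ``triples`` sequence).
    """
    if analysis_set is not None:
        fss = {t.item_id: t.high_fss for _, t in analysis_set.retained}
        nova = {it.item_id: it.nova for it, _ in analysis_set.retained}
        group = {it.item_id: it.food_group for it, _ in analysis_set.retained}
    elif triples is not None:
        fss = {t.item_id: t.high_fss for t in triples}
        nova, group = {}, {}
    else:
        raise DomainError("score_distribution needs an analysis set or triples")

    strata = {"high": [], "low": []}
    for r in records:
        strata["high" if fss[r.item_id] else "low"].append(r)

    summary_rows, nova_rows, group_rows = [], [], []
    for label in ("high", "low"):
        recs = strata[label]
        top = [r for r in recs if r.score == 3]
        pct = round_half_up(100.0 * len(top) / len(recs), 1) if recs else 0.0
        summary_rows.append(
            {
                "fss_stratum": label,
                "n": len(recs),
                "n_score3": len(top),
                "pct_score3": pct,
            }
        )
        if top and nova:
            for nv in sorted({nova[r.item_id] for r in top}):
                k = sum(nova[r.item_id] == nv for r in top)
                nova_rows.append(
                    {
                        "fss_stratum": label,
                        "nova": nv,
                        "n_score3": k,
                        "pct_of_score3": round_half_up(100.0 * k / len(top), 1),
                    }
                )
        if top and group:
            for g in sorted({group[r.item_id] for r in top}):
                k = sum(group[r.item_id] == g for r in top)
                group_rows.append(
                    {
                        "fss_stratum": label,
                        "food_group": g,
                        "n_score3": k,
                        "pct_of_score3": round_half_up(100.0 * k / len(top), 1),
                    }
                )
    return {
        "summary": pd.DataFrame(
            summary_rows, columns=["fss_stratum", "n", "n_score3", "pct_score3"]
        ),
        "by_nova": pd.DataFrame(
            nova_rows, columns=["fss_stratum", "nova", "n_score3", "pct_of_score3"]
        ),
        "by_group": pd.DataFrame(
            group_rows,
            columns=["fss_stratum", "food_group", "n_score3", "pct_of_score3"],
        ),
    }
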