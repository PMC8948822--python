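"""End-to-end orchestration: load/generate -> indicators -> strata ->
bootstrap -> composite score -> report files, with a run manifest.

A run is fully deterministic given (analysis config, input or synthetic
config): the generator is seeded by the synthetic config, the bootstrap by
the analysis config. Every stage's counts are reconciled in the manifest
(loaded = excluded-by-reason + retained).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .databank import (
    FoodItem,
    load_databank,
    write_databank,
    write_item_results,
    write_summary_tables,
)
from .errors import NutrinovaError
from .indicators import compute_indicators
from .scoring import group_medians, score_distribution, score_items
from .stats import summarize_stratum
from .stratify import (
    build_analysis_set,
    exclusion_report,
    split_protein_subgroups,
)
from .synthetic import SyntheticConfig, generate_databank

log = logging.getLogger(__name__)

INDICATORS = ("nrf83", "ghge", "cost")


@dataclass
class RunManifest:
    """Audit record for one pipeline run."""

    config_hash: str
    seed: int
    B: int
    input: str
    software_version: str = __version__
    loaded: int = 0
    excluded: Mapping[str, int] = field(default_factory=dict)
    included: int = 0  # loaded minus pre-analysis removals
    retained: int = 0
    strata_sizes: Mapping[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.loaded != sum(self.excluded.values()) + self.retained:
            raise NutrinovaError(
                f"manifest counts do not reconcile: loaded={self.loaded}, "
                f"excluded={sum(self.excluded.values())}, retained={self.retained}"
            )

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "B": self.B,
            "input": self.input,
            "software_version": self.software_version,
            "loaded": self.loaded,
            "excluded": dict(self.excluded),
            "included": self.included,
            "retained": self.retained,
            "strata_sizes": dict(self.strata_sizes),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def run_pipeline(
    config: AnalysisConfig,
    source: Union[str, Path, SyntheticConfig, Sequence[FoodItem]],
    outdir: Union[str, Path],
    protein_split: bool = True,
) -> RunManifest:
    """Run the whole analysis and write all result files into ``outdir``.

    ``source`` may be a databank file path, a :class:`SyntheticConfig`
    (the databank and its ground truth are then generated and written), or an
    already-loaded item list.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if isinstance(source, SyntheticConfig):
        items, truth = generate_databank(source)
        write_databank(items, outdir / "databank.tsv", config)
        truth.to_json(str(outdir / "truth.json"))
        input_desc = f"synthetic(n={source.n_items}, seed={source.seed})"
    elif isinstance(source, (str, Path)):
        items = load_databank(source, config)
        input_desc = str(source)
    else:
        items = list(source)
        input_desc = f"in-memory({len(items)} items)"
    log.info("stage load: %d items", len(items))

    triples = compute_indicators(items, config.reference_values, config.fop)
    log.info("stage indicators: %d triples (%d zero-energy dropped)",
             len(triples), len(items) - len(triples))

    aset = build_analysis_set(items, triples, config)
    if protein_split and any(it.food_group == "protein" for it, _ in aset.retained):
        aset = split_protein_subgroups(aset, config)
    excl = exclusion_report(aset)
    log.info("stage stratify: retained %d, excluded %s", len(aset.retained), dict(excl))

    estimates = []
    for indicator in INDICATORS:
        estimates.extend(summarize_stratum(aset, indicator, config.bootstrap))

    medians = group_medians(aset.retained, global_medians=config.global_medians)
    records = score_items(aset.retained, medians)
    scores = score_distribution(records, analysis_set=aset)

    write_summary_tables(estimates, scores, outdir, config)
    write_item_results(
        [t for _, t in aset.retained], records, outdir / "item_indicators.tsv"
    )
    pd.DataFrame(
        [{"reason": r, "count": c} for r, c in excl.items()]
    ).to_csv(outdir / "exclusions.tsv", sep="\t", index=False)

    manifest = RunManifest(
        config_hash=config.content_hash(),
        seed=config.bootstrap.seed,
        B=config.bootstrap.B,
        input=input_desc,
        loaded=len(items),
        excluded=dict(excl),
        included=len(items) - excl["irrelevant_category"] - excl["unlinked"],
        retained=len(aset.retained),
        strata_sizes={
            f"{g}|{fss}|{nova}": len(ids)
            for (g, fss, nova), ids in sorted(aset.strata.items())
        },
    )
    manifest.validate()
    manifest.to_json(outdir / "manifest.json")
    return manifest
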