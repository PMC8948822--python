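"""Bootstrapped medians, median differences vs NOVA 1, and auxiliary tests.

The inferential core of the analysis: for each stratum cell the median is
bootstrapped (B same-size resamples with replacement), and the NOVA 3 vs 1
and NOVA 4 vs 1 contrasts are formed per replicate as the difference of the
two arms' resampled medians (arms resampled independently — they are
disjoint item sets). Confidence intervals are percentile intervals of the B
draws; a difference is significant when its CI excludes zero.

Kruskal–Wallis and Shapiro–Wilk delegate to scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .config import BootstrapSettings
from .databank import StratumEstimate
from .errors import DomainError
from .stratify import AnalysisSet, RETAINED_NOVAS, FSS_STRATA, stratum_values

#: Largest sample passed to the Shapiro–Wilk routine; bigger samples are
#: subsampled (the test's small-sample calibration degrades far beyond this).
SHAPIRO_MAX_N = 5000


@dataclass(frozen=True)
class BootstrapResult:
    boot_median: float
    ci_low: float
    ci_high: float
    draws: np.ndarray


@dataclass(frozen=True)
class BootstrapDifference:
    diff: float
    ci_low: float
    ci_high: float
    significant: bool
    raw_diff: float
    draws: np.ndarray


def _resampled_medians(
    values: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    n = values.size
    idx = rng.integers(0, n, size=(B, n))
    return np.median(values[idx], axis=1)


def bootstrap_median(
    values: Sequence[float],
    settings: BootstrapSettings,
    rng: Optional[np.random.Generator] = None,
) -> BootstrapResult:
    """Bootstrap the sample median: point estimate and percentile CI.

    The point estimate is the median of the B resampled medians. Even-sized
    resamples use the mean-of-central-order-statistics median convention.
    Deterministic given ``settings.seed`` (or a caller-supplied generator).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DomainError("bootstrap_median requires at least one value")
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    draws = _resampled_medians(values, settings.B, rng)
    lo, hi = np.quantile(draws, [settings.alpha / 2, 1 - settings.alpha / 2])
    return BootstrapResult(float(np.median(draws)), float(lo), float(hi), draws)


def bootstrap_median_difference(
    values_nova1: Sequence[float],
    values_novak: Sequence[float],
    settings: BootstrapSettings,
    rng: Optional[np.random.Generator] = None,
) -> BootstrapDifference:
    """Bootstrap the difference of medians (comparison arm minus NOVA 1).

    Per replicate both arms are resampled independently and the difference of
    their medians recorded; the estimate is the median of the B differences,
    the CI its percentile interval, and significance means the CI excludes
    zero.
    """
    v1 = np.asarray(values_nova1, dtype=float)
    vk = np.asarray(values_novak, dtype=float)
    if v1.size == 0 or vk.size == 0:
        raise DomainError("bootstrap_median_difference requires non-empty arms")
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    d = _resampled_medians(vk, settings.B, rng) - _resampled_medians(
        v1, settings.B, rng
    )
    lo, hi = np.quantile(d, [settings.alpha / 2, 1 - settings.alpha / 2])
    return BootstrapDifference(
        diff=float(np.median(d)),
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(lo > 0 or hi < 0),
        raw_diff=float(np.median(vk) - np.median(v1)),
        draws=d,
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected mid-ranks) and chi-square p-value."""
    if len(groups) < 2:
        raise DomainError("kruskal_wallis needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise DomainError("kruskal_wallis: every group must be non-empty")
    if sum(a.size for a in arrays) < 3:
        raise DomainError("kruskal_wallis needs total n >= 3")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # All observations identical: no evidence of any difference.
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def shapiro_wilk(
    values: Sequence[float], seed: Optional[int] = None
) -> tuple[float, float]:
    """Shapiro–Wilk normality test (W, p).

    Requires n >= 3. Samples larger than :data:`SHAPIRO_MAX_N` are subsampled
    without replacement using ``seed``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise DomainError(f"shapiro_wilk needs n >= 3, got n = {values.size}")
    if values.size > SHAPIRO_MAX_N:
        rng = np.random.default_rng(seed)
        values = rng.choice(values, size=SHAPIRO_MAX_N, replace=False)
    w, p = sps.shapiro(values)
    return float(w), float(p)


def summarize_stratum(
    analysis_set: AnalysisSet,
    indicator: str,
    settings: BootstrapSettings,
    groups: Optional[Sequence[str]] = None,
) -> list[StratumEstimate]:
    """Bootstrapped medians and NOVA 3/4-vs-1 contrasts for one indicator.

    One :class:`StratumEstimate` per (group, FSS stratum, NOVA) cell. Strata
    are processed in sorted key order with a single generator seeded from
    ``settings.seed``, so results do not depend on input row order. Empty
    cells yield an ``n=0`` row with absent estimates rather than an error.
    """
    rng = np.random.default_rng(settings.seed)
    group_list = sorted(groups) if groups is not None else analysis_set.group_labels()
    out: list[StratumEstimate] = []
    for group in group_list:
        for fss in FSS_STRATA:
            results: dict[int, tuple[list[float], Optional[BootstrapResult]]] = {}
            for nova in RETAINED_NOVAS:
                # sorted so draws do not depend on databank row order
                vals = sorted(stratum_values(analysis_set, group, fss, nova, indicator))
                res = (
                    bootstrap_median(vals, settings, rng) if len(vals) > 0 else None
                )
                results[nova] = (vals, res)
            ref_vals, ref_res = results[1]
            for nova in RETAINED_NOVAS:
                vals, res = results[nova]
                est = StratumEstimate(
                    food_group=group,
                    fss_stratum=fss,
                    nova=nova,
                    indicator=indicator,
                    n=len(vals),
                )
                if res is not None:
                    est.raw_median = float(np.median(vals))
                    est.boot_median = res.boot_median
                    est.ci_low = res.ci_low
                    est.ci_high = res.ci_high
                if nova != 1 and res is not None and ref_res is not None:
                    d = res.draws - ref_res.draws
                    lo, hi = np.quantile(
                        d, [settings.alpha / 2, 1 - settings.alpha / 2]
                    )
                    est.diff_vs_nova1 = float(np.median(d))
                    est.diff_ci_low = float(lo)
                    est.diff_ci_high = float(hi)
                    est.significant = bool(lo > 0 or hi < 0)
                out.append(est)
    return out
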