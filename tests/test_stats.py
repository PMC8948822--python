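"""Bootstrap machinery and the auxiliary rank/normality tests."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from nutrinova import (
    AnalysisConfig,
    BootstrapSettings,
    FoPThresholds,
    bootstrap_median,
    bootstrap_median_difference,
    build_analysis_set,
    compute_indicators,
    kruskal_wallis,
    shapiro_wilk,
    summarize_stratum,
)
from nutrinova.config import DEFAULT_REFERENCE_VALUES as RV
from nutrinova.errors import DomainError

from conftest import make_item

SET = BootstrapSettings(B=2000, seed=11)


class TestBootstrapMedian:
    def test_constant_data_collapses_to_point_mass(self):
        res = bootstrap_median([5.0] * 12, SET)
        assert (res.boot_median, res.ci_low, res.ci_high) == (5.0, 5.0, 5.0)
        assert np.all(res.draws == 5.0)

    def test_seed_determinism(self):
        a = bootstrap_median(list(range(30)), SET)
        b = bootstrap_median(list(range(30)), SET)
        assert np.array_equal(a.draws, b.draws)

    def test_one_to_nine_estimate_and_ci(self):
        res = bootstrap_median(list(range(1, 10)), SET)
        assert 3.0 <= res.boot_median <= 7.0
        assert res.ci_low <= 5.0 <= res.ci_high

    def test_empty_input_is_error(self):
        with pytest.raises(DomainError):
            bootstrap_median([], SET)


class TestBootstrapDifference:
    def test_identical_constant_arms(self):
        res = bootstrap_median_difference([5.0] * 8, [5.0] * 8, SET)
        assert (res.diff, res.ci_low, res.ci_high) == (0.0, 0.0, 0.0)
        assert not res.significant

    def test_constant_shift_is_recovered_exactly(self):
        res = bootstrap_median_difference([5.0] * 8, [15.0] * 10, SET)
        assert (res.diff, res.ci_low, res.ci_high) == (10.0, 10.0, 10.0)
        assert res.significant

    def test_sign_convention_is_arm2_minus_arm1(self):
        res = bootstrap_median_difference([10.0] * 5, [3.0] * 5, SET)
        assert res.diff == -7.0 and res.raw_diff == -7.0

    def test_empty_arm_is_error(self):
        with pytest.raises(DomainError):
            bootstrap_median_difference([], [1.0], SET)


def _hand_h(groups: list[list[float]]) -> float:
    """Independent mid-rank H with tie correction (textbook formula)."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n = pooled.size
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-rank of the tie block
        i = j
    offsets = np.cumsum([0] + [len(g) for g in groups])
    h = 12.0 / (n * (n + 1)) * sum(
        ranks[offsets[k]:offsets[k + 1]].sum() ** 2 / len(g)
        for k, g in enumerate(groups)
    ) - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / correction


class TestKruskalWallis:
    def test_hand_value_on_two_triples(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(3.857, abs=1e-3)
        assert 0 < p < 1

    def test_identical_groups_give_zero(self):
        h, _ = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_constant_data(self):
        h, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert h == 0.0 and p == 1.0

    def test_invariant_under_monotone_transform(self):
        g1, g2 = [0.3, 2.0, 5.5, 9.1], [1.2, 4.4, 7.7]
        h1, _ = kruskal_wallis([g1, g2])
        h2, _ = kruskal_wallis([np.exp(g1), np.exp(g2)])
        assert h1 == pytest.approx(h2)

    def test_exhaustive_small_cases_match_hand_formula(self):
        """All 2-group splits of small pooled samples (with ties) agree with
        the hand-computed tie-corrected rank statistic."""
        for pooled in ([1, 2, 3, 4, 5, 6], [1, 1, 2, 3, 3, 4], [2, 2, 2, 3, 5]):
            n = len(pooled)
            for size1 in range(1, n):
                for idx in combinations(range(n), size1):
                    g1 = [pooled[i] for i in idx]
                    g2 = [pooled[i] for i in range(n) if i not in idx]
                    if all(v == pooled[0] for v in pooled):
                        continue
                    h, _ = kruskal_wallis([g1, g2])
                    assert h == pytest.approx(_hand_h([g1, g2]), abs=1e-9)

    def test_empty_group_is_error(self):
        with pytest.raises(DomainError):
            kruskal_wallis([[1.0], []])


class TestShapiroWilk:
    def test_normal_samples_rarely_rejected(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=400)
            _, p = shapiro_wilk(x)
            hits += p > 0.05
        assert hits >= 18  # >= 90% of seeded repeats

    def test_exponential_samples_always_rejected(self):
        for seed in range(20):
            x = np.random.default_rng(seed).exponential(size=500)
            _, p = shapiro_wilk(x)
            assert p < 0.05

    def test_large_sample_is_subsampled_not_an_error(self):
        x = np.random.default_rng(0).normal(size=8000)
        w, p = shapiro_wilk(x, seed=1)
        assert 0 < w <= 1

    def test_too_small_sample_is_error(self):
        with pytest.raises(DomainError):
            shapiro_wilk([1.0, 2.0])


class TestSummarizeStratum:
    def _aset(self, items):
        cfg = AnalysisConfig()
        triples = compute_indicators(items, RV, FoPThresholds())
        return build_analysis_set(items, triples, cfg)

    def test_single_item_strata_have_zero_width_cis(self):
        items = [
            make_item(item_id="a", nova=1, cost=0.5),
            make_item(item_id="b", nova=3, cost=0.3),
            make_item(item_id="c", nova=4, cost=0.2),
        ]
        ests = summarize_stratum(self._aset(items), "cost",
                                 BootstrapSettings(B=100, seed=1),
                                 groups=["protein"])
        by_nova = {e.nova: e for e in ests if e.fss_stratum == "all"}
        assert by_nova[1].boot_median == by_nova[1].ci_low == by_nova[1].ci_high == 0.5
        assert by_nova[3].diff_vs_nova1 == pytest.approx(-0.2)
        assert by_nova[3].significant
        assert by_nova[1].diff_vs_nova1 is None

    def test_empty_stratum_yields_n0_row_not_crash(self):
        items = [make_item(item_id="a", nova=1), make_item(item_id="b", nova=3)]
        ests = summarize_stratum(self._aset(items), "ghge",
                                 BootstrapSettings(B=50, seed=2),
                                 groups=["protein"])
        nova4 = [e for e in ests if e.nova == 4 and e.fss_stratum == "all"]
        assert nova4 and nova4[0].n == 0 and nova4[0].boot_median is None

    def test_determinism_independent_of_row_order(self):
        rng = np.random.default_rng(5)
        items = [
            make_item(item_id=f"i{k}", nova=int(rng.choice([1, 3, 4])),
                      cost=float(rng.lognormal()), energy=100.0)
            for k in range(60)
        ]
        s = BootstrapSettings(B=300, seed=9)
        a = summarize_stratum(self._aset(items), "cost", s)
        b = summarize_stratum(self._aset(items[::-1]), "cost", s)
        key = lambda e: (e.food_group, e.fss_stratum, e.nova)
        for ea, eb in zip(sorted(a, key=key), sorted(b, key=key)):
            assert ea == eb
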