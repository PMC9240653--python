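"""Synchrony metrics against a brute-force recomputation of the formulas."""

import math

import numpy as np
import pytest

from gemtap.engine import MISSING, TrialConfig, replay_trial
from gemtap.metrics import (
    adaptivity_benefit,
    group_asyncs,
    individual_asyncs,
    metric_table,
    rank_tappers,
    sd_async,
    sd_async_difference,
    sd_of_sd,
    trial_metrics,
    within_window_sd,
)
from gemtap.simulate import TapperParams, run_trial
from helpers import build_trial, random_trial


# ---- brute-force oracle: direct loops over the defining formulas --------

def brute_population_sd(xs):
    mu = sum(xs) / len(xs)
    return math.sqrt(sum((x - mu) ** 2 for x in xs) / len(xs))


def brute_metrics(trial):
    """Recompute every metric with explicit loops, excluding missing taps."""
    n = trial.config.n_tappers
    indiv = [
        [rec.tap_rel[i] for rec in trial.records if rec.tap_rel[i] is not MISSING]
        for i in range(n)
    ]
    group = []
    for rec in trial.records:
        obs = [r for r in rec.tap_rel if r is not MISSING]
        if obs:
            group.append(sum(obs) / len(obs))
    group_sd = brute_population_sd(group)
    diffs = [brute_population_sd(s) - group_sd for s in indiv]
    window_sds = []
    for rec in trial.records:
        obs = [r for r in rec.tap_rel if r is not MISSING]
        if obs:
            window_sds.append(brute_population_sd(obs))
    return {
        "indiv_sds": [brute_population_sd(s) for s in indiv],
        "group_sd": group_sd,
        "diffs": diffs,
        "sd_of_sd": brute_population_sd(window_sds),
    }


class TestSdAsync:
    @pytest.mark.parametrize(
        "series,expected",
        [([5, -5, 5, -5], 5.0), ([3.0, 3.0, 3.0], 0.0), ([0, 10, 0, 10], 5.0)],
    )
    def test_population_form(self, series, expected):
        assert sd_async(series) == pytest.approx(expected)

    def test_sample_form_available(self):
        assert sd_async([0, 10], ddof=1) == pytest.approx(np.std([0, 10], ddof=1))

    def test_empty_series_is_nan(self):
        assert math.isnan(sd_async([]))


class TestSeriesExtraction:
    def test_exact_taps_give_zero_series(self):
        trial = build_trial([[0.0, 0.0]] * 6)
        for series in individual_asyncs(trial):
            assert list(series.values()) == [0.0] * 6
        assert list(group_asyncs(trial).values()) == [0.0] * 6

    def test_missed_window_excluded_with_index_preserved(self):
        windows = [[10.0]] * 10
        windows[5] = [MISSING]
        trial = build_trial(windows)
        series = individual_asyncs(trial)[0]
        assert len(series) == 9
        assert 5 not in series and 6 in series

    def test_group_mean_over_observed_only(self):
        trial = build_trial([[MISSING, 0.0, 0.0, 0.0]])
        assert group_asyncs(trial) == {0: 0.0}
        trial = build_trial([[-20.0, 10.0, -10.0, 40.0]])
        assert group_asyncs(trial) == {0: 5.0}

    def test_single_tapper_group_equals_individual(self, rng):
        trial = random_trial(rng, n_tappers=1)
        assert group_asyncs(trial) == individual_asyncs(trial)[0]


class TestSdDifferenceAndSpread:
    def test_individual_vs_constant_group(self):
        # tapper 0 alternates 0/10 (SD 5); tapper 1 mirrors so the group
        # mean is constant 5 (SD 0) => difference +5 for each
        windows = [[0.0, 10.0], [10.0, 0.0], [0.0, 10.0], [10.0, 0.0]]
        trial = build_trial(windows)
        assert sd_async_difference(trial) == pytest.approx([5.0, 5.0])

    def test_single_tapper_difference_is_zero(self, rng):
        trial = random_trial(rng, n_tappers=1, miss_prob=0.0)
        assert sd_async_difference(trial) == pytest.approx([0.0])

    def test_antiphase_pair(self):
        windows = [[10.0, -10.0], [-10.0, 10.0]] * 3
        trial = build_trial(windows)
        assert sd_async_difference(trial) == pytest.approx([10.0, 10.0])

    def test_within_window_sd_example(self):
        trial = build_trial([[-20.0, 10.0, -10.0, 40.0]])
        assert within_window_sd(trial)[0] == pytest.approx(math.sqrt(525), abs=0.01)

    def test_identical_tappers_have_zero_spread(self):
        trial = build_trial([[7.0] * 4, [-3.0] * 4, [11.0] * 4])
        assert all(v == 0.0 for v in within_window_sd(trial).values())
        assert sd_of_sd(trial) == 0.0

    def test_constant_window_spread_gives_zero_sd_of_sd(self):
        # each window has the same cross-tapper SD c > 0
        trial = build_trial([[0.0, 10.0], [20.0, 30.0], [-5.0, 5.0]])
        sds = list(within_window_sd(trial).values())
        assert sds == pytest.approx([5.0, 5.0, 5.0])
        assert sd_of_sd(trial) == pytest.approx(0.0)


class TestRanking:
    @pytest.mark.parametrize(
        "diffs,ranks",
        [
            ([10.9, -7.8, 6.5, 15.4], [3, 2, 1, 4]),
            ([1, 2, 3, 4], [1, 2, 3, 4]),
            ([-5, 5, -5, 5], [1, 2, 3, 4]),  # ties broken by index
        ],
    )
    def test_rank_by_absolute_difference(self, diffs, ranks):
        assert rank_tappers(diffs) == ranks

    def test_ranks_are_permutation(self, rng):
        diffs = rng.normal(size=4).tolist()
        assert sorted(rank_tappers(diffs)) == [1, 2, 3, 4]


class TestBruteForceAgreement:
    def test_metrics_match_direct_loops_on_random_trials(self, rng):
        """Package metrics agree with an explicit-loop recomputation of
        the defining formulas on 100 random small trials to 1e-9."""
        for _ in range(100):
            n_tappers = int(rng.integers(1, 5))
            trial = random_trial(rng, n_windows=int(rng.integers(4, 20)),
                                 n_tappers=n_tappers, miss_prob=0.2)
            expected = brute_metrics(trial)
            got_group = sd_async(list(group_asyncs(trial).values()))
            assert got_group == pytest.approx(expected["group_sd"], rel=1e-9, abs=1e-12)
            assert sd_async_difference(trial) == pytest.approx(
                expected["diffs"], rel=1e-9, abs=1e-12
            )
            indiv = [sd_async(list(s.values())) for s in individual_asyncs(trial)]
            assert indiv == pytest.approx(expected["indiv_sds"], rel=1e-9, abs=1e-12)
            assert sd_of_sd(trial) == pytest.approx(
                expected["sd_of_sd"], rel=1e-9, abs=1e-12
            )

    def test_metrics_invariant_to_tapper_order(self, rng):
        """Group-level metrics are exchangeable in the tappers."""
        trial = random_trial(rng, n_windows=15, n_tappers=4, miss_prob=0.1)
        perm = [2, 0, 3, 1]
        permuted = build_trial(
            [[rec.tap_rel[p] for p in perm] for rec in trial.records]
        )
        assert sd_async(list(group_asyncs(permuted).values())) == pytest.approx(
            sd_async(list(group_asyncs(trial).values()))
        )
        assert sd_of_sd(permuted) == pytest.approx(sd_of_sd(trial))

    def test_replayed_trial_yields_identical_metrics(self):
        cfg = TrialConfig(alpha=0.5, n_tones=30, n_tappers=3)
        trial = run_trial(cfg, [TapperParams(p_miss=0.1)] * 3, 4)
        a = trial_metrics(trial)
        b = trial_metrics(replay_trial(trial))
        assert a == b


class TestAdaptivityBenefit:
    def test_sign_convention(self):
        import pandas as pd

        table = pd.DataFrame(
            {"alpha": [0.0, 0.0, 0.35, 0.35], "group_sd_async": [20.0, 20.0, 14.0, 14.0]}
        )
        assert adaptivity_benefit(table, 0.0, 0.35) == pytest.approx(6.0)
        assert adaptivity_benefit(table, 0.35, 0.35) == 0.0
        with pytest.raises(ValueError):
            adaptivity_benefit(table, 0.5, 0.35)

    def test_simulated_tappers_benefit_from_moderate_adaptivity(self):
        """Phase-correcting noisy tappers tap more stably under moderate
        metronome adaptivity: positive benefit, sign test p < 0.01."""
        from scipy.stats import binomtest

        params = TapperParams(beta=0.2, sigma_timekeeper=10, sigma_motor=10, p_miss=0)
        diffs = []
        for seed in range(60):
            base = run_trial(TrialConfig(alpha=0.0, n_tones=60), [params], (1, seed))
            adapt = run_trial(TrialConfig(alpha=0.35, n_tones=60), [params], (2, seed))
            sd_base = sd_async(list(group_asyncs(base).values()))
            sd_adapt = sd_async(list(group_asyncs(adapt).values()))
            diffs.append(sd_base - sd_adapt)
        assert np.mean(diffs) > 0
        wins = sum(d > 0 for d in diffs)
        assert binomtest(wins, len(diffs), alternative="greater").pvalue < 0.01

    def test_group_sd_scales_inverse_sqrt_k_for_white_noise_tappers(self):
        """At alpha=0 with motor noise off, K independent identical
        tappers give a group-mean asynchrony SD ~ 1/sqrt(K) of a single
        tapper's (random-walk increments are white)."""
        # Timekeeper-only tappers at alpha=0, beta high enough to be
        # stationary white-ish: use beta=1 so async is iid N(0, sigma_T).
        params = TapperParams(beta=1.0, sigma_timekeeper=10, sigma_motor=0, p_miss=0)
        n_tones = 4000

        def group_sd(k, seed):
            cfg = TrialConfig(alpha=0.0, n_tones=n_tones, n_tappers=k)
            trial = run_trial(cfg, [params] * k, seed)
            return sd_async(list(group_asyncs(trial).values()))

        sd1 = np.mean([group_sd(1, s) for s in range(4)])
        sd4 = np.mean([group_sd(4, s) for s in range(4, 8)])
        assert sd4 == pytest.approx(sd1 / 2, rel=0.1)


def test_metric_table_shape():
    cfg = TrialConfig(alpha=0.35, n_tones=20, n_tappers=2)
    trials = [run_trial(cfg, [TapperParams()] * 2, s) for s in range(3)]
    table = metric_table(trials)
    assert len(table) == 3
    assert {"trial_id", "alpha", "group_sd_async", "sd_of_sd",
            "sd_async_diff_0", "rank_1"} <= set(table.columns)
    assert (table["group_sd_async"] >= 0).all()
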