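"""Analysis stages: aggregation, time-series fits, the phase-transition
profile, learning rates, the joint surface, and effect summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import spearmanr

from tiseries import analysis as an
from tiseries import gp
from tiseries.agents import (
    records_to_frame,
    simulate_bernoulli,
    simulate_rt,
    RTConfig,
)
from tiseries.errors import AnalysisError
from tiseries.schedule import HUMAN, MONKEY, build_schedule


def parametric_cohort(prob_fn, n_sessions=20, profile=MONKEY, seed0=9000,
                      rt_config=None):
    frames = []
    for s in range(n_sessions):
        sched = build_schedule(profile, seed=seed0 + s)
        recs = simulate_bernoulli(sched, prob_fn, seed=seed0 + 10_000 + s, session=s + 1)
        if rt_config is not None:
            recs = simulate_rt(recs, rt_config, seed=seed0 + 20_000 + s)
        frames.append(records_to_frame(recs))
    return pd.concat(frames, ignore_index=True)


class TestAggregateCounts:
    def test_counts_simple_toy(self, pair7):
        frame = pd.DataFrame(
            {
                "subject": ["a", "a", "b"],
                "session": [1, 2, 1],
                "trial_index": [41, 41, 42],
                "phase": [2, 2, 2],
                "item_lo": ["E", "E", "E"],
                "item_hi": ["F", "F", "F"],
                "distance": [1, 1, 1],
                "joint_rank": [11, 11, 11],
                "chosen": ["E", "E", "F"],
                "correct": [1, 1, 0],
                "rt_seconds": [0.3, 0.3, 0.3],
            }
        )
        series = an.aggregate_counts(frame, pair7("EF"), 2)
        assert list(series.trial_index) == [41, 42]
        assert list(series.k) == [2, 0]
        assert list(series.m) == [2, 1]
        # permutation invariance
        shuffled = an.aggregate_counts(frame.sample(frac=1, random_state=0), pair7("EF"), 2)
        assert np.array_equal(series.k, shuffled.k)

    def test_phase1_totals_equal_session_count(self, monkey_cohort, pair7):
        n_sessions = monkey_cohort.groupby(["subject", "session"]).ngroups
        series = an.aggregate_counts(monkey_cohort, pair7("FG"), 1)
        assert (series.m == n_sessions).all()
        assert series.m.sum() == 40 * n_sessions

    def test_empty_selection_is_explicit(self, monkey_cohort, pair7):
        series = an.aggregate_counts(monkey_cohort, pair7("AC"), 1)
        assert series.empty and len(series) == 0


class TestAccuracyTimeseries:
    def test_chance_agent_recovers_flat_half(self, pair7):
        frame = parametric_cohort(lambda s: 0.5, n_sessions=30)
        fit = an.accuracy_timeseries(frame, pair7("FG"), 1)
        assert np.all(np.abs(fit.mean - 0.5) < 0.1)
        assert all(p.lo99 < 0.5 < p.hi99 for p in fit.points)

    def test_duplicating_sessions_narrows_bands(self, monkey_cohort, pair7):
        fit1 = an.accuracy_timeseries(monkey_cohort, pair7("FG"), 1)
        doubled = pd.concat(
            [monkey_cohort, monkey_cohort.assign(session=monkey_cohort["session"] + 1000)],
            ignore_index=True,
        )
        fit2 = an.accuracy_timeseries(doubled, pair7("FG"), 1)
        w1 = np.array([p.hi99 - p.lo99 for p in fit1.points])
        w2 = np.array([p.hi99 - p.lo99 for p in fit2.points])
        assert np.all(w2 < w1)
        assert np.max(np.abs(fit1.mean - fit2.mean)) < 0.03

    def test_fg_step_drop_signature(self, monkey_cohort, pair7):
        """Massed-pair accuracy rises across phase 1 and drops at the
        phase boundary (interleaving removes the one-trial memory trace)."""
        fit1 = an.accuracy_timeseries(monkey_cohort, pair7("FG"), 1)
        assert fit1.mean[-1] > fit1.mean[0]
        fit2 = an.accuracy_timeseries(monkey_cohort, pair7("FG"), 2)
        assert fit2.mean[0] < fit1.mean[-1]

    def test_missing_pair_raises(self, monkey_cohort, pair7):
        with pytest.raises(AnalysisError):
            an.accuracy_timeseries(monkey_cohort, pair7("AC"), 1)


class TestRTTimeseries:
    def test_constant_rt_gives_flat_log_curve(self, pair7):
        frame = parametric_cohort(lambda s: 0.5, n_sessions=5)
        frame["rt_seconds"] = 0.26
        fit = an.rt_timeseries(frame, pair7("FG"), 1, noise_variance=1e-6)
        assert np.allclose(fit.mean, np.log(0.26), atol=1e-3)

    def test_practice_trend_recovered(self, pair7):
        frame = parametric_cohort(
            lambda s: 0.5, n_sessions=10, profile=HUMAN,
            rt_config=RTConfig(mu0=0.5, practice_slope=-1e-3, sigma=0.2),
        )
        fit = an.rt_timeseries(frame, pair7("FG"), 2)
        assert fit.mean[-1] < fit.mean[0]

    def test_grand_mean_recovery(self, monkey_cohort, pair7):
        fit = an.rt_timeseries(monkey_cohort, pair7("FG"), 3)
        # generator: mu0 = -1.35, distance slope -0.02 at distance 1
        assert np.mean(fit.mean) == pytest.approx(-1.37, abs=0.05)

    def test_nonpositive_rt_rejected(self, monkey_cohort, pair7):
        bad = monkey_cohort.copy()
        bad.loc[bad.index[0], "rt_seconds"] = -1.0
        pair = pair7(bad.iloc[0]["item_lo"] + bad.iloc[0]["item_hi"])
        with pytest.raises(Exception):
            an.rt_timeseries(bad, pair, int(bad.iloc[0]["phase"]))


class TestTransitionProfile:
    def test_all_correct_toy_beta_update(self):
        # 3 sessions, every response correct: posterior mean (k+1)/(m+2)
        frames = []
        for s in range(3):
            sched = build_schedule(HUMAN, seed=s)
            frames.append(records_to_frame(simulate_bernoulli(sched, lambda _: 1.0, seed=s,
                                                              session=s + 1)))
        prof = an.transition_profile(pd.concat(frames, ignore_index=True))
        for est in prof.fg_phase1 + prof.fg:
            assert est.k == est.m == 3
            assert est.mean == pytest.approx(4 / 5)
        for est in prof.xf:  # all-correct means F never chosen on xF
            assert est.k == 0
            assert est.accuracy_mean == pytest.approx(4 / 5)
            lo, hi = est.accuracy_interval(99)
            lo_p, hi_p = est.interval(99)
            assert (lo, hi) == pytest.approx((1 - hi_p, 1 - lo_p))

    def test_presentation_indices_and_classes(self, monkey_cohort):
        prof = an.transition_profile(monkey_cohort)
        assert [e.presentation for e in prof.fg_phase1] == [1, 2, 3, 4]
        for ests in (prof.fg, prof.xf, prof.xg):
            assert [e.presentation for e in ests] == [1, 2, 3, 4, 5, 6]
        assert not prof.truncated
        # xF excludes FG itself: counted event is choosing F, an error
        assert all(not e.counted_is_correct for e in prof.xf)

    def test_truncation_flagged_when_phase2_is_short(self, monkey_cohort):
        ph2_starts = monkey_cohort[monkey_cohort["phase"] == 2]["trial_index"]
        cut = monkey_cohort[
            (monkey_cohort["phase"] != 2) | (monkey_cohort["trial_index"] < ph2_starts.min() + 20)
        ]
        prof = an.transition_profile(cut)
        assert prof.truncated

    def test_requires_both_phases(self, monkey_cohort):
        with pytest.raises(AnalysisError):
            an.transition_profile(monkey_cohort[monkey_cohort["phase"] == 3])


class TestLearningRates:
    def test_static_probability_rates_include_zero(self):
        frame = parametric_cohort(lambda s: 0.65, n_sessions=15)
        rates = an.learning_rates(frame, 3)
        assert len(rates) == 21
        for r in rates:
            assert r.estimate.lo99 < 0.0 < r.estimate.hi99
        # deterministic (distance, joint rank) ordering
        keys = [(r.pair.distance, r.pair.joint_rank) for r in rates]
        assert keys == sorted(keys)

    def test_built_in_distance_effect_recovered_in_rates(self):
        slopes = {d: 0.002 + 0.004 * d for d in range(1, 7)}

        def prob(slot):
            if slot.phase < 3:
                return 0.5
            t = slot.trial_index - 341
            return float(expit(slopes[slot.pair.distance] * t))

        frame = parametric_cohort(prob, n_sessions=25)
        rates = an.learning_rates(frame, 3, optimize="shared")
        est = np.array([r.estimate.mean for r in rates])
        dist = np.array([r.pair.distance for r in rates])
        assert spearmanr(est, dist).statistic > 0.5

    def test_fast_vs_slow_cohort_rate_ratio(self):
        def make(slope):
            def prob(slot):
                if slot.phase != 2:
                    return 0.5
                return float(expit(slope * (slot.trial_index - 41)))
            return prob

        slow = parametric_cohort(make(0.005), n_sessions=25, seed0=100)
        fast = parametric_cohort(make(0.05), n_sessions=25, seed0=200)
        r_slow = np.mean(
            [r.estimate.mean for r in an.learning_rates(slow, 2, optimize="shared")]
        )
        r_fast = np.mean(
            [r.estimate.mean for r in an.learning_rates(fast, 2, optimize="shared")]
        )
        ratio = r_fast / r_slow
        assert 5.0 < ratio < 20.0  # configured 10x, recovered within 2x

    def test_phase_must_be_two_or_three(self, monkey_cohort):
        with pytest.raises(AnalysisError):
            an.learning_rates(monkey_cohort, 1)


class TestJointSurface:
    def test_marker_equals_grid_at_pair_coordinate(self, monkey_cohort):
        surf = an.joint_surface(monkey_cohort, grid_step=0.5)
        d_axis, j_axis = list(surf.distance), list(surf.joint_rank)
        for pair, pt in surf.pair_points:
            i, j = d_axis.index(pair.distance), j_axis.index(pair.joint_rank)
            assert surf.mean[i, j] == pytest.approx(pt.response_mean, abs=1e-10)
            assert surf.valid_pair[i, j]

    def test_parity_invalid_cells_flagged_as_interpolated(self, monkey_cohort):
        surf = an.joint_surface(monkey_cohort, grid_step=0.5)
        D, J = np.meshgrid(surf.distance, surf.joint_rank, indexing="ij")
        # odd distance with even joint rank can never be a pair
        assert not surf.valid_pair[(D == 1) & (J == 4)].any()
        # fractional coordinates are interpolation, not pairs
        assert not surf.valid_pair[(D == 1.5)].any()
        assert surf.valid_pair.sum() == 21

    def test_rt_surface_shows_configured_distance_speedup(self):
        frame = parametric_cohort(
            lambda s: 0.7, n_sessions=10,
            rt_config=RTConfig(mu0=-1.0, distance_slope=-0.08, sigma=0.15),
        )
        surf = an.joint_surface(frame, response="rt", grid_step=0.5)
        by_pair = {p.label: pt.response_mean for p, pt in surf.pair_points}
        assert by_pair["AF"] < by_pair["EF"]  # distance 5 faster than distance 1
        assert by_pair["AG"] < by_pair["FG"]

    def test_accuracy_surface_distance_effect(self, monkey_cohort):
        surf = an.joint_surface(monkey_cohort, grid_step=0.5)
        # at joint rank 8 the distances 2, 4, 6 are all valid pairs (CE, BF, AG)
        j = list(surf.joint_rank).index(8.0)
        d = [list(surf.distance).index(x) for x in (2.0, 4.0, 6.0)]
        vals = [surf.mean[i, j] for i in d]
        assert vals[0] < vals[2]


class TestEffectStats:
    def _points(self, accs, pairs):
        return [
            (
                p,
                gp.PredictionPoint(
                    x=(0.0,), latent_mean=float(np.log(a / (1 - a))), latent_sd=0.05,
                    response_mean=a, lo80=a, hi80=a, lo99=a, hi99=a,
                ),
            )
            for p, a in zip(pairs, accs)
        ]

    def test_flat_surface_has_no_trend(self, monkey_cohort):
        from tiseries.schedule import all_pairs

        pairs = sorted(all_pairs(7))
        stats = an.effect_stats(self._points([0.7] * 21, pairs))
        assert abs(stats.distance_trend) < 0.3
        lo, hi = stats.distance_trend_ci99
        assert lo < 0 < hi

    def test_monotone_surface_has_perfect_trend(self):
        from tiseries.schedule import all_pairs

        pairs = sorted(all_pairs(7))
        accs = [0.5 + 0.07 * p.distance for p in pairs]
        stats = an.effect_stats(self._points(accs, pairs))
        assert stats.distance_trend == pytest.approx(1.0)

    def test_terminal_boost_gives_positive_contrast(self):
        from tiseries.schedule import all_pairs

        pairs = sorted(all_pairs(7))
        accs = [0.8 if (p.lo.rank == 1 or p.hi.rank == 7) else 0.6 for p in pairs]
        stats = an.effect_stats(self._points(accs, pairs))
        assert stats.terminal_contrast > 0.1
        assert stats.terminal_contrast_ci99[0] > 0

    def test_too_few_distances_rejected(self, pair7):
        pts = self._points([0.5, 0.6], [pair7("AB"), pair7("BC")])
        with pytest.raises(AnalysisError):
            an.effect_stats(pts)


class TestDerivativeAccuracyConsistency:
    def test_integrated_rate_matches_latent_change(self, monkey_cohort, pair7):
        """Trapezoid-integrating the learning-rate curve over a phase
        reproduces the latent log-odds change across that phase."""
        fit = an.accuracy_timeseries(monkey_cohort, pair7("FG"), 2)
        t = fit.trial_index.astype(float)
        grid = np.linspace(t.min(), t.max(), 200)
        derivs = gp.derivative(fit.posterior, grid[:, None])
        integral = np.trapezoid([d.mean for d in derivs], grid)
        change = fit.points[-1].latent_mean - fit.points[0].latent_mean
        assert integral == pytest.approx(change, rel=0.05, abs=1e-3)
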