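import numpy as np
import pytest

from kage.io_core import BehaviorInterval, LightSchedule, VisitEvent
from kage.phenotype_metrics import (
    FEATURE_CATEGORIES,
    FEATURE_NAMES,
    PerformanceCurve,
    build_feature_table,
    default_iti_bins,
    exploration_response,
    locomotion_summary,
    memory_time_span,
    performance_by_iti,
    quiescence_summary,
    tmaze_summary,
)
from kage.synthetic_cohort import (
    GroupProfile,
    make_cohort,
    paper_like_spec,
    simulate_visits,
)


def visits_from_times(times, sides, mouse="m0"):
    from kage.io_core import derive_visit_fields
    return derive_visit_fields(
        [VisitEvent(mouse, float(t), s) for t, s in zip(times, sides)])


class TestPerformanceByIti:
    def test_perfect_alternator(self):
        times = np.arange(0, 4000, 100.0)
        sides = ["L", "R"] * (len(times) // 2)
        curve = performance_by_iti(visits_from_times(times, sides))
        occupied = curve.n > 0
        assert np.all(curve.p_hat[occupied] == 1.0)

    def test_fair_coin_no_significant_bins(self):
        # type-I calibration: a chance-level chooser should rarely produce
        # a significant bin
        n_runs, bad = 20, 0
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            times = np.cumsum(rng.exponential(120.0, size=1000))
            sides = rng.choice(["L", "R"], size=1000)
            curve = performance_by_iti(visits_from_times(times, sides))
            rel = curve.reliable & ~np.isnan(curve.p_binom)
            bad += bool(np.any(curve.p_binom[rel] < 0.05))
        assert bad <= n_runs * 0.35  # several bins tested per run

    def test_below_chance_at_long_iti(self):
        prof = GroupProfile(p_max=0.8, tau_mem=10.0, persev=0.05,
                            visit_rate_light=2.0, visit_rate_dark=4.0)
        trials = []
        for seed in range(8):
            trials += simulate_visits(prof, 15, seed=seed)
        curve = performance_by_iti(trials, n_min=50)
        centers = curve.centers_min
        long_bins = (centers > 30) & curve.reliable
        assert long_bins.any()
        assert np.nanmean(curve.p_hat[long_bins]) < 0.5

    def test_time_origin_invariance(self):
        times = np.arange(0, 5000, 70.0)
        rng = np.random.default_rng(1)
        sides = rng.choice(["L", "R"], size=len(times))
        c1 = performance_by_iti(visits_from_times(times, sides))
        c2 = performance_by_iti(visits_from_times(times + 12345.0, sides))
        np.testing.assert_array_equal(c1.k, c2.k)
        np.testing.assert_array_equal(c1.n, c2.n)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            performance_by_iti([])


class TestMemoryTimeSpan:
    def make_curve(self, p_fn, n=1000):
        edges = default_iti_bins(24)
        centers = np.sqrt(edges[:-1] * edges[1:])
        p = np.array([p_fn(c) for c in centers])
        k = np.round(p * n).astype(int)
        return PerformanceCurve(edges, np.full(len(centers), n), k,
                                k / n, np.ones(len(centers)))

    def test_closed_form_crossing(self):
        # p(t) = 0.45 + 0.35 exp(-t/5) crosses 0.5 at 5 ln 7 = 9.73 min
        curve = self.make_curve(lambda t: 0.45 + 0.35 * np.exp(-t / 5.0))
        span = memory_time_span(curve)
        edges = curve.bin_edges_min
        i = np.searchsorted(edges, 5 * np.log(7))
        bin_width = edges[i] - edges[i - 1]
        assert abs(span - 5 * np.log(7)) < bin_width

    def test_constant_above_half_undefined(self):
        curve = self.make_curve(lambda t: 0.9)
        assert np.isnan(memory_time_span(curve))

    def test_never_above_half_undefined(self):
        curve = self.make_curve(lambda t: 0.45)
        assert np.isnan(memory_time_span(curve))

    def test_monotone_in_generator_memory(self):
        # shorter memory decay gives a shorter measured span
        spans = []
        for tau in (3.0, 6.0, 12.0):
            prof = GroupProfile(p_max=0.85, tau_mem=tau, persev=0.05,
                                visit_rate_light=2.0, visit_rate_dark=4.0)
            trials = []
            for seed in range(6):
                trials += simulate_visits(prof, 12, seed=seed)
            spans.append(memory_time_span(
                performance_by_iti(trials, n_min=30)))
        assert spans[0] < spans[1] < spans[2]


class TestTmazeSummary:
    def test_deterministic_daily_alternator(self):
        times = np.arange(0, 5 * 86400.0, 86400.0) + 100.0
        sides = ["L", "R", "L", "R", "L"]
        bins = np.logspace(np.log10(0.25), np.log10(2880.0), 13)
        s = tmaze_summary(visits_from_times(times, sides), 5 * 86400.0,
                          bins=bins, n_min=1)
        assert s["mean_daily_visits"] == pytest.approx(1.0)
        assert s["max_performance"] == pytest.approx(1.0)

    def test_median_iti(self):
        times = [0.0, 60.0, 180.0, 780.0]
        s = tmaze_summary(visits_from_times(times, "LRLR"), 86400.0, n_min=1)
        assert s["median_iti"] == pytest.approx(2.0)  # median{1,2,10} min


class TestExplorationResponse:
    def test_zero_bouts_censored(self):
        from kage.io_core import DrumChangeEvent
        drums = [DrumChangeEvent(86400.0 * 1.7, "L-NOR", 2, 5)]
        er = exploration_response([], drums, 3 * 86400.0)
        rec = er["records"][0]
        assert rec["post_s"] == 0.0 and rec["censored"]

    def test_novelty_boost_raises_post(self):
        from kage.synthetic_cohort import (
            simulate_drum_schedule, simulate_ethogram)
        prof = GroupProfile(novelty_boost=3.0, explore_rate=1.0)
        pre, post = [], []
        for seed in range(10):
            days = 8
            visits = simulate_visits(prof, days, seed=seed)
            drums = simulate_drum_schedule(days, seed=seed)
            etho = simulate_ethogram(prof, visits, drums, days, seed + 50)
            er = exploration_response(etho, drums, days * 86400.0)
            pre += [r["pre_s"] for r in er["records"]]
            post += [r["post_s"] for r in er["records"]]
        assert len(pre) >= 30
        diff = np.asarray(post) - np.asarray(pre)
        t = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        assert t > 2.0  # paired one-sided check

    def test_latency_matches_notice_parameter(self):
        from kage.synthetic_cohort import (
            simulate_drum_schedule, simulate_ethogram)
        prof = GroupProfile(notice_latency_mean=1.3, explore_rate=0.3,
                            novelty_boost=3.0)
        lats = []
        for seed in range(25):
            days = 10
            visits = simulate_visits(prof, days, seed=seed)
            drums = simulate_drum_schedule(days, seed=seed)
            etho = simulate_ethogram(prof, visits, drums, days, seed + 70)
            er = exploration_response(etho, drums, days * 86400.0)
            lats += [r["latency_min"] for r in er["records"]
                     if not r["censored"]]
        assert len(lats) >= 100
        assert 1.0 <= np.mean(lats) <= 1.7


class TestQuiescenceSummary:
    def test_phase_boundary_split(self):
        # 600-min nap starting 60 min before lights-off: 60 light + 540 dark
        sched = LightSchedule()
        start = 11 * 3600.0  # clock 20:00, one hour before lights-off
        iv = BehaviorInterval(start, start + 600 * 60.0, "quiescence")
        out = quiescence_summary([iv], sched, t_max=86400.0)
        assert out["quiesc_total_light"] == pytest.approx(60.0)
        assert out["quiesc_total_dark"] == pytest.approx(540.0)

    def test_empty_all_zero(self):
        out = quiescence_summary([], t_max=86400.0)
        assert out["quiesc_total_light"] == 0.0
        assert out["quiesc_freq_dark"] == 0.0
        assert out["longest_bout"] == 0.0

    def test_control_preset_daily_totals(self):
        from kage.synthetic_cohort import (
            GroupProfile, draw_quiescence)
        prof = GroupProfile()
        naps = draw_quiescence(prof, 20, 3)
        ivs = [BehaviorInterval(s, e, "quiescence") for s, e in naps]
        out = quiescence_summary(ivs, t_max=20 * 86400.0)
        assert 480.0 <= out["quiesc_total_light"] <= 600.0  # 8-10 h
        assert 150.0 <= out["quiesc_total_dark"] <= 210.0   # 2.5-3.5 h
        assert out["quiesc_total_light"] > 2 * out["quiesc_total_dark"]

    def test_out_of_range_interval(self):
        with pytest.raises(ValueError):
            quiescence_summary(
                [BehaviorInterval(-5.0, 400.0, "quiescence")],
                t_max=86400.0)


class TestLocomotionSummary:
    def test_all_quiescent_zero_movement(self):
        ivs = [BehaviorInterval(0, 86400.0, "quiescence")]
        out = locomotion_summary(ivs, 86400.0)
        assert out["movement_per_day"] == 0.0
        assert out["wheel_per_day"] == 0.0

    def test_constructed_wheel_arithmetic(self):
        ivs = [BehaviorInterval(3600.0 * k, 3600.0 * k + 1200.0, "wheel")
               for k in (1, 5, 9)]
        out = locomotion_summary(ivs, 86400.0)
        assert out["wheel_per_day"] == pytest.approx(60.0)
        assert out["wheel_bouts_per_day"] == pytest.approx(3.0)
        assert out["mean_wheel_bout"] == pytest.approx(20.0)

    def test_conservation_of_daily_time(self):
        spec = paper_like_spec(n_per_group=1, duration_days=6, master_seed=2)
        cohort = make_cohort(spec)
        for md in cohort.mice.values():
            t_max = 6 * 86400.0
            loco = locomotion_summary(md.ethogram, t_max)
            qs = quiescence_summary(md.ethogram, t_max=t_max)
            tmaze = sum(iv.duration for iv in md.ethogram
                        if iv.label.startswith("tmaze")) / 60.0 / 6
            total = (loco["movement_per_day"] + tmaze
                     + qs["quiesc_total_light"] + qs["quiesc_total_dark"])
            assert total <= 1440.0 + 1e-6


class TestFeatureTable:
    def test_shape_and_category_partition(self):
        spec = paper_like_spec(n_per_group=2, duration_days=6, master_seed=0)
        table, cats, audit = build_feature_table(make_cohort(spec))
        assert table.shape == (8, 32)
        assert not table.isna().any().any()
        sizes = {c: sum(1 for f in FEATURE_NAMES if cats[f] == c)
                 for c in FEATURE_CATEGORIES}
        assert sizes == {"tmaze": 8, "nor_opr": 8, "quiescence": 8,
                         "wheel_locomotion": 8}

    def test_identical_mice_identical_rows(self):
        from kage.synthetic_cohort import CohortSpec, PRESETS
        spec = CohortSpec(groups=[("a", PRESETS["control"], 1)],
                          duration_days=5, master_seed=4)
        t1, _, _ = build_feature_table(make_cohort(spec))
        t2, _, _ = build_feature_table(make_cohort(spec))
        np.testing.assert_allclose(t1.to_numpy(), t2.to_numpy())
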