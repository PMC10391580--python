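import numpy as np
import pytest

from kage.io_core import BehaviorInterval, LightSchedule, DRUM_KINDS
from kage.synthetic_cohort import (
    CohortSpec,
    GroupProfile,
    PRESETS,
    alternation_probability,
    changed_sides,
    draw_quiescence,
    make_cohort,
    paper_like_spec,
    render_pose,
    simulate_drum_schedule,
    simulate_ethogram,
    simulate_visits,
)


class TestAlternationModel:
    def test_perfect_memory_limit(self):
        prof = GroupProfile(p_max=1.0, tau_mem=1e9, persev=0.0)
        visits = simulate_visits(prof, 3, seed=0)
        rewarded = [v.rewarded for v in visits[1:]]
        assert all(rewarded)

    def test_chance_level(self):
        prof = GroupProfile(p_max=0.5, persev=0.0, visit_rate_light=6,
                            visit_rate_dark=6)
        visits = simulate_visits(prof, 10, seed=1)
        succ = np.array([v.rewarded for v in visits[1:]], float)
        n = len(succ)
        assert n >= 1000
        se = np.sqrt(0.25 / n)
        assert abs(succ.mean() - 0.5) < 3 * se

    def test_closed_form_at_ten_minutes(self):
        # P(ITI=10) = 0.5 + 0.35 e^-1 - 0.05 = 0.57876
        prof = GroupProfile(p_max=0.8, tau_mem=10.0, persev=0.05)
        assert float(alternation_probability(10.0, prof)) == pytest.approx(
            0.5 + 0.35 * np.exp(-1) - 0.05)
        rng_success = []
        for seed in range(40):
            visits = simulate_visits(prof, 20, seed=seed)
            for v in visits:
                if v.iti is not None and 9.5 * 60 <= v.iti <= 10.5 * 60:
                    rng_success.append(v.rewarded)
        n = len(rng_success)
        assert n >= 100
        p = np.mean(rng_success)
        se = np.sqrt(0.5788 * (1 - 0.5788) / n)
        assert abs(p - 0.5788) < 3 * se

    def test_monotone_in_memory_constant(self):
        # longer memory never lowers expected performance at any ITI
        itis = np.linspace(0.1, 60, 50)
        prev = None
        for tau in (1.0, 3.0, 10.0, 30.0):
            p = alternation_probability(itis, GroupProfile(tau_mem=tau))
            if prev is not None:
                assert np.all(p >= prev - 1e-12)
            prev = p

    def test_invalid_days(self):
        with pytest.raises(ValueError):
            simulate_visits(GroupProfile(), 0, seed=0)


class TestDrumSchedule:
    def test_sixteen_days_all_eight_kinds(self):
        evs = simulate_drum_schedule(16, seed=0)
        assert len(evs) == 8
        assert sorted(e.kind for e in evs) == sorted(DRUM_KINDS)

    def test_opr_takes_opposite_pattern(self):
        for seed in range(5):
            evs = simulate_drum_schedule(32, seed=seed)
            prev_l, prev_r = None, None
            for e in evs:
                if prev_l is not None:
                    if e.kind == "L-OPR":
                        assert e.pattern_left == prev_r
                    if e.kind in ("L-OPR", "double-OPR", "L-OPR+R-NOR"):
                        assert e.pattern_left == prev_r
                    if e.kind in ("R-OPR", "double-OPR", "L-NOR+R-OPR"):
                        assert e.pattern_right == prev_l
                prev_l, prev_r = e.pattern_left, e.pattern_right

    def test_nor_pattern_is_novel(self):
        for seed in range(5):
            evs = simulate_drum_schedule(32, seed=seed)
            prev_l, prev_r = None, None
            for e in evs:
                if prev_l is not None:
                    if e.kind in ("L-NOR", "double-NOR", "L-NOR+R-OPR"):
                        assert e.pattern_left not in (prev_l, prev_r)
                    if e.kind in ("R-NOR", "double-NOR", "L-OPR+R-NOR"):
                        assert e.pattern_right not in (prev_l, prev_r)
                prev_l, prev_r = e.pattern_left, e.pattern_right

    def test_changes_in_dark_window(self):
        sched = LightSchedule()
        evs = simulate_drum_schedule(30, seed=1, schedule=sched)
        for e in evs:
            clock = float(sched.clock(e.t))
            assert 0.0 <= clock <= 4 * 3600.0
            assert not sched.is_light(e.t)


class TestEthogram:
    def test_quiescence_bouts_at_least_five_minutes(self):
        prof = PRESETS["control"]
        visits = simulate_visits(prof, 5, seed=0)
        drums = simulate_drum_schedule(5, seed=0)
        etho = simulate_ethogram(prof, visits, drums, 5, seed=1)
        quiesc = [iv for iv in etho if iv.label == "quiescence"]
        assert quiesc
        assert min(iv.duration for iv in quiesc) >= 300.0

    def test_intervals_non_overlapping(self):
        prof = PRESETS["hippocampal"]
        visits = simulate_visits(prof, 3, seed=2)
        drums = simulate_drum_schedule(3, seed=2)
        etho = simulate_ethogram(prof, visits, drums, 3, seed=3)
        ivs = sorted(etho, key=lambda iv: iv.start)
        for a, b in zip(ivs[:-1], ivs[1:]):
            assert a.end <= b.start + 1e-9

    def test_renewal_expectation_light_phase(self):
        # quiesc_frac_light=0.8 over a 12 h phase: about 576 min/day
        prof = GroupProfile()
        totals = []
        for seed in range(3):
            naps = draw_quiescence(prof, 30, seed)
            sched = LightSchedule()
            light = sum(
                max(0.0, min(e, b + 43200.0) - max(s, b))
                for b in np.arange(0, 30 * 86400.0, 86400.0)
                for s, e in naps)
            totals.append(light / 60.0 / 30.0)
        assert np.mean(totals) == pytest.approx(576.0, rel=0.05)

    def test_no_novelty_effect_when_boost_one(self):
        from kage.phenotype_metrics import exploration_response
        prof = GroupProfile(novelty_boost=1.0, explore_rate=2.0)
        pre_all, post_all = [], []
        for seed in range(13):
            days = 8
            visits = simulate_visits(prof, days, seed=seed)
            drums = simulate_drum_schedule(days, seed=seed)
            etho = simulate_ethogram(prof, visits, drums, days, seed + 100)
            er = exploration_response(etho, drums, days * 86400.0)
            for r in er["records"]:
                pre_all.append(r["pre_s"])
                post_all.append(r["post_s"])
        assert len(pre_all) >= 50
        diff = np.asarray(post_all) - np.asarray(pre_all)
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se + 1e-9

    def test_visit_outside_range_rejected(self):
        prof = GroupProfile()
        visits = simulate_visits(prof, 2, seed=0)
        bad = visits + [type(visits[0])("m0", 10 * 86400.0, "L")]
        with pytest.raises(ValueError):
            simulate_ethogram(prof, bad, [], 2, seed=0)


class TestRenderPose:
    def test_quiescence_below_motion_threshold(self):
        from kage.behavior_labeling import MOTION_THRESHOLD_MM
        etho = [BehaviorInterval(0.0, 360.0, "quiescence")]
        traj = render_pose(etho, 360.0, seed=0)
        pos = traj.positions()
        disp = np.linalg.norm(np.diff(pos, axis=0), axis=2).sum(axis=1)
        assert disp.max() < MOTION_THRESHOLD_MM

    def test_panel_interval_at_left_panel_zone(self):
        from kage.io_core import CageGeometry
        etho = [BehaviorInterval(0.0, 120.0, "panel_L")]
        traj = render_pose(etho, 120.0, seed=1)
        geom = CageGeometry()
        snout = traj.xy("snout")
        inside = geom.contains("panel_L", snout, margin=45.0)
        assert inside.mean() > 0.9

    def test_bit_identical_under_seed(self):
        etho = [BehaviorInterval(0.0, 100.0, "wheel"),
                BehaviorInterval(150.0, 600.0, "quiescence")]
        a = render_pose(etho, 600.0, seed=42)
        b = render_pose(etho, 600.0, seed=42)
        np.testing.assert_array_equal(a.positions(), b.positions())

    def test_within_cage_bounds(self):
        prof = PRESETS["control"]
        visits = simulate_visits(prof, 1, seed=5)
        drums = simulate_drum_schedule(2, seed=5)
        etho = simulate_ethogram(prof, visits, drums, 1, seed=6)
        traj = render_pose(etho, 86400.0, seed=7)
        pos = traj.positions()
        assert pos[..., 0].min() >= 0 and pos[..., 0].max() <= 390.0
        assert pos[..., 1].min() >= 0 and pos[..., 1].max() <= 320.0


class TestMakeCohort:
    def test_balanced_labels(self):
        spec = paper_like_spec(n_per_group=2, duration_days=3, master_seed=0)
        cohort = make_cohort(spec)
        assert len(cohort.mice) == 8
        groups = list(cohort.truth.values())
        assert all(groups.count(g) == 2 for g in set(groups))

    def test_deterministic(self):
        spec = paper_like_spec(n_per_group=1, duration_days=3, master_seed=5)
        a = make_cohort(spec)
        b = make_cohort(spec)
        for mid in a.mice:
            assert a.mice[mid].visits == b.mice[mid].visits
            assert a.mice[mid].ethogram == b.mice[mid].ethogram
            assert a.mice[mid].drum_schedule == b.mice[mid].drum_schedule

    def test_duplicate_group_names_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(groups=[("a", PRESETS["control"], 2),
                               ("a", PRESETS["amyloid"], 2)])

    def test_effect_directions(self):
        # preset directions: lesioned hippocampus drinks more, moves more,
        # naps less; amyloid model explores less, naps longer in light
        from kage.phenotype_metrics import build_feature_table
        spec = paper_like_spec(n_per_group=3, duration_days=8, master_seed=3)
        cohort = make_cohort(spec)
        table, _, _ = build_feature_table(cohort)
        g = {grp: table.loc[[m for m, gg in cohort.truth.items() if gg == grp]]
             for grp in ("control", "hippocampal", "entorhinal", "amyloid")}
        assert g["hippocampal"]["max_performance"].mean() \
            < g["control"]["max_performance"].mean()
        assert g["hippocampal"]["mean_daily_visits"].mean() \
            > g["control"]["mean_daily_visits"].mean()
        assert g["hippocampal"]["movement_per_day"].mean() \
            > g["control"]["movement_per_day"].mean()
        assert g["hippocampal"]["quiesc_total_light"].mean() \
            < g["control"]["quiesc_total_light"].mean()
        assert g["entorhinal"]["quiesc_bout_dark"].mean() \
            < g["control"]["quiesc_bout_dark"].mean()
        assert g["amyloid"]["mean_daily_exploration"].mean() \
            < g["control"]["mean_daily_exploration"].mean()
        assert g["amyloid"]["movement_per_day"].mean() \
            < g["control"]["movement_per_day"].mean()

    def test_all_streams_pass_io_validation(self, tmp_path):
        from kage import io_core
        spec = paper_like_spec(n_per_group=1, duration_days=4, master_seed=9)
        cohort = make_cohort(spec)
        visits = {m: md.visits for m, md in cohort.mice.items()}
        etho = {m: md.ethogram for m, md in cohort.mice.items()}
        io_core.write_events(tmp_path / "v.csv", visits, "visits")
        io_core.write_events(tmp_path / "e.csv", etho, "intervals")
        first = next(iter(cohort.mice.values()))
        io_core.write_events(tmp_path / "d.csv", first.drum_schedule,
                             "drum_changes")
        assert io_core.read_events(tmp_path / "v.csv", "visits")
        assert io_core.read_events(tmp_path / "e.csv", "intervals")
        assert io_core.read_events(tmp_path / "d.csv", "drum_changes")

    def test_changed_sides_helper(self):
        assert changed_sides("L-NOR") == ("L",)
        assert changed_sides("double-OPR") == ("L", "R")
        assert changed_sides("L-NOR+R-OPR") == ("L", "R")
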