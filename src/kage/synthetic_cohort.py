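"""Synthetic cohorts of single-housed mice in automated home cages.

The generator emulates the data streams the phenotyping pipeline consumes:
spout-visit logs under a circadian visit rate, a drum-change schedule
cycling the eight NOR/OPR combinations, interval ethograms built from
renewal/Poisson bout processes, and 2 Hz keypoint trajectories rendered
from the ethogram.  Group presets encode the effect profiles of
hippocampal-lesion, medial-entorhinal-lesion, amyloid-model and control
animals so that every downstream stage can be tested against known ground
truth.

The alternation-memory model: the probability that a visit alternates from
the previous side after an inter-trial interval ITI (minutes) is

    P(ITI) = 0.5 + (p_max - 0.5 + persev) * exp(-ITI / tau_mem) - persev

which rises to ``p_max`` at short ITI, crosses chance, and settles at
``0.5 - persev`` (below chance: side perseveration) at long ITI.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .io_core import (
    BehaviorInterval,
    CageGeometry,
    DrumChangeEvent,
    DRUM_KINDS,
    BODY_PARTS,
    CAGE_X_MM,
    CAGE_Y_MM,
    LightSchedule,
    TrajectoryTable,
    VisitEvent,
    derive_visit_fields,
)

import pandas as pd

__all__ = [
    "GroupProfile",
    "CohortSpec",
    "Cohort",
    "MouseData",
    "PRESETS",
    "alternation_probability",
    "draw_quiescence",
    "simulate_visits",
    "simulate_drum_schedule",
    "simulate_ethogram",
    "render_pose",
    "make_cohort",
    "paper_like_spec",
]


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters for one mouse group.

    Rates are per hour, durations in minutes, fractions of phase time.
    """

    p_max: float = 0.78            # asymptotic short-ITI alternation success
    tau_mem: float = 5.3           # memory decay constant, min
    persev: float = 0.05           # long-ITI below-chance offset
    visit_rate_light: float = 0.7  # visits/h
    visit_rate_dark: float = 2.6
    explore_rate: float = 0.40     # panel bouts/h (both sides combined)
    novelty_boost: float = 3.0     # multiplier on changed-side rate
    novelty_decay: float = 6.0     # min
    notice_latency_mean: float = 1.2   # min
    quiesc_bout_mean_light: float = 67.0   # min
    quiesc_bout_mean_dark: float = 29.0
    quiesc_frac_light: float = 0.80
    quiesc_frac_dark: float = 0.23
    wheel_min_per_day: float = 133.0
    locomotion_min_per_day: float = 450.0

    def __post_init__(self):
        if not 0.5 <= self.p_max <= 1.0:
            raise ValueError(f"p_max {self.p_max} outside [0.5, 1]")
        if not 0 <= self.persev < 0.5:
            raise ValueError(f"persev {self.persev} outside [0, 0.5)")
        for name in ("tau_mem", "visit_rate_light", "visit_rate_dark",
                     "explore_rate", "novelty_decay", "notice_latency_mean",
                     "quiesc_bout_mean_light", "quiesc_bout_mean_dark"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("quiesc_frac_light", "quiesc_frac_dark"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} outside [0, 1]")


#: Group presets.  Means are anchored to the reported group statistics
#: (post-lesion values for the lesion groups, late-period values for the
#: amyloid model); the entorhinal group's dark-phase nap shortening is the
#: group's distinguishing trait and is set to a clearly separable value.
PRESETS: dict[str, GroupProfile] = {
    "control": GroupProfile(),
    "hippocampal": GroupProfile(
        p_max=0.583, tau_mem=5.7, persev=0.05,
        visit_rate_light=2.5, visit_rate_dark=9.8,
        explore_rate=0.85, notice_latency_mean=1.6,
        quiesc_bout_mean_light=68.0, quiesc_bout_mean_dark=20.0,
        quiesc_frac_light=0.73, quiesc_frac_dark=0.073,
        wheel_min_per_day=61.0, locomotion_min_per_day=685.0),
    "entorhinal": GroupProfile(
        p_max=0.751, tau_mem=5.6, persev=0.05,
        visit_rate_light=0.9, visit_rate_dark=3.35,
        explore_rate=0.50, notice_latency_mean=1.4,
        quiesc_bout_mean_light=55.0, quiesc_bout_mean_dark=15.0,
        quiesc_frac_light=0.75, quiesc_frac_dark=0.236,
        wheel_min_per_day=141.0, locomotion_min_per_day=500.0),
    "amyloid": GroupProfile(
        p_max=0.70, tau_mem=5.0, persev=0.05,
        visit_rate_light=0.7, visit_rate_dark=2.6,
        explore_rate=0.13, notice_latency_mean=1.4,
        quiesc_bout_mean_light=90.0, quiesc_bout_mean_dark=30.0,
        quiesc_frac_light=0.82, quiesc_frac_dark=0.25,
        wheel_min_per_day=91.0, locomotion_min_per_day=380.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout: ``groups`` is a list of (name, profile, n_mice)."""

    groups: list
    duration_days: int = 10
    light_schedule: LightSchedule = field(default_factory=LightSchedule)
    master_seed: int = 0
    include_pose: bool = False
    mouse_cv: float = 0.06   # inter-mouse lognormal CV on rate/duration params

    def __post_init__(self):
        names = [g[0] for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate group names in {names}")
        if self.duration_days < 2:
            raise ValueError("duration_days must be >= 2 (one drum change)")
        for _, _, n in self.groups:
            if n < 1:
                raise ValueError("each group needs n_mice >= 1")


@dataclass
class MouseData:
    mouse_id: str
    group: str
    profile: GroupProfile
    visits: list
    drum_schedule: list
    ethogram: list
    pose: TrajectoryTable | None = None


@dataclass
class Cohort:
    spec: CohortSpec
    mice: dict  # mouse_id -> MouseData

    @property
    def truth(self) -> dict:
        return {mid: md.group for mid, md in self.mice.items()}


def alternation_probability(iti_min, profile: GroupProfile):
    """P(alternate | ITI in minutes) under the exponential memory model."""
    iti_min = np.asarray(iti_min, float)
    amp = profile.p_max - 0.5 + profile.persev
    return 0.5 + amp * np.exp(-iti_min / profile.tau_mem) - profile.persev


# ---------------------------------------------------------------------------
# Visits

def _poisson_times(rate_of_t, rate_max, t_max, rng) -> np.ndarray:
    """Inhomogeneous Poisson times on [0, t_max] by thinning (rates per s)."""
    n = rng.poisson(rate_max * t_max)
    cand = np.sort(rng.uniform(0.0, t_max, n))
    keep = rng.uniform(0.0, 1.0, n) < rate_of_t(cand) / rate_max
    return cand[keep]


def draw_quiescence(profile: GroupProfile, days: int, seed: int,
                    schedule: LightSchedule | None = None):
    """Nap bouts as (start, end) pairs, for sharing between generators.

    Drawing the nap process once and passing it to both
    :func:`simulate_visits` and :func:`simulate_ethogram` keeps the two
    streams coherent: the mouse neither drinks nor moves while asleep.
    """
    schedule = schedule or LightSchedule()
    rng = np.random.default_rng(seed)
    return [(s, e) for s, e, _ in
            _renewal_quiescence(profile, days, schedule, rng)]


def simulate_visits(profile: GroupProfile, days: int, seed: int,
                    schedule: LightSchedule | None = None,
                    mouse_id: str = "m0",
                    nap_intervals=None) -> list[VisitEvent]:
    """Spout visits: phase-modulated Poisson timing, memory-model sides.

    When ``nap_intervals`` is given, the visit rate is zero inside naps
    and inflated by the awake fraction of each phase elsewhere, so daily
    visit counts still match the profile's rates.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    schedule = schedule or LightSchedule()
    rng = np.random.default_rng(seed)
    r_l = profile.visit_rate_light / 3600.0
    r_d = profile.visit_rate_dark / 3600.0

    if nap_intervals is not None:
        nap_s = np.asarray([s for s, _ in nap_intervals])
        nap_e = np.asarray([e for _, e in nap_intervals])

    def rate(t):
        r = np.where(schedule.is_light(t), r_l, r_d)
        if nap_intervals is not None and len(nap_s):
            f = np.where(schedule.is_light(t),
                         profile.quiesc_frac_light, profile.quiesc_frac_dark)
            r = r / np.clip(1.0 - f, 0.1, 1.0)
            i = np.searchsorted(nap_e, np.asarray(t, float), side="right")
            i = np.clip(i, 0, len(nap_s) - 1)
            asleep = (np.asarray(t) >= nap_s[i]) & (np.asarray(t) < nap_e[i])
            r = np.where(asleep, 0.0, r)
        return r

    # drinking comes in bouts: Poisson bout initiations plus geometric
    # follow-up visits at short gaps, so short-ITI trials are well sampled
    p_follow = 0.55
    init_rate_scale = 1.0 - p_follow

    def init_rate(t):
        return rate(t) * init_rate_scale

    comp_max = 1.0
    if nap_intervals is not None:
        comp_max = 1.0 / np.clip(
            1.0 - max(profile.quiesc_frac_light, profile.quiesc_frac_dark),
            0.1, 1.0)
    inits = _poisson_times(
        init_rate, max(r_l, r_d) * init_rate_scale * comp_max,
        days * 86400.0, rng)
    t_max = days * 86400.0
    times = []
    for t0 in inits:
        times.append(t0)
        t = t0
        while rng.uniform() < p_follow:
            t = t + rng.exponential(40.0)
            if t >= t_max:
                break
            times.append(t)
    times = np.sort(np.asarray(times))
    sides = []
    prev_side = "L" if rng.uniform() < 0.5 else "R"
    prev_t = None
    for t in times:
        if prev_t is None:
            side = prev_side
        else:
            p_alt = float(alternation_probability((t - prev_t) / 60.0, profile))
            if rng.uniform() < p_alt:
                side = "R" if prev_side == "L" else "L"
            else:
                side = prev_side
        sides.append(side)
        prev_side, prev_t = side, t
    events = [VisitEvent(mouse_id, float(t), s) for t, s in zip(times, sides)]
    return derive_visit_fields(events)


# ---------------------------------------------------------------------------
# Drum schedule

def simulate_drum_schedule(days: int, seed: int,
                           schedule: LightSchedule | None = None,
                           window_clock: tuple = (0.0, 4 * 3600.0),
                           ) -> list[DrumChangeEvent]:
    """One drum change per two days, inside the mid-dark clock window.

    Kinds cycle through the eight NOR/OPR combinations in a randomized
    order per 16-day block.  Pattern bookkeeping follows the task rules:
    an OPR side takes the pattern previously shown on the opposite side, a
    NOR side takes a pattern different from both currently shown ones.
    """
    if days < 2:
        raise ValueError("days must be >= 2")
    schedule = schedule or LightSchedule()
    rng = np.random.default_rng(seed)
    n_changes = days // 2

    kinds: list[str] = []
    while len(kinds) < n_changes:
        kinds.extend(rng.permutation(DRUM_KINDS))
    kinds = kinds[:n_changes]

    w0, w1 = window_clock
    left, right = rng.choice(np.arange(1, 9), size=2, replace=False)
    events = []
    for k, kind in enumerate(kinds):
        day_start = (2 * k + 1) * 86400.0
        clock = rng.uniform(w0, w1)
        offset = (clock - schedule.experiment_start) % 86400.0
        t = day_start + offset
        left, right = _apply_drum_kind(kind, int(left), int(right), rng)
        events.append(DrumChangeEvent(float(t), kind, left, right))
    return events


def _novel(exclude, rng) -> int:
    choices = [p for p in range(1, 9) if p not in exclude]
    return int(rng.choice(choices))


def _apply_drum_kind(kind: str, left: int, right: int, rng):
    if kind == "L-NOR":
        return _novel({left, right}, rng), right
    if kind == "R-NOR":
        return left, _novel({left, right}, rng)
    if kind == "double-NOR":
        new_l = _novel({left, right}, rng)
        new_r = _novel({left, right, new_l}, rng)
        return new_l, new_r
    if kind == "L-OPR":
        return right, right
    if kind == "R-OPR":
        return left, left
    if kind == "double-OPR":
        return right, left
    if kind == "L-NOR+R-OPR":
        return _novel({left, right}, rng), left
    if kind == "L-OPR+R-NOR":
        return right, _novel({left, right}, rng)
    raise ValueError(f"unknown kind {kind!r}")


def changed_sides(kind: str) -> tuple:
    """Which panels a change of this kind altered."""
    if kind in ("L-NOR", "L-OPR"):
        return ("L",)
    if kind in ("R-NOR", "R-OPR"):
        return ("R",)
    return ("L", "R")


# ---------------------------------------------------------------------------
# Ethogram

def _renewal_quiescence(profile, days, schedule, rng, visit_times=None):
    """Alternating-renewal nap bouts, phase-dependent mean and fraction.

    Naps never span a spout visit: a bout that would overlap the next
    visit is truncated there (dropped if the remainder falls under 5 min),
    since a drinking mouse is by definition not quiescent.
    """
    t_max = days * 86400.0
    visits = (np.sort(np.asarray(visit_times, float))
              if visit_times is not None else np.empty(0))
    bounds = schedule.phase_boundaries(t_max + 86400.0)
    out = []
    t = 0.0
    while t < t_max:
        # exponential gap with a phase-dependent hazard: memorylessness
        # lets us redraw whenever the gap crosses a phase boundary
        while True:
            light = bool(schedule.is_light(t))
            m = (profile.quiesc_bout_mean_light if light
                 else profile.quiesc_bout_mean_dark) * 60.0
            f = (profile.quiesc_frac_light if light
                 else profile.quiesc_frac_dark)
            f = min(max(f, 1e-6), 0.999)
            gap = rng.exponential(m * (1.0 - f) / f)
            nxt = bounds[np.searchsorted(bounds, t, side="right")] \
                if np.searchsorted(bounds, t, side="right") < len(bounds) \
                else t_max
            if t + gap <= nxt or nxt >= t_max:
                t += gap
                break
            t = nxt
        if t >= t_max:
            break
        light = bool(schedule.is_light(t))
        m = (profile.quiesc_bout_mean_light if light
             else profile.quiesc_bout_mean_dark) * 60.0
        # bouts are >= 5 min by construction: 300 s plus a gamma excess
        excess = max(m - 300.0, 1.0)
        dur = 300.0 + rng.gamma(3.0, excess / 3.0)
        end = min(t + dur, t_max)
        i = np.searchsorted(visits, t)
        if i < len(visits) and visits[i] < end:
            end = visits[i] - 5.0
        if end - t >= 300.0:
            out.append((t, end, "quiescence"))
        t = max(end, t + 1.0)
    return out


def _poisson_bouts(rate_per_h_of_t, rate_max_per_h, t_max, dur_sampler, label,
                   rng):
    starts = _poisson_times(
        lambda t: np.asarray(rate_per_h_of_t(t)) / 3600.0,
        rate_max_per_h / 3600.0, t_max, rng)
    return [(float(s), float(min(s + dur_sampler(), t_max)), label)
            for s in starts]


class _ClaimedTime:
    """Disjoint sorted claimed intervals with fast subtract-and-claim."""

    def __init__(self):
        self.starts: list[float] = []
        self.ends: list[float] = []

    def subtract_and_claim(self, s: float, e: float, min_keep: float):
        """Free sub-pieces of [s, e) of length >= min_keep; claim them."""
        import bisect
        i = bisect.bisect_right(self.ends, s)
        pieces = []
        cur = s
        j = i
        while j < len(self.starts) and self.starts[j] < e:
            if self.starts[j] > cur:
                pieces.append((cur, min(self.starts[j], e)))
            cur = max(cur, self.ends[j])
            j += 1
        if cur < e:
            pieces.append((cur, e))
        kept = [(a, b) for a, b in pieces if b - a >= min_keep]
        for a, b in kept:
            k = bisect.bisect_left(self.starts, a)
            self.starts.insert(k, a)
            self.ends.insert(k, b)
        return kept


def simulate_ethogram(profile: GroupProfile, visits, drum_schedule, days: int,
                      seed: int, schedule: LightSchedule | None = None,
                      nap_intervals=None) -> list[BehaviorInterval]:
    """Interval ethogram consistent with the visits and drum schedule.

    Priority on overlap: T-maze > quiescence > wheel > panel > other-mobile;
    lower-priority bouts are trimmed against time already claimed.
    Quiescence pieces shorter than 5 min after trimming are dropped so the
    ethogram honours the nap definition.
    """
    schedule = schedule or LightSchedule()
    t_max = days * 86400.0
    for v in visits:
        if not 0 <= v.t <= t_max:
            raise ValueError(f"visit at t={v.t} outside [0, {t_max}]")
    rng = np.random.default_rng(seed)

    # 1. T-maze dwells around each visit
    tmaze = []
    for v in visits:
        dwell = rng.uniform(8.0, 25.0)
        s = max(v.t - 3.0, 0.0)
        e = min(v.t + dwell, t_max)
        label = "tmaze_L" if v.side == "L" else "tmaze_R"
        if tmaze and s < tmaze[-1][1]:
            s = tmaze[-1][1]
            if e - s < 2.0:
                continue
        tmaze.append((s, e, label))

    # 2. quiescence renewal (naps never span a visit); a pre-drawn nap
    # process (shared with simulate_visits) is used when supplied
    if nap_intervals is not None:
        vt = np.sort(np.asarray([v.t for v in visits]))
        quiesc = []
        for s, e in nap_intervals:
            i = np.searchsorted(vt, s)
            if i < len(vt) and vt[i] < e:
                e = float(vt[i]) - 5.0
            if e - s >= 300.0:
                quiesc.append((s, min(e, t_max), "quiescence"))
    else:
        quiesc = _renewal_quiescence(
            profile, days, schedule, rng,
            visit_times=[v.t for v in visits])

    # awake-time compensation: bout processes are thinned later against
    # already-claimed (mostly quiescent) time, so placement rates are
    # inflated by the expected awake fraction of each phase
    def awake_comp(t):
        f = np.where(schedule.is_light(t),
                     profile.quiesc_frac_light, profile.quiesc_frac_dark)
        return 1.0 / np.clip(1.0 - f, 0.1, 1.0)

    comp_max = 1.0 / np.clip(
        1.0 - max(profile.quiesc_frac_light, profile.quiesc_frac_dark),
        0.1, 1.0)

    # 3. wheel bouts, concentrated in the dark phase (4:1)
    wheel_bout_mean = 10 * 60.0
    n_per_day = profile.wheel_min_per_day * 60.0 / wheel_bout_mean
    base = n_per_day / 24.0  # bouts/h if uniform

    def wheel_rate(t):
        w = np.where(schedule.is_light(t), 0.4, 1.6)
        return base * w * awake_comp(t)

    wheel = _poisson_bouts(
        wheel_rate, base * 1.6 * comp_max, t_max,
        lambda: rng.gamma(2.0, wheel_bout_mean / 2.0), "wheel", rng)

    # 4. panel exploration, with post-change novelty response
    panel_bout_mean = 30.0
    changes_by_side = {"L": [], "R": []}
    for ev in drum_schedule:
        for side in changed_sides(ev.kind):
            changes_by_side[side].append(ev.t)
    panel = []
    for side in ("L", "R"):
        base_side = profile.explore_rate / 2.0
        ch = np.asarray(changes_by_side[side])

        def rate(t, ch=ch, base_side=base_side):
            t = np.asarray(t, float)
            r = np.full(t.shape, base_side)
            for c in ch:
                dt = (t - c) / 60.0
                mask = dt >= 0
                r = r + np.where(
                    mask,
                    base_side * (profile.novelty_boost - 1.0)
                    * np.exp(-np.clip(dt, 0, None) / profile.novelty_decay),
                    0.0)
            return r * awake_comp(t)

        rmax = base_side * max(profile.novelty_boost, 1.0) * comp_max
        panel += _poisson_bouts(
            rate, rmax, t_max,
            lambda: max(rng.exponential(panel_bout_mean), 5.0),
            f"panel_{side}", rng)
        if profile.novelty_boost > 1.0:
            # first-notice bout after each change on this side
            for c in ch:
                lat = rng.exponential(profile.notice_latency_mean * 60.0)
                s = c + lat
                if s < t_max:
                    d = max(rng.exponential(panel_bout_mean), 5.0)
                    panel.append((s, min(s + d, t_max), f"panel_{side}"))

    # 5. other-mobile fills toward the locomotion target
    panel_min_day = len(panel) * panel_bout_mean / 60.0 / days
    other_target = max(
        profile.locomotion_min_per_day - profile.wheel_min_per_day
        - panel_min_day, 10.0)
    other_bout_mean = 8 * 60.0
    n_other = other_target * 60.0 / other_bout_mean / 24.0

    def other_rate(t):
        return n_other * np.where(schedule.is_light(t), 0.5, 1.5) \
            * awake_comp(t)

    other = _poisson_bouts(
        other_rate, n_other * 1.5 * comp_max, t_max,
        lambda: rng.gamma(2.0, other_bout_mean / 2.0), "other_mobile", rng)

    # merge by priority with trimming
    claimed = _ClaimedTime()
    final = []
    for group, min_keep in ((tmaze, 2.0), (quiesc, 300.0), (wheel, 2.0),
                            (sorted(panel), 2.0), (other, 2.0)):
        for s, e, label in group:
            for ps, pe in claimed.subtract_and_claim(s, e, min_keep):
                final.append(BehaviorInterval(ps, pe, label))
    final.sort(key=lambda iv: iv.start)
    return final


# ---------------------------------------------------------------------------
# Pose rendering

_ANCHOR_OF = {
    "tmaze_L": "corridor_L", "tmaze_R": "corridor_R",
    "panel_L": "panel_L", "panel_R": "panel_R",
    "wheel": "wheel", "quiescence": "nest",
}

# anatomical offsets (mm) along the heading axis (u) and lateral axis (v)
_PART_OFFSETS = {
    "snout": (28.0, 0.0), "ear_L": (18.0, 9.0), "ear_R": (18.0, -9.0),
    "neck": (12.0, 0.0), "spine1": (2.0, 0.0), "spine2": (-10.0, 0.0),
    "spine3": (-22.0, 0.0), "tail_base": (-34.0, 0.0),
}


def render_pose(ethogram, duration_s: float, seed: int,
                geometry: CageGeometry | None = None,
                fps: float = 2.0) -> TrajectoryTable:
    """2 Hz body-part trajectories consistent with an interval ethogram.

    Anchored behaviors (quiescence, wheel, panels, T-maze) keep the body at
    the corresponding landmark with bout-scale jitter (sub-threshold during
    quiescence); other-mobile segments and unlabeled gaps follow a bounded
    random walk.  Deterministic for a given seed.
    """
    geometry = geometry or CageGeometry()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    dt = 1.0 / fps

    # per-frame segment labels from the ethogram, "" = unlabeled gap
    labels = np.full(n, "", dtype=object)
    times = np.arange(n) * dt
    for iv in ethogram:
        i0 = int(np.ceil(iv.start * fps))
        i1 = min(int(np.floor(iv.end * fps)) + 1, n)
        if i1 > i0:
            labels[i0:i1] = iv.label

    center = np.empty((n, 2))
    heading = np.empty(n)
    pos = np.array([CAGE_X_MM / 2, CAGE_Y_MM / 2])
    ang = 0.0
    # iterate over constant-label runs
    run_edges = np.flatnonzero(
        np.r_[True, labels[1:] != labels[:-1], True])
    for a, b in zip(run_edges[:-1], run_edges[1:]):
        lab = labels[a]
        m = b - a
        if lab in _ANCHOR_OF:
            anchor = geometry.center(_ANCHOR_OF[lab])
            if lab == "quiescence":
                # sub-threshold jitter: summed 8-part displacement << 2 mm
                jit = rng.uniform(-0.04, 0.04, size=(m, 2))
                center[a:b] = anchor + jit
                heading[a:b] = ang
            else:
                jit = rng.normal(0.0, 4.0, size=(m, 2))
                center[a:b] = anchor + np.clip(jit, -20, 20)
                heading[a:b] = ang + rng.normal(0.0, 0.3, size=m)
                ang = heading[b - 1]
            pos = center[b - 1].copy()
        else:
            step_sd = 12.0 if lab == "other_mobile" else 1.5
            steps = rng.normal(0.0, step_sd, size=(m, 2))
            path = pos + np.cumsum(steps, axis=0)
            # reflect into cage bounds
            path[:, 0] = np.abs(path[:, 0])
            path[:, 0] = CAGE_X_MM - np.abs(CAGE_X_MM - path[:, 0] % (2 * CAGE_X_MM))
            path[:, 1] = np.abs(path[:, 1])
            path[:, 1] = CAGE_Y_MM - np.abs(CAGE_Y_MM - path[:, 1] % (2 * CAGE_Y_MM))
            center[a:b] = path
            d = np.diff(np.vstack([pos[None, :], path]), axis=0)
            heading[a:b] = np.arctan2(d[:, 1], d[:, 0])
            pos = path[-1].copy()
            ang = heading[b - 1]

    u = np.stack([np.cos(heading), np.sin(heading)], axis=1)
    v = np.stack([-np.sin(heading), np.cos(heading)], axis=1)
    cols = {}
    for part in BODY_PARTS:
        du, dv = _PART_OFFSETS[part]
        xy = center + du * u + dv * v
        xy[:, 0] = np.clip(xy[:, 0], 0.0, CAGE_X_MM)
        xy[:, 1] = np.clip(xy[:, 1], 0.0, CAGE_Y_MM)
        cols[(part, "x")] = xy[:, 0]
        cols[(part, "y")] = xy[:, 1]
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return TrajectoryTable(df, fps=fps, t0=0.0)


# ---------------------------------------------------------------------------
# Cohort assembly

def _jitter_profile(profile: GroupProfile, rng, cv: float) -> GroupProfile:
    """Per-mouse individuality: lognormal jitter on rates/durations,
    additive jitter on probabilities, all kept inside valid ranges."""
    kw = {}
    for f in dataclasses.fields(profile):
        val = getattr(profile, f.name)
        if f.name in ("p_max", "persev"):
            kw[f.name] = float(np.clip(
                val + rng.normal(0.0, 0.015),
                0.5 if f.name == "p_max" else 0.0,
                1.0 if f.name == "p_max" else 0.49))
        elif f.name in ("quiesc_frac_light", "quiesc_frac_dark"):
            kw[f.name] = float(np.clip(val + rng.normal(0.0, 0.02), 0.01, 0.97))
        else:
            kw[f.name] = float(val * rng.lognormal(0.0, cv))
    return GroupProfile(**kw)


def make_cohort(spec: CohortSpec) -> Cohort:
    """Generate all raw data streams plus ground-truth group labels.

    Per-mouse random streams are spawned from the master seed, so changing
    one mouse's data requires changing the master seed; a given spec is
    bit-reproducible.
    """
    root = np.random.SeedSequence(spec.master_seed)
    # one drum schedule per cohort: rotations are programmed by the
    # experimenter and shared across cages
    drum_seed = int(root.generate_state(1)[0] % (2 ** 31))
    drums = simulate_drum_schedule(spec.duration_days, drum_seed,
                                   schedule=spec.light_schedule)
    mice: dict[str, MouseData] = {}
    for g_idx, (name, profile, n_mice) in enumerate(spec.groups):
        group_ss = root.spawn(len(spec.groups))[g_idx]
        mouse_sss = group_ss.spawn(n_mice)
        for j in range(n_mice):
            mid = f"{name}_{j:02d}"
            seeds = mouse_sss[j].generate_state(5) % (2**31)
            rng_prof = np.random.default_rng(int(seeds[0]))
            prof = _jitter_profile(profile, rng_prof, spec.mouse_cv)
            naps = draw_quiescence(
                prof, spec.duration_days, int(seeds[1]) ^ 0x5A5A5A,
                schedule=spec.light_schedule)
            visits = simulate_visits(
                prof, spec.duration_days, int(seeds[1]),
                schedule=spec.light_schedule, mouse_id=mid,
                nap_intervals=naps)
            etho = simulate_ethogram(
                prof, visits, drums, spec.duration_days, int(seeds[3]),
                schedule=spec.light_schedule, nap_intervals=naps)
            pose = None
            if spec.include_pose:
                pose = render_pose(
                    etho, spec.duration_days * 86400.0, int(seeds[4]))
            mice[mid] = MouseData(mid, name, prof, visits, drums, etho, pose)
    return Cohort(spec, mice)


def paper_like_spec(n_per_group: int = 5, duration_days: int = 10,
                    master_seed: int = 0, **kw) -> CohortSpec:
    """Four-group cohort with the preset effect profiles."""
    groups = [(name, PRESETS[name], n_per_group) for name in
              ("control", "hippocampal", "entorhinal", "amyloid")]
    return CohortSpec(groups=groups, duration_days=duration_days,
                      master_seed=master_seed, **kw)
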