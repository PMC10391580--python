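"""Per-mouse behavioral statistics and the 32-feature phenotype table.

Everything here reduces raw event streams to the per-animal numbers used
for group comparison and clustering: the alternation-performance curve
over log-spaced ITI bins and its derived memory time span, novelty
exploration responses around drum changes, quiescence ("nap") statistics
split by light phase, and wheel/locomotion summaries.  The canonical
32-feature list is fixed in :data:`FEATURE_CATEGORIES` with eight features
per behavioral category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import BehaviorInterval, LightSchedule, TrajectoryTable
from .synthetic_cohort import Cohort, changed_sides

__all__ = [
    "PerformanceCurve",
    "FEATURE_CATEGORIES",
    "FEATURE_NAMES",
    "default_iti_bins",
    "performance_by_iti",
    "memory_time_span",
    "tmaze_summary",
    "exploration_response",
    "quiescence_summary",
    "locomotion_summary",
    "phenotype_mouse",
    "impute_features",
    "build_feature_table",
]

#: The canonical 32 features, 8 per category.
FEATURE_CATEGORIES = {
    "tmaze": [
        "max_performance", "memory_time_span", "perf_short", "perf_mid",
        "perf_long", "max_daily_visits", "mean_daily_visits", "median_iti",
    ],
    "nor_opr": [
        "mean_daily_exploration", "nor_post_pre", "opr_post_pre",
        "mean_latency", "side_asymmetry", "mean_panel_bout",
        "nochange_exploration", "post_pre_ratio",
    ],
    "quiescence": [
        "quiesc_total_light", "quiesc_total_dark", "quiesc_bout_light",
        "quiesc_bout_dark", "quiesc_freq_light", "quiesc_freq_dark",
        "longest_bout", "light_dark_ratio",
    ],
    "wheel_locomotion": [
        "movement_per_day", "wheel_per_day", "max_daily_wheel",
        "wheel_bouts_per_day", "mean_wheel_bout", "dark_movement_fraction",
        "mean_mobile_speed", "distance_per_day",
    ],
}

FEATURE_NAMES = [f for fs in FEATURE_CATEGORIES.values() for f in fs]

CATEGORY_OF = {f: c for c, fs in FEATURE_CATEGORIES.items() for f in fs}


def default_iti_bins(n_bins: int = 12, lo_min: float = 0.25,
                     hi_min: float = 240.0) -> np.ndarray:
    """Log-spaced ITI bin edges in minutes."""
    return np.logspace(np.log10(lo_min), np.log10(hi_min), n_bins + 1)


@dataclass
class PerformanceCurve:
    """Alternation success per log-spaced ITI bin."""

    bin_edges_min: np.ndarray
    n: np.ndarray
    k: np.ndarray
    p_hat: np.ndarray
    p_binom: np.ndarray       # exact two-sided binomial p vs 0.5
    n_min: int = 20

    @property
    def reliable(self) -> np.ndarray:
        return self.n >= self.n_min

    @property
    def centers_min(self) -> np.ndarray:
        e = self.bin_edges_min
        return np.sqrt(e[:-1] * e[1:])


def performance_by_iti(visits, bins: np.ndarray | None = None,
                       n_min: int = 20) -> PerformanceCurve:
    """Bin trials by ITI and test each bin's success fraction against 0.5."""
    trials = [(v.iti / 60.0, v.rewarded) for v in visits if v.iti is not None]
    if not trials:
        raise ValueError("no visits with an ITI (need >= 2 visits)")
    iti = np.array([t[0] for t in trials])
    success = np.array([t[1] for t in trials], bool)
    edges = default_iti_bins() if bins is None else np.asarray(bins, float)
    idx = np.digitize(iti, edges) - 1
    nb = len(edges) - 1
    n = np.zeros(nb, int)
    k = np.zeros(nb, int)
    for i in range(nb):
        m = idx == i
        n[i] = m.sum()
        k[i] = success[m].sum()
    with np.errstate(invalid="ignore"):
        p_hat = np.where(n > 0, k / np.maximum(n, 1), np.nan)
    p_binom = np.array([
        stats.binomtest(int(k[i]), int(n[i]), 0.5).pvalue if n[i] > 0
        else np.nan for i in range(nb)])
    return PerformanceCurve(edges, n, k, p_hat, p_binom, n_min=n_min)


def memory_time_span(curve: PerformanceCurve) -> float:
    """ITI (minutes) of the first downward crossing of 50% performance.

    Located by linear interpolation between adjacent reliable bin centers
    on a log-ITI axis; NaN if the curve never exceeds 0.5 or never crosses.
    """
    mask = curve.reliable & ~np.isnan(curve.p_hat)
    if mask.sum() < 2:
        return float("nan")
    c = curve.centers_min[mask]
    p = curve.p_hat[mask]
    if p.max() <= 0.5:
        return float("nan")
    for i in range(len(p) - 1):
        if p[i] > 0.5 >= p[i + 1]:
            lo, hi = np.log(c[i]), np.log(c[i + 1])
            frac = (p[i] - 0.5) / (p[i] - p[i + 1])
            return float(np.exp(lo + frac * (hi - lo)))
    return float("nan")


def _band_performance(visits, lo_min: float, hi_min: float) -> float:
    sel = [v.rewarded for v in visits
           if v.iti is not None and lo_min <= v.iti / 60.0 < hi_min]
    return float(np.mean(sel)) if sel else float("nan")


def tmaze_summary(visits, t_max: float,
                  schedule: LightSchedule | None = None,
                  bins: np.ndarray | None = None, n_min: int = 20,
                  running_window_days: int = 3) -> dict:
    """Alternation-task summary for one mouse over [0, t_max] seconds."""
    schedule = schedule or LightSchedule()
    visits = [v for v in visits if 0 <= v.t <= t_max]
    if not visits:
        raise ValueError("no visits inside the requested period")
    curve = performance_by_iti(visits, bins=bins, n_min=n_min)
    rel = curve.reliable & ~np.isnan(curve.p_hat)
    max_perf = float(np.max(curve.p_hat[rel])) if rel.any() else float("nan")

    days = schedule.day_index(np.array([v.t for v in visits]))
    n_days = max(int(np.floor(t_max / 86400.0)), 1)
    counts = np.bincount(days - days.min(), minlength=n_days)
    itis = np.array([v.iti for v in visits if v.iti is not None])

    day_rewarded: dict[int, list] = {}
    for v in visits:
        if v.rewarded is not None:
            day_rewarded.setdefault(
                int(schedule.day_index(v.t)), []).append(v.rewarded)
    day_ids = sorted(day_rewarded)
    daily_perf = np.array([np.mean(day_rewarded[d]) for d in day_ids])
    w = running_window_days
    running = (pd.Series(daily_perf).rolling(w, min_periods=1, center=True)
               .mean().to_numpy() if len(daily_perf) else np.array([]))

    return {
        "curve": curve,
        "max_performance": max_perf,
        "memory_time_span": memory_time_span(curve),
        "perf_short": _band_performance(visits, 0.0, 2.0),
        "perf_mid": _band_performance(visits, 2.0, 10.0),
        "perf_long": _band_performance(visits, 10.0, np.inf),
        "max_daily_visits": float(counts.max()),
        "mean_daily_visits": float(len(visits) / n_days),
        "median_iti": float(np.median(itis) / 60.0) if itis.size
        else float("nan"),
        "daily_days": np.asarray(day_ids),
        "daily_performance": daily_perf,
        "running_performance": running,
    }


# ---------------------------------------------------------------------------
# Novelty exploration

def _panel_time_in(intervals, side, t0, t1) -> float:
    label = f"panel_{side}"
    tot = 0.0
    for iv in intervals:
        if iv.label == label:
            tot += max(0.0, min(iv.end, t1) - max(iv.start, t0))
    return tot


def exploration_response(ethogram, drum_schedule, t_max: float,
                         window_s: float = 1200.0,
                         schedule: LightSchedule | None = None,
                         reference_clock: float = 12 * 3600.0) -> dict:
    """Panel-exploration response to drum changes.

    For each change: total changed-side panel time in the 20-min windows
    before and after, and the latency to the first changed-panel bout
    onset (censored at the window end).  Days without a change are scored
    at a fixed reference clock time as a no-change control.
    """
    schedule = schedule or LightSchedule()
    panel = [iv for iv in ethogram if iv.label.startswith("panel_")]
    records = []
    for ev in drum_schedule:
        if ev.t < window_s or ev.t > t_max - window_s:
            warnings.warn(f"drum change at t={ev.t} too close to data edge; "
                          "skipped")
            continue
        sides = changed_sides(ev.kind)
        task_of = _side_tasks(ev.kind)
        for side in sides:
            pre = _panel_time_in(panel, side, ev.t - window_s, ev.t)
            post = _panel_time_in(panel, side, ev.t, ev.t + window_s)
            onsets = [iv.start - ev.t for iv in panel
                      if iv.label == f"panel_{side}"
                      and ev.t < iv.start <= ev.t + window_s]
            censored = not onsets
            latency = min(onsets) if onsets else window_s
            records.append({
                "t": ev.t, "kind": ev.kind, "side": side,
                "task": task_of[side], "pre_s": pre, "post_s": post,
                "latency_min": latency / 60.0, "censored": censored,
            })

    change_days = {int(schedule.day_index(ev.t)) for ev in drum_schedule}
    n_days = int(np.floor(t_max / 86400.0))
    nochange = []
    for d in range(n_days):
        if d in change_days:
            continue
        t_ref = d * 86400.0 + (reference_clock - schedule.experiment_start) \
            % 86400.0
        if t_ref < window_s or t_ref > t_max - window_s:
            continue
        tot = sum(_panel_time_in(panel, s, t_ref, t_ref + window_s)
                  for s in ("L", "R"))
        nochange.append(tot)

    pre = np.array([r["pre_s"] for r in records])
    post = np.array([r["post_s"] for r in records])
    lat = np.array([r["latency_min"] for r in records
                    if not r["censored"]])
    nor = [r["post_s"] - r["pre_s"] for r in records if r["task"] == "NOR"]
    opr = [r["post_s"] - r["pre_s"] for r in records if r["task"] == "OPR"]
    total_l = _panel_time_in(panel, "L", 0, t_max)
    total_r = _panel_time_in(panel, "R", 0, t_max)
    denom = total_l + total_r
    bouts = [iv.duration for iv in panel]
    agg = {
        "mean_daily_exploration": denom / 60.0 / max(n_days, 1),
        "nor_post_pre": float(np.mean(nor)) / 60.0 if nor else float("nan"),
        "opr_post_pre": float(np.mean(opr)) / 60.0 if opr else float("nan"),
        "mean_latency": float(np.mean(lat)) if lat.size else float("nan"),
        "side_asymmetry": (total_l - total_r) / denom if denom > 0
        else float("nan"),
        "mean_panel_bout": float(np.mean(bouts)) / 60.0 if bouts
        else float("nan"),
        "nochange_exploration": float(np.mean(nochange)) / 60.0
        if nochange else float("nan"),
        "post_pre_ratio": float(post.sum() / pre.sum())
        if pre.sum() > 0 else float("nan"),
    }
    return {"records": records, "nochange_s": nochange, "aggregates": agg}


def _side_tasks(kind: str) -> dict:
    out = {}
    if "double" in kind:
        task = "NOR" if "NOR" in kind else "OPR"
        return {"L": task, "R": task}
    for part in kind.split("+"):
        side, task = part.split("-")
        out[side] = task
    return out


# ---------------------------------------------------------------------------
# Quiescence and locomotion

def _split_by_phase(iv: BehaviorInterval, schedule: LightSchedule,
                    t_max: float, bounds: np.ndarray | None = None):
    """Segments of an interval split at light/dark boundaries."""
    if bounds is None:
        bounds = schedule.phase_boundaries(t_max)
    i0, i1 = np.searchsorted(bounds, [iv.start, iv.end])
    cuts = [iv.start] + list(bounds[i0:i1]) + [iv.end]
    return [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)
            if cuts[i + 1] > cuts[i]]


def quiescence_summary(intervals, schedule: LightSchedule | None = None,
                       t_max: float | None = None) -> dict:
    """Nap statistics per light phase; bouts straddling a phase boundary
    are split at the boundary before accumulation."""
    schedule = schedule or LightSchedule()
    quiesc = [iv for iv in intervals if iv.label == "quiescence"]
    if t_max is None:
        t_max = max((iv.end for iv in quiesc), default=86400.0)
    for iv in quiesc:
        if iv.start < 0 or iv.end > t_max:
            raise ValueError(f"interval [{iv.start}, {iv.end}] outside "
                             f"[0, {t_max}]")
    n_days = max(t_max / 86400.0, 1e-9)
    bounds = schedule.phase_boundaries(t_max)
    seg = {"light": [], "dark": []}
    for iv in quiesc:
        for s, e in _split_by_phase(iv, schedule, t_max, bounds):
            phase = "light" if schedule.is_light((s + e) / 2) else "dark"
            seg[phase].append(e - s)
    out = {}
    for phase in ("light", "dark"):
        durs = np.asarray(seg[phase])
        out[f"quiesc_total_{phase}"] = float(durs.sum() / 60.0 / n_days)
        out[f"quiesc_bout_{phase}"] = (float(durs.mean() / 60.0)
                                       if durs.size else 0.0)
        out[f"quiesc_freq_{phase}"] = float(durs.size / n_days)
    out["longest_bout"] = (max((iv.duration for iv in quiesc)) / 60.0
                           if quiesc else 0.0)
    dark = out["quiesc_total_dark"]
    out["light_dark_ratio"] = (out["quiesc_total_light"] / dark
                               if dark > 0 else float("nan"))
    return out


MOBILE_LABELS = ("wheel", "panel_L", "panel_R", "other_mobile")


def locomotion_summary(ethogram, t_max: float,
                       schedule: LightSchedule | None = None,
                       traj: TrajectoryTable | None = None) -> dict:
    """Movement and wheel-running summary.

    Movement is time in the mobile labels (wheel, panels, other-mobile);
    T-maze dwell is excluded.  Speed and distance come from the trajectory
    when one is supplied, else NaN.
    """
    schedule = schedule or LightSchedule()
    n_days = max(t_max / 86400.0, 1e-9)
    mobile = [iv for iv in ethogram if iv.label in MOBILE_LABELS]
    wheel = [iv for iv in ethogram if iv.label == "wheel"]
    movement = sum(iv.duration for iv in mobile)
    bounds = schedule.phase_boundaries(t_max)
    dark_movement = sum(
        e - s for iv in mobile
        for s, e in _split_by_phase(iv, schedule, t_max, bounds)
        if not schedule.is_light((s + e) / 2))

    wheel_daily = np.zeros(max(int(np.ceil(n_days)), 1))
    for iv in wheel:
        wheel_daily[int(schedule.day_index(iv.start))
                    % len(wheel_daily)] += iv.duration

    out = {
        "movement_per_day": movement / 60.0 / n_days,
        "wheel_per_day": sum(iv.duration for iv in wheel) / 60.0 / n_days,
        "max_daily_wheel": float(wheel_daily.max() / 60.0),
        "wheel_bouts_per_day": len(wheel) / n_days,
        "mean_wheel_bout": (float(np.mean([iv.duration for iv in wheel]))
                            / 60.0 if wheel else 0.0),
        "dark_movement_fraction": (dark_movement / movement
                                   if movement > 0 else float("nan")),
        "mean_mobile_speed": float("nan"),
        "distance_per_day": float("nan"),
    }
    if traj is not None:
        pos = traj.positions()
        disp = np.linalg.norm(np.diff(pos, axis=0), axis=2).mean(axis=1)
        times = traj.times[1:]
        in_mobile = np.zeros(len(times), bool)
        for iv in mobile:
            in_mobile |= (times >= iv.start) & (times < iv.end)
        if in_mobile.any():
            d = disp[in_mobile]
            out["mean_mobile_speed"] = float(d.mean() * traj.fps)  # mm/s
            out["distance_per_day"] = float(d.sum() / 1000.0 / n_days)  # m
    return out


# ---------------------------------------------------------------------------
# Feature table

def phenotype_mouse(visits, drum_schedule, ethogram, t_max: float,
                    schedule: LightSchedule | None = None,
                    traj: TrajectoryTable | None = None,
                    n_min: int = 20) -> dict:
    """All 32 features for one mouse over [0, t_max]."""
    schedule = schedule or LightSchedule()
    feats = {}
    tm = tmaze_summary(visits, t_max, schedule, n_min=n_min)
    for name in FEATURE_CATEGORIES["tmaze"]:
        feats[name] = tm[name]
    er = exploration_response(ethogram, drum_schedule, t_max,
                              schedule=schedule)
    feats.update(er["aggregates"])
    feats.update(quiescence_summary(ethogram, schedule, t_max))
    feats.update(locomotion_summary(ethogram, t_max, schedule, traj))
    return {k: feats[k] for k in FEATURE_NAMES}


def impute_features(table: pd.DataFrame):
    """Fill undefined feature values with the across-mice column median.

    A feature undefined for every mouse becomes 0.  Returns the imputed
    table and an audit list of (mouse, feature, fill value).
    """
    table = table.copy()
    audit = []
    for col in table.columns:
        nan_idx = table.index[table[col].isna()]
        if not len(nan_idx):
            continue
        med = table[col].median()
        fill = 0.0 if np.isnan(med) else float(med)
        for mid in nan_idx:
            audit.append((mid, col, fill))
        table[col] = table[col].fillna(fill)
    return table, audit


def build_feature_table(cohort: Cohort, t_max: float | None = None,
                        n_min: int = 20):
    """mice x 32 feature table with category tags and an imputation audit.

    Undefined values (e.g. a memory span that never crosses 50%) are
    imputed with the across-mice median of the same feature; a feature
    undefined for every mouse is set to 0 and logged.

    Returns (DataFrame indexed by mouse_id, categories dict, audit list).
    """
    spec = cohort.spec
    t_max = t_max or spec.duration_days * 86400.0
    rows = {}
    for mid, md in cohort.mice.items():
        rows[mid] = phenotype_mouse(
            md.visits, md.drum_schedule, md.ethogram, t_max,
            schedule=spec.light_schedule, traj=md.pose, n_min=n_min)
    table = pd.DataFrame.from_dict(rows, orient="index")[FEATURE_NAMES]

    for mid in table.index:
        for cat, names in FEATURE_CATEGORIES.items():
            if table.loc[mid, names].isna().all():
                raise ValueError(
                    f"mouse {mid} has no defined feature in category {cat!r}")

    table, audit = impute_features(table)
    return table, dict(CATEGORY_OF), audit
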