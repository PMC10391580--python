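"""Behavioral labeling from keypoint trajectories.

Three routes, mirroring how home-cage frames are labeled in practice:
T-maze trials are rule-based (beam-break events coinciding with corridor
presence), quiescence is rule-based (sustained sub-threshold motion for at
least 5 minutes), and the remaining mobile behaviors (panel exploration
left/right, wheel running, other locomotion) are assigned by a random
forest acting on a 32-dimensional frame feature vector: (x, y) positions
and rolling-median-smoothed absolute speeds (|vx|, |vy|) for each of the
eight body parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import RandomizedSearchCV, train_test_split

from .io_core import (
    BehaviorInterval,
    BODY_PARTS,
    CageGeometry,
    TrajectoryTable,
)

__all__ = [
    "SPEED_SMOOTH_FRAMES",
    "MOTION_THRESHOLD_MM",
    "ClassifierReport",
    "frame_features",
    "label_tmaze",
    "detect_quiescence",
    "fit_behavior_classifier",
    "assemble_ethogram",
    "DEFAULT_RF_GRID",
]

#: Rolling-median window for the speed channels (frames; ~40 s at 2 Hz).
SPEED_SMOOTH_FRAMES = 81

#: Default motion threshold: summed per-frame displacement over the eight
#: body parts (mm) below which a frame counts as motionless.
MOTION_THRESHOLD_MM = 2.0

CLASSIFIER_LABELS = ("panel_L", "panel_R", "wheel", "other_mobile")

#: Hyperparameter grid searched by randomized 3-fold CV.
DEFAULT_RF_GRID = {
    "n_estimators": [100, 200, 300],
    "max_depth": [None, 10, 20],
    "max_features": ["sqrt", 0.25, 0.5],
    "min_samples_leaf": [1, 2, 5],
}


@dataclass
class ClassifierReport:
    classes: list
    precision: dict
    recall: dict
    f1: dict
    support: dict
    cv_params: dict

    def min_f1(self) -> float:
        return min(self.f1.values())


def _shrinking_rolling_median(arr: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling median; the window shrinks at the sequence edges."""
    out = median_filter(arr, size=(window, 1), mode="nearest", axes=(0, 1))
    half = window // 2
    n = arr.shape[0]
    for i in range(min(half, n)):
        out[i] = np.median(arr[: i + half + 1], axis=0)
    for i in range(max(n - half, 0), n):
        out[i] = np.median(arr[i - half:], axis=0)
    return out


def frame_features(traj: TrajectoryTable,
                   smooth_frames: int = SPEED_SMOOTH_FRAMES) -> np.ndarray:
    """(n_frames, 32) feature matrix: x, y, |vx|, |vy| per body part.

    Speeds are one-frame forward differentials (mm/frame), absolute value,
    then a centered rolling median of ``smooth_frames`` with shrinking
    windows at the edges; the last frame repeats the previous differential.
    """
    n = traj.n_frames
    if n < smooth_frames + 1:
        raise ValueError(
            f"need >= {smooth_frames + 1} frames to form the smoothing "
            f"window, got {n}")
    pos = traj.positions()  # (n, 8, 2)
    v = np.abs(np.diff(pos, axis=0))
    v = np.concatenate([v, v[-1:]], axis=0)  # (n, 8, 2)
    v_flat = v.reshape(n, -1)
    v_s = _shrinking_rolling_median(v_flat, smooth_frames).reshape(n, 8, 2)
    feats = np.concatenate([pos, v_s], axis=2)  # (n, 8, 4): x, y, |vx|, |vy|
    return feats.reshape(n, 32)


# ---------------------------------------------------------------------------
# Rule-based labels

def label_tmaze(traj: TrajectoryTable, beam_events,
                geometry: CageGeometry | None = None,
                cluster_gap_s: float = 2.0):
    """T-maze intervals from beam-break events coinciding with corridor dwell.

    ``beam_events`` is a sequence of (t, side) or VisitEvent.  Events less
    than ``cluster_gap_s`` apart on the same side merge into one trial.
    Events whose snout position lies outside the corridor zone are rejected
    and returned separately.

    Returns (intervals, rejected_events).
    """
    geometry = geometry or CageGeometry()
    events = [(e.t, e.side) if hasattr(e, "t") else (float(e[0]), str(e[1]))
              for e in beam_events]
    t_end = traj.t0 + (traj.n_frames - 1) / traj.fps
    snout = traj.xy("snout")

    intervals, rejected = [], []
    clusters: list[list] = []
    for t, side in sorted(events):
        if not traj.t0 <= t <= t_end:
            raise ValueError(f"beam event at t={t} outside trajectory range")
        if clusters and clusters[-1][1] == side and \
                t - clusters[-1][0][-1] < cluster_gap_s:
            clusters[-1][0].append(t)
        else:
            clusters.append([[t], side])
    for times, side in clusters:
        zone = "corridor_L" if side == "L" else "corridor_R"
        idx = np.clip(((np.asarray(times) - traj.t0) * traj.fps).round()
                      .astype(int), 0, traj.n_frames - 1)
        inside = geometry.contains(zone, snout[idx], margin=15.0)
        if not inside.any():
            rejected.extend((t, side) for t in times)
            continue
        # expand across the corridor dwell containing the beam cluster
        i0 = i1 = idx[0]
        while i0 > 0 and geometry.contains(
                zone, snout[i0 - 1:i0], margin=15.0)[0]:
            i0 -= 1
        while i1 < traj.n_frames - 1 and geometry.contains(
                zone, snout[i1 + 1:i1 + 2], margin=15.0)[0]:
            i1 += 1
        start = traj.t0 + i0 / traj.fps
        end = traj.t0 + (i1 + 1) / traj.fps
        end = max(end, times[-1] + 1.0 / traj.fps)
        label = "tmaze_L" if side == "L" else "tmaze_R"
        if intervals and start < intervals[-1].end and \
                intervals[-1].label == label:
            intervals[-1] = BehaviorInterval(
                intervals[-1].start, max(end, intervals[-1].end), label)
        else:
            start = max(start, intervals[-1].end if intervals else start)
            if end > start:
                intervals.append(BehaviorInterval(start, end, label))
    return intervals, rejected


def detect_quiescence(traj: TrajectoryTable,
                      motion_threshold: float = MOTION_THRESHOLD_MM,
                      min_duration: float = 300.0):
    """Maximal runs of motionless frames lasting at least ``min_duration``.

    A frame is motionless when the summed Euclidean displacement of all
    eight body parts since the previous frame is strictly below
    ``motion_threshold`` (mm).  Continuity is strict: a single
    supra-threshold frame breaks the run.
    """
    if motion_threshold <= 0:
        raise ValueError("motion_threshold must be > 0")
    pos = traj.positions()
    disp = np.linalg.norm(np.diff(pos, axis=0), axis=2).sum(axis=1)
    still = disp < motion_threshold  # still[i]: frame i+1 vs frame i
    out = []
    edges = np.flatnonzero(np.r_[True, still[1:] != still[:-1], True])
    for a, b in zip(edges[:-1], edges[1:]):
        if not still[a]:
            continue
        # frames a .. b inclusive are mutually motionless
        start = traj.t0 + a / traj.fps
        end = traj.t0 + (b + 1) / traj.fps
        if end - start >= min_duration:
            out.append(BehaviorInterval(start, end, "quiescence"))
    return out


# ---------------------------------------------------------------------------
# Random-forest classifier

def fit_behavior_classifier(features: np.ndarray, labels, seed: int = 0,
                            grid: dict | None = None, n_iter: int = 8,
                            test_size: float = 0.2):
    """Train the mobile-behavior random forest and report held-out scores.

    Hyperparameters are tuned by randomized 3-fold cross-validation over
    ``grid`` on a seeded 80% split; per-class precision/recall/F1 are
    computed on the held-out 20%.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    bad = classes[counts < 3]
    if bad.size:
        raise ValueError(f"classes {list(bad)} have < 3 samples; "
                         "3-fold CV infeasible")
    unknown = set(classes) - set(CLASSIFIER_LABELS)
    if unknown:
        raise ValueError(f"unknown classifier labels {sorted(unknown)}")

    X_tr, X_te, y_tr, y_te = train_test_split(
        features, labels, test_size=test_size, random_state=seed,
        stratify=labels)
    grid = grid or DEFAULT_RF_GRID
    search = RandomizedSearchCV(
        RandomForestClassifier(random_state=seed, n_jobs=1),
        grid, n_iter=n_iter, cv=3, random_state=seed, n_jobs=1)
    search.fit(X_tr, y_tr)
    model = search.best_estimator_
    y_hat = model.predict(X_te)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_te, y_hat, labels=classes, zero_division=0)
    report = ClassifierReport(
        classes=list(classes),
        precision=dict(zip(classes, prec)),
        recall=dict(zip(classes, rec)),
        f1=dict(zip(classes, f1)),
        support=dict(zip(classes, support.astype(int))),
        cv_params=dict(search.best_params_),
    )
    return model, report


def _majority_smooth(pred: np.ndarray, window: int) -> np.ndarray:
    """Majority vote over non-overlapping windows of ``window`` frames."""
    out = pred.copy()
    for a in range(0, len(pred), window):
        chunk = pred[a:a + window]
        vals, counts = np.unique(chunk, return_counts=True)
        out[a:a + window] = vals[np.argmax(counts)]
    return out


def assemble_ethogram(traj: TrajectoryTable, beam_events, model,
                      geometry: CageGeometry | None = None,
                      motion_threshold: float = MOTION_THRESHOLD_MM,
                      smooth_window_s: float = 60.0):
    """Merged non-overlapping ethogram from all three labeling routes.

    Priority on overlap: T-maze > quiescence > classifier labels.
    Classifier frame predictions are smoothed by majority vote over
    ``smooth_window_s`` windows before being turned into intervals.
    """
    geometry = geometry or CageGeometry()
    tmaze, _rej = label_tmaze(traj, beam_events, geometry)
    quiesc = detect_quiescence(traj, motion_threshold)
    feats = frame_features(traj)
    pred = model.predict(feats)
    pred = _majority_smooth(pred, int(round(smooth_window_s * traj.fps)))

    n = traj.n_frames
    frame_label = pred.astype(object)
    for group in (quiesc, tmaze):  # later assignment wins: tmaze on top
        for iv in group:
            i0 = int(np.ceil((iv.start - traj.t0) * traj.fps))
            i1 = min(int(np.floor((iv.end - traj.t0) * traj.fps)) + 1, n)
            frame_label[max(i0, 0):i1] = iv.label

    out = []
    edges = np.flatnonzero(
        np.r_[True, frame_label[1:] != frame_label[:-1], True])
    for a, b in zip(edges[:-1], edges[1:]):
        out.append(BehaviorInterval(
            traj.t0 + a / traj.fps, traj.t0 + b / traj.fps,
            str(frame_label[a])))
    return out
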