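"""End-to-end validation workflows on synthetic cohorts.

Two self-contained experiments used to exercise the full pipeline with
known ground truth: training the frame-level behavior classifier on
rendered trajectories, and recovering preset group structure from the
32-feature table via the semi-supervised cluster search.
"""

from __future__ import annotations

import numpy as np

from .behavior_labeling import CLASSIFIER_LABELS, fit_behavior_classifier, \
    frame_features
from .cluster_phenotype import cluster_search, score_confusion, select_final
from .phenotype_metrics import build_feature_table
from .synthetic_cohort import (
    PRESETS,
    draw_quiescence,
    paper_like_spec,
    make_cohort,
    render_pose,
    simulate_drum_schedule,
    simulate_ethogram,
    simulate_visits,
)

__all__ = [
    "labeled_frame_dataset",
    "classifier_benchmark",
    "clustering_recovery",
]


def labeled_frame_dataset(seed: int, days: int = 2,
                          groups=("control", "hippocampal",
                                  "entorhinal", "amyloid"),
                          cap_per_class: int = 8000):
    """32-dim frame features with ground-truth mobile-behavior labels.

    One mouse per group is simulated for ``days`` days, its pose rendered
    from the ethogram, and frames inside classifier-class intervals
    collected; classes are capped at ``cap_per_class`` frames to keep the
    heavily imbalanced wheel/other classes from dominating.
    """
    root = np.random.SeedSequence(seed)
    X_all, y_all = [], []
    for ss, name in zip(root.spawn(len(groups)), groups):
        s = ss.generate_state(5) % (2 ** 31)
        prof = PRESETS[name]
        naps = draw_quiescence(prof, days, int(s[0]))
        visits = simulate_visits(prof, days, int(s[1]), nap_intervals=naps)
        drums = simulate_drum_schedule(max(days, 2), int(s[2]))
        etho = simulate_ethogram(prof, visits, drums, days, int(s[3]),
                                 nap_intervals=naps)
        traj = render_pose(etho, days * 86400.0, int(s[4]))
        feats = frame_features(traj)
        labels = np.full(traj.n_frames, "", dtype=object)
        for iv in etho:
            i0 = int(np.ceil(iv.start * traj.fps))
            i1 = min(int(np.floor(iv.end * traj.fps)) + 1, traj.n_frames)
            labels[i0:i1] = iv.label
        keep = np.isin(labels, CLASSIFIER_LABELS)
        X_all.append(feats[keep])
        y_all.append(labels[keep])
    X = np.vstack(X_all)
    y = np.concatenate(y_all)
    rng = np.random.default_rng(seed)
    idx = []
    for c in np.unique(y):
        ci = np.flatnonzero(y == c)
        idx.append(rng.choice(ci, min(len(ci), cap_per_class),
                              replace=False))
    idx = np.concatenate(idx)
    return X[idx], y[idx]


def classifier_benchmark(seed: int, days: int = 2, cap_per_class: int = 8000,
                         n_iter: int = 4):
    """Train the behavior random forest on a synthetic labeled cohort.

    Returns (model, ClassifierReport) with per-class F1 on the held-out
    20% split.
    """
    X, y = labeled_frame_dataset(seed, days=days,
                                 cap_per_class=cap_per_class)
    return fit_behavior_classifier(X, y, seed=seed, n_iter=n_iter)


def clustering_recovery(master_seed: int, n_cohorts: int = 10,
                        n_per_group: int = 5, duration_days: int = 30,
                        n_sims: int = 120):
    """Group recovery on seeded synthetic cohorts.

    For each cohort: build the 32-feature table, run the semi-supervised
    cluster search (known controls = the control group), select the final
    model, and score the confusion against ground truth.  Returns a list
    of per-cohort dicts with overall and per-group accuracies.
    """
    out = []
    for k in range(n_cohorts):
        seed = int((master_seed + k) % (2 ** 31))
        spec = paper_like_spec(n_per_group=n_per_group,
                               duration_days=duration_days,
                               master_seed=seed)
        cohort = make_cohort(spec)
        table, _, _ = build_feature_table(cohort)
        controls = [m for m, g in cohort.truth.items() if g == "control"]
        cands = cluster_search(table, controls, n_sims=n_sims, seed=seed)
        model = select_final(table, controls, cands, seed=seed)
        truth = [cohort.truth[m] for m in table.index]
        if model is None:
            out.append({"seed": seed, "overall_accuracy": 0.0,
                        "per_group_accuracy": {}})
            continue
        sc = score_confusion(model.labels, truth)
        out.append({"seed": seed,
                    "n_clusters": model.n_clusters,
                    "overall_accuracy": sc["overall_accuracy"],
                    "per_group_accuracy": sc["per_group_accuracy"]})
    return out
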