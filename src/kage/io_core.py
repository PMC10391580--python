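"""Domain types, file I/O, and configuration shared by every pipeline stage.

Time is measured in seconds since experiment start (float); a wall-clock
anchor in :class:`LightSchedule` maps instants onto the 12:12 light/dark
cycle.  Coordinates are millimetres with the origin at a cage corner and x
running along the 39 cm wall.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BODY_PARTS",
    "BEHAVIOR_LABELS",
    "DRUM_KINDS",
    "CAGE_X_MM",
    "CAGE_Y_MM",
    "MM_PER_PX",
    "VisitEvent",
    "DrumChangeEvent",
    "BehaviorInterval",
    "TrajectoryTable",
    "LightSchedule",
    "CageGeometry",
    "SchemaError",
    "ValidationError",
    "read_events",
    "write_events",
    "read_pose",
    "write_pose",
    "write_features",
    "read_features",
    "load_zenodo_deposit",
]

#: The eight tracked body parts, snout to tail.
BODY_PARTS = (
    "snout", "ear_L", "ear_R", "neck",
    "spine1", "spine2", "spine3", "tail_base",
)

#: Ethogram labels in merge-priority order (earlier wins on overlap).
BEHAVIOR_LABELS = (
    "tmaze_L", "tmaze_R", "quiescence", "wheel",
    "panel_L", "panel_R", "other_mobile",
)

#: The eight drum-change combinations, cycled once per 16-day block.
DRUM_KINDS = (
    "L-NOR", "R-NOR", "double-NOR",
    "L-OPR", "R-OPR", "double-OPR",
    "L-NOR+R-OPR", "L-OPR+R-NOR",
)

CAGE_X_MM = 390.0
CAGE_Y_MM = 320.0

#: Default pixel-to-mm scale (1.85 mm / 1.69 px), overridable in config.
MM_PER_PX = 1.85 / 1.69

QUIESCENCE_MIN_S = 300.0


class SchemaError(ValueError):
    """A file is missing a required column or header."""


class ValidationError(ValueError):
    """File contents violate a domain invariant (e.g. time ordering)."""


@dataclass(frozen=True)
class VisitEvent:
    """One spout visit.

    ``rewarded`` follows the alternation rule: a visit is rewarded iff its
    side differs from the previous visit's side.  ``iti`` is the gap since
    the previous visit (None for a mouse's first visit).
    """

    mouse_id: str
    t: float
    side: str  # "L" | "R"
    rewarded: bool | None = None
    iti: float | None = None

    def __post_init__(self):
        if self.side not in ("L", "R"):
            raise ValidationError(f"side must be 'L' or 'R', got {self.side!r}")
        if self.iti is not None and self.iti < 0:
            raise ValidationError(f"negative ITI {self.iti} at t={self.t}")


@dataclass(frozen=True)
class DrumChangeEvent:
    """One rotation of the side drums presenting new wall panels."""

    t: float
    kind: str
    pattern_left: int
    pattern_right: int

    def __post_init__(self):
        if self.kind not in DRUM_KINDS:
            raise ValidationError(f"unknown drum-change kind {self.kind!r}")
        for p in (self.pattern_left, self.pattern_right):
            if not 1 <= int(p) <= 8:
                raise ValidationError(f"pattern id {p} outside 1..8")


@dataclass(frozen=True)
class BehaviorInterval:
    start: float
    end: float
    label: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(
                f"interval end {self.end} not after start {self.start}")
        if self.label not in BEHAVIOR_LABELS:
            raise ValidationError(f"unknown behavior label {self.label!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class TrajectoryTable:
    """2 Hz keypoint positions for the eight body parts, in mm.

    ``data`` has a two-level column index ``(bodypart, coord)`` with coord in
    {x, y} plus optional ``likelihood``; rows are frames at ``1/fps`` second
    steps starting at ``t0``.
    """

    data: pd.DataFrame
    fps: float = 2.0
    t0: float = 0.0

    def __post_init__(self):
        parts = list(dict.fromkeys(self.data.columns.get_level_values(0)))
        missing = [p for p in BODY_PARTS if p not in parts]
        if missing:
            raise SchemaError(
                f"missing body parts {missing}; expected {list(BODY_PARTS)}")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.fps

    def xy(self, part: str) -> np.ndarray:
        """(n_frames, 2) array of x, y for one body part."""
        return self.data[part][["x", "y"]].to_numpy(float)

    def positions(self) -> np.ndarray:
        """(n_frames, 8, 2) array ordered as BODY_PARTS."""
        return np.stack([self.xy(p) for p in BODY_PARTS], axis=1)


@dataclass(frozen=True)
class LightSchedule:
    """12:12 light cycle; clock values are seconds after midnight."""

    lights_on: float = 9 * 3600.0
    lights_off: float = 21 * 3600.0
    experiment_start: float = 9 * 3600.0

    def clock(self, t: float | np.ndarray) -> np.ndarray:
        return np.asarray((self.experiment_start + np.asarray(t)) % 86400.0)

    def is_light(self, t: float | np.ndarray) -> np.ndarray:
        c = self.clock(t)
        if self.lights_on <= self.lights_off:
            return (c >= self.lights_on) & (c < self.lights_off)
        return (c >= self.lights_on) | (c < self.lights_off)

    def phase(self, t: float) -> str:
        return "light" if bool(np.all(self.is_light(t))) else "dark"

    def day_index(self, t: float | np.ndarray) -> np.ndarray:
        """Calendar day number with the boundary at lights-on."""
        c = self.experiment_start + np.asarray(t) - self.lights_on
        return np.floor(c / 86400.0).astype(int)

    def phase_boundaries(self, t_max: float) -> np.ndarray:
        """Sorted times in [0, t_max] at which the phase flips."""
        bounds = []
        for edge in (self.lights_on, self.lights_off):
            first = (edge - self.experiment_start) % 86400.0
            bounds.extend(np.arange(first, t_max, 86400.0))
        out = np.sort(np.asarray(bounds))
        return out[out > 0]


@dataclass(frozen=True)
class CageGeometry:
    """Landmark rectangles (x0, y0, x1, y1) in mm inside the 390x320 floor.

    Proportions follow the cage schematic: corridors at the two front
    corners leading to the spouts, drum panels mid-way along each side
    wall, the wheel at the back, and the nest in the open middle area.
    """

    corridor_L: tuple = (0.0, 0.0, 80.0, 90.0)
    corridor_R: tuple = (310.0, 0.0, 390.0, 90.0)
    panel_L: tuple = (0.0, 110.0, 55.0, 230.0)
    panel_R: tuple = (335.0, 110.0, 390.0, 230.0)
    wheel: tuple = (150.0, 225.0, 250.0, 315.0)
    nest: tuple = (100.0, 100.0, 180.0, 190.0)

    def zone(self, name: str) -> tuple:
        return getattr(self, name)

    def center(self, name: str) -> np.ndarray:
        x0, y0, x1, y1 = self.zone(name)
        return np.array([(x0 + x1) / 2, (y0 + y1) / 2])

    def contains(self, name: str, xy: np.ndarray, margin: float = 0.0) -> np.ndarray:
        x0, y0, x1, y1 = self.zone(name)
        xy = np.atleast_2d(xy)
        return ((xy[:, 0] >= x0 - margin) & (xy[:, 0] <= x1 + margin)
                & (xy[:, 1] >= y0 - margin) & (xy[:, 1] <= y1 + margin))


# ---------------------------------------------------------------------------
# Event-table I/O

_SCHEMAS = {
    "visits": ["mouse_id", "t", "side"],
    "drum_changes": ["t", "kind", "pattern_left", "pattern_right"],
    "intervals": ["mouse_id", "start", "end", "label"],
}


def _check_columns(df: pd.DataFrame, schema: str) -> None:
    for col in _SCHEMAS[schema]:
        if col not in df.columns:
            raise SchemaError(f"{schema} file missing column {col!r}")


def derive_visit_fields(events: Sequence[VisitEvent]) -> list[VisitEvent]:
    """Populate iti and rewarded from the visit sequence of one mouse."""
    out: list[VisitEvent] = []
    prev: VisitEvent | None = None
    for ev in events:
        if prev is None:
            out.append(dataclasses.replace(ev, iti=None, rewarded=None))
        else:
            out.append(dataclasses.replace(
                ev, iti=ev.t - prev.t, rewarded=ev.side != prev.side))
        prev = out[-1]
    return out


def read_events(path: str | Path, schema: str):
    """Read a delimited event file into validated, typed event lists.

    visits return ``{mouse_id: [VisitEvent, ...]}`` with iti/rewarded
    derived; drum_changes return a list of DrumChangeEvent; intervals return
    ``{mouse_id: [BehaviorInterval, ...]}``.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path)
    _check_columns(df, schema)

    if schema == "drum_changes":
        t = df["t"].to_numpy(float)
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise ValidationError(
                f"non-monotonic timestamps at row {bad[0] + 1}")
        return [DrumChangeEvent(float(r.t), str(r.kind),
                                int(r.pattern_left), int(r.pattern_right))
                for r in df.itertuples()]

    key = "t" if schema == "visits" else "start"
    out: dict[str, list] = {}
    for mouse, sub in df.groupby("mouse_id", sort=False):
        t = sub[key].to_numpy(float)
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            row = sub.index[bad[0] + 1]
            raise ValidationError(
                f"non-monotonic timestamps for mouse {mouse} at row {row}")
        if schema == "visits":
            evs = [VisitEvent(str(mouse), float(r.t), str(r.side))
                   for r in sub.itertuples()]
            out[str(mouse)] = derive_visit_fields(evs)
        else:
            out[str(mouse)] = [
                BehaviorInterval(float(r.start), float(r.end), str(r.label))
                for r in sub.itertuples()]
    return out


def write_events(path: str | Path, events, schema: str) -> None:
    """Inverse of :func:`read_events` (derived fields are not persisted)."""
    if schema == "visits":
        rows = [(e.mouse_id, e.t, e.side)
                for evs in events.values() for e in evs]
        df = pd.DataFrame(rows, columns=_SCHEMAS["visits"])
        df = df.sort_values(["mouse_id", "t"], kind="stable")
    elif schema == "drum_changes":
        df = pd.DataFrame(
            [(e.t, e.kind, e.pattern_left, e.pattern_right) for e in events],
            columns=_SCHEMAS["drum_changes"])
    elif schema == "intervals":
        rows = [(m, iv.start, iv.end, iv.label)
                for m, ivs in events.items() for iv in ivs]
        df = pd.DataFrame(rows, columns=_SCHEMAS["intervals"])
        df = df.sort_values(["mouse_id", "start"], kind="stable")
    else:
        raise ValueError(f"unknown schema {schema!r}")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pose I/O (keypoint-CSV dialect: 3 header rows scorer/bodyparts/coords)

def read_pose(path: str | Path, mm_per_px: float = 1.0,
              fps: float = 2.0, t0: float = 0.0) -> TrajectoryTable:
    """Read a keypoint CSV (3 header rows) into a :class:`TrajectoryTable`.

    Coordinates are multiplied by ``mm_per_px`` (use :data:`MM_PER_PX` for
    files in camera pixels; files written by this package are already in mm).
    NaN coordinates are retained.
    """
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    df.columns = pd.MultiIndex.from_tuples(
        [(bp, coord) for _scorer, bp, coord in df.columns])
    parts = list(dict.fromkeys(df.columns.get_level_values(0)))
    missing = [p for p in BODY_PARTS if p not in parts]
    if missing:
        raise SchemaError(
            f"missing body parts {missing}; expected {list(BODY_PARTS)}")
    scaled = df.copy()
    for part in parts:
        for coord in ("x", "y"):
            scaled[(part, coord)] = df[(part, coord)].astype(float) * mm_per_px
    return TrajectoryTable(scaled, fps=fps, t0=t0)


def write_pose(path: str | Path, traj: TrajectoryTable,
               scorer: str = "kage") -> None:
    df = traj.data.copy()
    df.columns = pd.MultiIndex.from_tuples(
        [(scorer, bp, coord) for bp, coord in df.columns],
        names=["scorer", "bodyparts", "coords"])
    df.to_csv(path)


def write_features(path: str | Path, table: pd.DataFrame,
                   categories: dict) -> None:
    """Write a feature table with a second header row of category tags."""
    out = table.copy()
    out.columns = pd.MultiIndex.from_tuples(
        [(c, categories.get(c, "")) for c in table.columns],
        names=["feature", "category"])
    out.rename_axis("mouse_id").to_csv(path)


def read_features(path: str | Path):
    """Read a feature table written by :func:`write_features`.

    Returns (table indexed by mouse_id, {feature: category}).
    """
    df = pd.read_csv(path, header=[0, 1], index_col=0)
    categories = {feat: cat for feat, cat in df.columns}
    df.columns = [feat for feat, _cat in df.columns]
    return df, categories


def load_zenodo_deposit(path: str | Path):  # pragma: no cover - stub
    """Import adapter for the archived processed-data deposit.

    The deposit's on-disk layout is not described in any schema available to
    this package, so no adapter is shipped; convert the deposit's tables to
    the documented visits/drum_changes/intervals CSV schemas and use
    :func:`read_events` instead.
    """
    raise NotImplementedError(
        "no schema available for the archived deposit; convert to the "
        "documented CSV schemas and use read_events()")
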