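"""Digital twin of the thin-layer cell suspension.

Covers the four pieces of physics the sorting workflows depend on:

* **Floating motion** — a persistent random walk ("run and tumble"): each
  cell keeps a constant speed drawn once from a truncated normal and a
  heading that decorrelates with a persistence time; walls reflect.  Presets
  carry the measured regimes: 39 +- 12 um/min in an open dish, 5.4 +- 1.1
  um/min in the oil-covered thin layer, 2.3 +- 0.6 um/min in a thin layer
  inside a miniature well.
* **Capture physics** — a pick aspirates every cell within the capture
  radius of the aim point (34 um measured for the 30 um I.D. pipette in
  sparse mode; 63 um effective calibrated for the dense regime) and removes
  1.4 nl of medium; a deposit spreads the carried cells uniformly within a
  radius around the aim and adds 147 nl.
* **Volume ledger** — medium volumes are tracked exactly per event.
* **Microwell trapping** — Bernoulli-per-well occupancy at a measured fill
  efficiency, with a ~50% chance of successfully aspirating a trapped cell
  (the rest adhere too strongly to the PDMS).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import ArenaGeometry
from .records import CellRecord, positions as _positions

__all__ = [
    "MotionModel",
    "CaptureModel",
    "SuspensionState",
    "PickEvent",
    "MicrowellArray",
    "MicrowellLoad",
    "TrackSet",
    "step_motion",
    "pick_at",
    "deposit_at",
    "load_microwell_array",
    "pick_from_well",
    "simulate_timelapse",
]


@dataclass(frozen=True)
class MotionModel:
    """Persistent random walk for passive cell floating."""

    mean_speed: float  # um/min
    speed_sd: float  # um/min
    persistence_time: float = 300.0  # s, heading decorrelation

    def __post_init__(self) -> None:
        if self.mean_speed < 0 or self.speed_sd < 0:
            raise ValueError("speeds must be >= 0")
        if self.persistence_time <= 0:
            raise ValueError("persistence_time must be > 0")

    # measured floating regimes
    @classmethod
    def open_dish(cls) -> "MotionModel":
        return cls(39.0, 12.0)

    @classmethod
    def thin_layer(cls) -> "MotionModel":
        return cls(5.4, 1.1)

    @classmethod
    def thin_layer_well(cls) -> "MotionModel":
        return cls(2.3, 0.6)

    def draw_speeds(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Per-cell speeds in um/s from Normal(mean, sd) truncated at 0."""
        if self.mean_speed == 0:
            return np.zeros(n)
        from scipy.stats import truncnorm

        a = -self.mean_speed / self.speed_sd if self.speed_sd > 0 else -np.inf
        if self.speed_sd == 0:
            speeds = np.full(n, self.mean_speed)
        else:
            speeds = truncnorm.rvs(
                a, np.inf, loc=self.mean_speed, scale=self.speed_sd, size=n,
                random_state=rng,
            )
        return speeds / 60.0


@dataclass(frozen=True)
class CaptureModel:
    """Pick/deposit physics of the micropipette."""

    capture_radius: float = 34.0  # um
    radius_jitter_sd: float = 0.0  # um, per-pick Gaussian jitter
    pick_volume_nl: float = 1.4
    deposit_volume_nl: float = 147.0
    deposit_spread_radius: float = 127.0  # um, calibrated (not measured)
    pick_success_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.capture_radius <= 0:
            raise ValueError("capture_radius must be > 0")
        if self.pick_volume_nl <= 0 or self.deposit_volume_nl <= 0:
            raise ValueError("volumes must be > 0")
        if not (0.0 <= self.pick_success_prob <= 1.0):
            raise ValueError("pick_success_prob must be in [0, 1]")

    @classmethod
    def sparse(cls) -> "CaptureModel":
        """Measured sparse-suspension resolution: 34 um (+-4 um uncertainty).

        The +-4 um is treated as measurement uncertainty of the radius, not
        per-pick variability; set ``radius_jitter_sd`` to model the latter.
        """
        return cls(capture_radius=34.0)

    @classmethod
    def dense(cls) -> "CaptureModel":
        """Effective radius calibrated to the dense-regime bystander count."""
        return cls(capture_radius=63.0)

    def draw_radius(self, rng: np.random.Generator) -> float:
        if self.radius_jitter_sd == 0:
            return self.capture_radius
        return max(float(rng.normal(self.capture_radius, self.radius_jitter_sd)), 1.0)


class SuspensionState:
    """Arena + cells + medium volume + clock, stored as flat arrays."""

    def __init__(
        self,
        arena: ArenaGeometry,
        ids: Sequence,
        pos: np.ndarray,
        labeled: np.ndarray,
        medium_volume_nl: float | None = None,
        clock: float = 0.0,
        sizes: np.ndarray | None = None,
        brightness: np.ndarray | None = None,
    ) -> None:
        self.arena = arena
        self.ids = list(ids)
        self.pos = np.asarray(pos, dtype=float).reshape(-1, 2).copy()
        self.labeled = np.asarray(labeled, dtype=bool).copy()
        self.sizes = (
            np.full(len(self.ids), 16.0) if sizes is None else np.asarray(sizes, float).copy()
        )
        self.brightness = (
            np.full(len(self.ids), 500.0)
            if brightness is None
            else np.asarray(brightness, float).copy()
        )
        self.medium_volume_nl = (
            arena.medium_volume_nl if medium_volume_nl is None else float(medium_volume_nl)
        )
        if self.medium_volume_nl <= 0:
            raise ValueError("medium_volume_nl must be > 0")
        self.clock = float(clock)
        # motion bookkeeping (lazily initialized by step_motion)
        self.speeds: np.ndarray | None = None  # um/s
        self.headings: np.ndarray | None = None  # radians
        if len(self.pos) and not arena.contains(self.pos).all():
            raise ValueError("all cells must lie inside the arena")

    # -- constructors ---------------------------------------------------------
    @classmethod
    def from_cells(
        cls, arena: ArenaGeometry, cells: Sequence[CellRecord], **kw
    ) -> "SuspensionState":
        return cls(
            arena,
            [c.id for c in cells],
            _positions(cells),
            np.array([c.labeled for c in cells], dtype=bool),
            sizes=np.array([c.size for c in cells], dtype=float),
            brightness=np.array([c.brightness for c in cells], dtype=float),
            **kw,
        )

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_cells(self) -> list[CellRecord]:
        return [
            CellRecord(
                id=self.ids[i],
                x=float(self.pos[i, 0]),
                y=float(self.pos[i, 1]),
                brightness=float(self.brightness[i]),
                size=float(self.sizes[i]),
                labeled=bool(self.labeled[i]),
                t=self.clock,
            )
            for i in range(self.n)
        ]

    def copy(self) -> "SuspensionState":
        st = SuspensionState(
            self.arena,
            self.ids,
            self.pos,
            self.labeled,
            self.medium_volume_nl,
            self.clock,
            self.sizes,
            self.brightness,
        )
        st.speeds = None if self.speeds is None else self.speeds.copy()
        st.headings = None if self.headings is None else self.headings.copy()
        return st

    def index_of(self, cell_id) -> int | None:
        try:
            return self.ids.index(cell_id)
        except ValueError:
            return None

    def _take(self, keep: np.ndarray) -> None:
        self.ids = [i for i, k in zip(self.ids, keep) if k]
        self.pos = self.pos[keep]
        self.labeled = self.labeled[keep]
        self.sizes = self.sizes[keep]
        self.brightness = self.brightness[keep]
        if self.speeds is not None:
            self.speeds = self.speeds[keep]
            self.headings = self.headings[keep]

    def snapshot_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "t_s": self.clock,
                "id": self.ids,
                "x_um": self.pos[:, 0],
                "y_um": self.pos[:, 1],
                "labeled": self.labeled,
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class PickEvent:
    target_id: int | str | None
    aim: tuple[float, float]
    picked_ids: tuple
    picked_labeled: tuple
    removed_volume_nl: float
    success: bool
    t_s: float
    picked_cells: tuple = ()  # full CellRecords of the removed cells

    @property
    def n_picked(self) -> int:
        return len(self.picked_ids)

    def to_jsonl(self) -> str:
        return json.dumps(
            {
                "event": "pick",
                "t_s": self.t_s,
                "target_id": None if self.target_id is None else str(self.target_id),
                "aim_um": list(self.aim),
                "picked_ids": [str(i) for i in self.picked_ids],
                "removed_volume_nl": self.removed_volume_nl,
                "success": self.success,
            }
        )


def step_motion(
    state: SuspensionState,
    dt: float,
    model: MotionModel,
    rng: np.random.Generator,
    in_place: bool = False,
) -> SuspensionState:
    """Advance floating motion by ``dt`` seconds.

    Headings are redrawn uniformly with probability 1 - exp(-dt/tau); each
    cell then moves speed * dt along its heading, with specular reflection
    at the arena walls.  The clock advances by dt.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    st = state if in_place else state.copy()
    n = st.n
    if st.speeds is None:
        st.speeds = model.draw_speeds(n, rng)
        st.headings = rng.uniform(0.0, 2.0 * np.pi, size=n)
    if n:
        tumble = rng.random(n) < 1.0 - math.exp(-dt / model.persistence_time)
        if tumble.any():
            st.headings[tumble] = rng.uniform(0.0, 2.0 * np.pi, size=int(tumble.sum()))
        step = st.speeds * dt
        st.pos[:, 0] += step * np.cos(st.headings)
        st.pos[:, 1] += step * np.sin(st.headings)
        st.pos = st.arena.reflect(st.pos)
    st.clock += dt
    return st


def pick_at(
    state: SuspensionState,
    aim: tuple[float, float],
    capture: CaptureModel,
    rng: np.random.Generator,
    target_id=None,
    in_place: bool = False,
) -> tuple[PickEvent, SuspensionState]:
    """Aspirate at ``aim``: remove every cell within the capture radius.

    With probability ``pick_success_prob`` the pick fires and all cells
    within the (possibly jittered) capture radius are removed; on failure no
    cell is removed but the pick volume is still drawn (fluid moves
    regardless).  The aim must lie inside the arena.
    """
    if not state.arena.contains_point(*aim):
        raise ValueError(f"aim point {aim} lies outside the arena")
    st = state if in_place else state.copy()
    success = bool(rng.random() < capture.pick_success_prob)
    picked_ids: tuple = ()
    picked_labeled: tuple = ()
    picked_cells: tuple = ()
    if success and st.n:
        radius = capture.draw_radius(rng)
        d2 = (st.pos[:, 0] - aim[0]) ** 2 + (st.pos[:, 1] - aim[1]) ** 2
        hit = d2 <= radius * radius
        if hit.any():
            idx = np.flatnonzero(hit)
            picked_cells = tuple(
                CellRecord(
                    id=st.ids[i],
                    x=float(st.pos[i, 0]),
                    y=float(st.pos[i, 1]),
                    brightness=float(st.brightness[i]),
                    size=float(st.sizes[i]),
                    labeled=bool(st.labeled[i]),
                    t=st.clock,
                )
                for i in idx
            )
            picked_ids = tuple(c.id for c in picked_cells)
            picked_labeled = tuple(c.labeled for c in picked_cells)
            st._take(~hit)
    st.medium_volume_nl -= capture.pick_volume_nl
    event = PickEvent(
        target_id=target_id,
        aim=(float(aim[0]), float(aim[1])),
        picked_ids=picked_ids,
        picked_labeled=picked_labeled,
        removed_volume_nl=capture.pick_volume_nl,
        success=success,
        t_s=st.clock,
        picked_cells=picked_cells,
    )
    return event, st


def deposit_at(
    state_dest: SuspensionState,
    cells: Sequence[CellRecord],
    aim: tuple[float, float],
    capture: CaptureModel,
    rng: np.random.Generator,
    in_place: bool = False,
) -> SuspensionState:
    """Eject carried cells around ``aim`` in the destination arena.

    Cells land uniformly within ``deposit_spread_radius`` of the aim
    (clipped to the arena); ids are preserved and the medium volume grows by
    the deposit volume.
    """
    if not state_dest.arena.contains_point(*aim):
        raise ValueError(f"aim point {aim} lies outside the destination arena")
    st = state_dest if in_place else state_dest.copy()
    n = len(cells)
    if n:
        r = capture.deposit_spread_radius * np.sqrt(rng.random(n))
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        pts = np.column_stack([aim[0] + r * np.cos(theta), aim[1] + r * np.sin(theta)])
        pts = st.arena.clip(pts)
        st.ids.extend(c.id for c in cells)
        st.pos = np.vstack([st.pos, pts])
        st.labeled = np.concatenate([st.labeled, [c.labeled for c in cells]])
        st.sizes = np.concatenate([st.sizes, [c.size for c in cells]])
        st.brightness = np.concatenate([st.brightness, [c.brightness for c in cells]])
        if st.speeds is not None:
            # freshly deposited cells are treated as settled (zero residual speed)
            st.speeds = np.concatenate([st.speeds, np.zeros(n)])
            st.headings = np.concatenate([st.headings, np.zeros(n)])
    st.medium_volume_nl += capture.deposit_volume_nl
    return st


@dataclass(frozen=True)
class MicrowellArray:
    """PDMS microwell grid that passively traps settling single cells."""

    pitch: float = 100.0  # um lattice constant
    well_diameter: float = 20.0  # um (15 for monocytes, 20 for fibroblasts)
    n_rows: int = 100
    n_cols: int = 100  # 100 x 100 wells on a 10 x 10 mm^2 plate
    fill_efficiency: float = 0.25
    well_pick_success: float = 0.5

    def __post_init__(self) -> None:
        if self.well_diameter >= self.pitch:
            raise ValueError("well_diameter must be < pitch")
        for p in (self.fill_efficiency, self.well_pick_success):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    @classmethod
    def monocyte(cls) -> "MicrowellArray":
        """15 um wells; measured fill efficiency 54 +- 7%."""
        return cls(well_diameter=15.0, fill_efficiency=0.54)

    @classmethod
    def fibroblast(cls) -> "MicrowellArray":
        """20 um wells for 3T3 cells; measured fill efficiency 25 +- 8%."""
        return cls(well_diameter=20.0, fill_efficiency=0.25)


@dataclass
class MicrowellLoad:
    array: MicrowellArray
    occupancy: np.ndarray  # (n_rows, n_cols) bool
    n_applied: int

    @property
    def trapped(self) -> int:
        return int(self.occupancy.sum())

    @property
    def untrapped(self) -> int:
        return self.n_applied - self.trapped

    @property
    def untrapped_fraction(self) -> float:
        return self.untrapped / self.n_applied if self.n_applied else 0.0

    @property
    def fill_fraction(self) -> float:
        return self.trapped / self.array.n_wells


def load_microwell_array(
    array: MicrowellArray, n_applied: int, rng: np.random.Generator
) -> MicrowellLoad:
    """Settle ``n_applied`` cells onto the array; wash the rest away.

    Each well traps at most one cell, independently with probability
    ``fill_efficiency``; occupancy is capped by the applied count, and every
    cell not trapped counts as washed away.
    """
    if n_applied < 0:
        raise ValueError("n_applied must be >= 0")
    occ = rng.random((array.n_rows, array.n_cols)) < array.fill_efficiency
    excess = int(occ.sum()) - n_applied
    if excess > 0:  # cannot trap more cells than were applied
        filled = np.flatnonzero(occ.ravel())
        drop = rng.choice(filled, size=excess, replace=False)
        occ.ravel()[drop] = False
    return MicrowellLoad(array, occ, n_applied)


def pick_from_well(
    load: MicrowellLoad,
    well_index: tuple[int, int],
    well_pick_success: float | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Attempt to aspirate the cell in one well.

    Returns ``"empty"`` for an unoccupied well; an occupied well yields
    ``"isolated"`` with the pick-success probability (the cell leaves the
    well) or ``"stuck"`` (the cell adhered too strongly to the PDMS and
    stays, at risk of damage).
    """
    r, c = well_index
    if not (0 <= r < load.array.n_rows and 0 <= c < load.array.n_cols):
        raise ValueError(f"well index {well_index} out of range")
    if not load.occupancy[r, c]:
        return "empty"
    p = load.array.well_pick_success if well_pick_success is None else well_pick_success
    rng = rng or np.random.default_rng()
    if rng.random() < p:
        load.occupancy[r, c] = False
        return "isolated"
    return "stuck"


@dataclass(frozen=True)
class TrackSet:
    """Per-cell position time series from a simulated time-lapse."""

    ids: tuple
    times: np.ndarray  # (F,)
    tracks: np.ndarray  # (N, F, 2)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def sampling_interval(self) -> float:
        return float(self.times[1] - self.times[0]) if self.n_frames > 1 else 0.0

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for i, cid in enumerate(self.ids):
            for f, t in enumerate(self.times):
                rows.append(
                    {
                        "t_s": float(t),
                        "id": cid,
                        "x_um": float(self.tracks[i, f, 0]),
                        "y_um": float(self.tracks[i, f, 1]),
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrackSet":
        df = pd.read_csv(path)
        ids = tuple(df["id"].unique())
        times = np.sort(df["t_s"].unique())
        tracks = np.empty((len(ids), len(times), 2))
        for i, cid in enumerate(ids):
            sub = df[df["id"] == cid].sort_values("t_s")
            tracks[i, :, 0] = sub["x_um"].to_numpy()
            tracks[i, :, 1] = sub["y_um"].to_numpy()
        return cls(ids, times, tracks)


def simulate_timelapse(
    state: SuspensionState,
    model: MotionModel,
    frame_interval: float,
    duration: float,
    rng: np.random.Generator,
) -> TrackSet:
    """Record positions every ``frame_interval`` for ``duration`` seconds.

    Produces ``1 + floor(duration / frame_interval)`` frames per cell
    (the initial positions plus one frame per elapsed interval).
    """
    if frame_interval > duration:
        raise ValueError("frame_interval must be <= duration")
    st = state.copy()
    n_frames = 1 + int(math.floor(duration / frame_interval))
    tracks = np.empty((st.n, n_frames, 2))
    times = np.empty(n_frames)
    tracks[:, 0, :] = st.pos
    times[0] = st.clock
    for f in range(1, n_frames):
        st = step_motion(st, frame_interval, model, rng, in_place=True)
        tracks[:, f, :] = st.pos
        times[f] = st.clock
    return TrackSet(tuple(st.ids), times, tracks)
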