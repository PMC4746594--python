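"""Pick scheduling: visit order, destination assignment, valve protocol.

The route over all targets is a greedy nearest-neighbor tour (the visual
"visit all detected cells" path); destinations are either a deposition grid
(500 um pitch), the 2 x 2 mm^2 wells of the 24-well miniature plate (one
cell per well), or numbered PCR tubes.  ``emit_protocol`` expands a plan
into the timed pressure/valve actions of the micropipette: -100 Pa vacuum
for 10 ms to pick, 1 s of ambient pressure to stop the flow, +4,200 Pa for
1 s to deposit, approached to 5 um above the surface.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .records import CellRecord

__all__ = [
    "PickProtocol",
    "DestinationLayout",
    "Destination",
    "SortPlan",
    "Action",
    "plan_route",
    "assign_destinations",
    "build_sort_plan",
    "emit_protocol",
]


@dataclass(frozen=True)
class PickProtocol:
    """Pressures, pulse timings and approach geometry of one pick/deposit."""

    pipette_inner_diameter: float = 30.0  # um
    approach_height: float = 5.0  # um above the dish surface
    vacuum: float = -100.0  # Pa
    vacuum_pulse: float = 0.010  # s (10 ms)
    ambient_equilibrate: float = 1.0  # s at 0 Pa to stop the flow
    overpressure: float = 4200.0  # Pa
    deposit_pulse: float = 1.0  # s
    travel_height: float = 500.0  # um, z while moving between sites

    def __post_init__(self) -> None:
        if not (self.vacuum < 0 < self.overpressure):
            raise ValueError("need vacuum < 0 < overpressure")
        for name in ("vacuum_pulse", "ambient_equilibrate", "deposit_pulse"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class Destination:
    label: str
    x: float | None = None  # stage um; None for PCR tubes
    y: float | None = None


@dataclass(frozen=True)
class DestinationLayout:
    """Where isolated cells go: grid nodes, miniature wells or PCR tubes."""

    mode: str = "grid"  # "grid" | "miniature_wells" | "pcr_tubes"
    grid_pitch: float = 500.0  # um
    grid_origin: tuple[float, float] = (0.0, 0.0)
    grid_cols: int | None = None  # None -> ceil(sqrt(n))
    wells: tuple[tuple[float, float], ...] = ()  # centers of 2x2 mm wells
    tube_count: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("grid", "miniature_wells", "pcr_tubes"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.grid_pitch <= 0:
            raise ValueError("grid_pitch must be > 0")
        if self.mode == "miniature_wells" and not self.wells:
            raise ValueError("miniature_wells mode requires a non-empty well list")

    @classmethod
    def miniature_plate(
        cls, origin: tuple[float, float] = (0.0, 0.0), rows: int = 4, cols: int = 6
    ) -> "DestinationLayout":
        """The 24-well miniature plate: 2 x 2 mm^2 wells, one cell each."""
        ox, oy = origin
        pitch = 2000.0
        wells = tuple(
            (ox + 1000.0 + c * pitch, oy + 1000.0 + r * pitch)
            for r in range(rows)
            for c in range(cols)
        )
        return cls(mode="miniature_wells", wells=wells)


@dataclass
class SortPlan:
    """Ordered targets with destinations and the protocol to execute."""

    target_ids: list
    target_positions: list  # [(x, y)] parallel to target_ids
    destinations: list  # [Destination]
    protocol: PickProtocol
    path_length_um: float

    def __post_init__(self) -> None:
        if len(set(map(str, self.target_ids))) != len(self.target_ids):
            raise ValueError("every target must appear exactly once")
        if len(self.destinations) != len(self.target_ids):
            raise ValueError("one destination per target required")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "target_ids": [str(t) for t in self.target_ids],
                    "target_positions": self.target_positions,
                    "destinations": [asdict(d) for d in self.destinations],
                    "protocol": asdict(self.protocol),
                    "path_length_um": self.path_length_um,
                },
                indent=2,
            )
        )


def plan_route(
    cells: Sequence[CellRecord], start: tuple[float, float]
) -> tuple[list, float]:
    """Greedy nearest-neighbor tour over all cells from ``start``.

    Ties are broken by smaller id (string order).  Returns the ordered id
    list and the total Euclidean path length in micrometers.
    """
    remaining = list(cells)
    order: list = []
    pos = np.asarray(start, dtype=float)
    total = 0.0
    while remaining:
        dists = [float(np.hypot(c.x - pos[0], c.y - pos[1])) for c in remaining]
        best = min(range(len(remaining)), key=lambda i: (dists[i], str(remaining[i].id)))
        total += dists[best]
        chosen = remaining.pop(best)
        order.append(chosen.id)
        pos = np.array([chosen.x, chosen.y])
    return order, total


def assign_destinations(n: int, layout: DestinationLayout) -> list[Destination]:
    """Destination coordinates/labels for ``n`` isolated cells.

    Grid mode: row-major lattice at ``grid_pitch`` from ``grid_origin``;
    wells mode: one cell per well center, capped at the well count; tubes
    mode: tube indices 1..n.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    if layout.mode == "grid":
        cols = layout.grid_cols or max(1, math.ceil(math.sqrt(n)))
        ox, oy = layout.grid_origin
        return [
            Destination(
                label=f"grid_{i}",
                x=ox + (i % cols) * layout.grid_pitch,
                y=oy + (i // cols) * layout.grid_pitch,
            )
            for i in range(n)
        ]
    if layout.mode == "miniature_wells":
        capacity = len(layout.wells)
        if n > capacity:
            raise ValueError(
                f"{n} cells exceed miniature-plate capacity of {capacity} wells"
            )
        return [
            Destination(label=f"well_{i}", x=layout.wells[i][0], y=layout.wells[i][1])
            for i in range(n)
        ]
    capacity = layout.tube_count
    if capacity is not None and n > capacity:
        raise ValueError(f"{n} cells exceed tube capacity of {capacity}")
    return [Destination(label=f"tube_{i + 1}") for i in range(n)]


def build_sort_plan(
    cells: Sequence[CellRecord],
    start: tuple[float, float],
    layout: DestinationLayout,
    protocol: PickProtocol | None = None,
) -> SortPlan:
    protocol = protocol or PickProtocol()
    order, length = plan_route(cells, start)
    by_id = {c.id: c for c in cells}
    dests = assign_destinations(len(order), layout)
    return SortPlan(
        target_ids=order,
        target_positions=[(by_id[i].x, by_id[i].y) for i in order],
        destinations=dests,
        protocol=protocol,
        path_length_um=length,
    )


@dataclass(frozen=True)
class Action:
    t_s: float
    action: str
    x_um: float | None
    y_um: float | None
    z_um: float | None
    pressure_pa: float | None
    duration_s: float


def emit_protocol(plan: SortPlan, protocol: PickProtocol | None = None) -> list[Action]:
    """Expand a plan into timed actions.

    Each pick is exactly five actions (move, descend, vacuum pulse, ambient
    equilibration, ascend) and each deposit with stage coordinates exactly
    four (move, descend, overpressure pulse, ascend); moves and z-travel are
    modeled as instantaneous, so time advances only by the pulse durations.
    Tube destinations have no stage coordinates; the move targets the tube
    label instead.
    """
    p = protocol or plan.protocol
    actions: list[Action] = []
    t = 0.0

    def add(name, x, y, z, pressure, duration):
        nonlocal t
        actions.append(Action(t, name, x, y, z, pressure, duration))
        t += duration

    for (tx, ty), dest in zip(plan.target_positions, plan.destinations):
        # pick: 5 actions
        add("move", tx, ty, p.travel_height, None, 0.0)
        add("descend", tx, ty, p.approach_height, None, 0.0)
        add("valve1_vacuum", tx, ty, p.approach_height, p.vacuum, p.vacuum_pulse)
        add("valve2_ambient", tx, ty, p.approach_height, 0.0, p.ambient_equilibrate)
        add("ascend", tx, ty, p.travel_height, None, 0.0)
        # deposit: 4 actions
        add("move", dest.x, dest.y, p.travel_height, None, 0.0)
        add("descend", dest.x, dest.y, p.approach_height, None, 0.0)
        add(
            "valve1_overpressure",
            dest.x,
            dest.y,
            p.approach_height,
            p.overpressure,
            p.deposit_pulse,
        )
        add("ascend", dest.x, dest.y, p.travel_height, None, 0.0)
    return actions


def write_actions_csv(actions: Sequence[Action], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "t_s": a.t_s,
                "action": a.action,
                "x_um": a.x_um,
                "y_um": a.y_um,
                "z_um": a.z_um,
                "pressure_Pa": a.pressure_pa,
                "duration_s": a.duration_s,
            }
            for a in actions
        ]
    ).to_csv(path, index=False)
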