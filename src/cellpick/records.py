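"""The CellRecord container shared by every stage of the pipeline."""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["CellRecord", "records_to_frame", "frame_to_records", "positions"]


@dataclass
class CellRecord:
    """One detected or simulated cell.

    Attributes
    ----------
    id:
        Opaque unique token (int or str).
    x, y:
        Stage position in micrometers.
    brightness:
        Mean brightness in camera units (>= 0).
    size:
        Equivalent-circle diameter in micrometers.
    bbox_w, bbox_h:
        Optional bounding-box extents in micrometers.
    labeled:
        True for fluorescently labeled (CFSE/DiI-type) cells.
    t:
        Timestamp in seconds (when the record was made).
    """

    id: int | str
    x: float
    y: float
    brightness: float = 0.0
    size: float = 0.0
    bbox_w: float | None = None
    bbox_h: float | None = None
    labeled: bool = True
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.brightness < 0:
            raise ValueError("brightness must be >= 0")
        if self.size < 0:
            raise ValueError("size must be >= 0")

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)

    def distance_to(self, other: "CellRecord | tuple[float, float]") -> float:
        ox, oy = other.position if isinstance(other, CellRecord) else other
        return float(np.hypot(self.x - ox, self.y - oy))


def positions(cells: Sequence[CellRecord]) -> np.ndarray:
    """(N, 2) array of stage positions."""
    if not cells:
        return np.empty((0, 2))
    return np.array([[c.x, c.y] for c in cells], dtype=float)


def records_to_frame(cells: Iterable[CellRecord]) -> pd.DataFrame:
    """Tabulate records with the on-disk column names (x_um, y_um, ...)."""
    rows = [
        {
            "id": c.id,
            "x_um": c.x,
            "y_um": c.y,
            "size_um": c.size,
            "brightness": c.brightness,
            "labeled": c.labeled,
            "t_s": c.t,
        }
        for c in cells
    ]
    return pd.DataFrame(
        rows, columns=["id", "x_um", "y_um", "size_um", "brightness", "labeled", "t_s"]
    )


def frame_to_records(df: pd.DataFrame) -> list[CellRecord]:
    return [
        CellRecord(
            id=row["id"],
            x=float(row["x_um"]),
            y=float(row["y_um"]),
            size=float(row.get("size_um", 0.0) or 0.0),
            brightness=float(row.get("brightness", 0.0) or 0.0),
            labeled=bool(row.get("labeled", True)),
            t=float(row.get("t_s", 0.0) or 0.0),
        )
        for _, row in df.iterrows()
    ]
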