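"""Stage-frame geometry: arenas, camera frames and coordinate transforms.

All positions live in a single stage frame measured in micrometers, with x
increasing to the right (image columns) and y increasing downward (image
rows).  Pixel indices are 0-based and a pixel coordinate refers to the
center of that pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ArenaGeometry",
    "FrameSpec",
    "stage_from_pixel",
    "pixel_from_stage",
]

#: nanoliters per cubic micrometer
NL_PER_UM3 = 1e-6


@dataclass(frozen=True)
class ArenaGeometry:
    """A walled region of the dish holding a thin layer of cell suspension.

    Parameters
    ----------
    x0, y0, x1, y1:
        Bounding rectangle in stage micrometers.
    layer_height_um:
        Height of the medium layer under the oil (default 97 um, the
        measured thin-layer height).
    polygon:
        Optional list of (x, y) vertices for a non-rectangular arena; the
        rectangle must then be its bounding box.
    """

    x0: float
    y0: float
    x1: float
    y1: float
    layer_height_um: float = 97.0
    polygon: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("arena bounds must have positive extent")
        if self.layer_height_um <= 0:
            raise ValueError("layer_height_um must be > 0")
        if self.polygon is not None and len(self.polygon) < 3:
            raise ValueError("polygon needs at least 3 vertices")

    # -- construction helpers -------------------------------------------------
    @classmethod
    def square(
        cls, side_um: float, origin: tuple[float, float] = (0.0, 0.0), **kw
    ) -> "ArenaGeometry":
        """A side x side square with its top-left corner at *origin*."""
        ox, oy = origin
        return cls(ox, oy, ox + side_um, oy + side_um, **kw)

    @classmethod
    def from_polygon(cls, vertices: Sequence[tuple[float, float]], **kw) -> "ArenaGeometry":
        vs = np.asarray(vertices, dtype=float)
        return cls(
            float(vs[:, 0].min()),
            float(vs[:, 1].min()),
            float(vs[:, 0].max()),
            float(vs[:, 1].max()),
            polygon=tuple((float(x), float(y)) for x, y in vs),
            **kw,
        )

    # -- derived quantities ---------------------------------------------------
    @property
    def width_um(self) -> float:
        return self.x1 - self.x0

    @property
    def height_um(self) -> float:
        return self.y1 - self.y0

    @property
    def area_um2(self) -> float:
        if self.polygon is not None:
            return self._shapely().area
        return self.width_um * self.height_um

    @property
    def area_mm2(self) -> float:
        return self.area_um2 / 1e6

    @property
    def medium_volume_nl(self) -> float:
        """Medium volume = area x layer height, in nanoliters."""
        return self.area_um2 * self.layer_height_um * NL_PER_UM3

    def _shapely(self):
        from shapely.geometry import Polygon

        return Polygon(self.polygon)

    # -- predicates -----------------------------------------------------------
    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized containment test for an (N, 2) array of stage points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inside = (
            (pts[:, 0] >= self.x0)
            & (pts[:, 0] <= self.x1)
            & (pts[:, 1] >= self.y0)
            & (pts[:, 1] <= self.y1)
        )
        if self.polygon is not None and inside.any():
            from shapely import contains_xy

            poly = self._shapely().buffer(1e-9)
            inside = inside & contains_xy(poly, pts[:, 0], pts[:, 1])
        return inside

    def contains_point(self, x: float, y: float) -> bool:
        return bool(self.contains(np.array([[x, y]]))[0])

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw *n* uniform points inside the arena (rejection for polygons)."""
        if n == 0:
            return np.empty((0, 2))
        if self.polygon is None:
            return rng.uniform((self.x0, self.y0), (self.x1, self.y1), size=(n, 2))
        out = np.empty((0, 2))
        while len(out) < n:
            batch = rng.uniform((self.x0, self.y0), (self.x1, self.y1), size=(2 * n, 2))
            out = np.vstack([out, batch[self.contains(batch)]])
        return out[:n]

    def clip(self, points: np.ndarray) -> np.ndarray:
        """Clamp points into the bounding rectangle (polygon walls: see reflect)."""
        pts = np.array(points, dtype=float, copy=True)
        np.clip(pts[:, 0], self.x0, self.x1, out=pts[:, 0])
        np.clip(pts[:, 1], self.y0, self.y1, out=pts[:, 1])
        return pts

    def reflect(self, points: np.ndarray) -> np.ndarray:
        """Fold points that crossed a wall back inside (specular reflection).

        For polygonal arenas the reflection is applied on the bounding box and
        any point still outside the polygon is clamped to its previous clip.
        """
        pts = np.array(points, dtype=float, copy=True)
        for axis, (lo, hi) in enumerate(((self.x0, self.x1), (self.y0, self.y1))):
            span = hi - lo
            # triangular fold with period 2*span handles multiple bounces
            u = np.mod(pts[:, axis] - lo, 2.0 * span)
            pts[:, axis] = lo + np.where(u > span, 2.0 * span - u, u)
        if self.polygon is not None:
            outside = ~self.contains(pts)
            if outside.any():
                pts[outside] = self.clip(pts[outside])
        return pts


@dataclass(frozen=True)
class FrameSpec:
    """Camera frame geometry: size, scale and position on the stage."""

    width: int
    height: int
    pixel_size: float  # um per pixel
    stage_offset: tuple[float, float] = (0.0, 0.0)  # stage um of pixel (0, 0)
    channel: str = "fluorescent"  # "fluorescent" | "phase"
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("frame dimensions must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.channel not in ("fluorescent", "phase"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def dtype(self):
        return np.uint8 if self.bit_depth == 8 else np.uint16

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the field of view in micrometers."""
        return (self.width * self.pixel_size, self.height * self.pixel_size)

    def shifted(self, offset: tuple[float, float]) -> "FrameSpec":
        from dataclasses import replace

        return replace(self, stage_offset=(float(offset[0]), float(offset[1])))


def stage_from_pixel(spec: FrameSpec, pixel) -> np.ndarray:
    """Map (row, col) pixel coordinates to stage (x, y) in micrometers."""
    px = np.atleast_2d(np.asarray(pixel, dtype=float))
    ox, oy = spec.stage_offset
    out = np.empty_like(px)
    out[:, 0] = px[:, 1] * spec.pixel_size + ox  # col -> x
    out[:, 1] = px[:, 0] * spec.pixel_size + oy  # row -> y
    return out if np.asarray(pixel).ndim > 1 else out[0]


def pixel_from_stage(spec: FrameSpec, stage) -> np.ndarray:
    """Map stage (x, y) micrometers to (row, col) pixel coordinates."""
    xy = np.atleast_2d(np.asarray(stage, dtype=float))
    ox, oy = spec.stage_offset
    out = np.empty_like(xy)
    out[:, 0] = (xy[:, 1] - oy) / spec.pixel_size  # y -> row
    out[:, 1] = (xy[:, 0] - ox) / spec.pixel_size  # x -> col
    return out if np.asarray(stage).ndim > 1 else out[0]
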