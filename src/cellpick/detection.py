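"""Fluorescent-cell detection by the local-variance method.

A cell against a flat background produces a patch of high local intensity
variance; thresholding the variance map at ``noise_level**2 * sensitivity``
(so sensitivity = 1 sits exactly at the noise floor) and taking 8-connected
components with hole filling yields candidate blobs, which are then filtered
by equivalent diameter and mean brightness.  Detections from external
segmenters (e.g. ImageJ "Analyze Particles" result tables) can be imported
through a configurable CSV dialect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import FrameSpec, stage_from_pixel
from .records import CellRecord
from .synthetic import MosaicScan

__all__ = [
    "DetectionParams",
    "ExternalDetectionDialect",
    "IMAGEJ_DIALECT",
    "local_variance_map",
    "segment_frame",
    "detect_mosaic",
    "import_external_detections",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable detection knobs: brightness/size windows, sensitivity, noise."""

    window_radius: int = 2  # px
    min_brightness: float = 0.0
    max_brightness: float = float("inf")
    min_size: float = 4.0  # um, equivalent diameter
    max_size: float = 60.0  # um
    sensitivity: float = 4.0
    noise_level: float = 5.0  # brightness units

    def __post_init__(self) -> None:
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")
        if self.min_brightness > self.max_brightness:
            raise ValueError("min_brightness > max_brightness")
        if self.min_size > self.max_size:
            raise ValueError("min_size > max_size")
        if self.sensitivity < 0 or self.noise_level < 0:
            raise ValueError("sensitivity and noise_level must be >= 0")

    @property
    def variance_threshold(self) -> float:
        return self.noise_level**2 * self.sensitivity


def local_variance_map(image: np.ndarray, window_radius: int) -> np.ndarray:
    """Per-pixel intensity variance over a (2r+1)^2 window, reflected borders."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("image must be 2D")
    size = 2 * int(window_radius) + 1
    mean = ndimage.uniform_filter(img, size=size, mode="reflect")
    mean_sq = ndimage.uniform_filter(img * img, size=size, mode="reflect")
    var = mean_sq - mean * mean
    np.clip(var, 0.0, None, out=var)
    return var


_EIGHT = np.ones((3, 3), dtype=int)


def segment_frame(
    image: np.ndarray, spec: FrameSpec, params: DetectionParams
) -> list[CellRecord]:
    """Detect cells in one frame; records carry stage-um centroids.

    Per component the centroid is intensity-weighted (weights are the image
    minus its minimum over the component, so a constant offset cancels),
    size is the equivalent-circle diameter of the component area and
    brightness is the raw mean intensity.  Output is sorted by y then x.
    """
    img = np.asarray(image, dtype=np.float64)
    var = local_variance_map(img, params.window_radius)
    mask = var > params.variance_threshold
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask, structure=_EIGHT)
    out: list[CellRecord] = []
    if n == 0:
        return out
    slices = ndimage.find_objects(labels)
    for comp, slc in enumerate(slices, start=1):
        sub = labels[slc] == comp
        patch = img[slc]
        area_px = int(sub.sum())
        diameter = 2.0 * np.sqrt(area_px / np.pi) * spec.pixel_size
        if not (params.min_size <= diameter <= params.max_size):
            continue
        mean_brightness = float(patch[sub].mean())
        if not (params.min_brightness <= mean_brightness <= params.max_brightness):
            continue
        weights = patch[sub] - patch[sub].min()
        rr, cc = np.nonzero(sub)
        wsum = weights.sum()
        if wsum > 0:
            row = float((rr * weights).sum() / wsum) + slc[0].start
            col = float((cc * weights).sum() / wsum) + slc[1].start
        else:  # perfectly flat component: geometric centroid
            row = float(rr.mean()) + slc[0].start
            col = float(cc.mean()) + slc[1].start
        x, y = stage_from_pixel(spec, (row, col))
        h_um = (rr.max() - rr.min() + 1) * spec.pixel_size
        w_um = (cc.max() - cc.min() + 1) * spec.pixel_size
        out.append(
            CellRecord(
                id=-1,
                x=float(x),
                y=float(y),
                brightness=mean_brightness,
                size=float(diameter),
                bbox_w=float(w_um),
                bbox_h=float(h_um),
            )
        )
    out.sort(key=lambda c: (c.y, c.x))
    for i, c in enumerate(out):
        c.id = i
    return out


def detect_mosaic(
    mosaic: MosaicScan, params: DetectionParams, dedup_radius: float = 20.0
) -> list[CellRecord]:
    """Detect across all tiles and merge cross-tile duplicates.

    Detections from *different* tiles closer than ``dedup_radius`` (um) are
    considered the same cell; the record whose centroid lies farthest from
    its own tile border is kept (least edge truncation).  Ids are reassigned
    to be unique across the mosaic.
    """
    pixel_sizes = {t.spec.pixel_size for t in mosaic.tiles}
    if len(pixel_sizes) > 1:
        raise ValueError(f"inconsistent tile pixel sizes: {sorted(pixel_sizes)}")
    all_records: list[CellRecord] = []
    tile_of: list[int] = []
    border_dist: list[float] = []
    for ti, tile in enumerate(mosaic.tiles):
        recs = segment_frame(tile.image, tile.spec, params)
        ext_x, ext_y = tile.spec.extent_um
        ox, oy = tile.spec.stage_offset
        for r in recs:
            all_records.append(r)
            tile_of.append(ti)
            border_dist.append(
                min(r.x - ox, ox + ext_x - r.x, r.y - oy, oy + ext_y - r.y)
            )
    if not all_records:
        return []
    pts = np.array([[r.x, r.y] for r in all_records])
    tree = cKDTree(pts)
    parent = list(range(len(all_records)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in tree.query_pairs(dedup_radius):
        if tile_of[a] != tile_of[b]:
            parent[find(a)] = find(b)
    best: dict[int, int] = {}
    for i in range(len(all_records)):
        root = find(i)
        if root not in best or border_dist[i] > border_dist[best[root]]:
            best[root] = i
    merged = [all_records[i] for i in sorted(best.values())]
    merged.sort(key=lambda c: (c.y, c.x))
    for i, r in enumerate(merged):
        r.id = i
    return merged


@dataclass(frozen=True)
class ExternalDetectionDialect:
    """Column mapping for an external segmenter's result table.

    Each logical field maps to a tuple of candidate source column names,
    tried in order; x and y are mandatory, the rest optional.  ``units``
    declares whether coordinates are pixels (converted to stage um through a
    FrameSpec) or already micrometers.
    """

    x: tuple[str, ...]
    y: tuple[str, ...]
    width: tuple[str, ...] = ()
    height: tuple[str, ...] = ()
    brightness: tuple[str, ...] = ()
    units: str = "px"  # "px" | "um"

    def __post_init__(self) -> None:
        if not self.x or not self.y:
            raise ValueError("x and y column candidates are mandatory")
        if self.units not in ("px", "um"):
            raise ValueError("units must be 'px' or 'um'")

    def resolve(self, columns: Sequence[str], candidates: tuple[str, ...]) -> str | None:
        for name in candidates:
            if name in columns:
                return name
        return None


#: ImageJ "Analyze Particles" results dialect (Record starts option or centroids)
IMAGEJ_DIALECT = ExternalDetectionDialect(
    x=("XStart", "X", "XM", "BX"),
    y=("YStart", "Y", "YM", "BY"),
    width=("Width",),
    height=("Height",),
    brightness=("Mean",),
    units="px",
)


def import_external_detections(
    source: str | Path | io.IOBase,
    dialect: ExternalDetectionDialect,
    spec: FrameSpec,
) -> list[CellRecord]:
    """Read an external detection table (CSV with header) into CellRecords.

    Pixel-unit coordinates are converted to stage micrometers via *spec*;
    missing optional columns leave the corresponding fields unset.
    """
    df = pd.read_csv(source)
    cols = list(df.columns)
    x_col = dialect.resolve(cols, dialect.x)
    y_col = dialect.resolve(cols, dialect.y)
    if x_col is None:
        raise ValueError(f"no x column found; expected one of {dialect.x}")
    if y_col is None:
        raise ValueError(f"no y column found; expected one of {dialect.y}")
    w_col = dialect.resolve(cols, dialect.width)
    h_col = dialect.resolve(cols, dialect.height)
    b_col = dialect.resolve(cols, dialect.brightness)

    def _num(row_idx: int, col: str) -> float:
        v = df.iloc[row_idx][col]
        try:
            return float(v)
        except (TypeError, ValueError):
            raise ValueError(
                f"non-numeric value {v!r} in column {col!r} at row {row_idx + 1}"
            ) from None

    out: list[CellRecord] = []
    scale = spec.pixel_size if dialect.units == "px" else 1.0
    ox, oy = spec.stage_offset if dialect.units == "px" else (0.0, 0.0)
    for i in range(len(df)):
        x = _num(i, x_col) * scale + ox
        y = _num(i, y_col) * scale + oy
        w = _num(i, w_col) * scale if w_col else None
        h = _num(i, h_col) * scale if h_col else None
        size = 0.0
        if w is not None and h is not None:
            size = float(np.sqrt(w * h))  # equivalent square side as a proxy
        out.append(
            CellRecord(
                id=i,
                x=x,
                y=y,
                brightness=_num(i, b_col) if b_col else 0.0,
                size=size,
                bbox_w=w,
                bbox_h=h,
            )
        )
    return out


def write_detections_csv(cells: Sequence[CellRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [c.id for c in cells],
            "x_um": [c.x for c in cells],
            "y_um": [c.y for c in cells],
            "size_um": [c.size for c in cells],
            "brightness": [c.brightness for c in cells],
        }
    ).to_csv(path, index=False)
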