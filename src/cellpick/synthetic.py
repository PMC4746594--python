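"""Synthetic imaging: cell populations, rendered frames and mosaic scans.

Everything downstream (detection, targeting, the full sorting workflows) is
validated against ground truth produced here.  The renderer is deliberately
simple — an isotropic Gaussian spot per fluorescent cell on a constant
background with i.i.d. Gaussian noise — because its centroid, peak value and
translation behavior all have closed forms that tests can check exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import ArenaGeometry, FrameSpec, pixel_from_stage
from .records import CellRecord, records_to_frame

__all__ = [
    "RenderParams",
    "MosaicTile",
    "MosaicScan",
    "make_population",
    "render_frame",
    "generate_mosaic",
    "write_mosaic",
    "write_population_csv",
]

#: dart-throwing retry budget per requested cell
RETRY_FACTOR = 100


@dataclass(frozen=True)
class RenderParams:
    """Appearance of rendered cells.

    spot_sigma of ``None`` means "derive from the cell size" (sigma =
    size / 4, so the apparent blob diameter tracks the nominal cell size).
    """

    spot_sigma: float | None = None  # um; None -> cell size / 4
    peak: float = 500.0  # brightness units above background
    background: float = 100.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spot_sigma is not None and self.spot_sigma <= 0:
            raise ValueError("spot_sigma must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_population(
    arena: ArenaGeometry,
    n_labeled: int,
    n_unlabeled: int,
    min_separation: float = 0.0,
    seed: int = 0,
    cell_size: float = 16.0,
    brightness: float = 500.0,
    brightness_cv: float = 0.1,
) -> list[CellRecord]:
    """Place labeled + unlabeled cells uniformly at random in the arena.

    A hard-core constraint (``min_separation``) is enforced by dart throwing
    with a retry budget of 100 attempts per cell; labeled cells get ids
    ``L0..``, unlabeled ``U0..``.

    Raises
    ------
    ValueError
        If the packing is infeasible (packing fraction >= 0.5) or the retry
        budget is exhausted; the error names the achieved count.
    """
    if n_labeled < 0 or n_unlabeled < 0:
        raise ValueError("cell counts must be >= 0")
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    n = n_labeled + n_unlabeled
    if n == 0:
        return []
    if min_separation > 0:
        packing = n * math.pi * (min_separation / 2.0) ** 2 / arena.area_um2
        if packing >= 0.5:
            raise ValueError(
                f"infeasible hard-core packing: fraction {packing:.2f} >= 0.5"
            )
    rng = np.random.default_rng(seed)
    pts = _dart_throw(arena, n, min_separation, rng)
    bright = np.maximum(
        rng.normal(brightness, brightness_cv * brightness, size=n), 0.0
    )
    cells: list[CellRecord] = []
    for i in range(n):
        labeled = i < n_labeled
        cid = f"L{i}" if labeled else f"U{i - n_labeled}"
        cells.append(
            CellRecord(
                id=cid,
                x=float(pts[i, 0]),
                y=float(pts[i, 1]),
                brightness=float(bright[i]),
                size=cell_size,
                labeled=labeled,
            )
        )
    return cells


def _dart_throw(
    arena: ArenaGeometry, n: int, min_separation: float, rng: np.random.Generator
) -> np.ndarray:
    if min_separation == 0.0:
        return arena.sample_uniform(n, rng)
    accepted = np.empty((0, 2))
    tree: cKDTree | None = None
    attempts = 0
    budget = RETRY_FACTOR * n
    while len(accepted) < n:
        remaining = n - len(accepted)
        batch = arena.sample_uniform(min(4 * remaining, budget - attempts + 1), rng)
        attempts += len(batch)
        for p in batch:
            if tree is None or not tree.query_ball_point(p, min_separation):
                accepted = np.vstack([accepted, p[None, :]])
                if len(accepted) == n:
                    break
                # rebuilding per acceptance is fine at these problem sizes
                tree = cKDTree(accepted)
        if attempts >= budget and len(accepted) < n:
            raise ValueError(
                f"dart-throwing retry cap exceeded: placed {len(accepted)} of {n} "
                f"cells at min_separation={min_separation} um"
            )
    return accepted


def render_frame(
    cells: Sequence[CellRecord],
    spec: FrameSpec,
    params: RenderParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render cells into a single camera frame.

    Fluorescent channel: each *labeled* cell becomes an isotropic Gaussian
    spot of amplitude ``cell.brightness`` (or ``params.peak`` if the record
    carries none) on a constant background.  Phase channel: every cell is a
    faint bright ring at its nominal radius.  i.i.d. Gaussian noise of
    ``noise_sd`` is added and the image clipped to the bit range.  Cells
    outside the field of view are clipped silently.
    """
    img = np.full((spec.height, spec.width), float(params.background))
    for cell in cells:
        if spec.channel == "fluorescent":
            if not cell.labeled:
                continue
            amp = cell.brightness if cell.brightness > 0 else params.peak
            _add_gaussian_spot(img, spec, cell, amp, params)
        else:
            _add_phase_ring(img, spec, cell, params)
    if params.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    np.clip(img, 0, spec.max_value, out=img)
    return np.rint(img).astype(spec.dtype)


def _spot_sigma_um(cell: CellRecord, params: RenderParams) -> float:
    if params.spot_sigma is not None:
        return params.spot_sigma
    return max(cell.size / 4.0, 0.5)


def _patch_indices(spec: FrameSpec, row: float, col: float, half: float):
    r0 = max(int(math.floor(row - half)), 0)
    r1 = min(int(math.ceil(row + half)) + 1, spec.height)
    c0 = max(int(math.floor(col - half)), 0)
    c1 = min(int(math.ceil(col + half)) + 1, spec.width)
    if r0 >= r1 or c0 >= c1:
        return None
    return r0, r1, c0, c1


def _add_gaussian_spot(img, spec, cell, amplitude, params) -> None:
    sigma_px = _spot_sigma_um(cell, params) / spec.pixel_size
    row, col = pixel_from_stage(spec, (cell.x, cell.y))
    idx = _patch_indices(spec, row, col, 5.0 * sigma_px)
    if idx is None:
        return
    r0, r1, c0, c1 = idx
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d2 = (rr - row) ** 2 + (cc - col) ** 2
    img[r0:r1, c0:c1] += amplitude * np.exp(-d2 / (2.0 * sigma_px**2))


def _add_phase_ring(img, spec, cell, params) -> None:
    # low-contrast bright ring at the cell radius, ~10% of the peak
    radius_px = max(cell.size / 2.0, 1.0) / spec.pixel_size
    ring_sigma = max(0.15 * radius_px, 0.6)
    row, col = pixel_from_stage(spec, (cell.x, cell.y))
    idx = _patch_indices(spec, row, col, radius_px + 4 * ring_sigma)
    if idx is None:
        return
    r0, r1, c0, c1 = idx
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.sqrt((rr - row) ** 2 + (cc - col) ** 2)
    img[r0:r1, c0:c1] += 0.1 * params.peak * np.exp(
        -((d - radius_px) ** 2) / (2.0 * ring_sigma**2)
    )


@dataclass(frozen=True)
class MosaicTile:
    image: np.ndarray
    spec: FrameSpec
    index: tuple[int, int]  # (tile_row, tile_col)


@dataclass(frozen=True)
class MosaicScan:
    tiles: tuple[MosaicTile, ...]
    overlap: float
    pixel_size: float

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)


def generate_mosaic(
    arena: ArenaGeometry,
    cells: Sequence[CellRecord],
    spec: FrameSpec,
    overlap: float,
    params: RenderParams,
) -> MosaicScan:
    """Tile the arena bounding box with overlapping frames and render each.

    Tiles advance by ``extent * (1 - overlap)`` per axis, so the per-axis
    tile count is ``ceil(span / (extent * (1 - overlap)))``; a cell sitting
    in an overlap strip is rendered in every covering tile at consistent
    stage coordinates.
    """
    if not (0.0 <= overlap < 0.5):
        raise ValueError("overlap must be in [0, 0.5)")
    ext_x, ext_y = spec.extent_um
    step_x = ext_x * (1.0 - overlap)
    step_y = ext_y * (1.0 - overlap)
    nx = max(1, math.ceil(arena.width_um / step_x))
    ny = max(1, math.ceil(arena.height_um / step_y))
    rng = np.random.default_rng(params.seed)
    tiles = []
    for j in range(ny):
        for i in range(nx):
            offset = (arena.x0 + i * step_x, arena.y0 + j * step_y)
            tspec = spec.shifted(offset)
            tiles.append(
                MosaicTile(render_frame(cells, tspec, params, rng=rng), tspec, (j, i))
            )
    return MosaicScan(tuple(tiles), overlap, spec.pixel_size)


# -- on-disk formats ---------------------------------------------------------


def write_mosaic(mosaic: MosaicScan, out_dir: str | Path, stem: str = "tile") -> Path:
    """Write tiles as TIFF plus a JSON manifest of offsets; returns manifest path."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for t in mosaic.tiles:
        name = f"{stem}_r{t.index[0]:03d}_c{t.index[1]:03d}.tif"
        tifffile.imwrite(out / name, t.image)
        entries.append(
            {
                "file": name,
                "stage_offset_um": list(t.spec.stage_offset),
                "index": list(t.index),
            }
        )
    manifest = {
        "pixel_size_um": mosaic.pixel_size,
        "overlap": mosaic.overlap,
        "channel": mosaic.tiles[0].spec.channel if mosaic.tiles else "fluorescent",
        "bit_depth": mosaic.tiles[0].spec.bit_depth if mosaic.tiles else 16,
        "tiles": entries,
    }
    path = out / f"{stem}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_mosaic(manifest_path: str | Path) -> MosaicScan:
    import tifffile

    path = Path(manifest_path)
    manifest = json.loads(path.read_text())
    tiles = []
    for e in manifest["tiles"]:
        img = tifffile.imread(path.parent / e["file"])
        spec = FrameSpec(
            width=img.shape[1],
            height=img.shape[0],
            pixel_size=manifest["pixel_size_um"],
            stage_offset=tuple(e["stage_offset_um"]),
            channel=manifest.get("channel", "fluorescent"),
            bit_depth=manifest.get("bit_depth", 16),
        )
        tiles.append(MosaicTile(img, spec, tuple(e["index"])))
    return MosaicScan(tuple(tiles), manifest.get("overlap", 0.0), manifest["pixel_size_um"])


def write_population_csv(cells: Sequence[CellRecord], path: str | Path) -> None:
    records_to_frame(cells).to_csv(path, index=False)
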