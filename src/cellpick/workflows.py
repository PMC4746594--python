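"""The three end-to-end experiments, plus the estimators they report.

* :func:`run_sparse_isolation` — detect ~80 cells/mm^2 in a 5 x 5 mm^2
  arena from a rendered mosaic, tour them with the scheduler and pick each
  into its own vessel, with adaptive retargeting against thin-layer drift.
* :func:`run_successive_enrichment` — pick every labeled cell out of a
  dense 1,000:1 unlabeled:labeled culture and redeposit it (with its
  bystanders) into the next arena, repeating until the bystanders thin out.
* :func:`run_microwell_comparison` — the competing microwell-entrapment
  route: Bernoulli well filling, washing losses, and ~50% aspiration
  success per trapped cell.
* :func:`estimate_floating_speed` — the time-lapse speed estimator
  (non-overlapping 120 s displacement intervals, averaged per cell).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .detection import DetectionParams, detect_mosaic, segment_frame
from .geometry import ArenaGeometry, FrameSpec
from .records import CellRecord, positions
from .scheduler import DestinationLayout, assign_destinations, plan_route
from .suspension import (
    CaptureModel,
    MicrowellArray,
    MotionModel,
    SuspensionState,
    TrackSet,
    deposit_at,
    load_microwell_array,
    pick_at,
    pick_from_well,
    step_motion,
)
from .synthetic import RenderParams, generate_mosaic, make_population, render_frame
from .targeting import adaptive_retarget, fresh_frame_spec

__all__ = [
    "SparseIsolationConfig",
    "IsolationReport",
    "EnrichmentConfig",
    "EnrichmentReport",
    "PassStats",
    "MicrowellConfig",
    "ComparisonReport",
    "SpeedEstimate",
    "run_sparse_isolation",
    "run_successive_enrichment",
    "run_microwell_comparison",
    "estimate_floating_speed",
    "detection_metrics",
    "expected_untrapped_fraction",
]


def _subseed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# sparse isolation
# ---------------------------------------------------------------------------


@dataclass
class SparseIsolationConfig:
    """Study conditions for sparse single-cell isolation.

    Defaults follow the sparse experiment: 2,000 fluorescent cells injected
    into a 5 x 5 mm^2 square (80 cells/mm^2), thin-layer floating motion,
    the measured 34 +- 4 um capture radius, one pick-deposit cycle every
    20 s (3 cells/min) and adaptive retargeting from a 200 um fresh frame.
    """

    arena: ArenaGeometry = field(default_factory=lambda: ArenaGeometry.square(5000.0))
    n_cells: int = 2000
    min_separation: float = 50.0  # um; sparse trypsinized singles
    cell_size: float = 16.0
    motion: MotionModel | None = field(default_factory=MotionModel.thin_layer)
    capture: CaptureModel = field(default_factory=CaptureModel.sparse)
    detection: DetectionParams = field(default_factory=DetectionParams)
    render: RenderParams = field(default_factory=RenderParams)
    pixel_size: float = 2.0  # um/px
    tile_px: int = 640
    overlap: float = 0.1
    dedup_radius: float = 20.0
    adaptive: bool = True
    search_radius: float = 50.0
    fresh_extent: float = 200.0  # um
    cycle_time: float = 20.0  # s per pick-deposit cycle
    n_targets: int | None = None  # None -> all detected cells
    use_imaging: bool = True
    rescan_every: int = 15  # picks between ROI rescans (0 disables)
    rescan_noise_sd: float = 1.0  # um, rescan re-detection error
    exclude_crowded: bool = True  # only target cells isolated at scan time
    max_deferrals: int = 2  # re-queue a target whose fresh frame shows a
    # neighbor inside the capture disc, at most this many times
    doublet_size_um: float = 34.0  # defer if the matched blob exceeds this
    # apparent diameter (doublet exclusion; singles image at ~29 um here)
    layout: DestinationLayout = field(
        default_factory=lambda: DestinationLayout(mode="pcr_tubes")
    )
    match_radius: float = 10.0  # um, detection <-> ground-truth pairing


@dataclass
class IsolationReport:
    attempted: int
    successes: int  # exactly the target, alone, in its vessel
    lost_targets: int
    contaminations: int  # vessel received bystanders or a wrong cell
    recovery: float
    hit_fraction: float  # target truly within capture radius at pick time
    n_initial: int
    n_remaining: int
    n_transferred: int
    n_pick_attempts: int
    initial_volume_nl: float
    final_volume_nl: float
    pick_volume_nl: float
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _match_to_truth(
    detections: Sequence[CellRecord], truth: Sequence[CellRecord], radius: float
) -> list:
    """Nearest ground-truth id within *radius* for each detection (or None)."""
    if not truth:
        return [None] * len(detections)
    tree = cKDTree(positions(truth))
    out = []
    for det in detections:
        d, i = tree.query((det.x, det.y))
        out.append(truth[i].id if d <= radius else None)
    return out


def _cells_near(state: SuspensionState, spec: FrameSpec, margin: float = 40.0):
    """CellRecords of state cells inside the frame (plus margin), for rendering."""
    if state.n == 0:
        return []
    ox, oy = spec.stage_offset
    ex, ey = spec.extent_um
    m = margin
    sel = (
        (state.pos[:, 0] >= ox - m)
        & (state.pos[:, 0] <= ox + ex + m)
        & (state.pos[:, 1] >= oy - m)
        & (state.pos[:, 1] <= oy + ey + m)
    )
    idx = np.flatnonzero(sel)
    return [
        CellRecord(
            id=state.ids[i],
            x=float(state.pos[i, 0]),
            y=float(state.pos[i, 1]),
            brightness=float(state.brightness[i]),
            size=float(state.sizes[i]),
            labeled=bool(state.labeled[i]),
        )
        for i in idx
    ]


def _rescan(
    state: SuspensionState,
    pending: Sequence[tuple],
    noise_sd: float,
    rng: np.random.Generator,
) -> None:
    """Refresh pending targets' coordinates from a new ROI scan.

    Modeled as an idealized re-detection: each pending target still present
    in the suspension gets its current position plus a small detection
    error; targets whose cell is gone (picked as a bystander) stay stale
    and will be reported lost at their turn.
    """
    for det, true_id in pending:
        if true_id is None:
            continue
        i = state.index_of(true_id)
        if i is None:
            continue
        err = rng.normal(0.0, noise_sd, size=2) if noise_sd > 0 else np.zeros(2)
        det.x = float(state.pos[i, 0] + err[0])
        det.y = float(state.pos[i, 1] + err[1])


def _refresh_pending(
    pending: Sequence[CellRecord],
    fresh: Sequence[CellRecord],
    fspec: FrameSpec,
    search_radius: float,
) -> None:
    """Update expected coordinates of pending targets from one fresh frame.

    Greedy one-to-one matching by ascending distance between fresh
    detections and pending targets expected inside the frame, capped at the
    search radius; matched targets' coordinates are overwritten in place.
    """
    if not fresh or not pending:
        return
    ox, oy = fspec.stage_offset
    ex, ey = fspec.extent_um
    in_frame = [
        p
        for p in pending
        if ox <= p.x <= ox + ex and oy <= p.y <= oy + ey
    ]
    if not in_frame:
        return
    pairs = []
    for pi, p in enumerate(in_frame):
        for fi, f in enumerate(fresh):
            d = f.distance_to(p)
            if d <= search_radius:
                pairs.append((d, pi, fi))
    pairs.sort()
    used_p: set[int] = set()
    used_f: set[int] = set()
    for _, pi, fi in pairs:
        if pi in used_p or fi in used_f:
            continue
        used_p.add(pi)
        used_f.add(fi)
        in_frame[pi].x = fresh[fi].x
        in_frame[pi].y = fresh[fi].y


def run_sparse_isolation(
    config: SparseIsolationConfig, rng: np.random.Generator
) -> IsolationReport:
    """Full sparse-isolation loop; returns per-run accounting.

    A pick counts as a *success* only when exactly the intended cell was
    transferred alone to its vessel; co-picked neighbors (or a wrong cell)
    count as contamination, everything else as a lost target.
    """
    cfg = config
    warnings: list[str] = []
    density = cfg.n_cells / cfg.arena.area_um2
    expected_bystanders = density * math.pi * cfg.capture.capture_radius**2
    if expected_bystanders > 1.0:
        warnings.append(
            f"capture disc expects {expected_bystanders:.1f} cells at this density; "
            "single-cell isolation is a priori unlikely"
        )

    cells = make_population(
        cfg.arena,
        n_labeled=cfg.n_cells,
        n_unlabeled=0,
        min_separation=cfg.min_separation,
        seed=_subseed(rng),
        cell_size=cfg.cell_size,
    )
    state = SuspensionState.from_cells(cfg.arena, cells)
    initial_volume = state.medium_volume_nl

    if cfg.use_imaging:
        spec = FrameSpec(cfg.tile_px, cfg.tile_px, cfg.pixel_size)
        render = RenderParams(
            spot_sigma=cfg.render.spot_sigma,
            peak=cfg.render.peak,
            background=cfg.render.background,
            noise_sd=cfg.render.noise_sd,
            seed=_subseed(rng),
        )
        mosaic = generate_mosaic(cfg.arena, cells, spec, cfg.overlap, render)
        detections = detect_mosaic(mosaic, cfg.detection, cfg.dedup_radius)
    else:
        detections = [
            CellRecord(id=f"D{i}", x=c.x, y=c.y, brightness=c.brightness, size=c.size)
            for i, c in enumerate(cells)
        ]
    true_ids = _match_to_truth(detections, cells, cfg.match_radius)
    by_det_id = {d.id: (d, t) for d, t in zip(detections, true_ids)}

    targets = detections
    if cfg.exclude_crowded and len(detections) > 1:
        # single-cell isolation targets only cells with no neighbor inside
        # the capture disc at scan time, as an operator would select them
        tree = cKDTree(positions(detections))
        nn_d, _ = tree.query(positions(detections), k=2)
        targets = [
            d
            for d, dist in zip(detections, nn_d[:, 1])
            if dist > cfg.capture.capture_radius
        ]
    order, _ = plan_route(targets, start=(cfg.arena.x0, cfg.arena.y0))
    if cfg.n_targets is not None:
        order = order[: cfg.n_targets]
    pending = set(order)

    successes = lost = contaminations = 0
    hits = 0
    n_transferred = 0
    n_pick_attempts = 0
    from collections import deque

    queue = deque(order)
    deferrals: dict = {}
    attempt = 0
    while queue:
        det_id = queue.popleft()
        if cfg.rescan_every and attempt and attempt % cfg.rescan_every == 0:
            # periodic ROI rescan: without it, accumulated staleness outruns
            # the fixed search radius on long routes (drift ~ sqrt(t))
            _rescan(state, [by_det_id[p] for p in pending], cfg.rescan_noise_sd, rng)
        attempt += 1
        det, true_id = by_det_id[det_id]
        if cfg.motion is not None and cfg.motion.mean_speed > 0:
            state = step_motion(state, cfg.cycle_time, cfg.motion, rng, in_place=True)
        else:
            state.clock += cfg.cycle_time
        if cfg.adaptive:
            fspec = fresh_frame_spec(det, cfg.pixel_size, cfg.fresh_extent)
            if cfg.use_imaging:
                img = render_frame(_cells_near(state, fspec), fspec, cfg.render, rng=rng)
                fresh = segment_frame(img, fspec, cfg.detection)
            else:
                fresh = _cells_near(state, fspec)
            result = adaptive_retarget(det, fresh, cfg.search_radius)
            # every fresh frame re-detects nearby cells too; refresh the
            # coordinates of pending targets it covers so they never go stale
            _refresh_pending(
                [by_det_id[p][0] for p in pending], fresh, fspec, cfg.search_radius
            )
            if result.status == "lost":
                pending.discard(det_id)
                lost += 1
                continue
            aim = result.corrected_position
            # purity gate: a neighbor inside the capture disc right now would
            # be co-picked; defer the target and let the neighbor drift away.
            # An oversized matched blob is an unresolved doublet (two cells
            # closer than the imaging can split) and is deferred as well.
            matched = next((f for f in fresh if f.id == result.matched_id), None)
            crowded = any(
                f.id != result.matched_id
                and np.hypot(f.x - aim[0], f.y - aim[1]) <= cfg.capture.capture_radius
                for f in fresh
            ) or (
                matched is not None
                and matched.size > 0
                and matched.size > cfg.doublet_size_um
            )
            if crowded and deferrals.get(det_id, 0) < cfg.max_deferrals:
                deferrals[det_id] = deferrals.get(det_id, 0) + 1
                det.x, det.y = aim  # keep the corrected coordinates
                queue.append(det_id)
                continue
        else:
            aim = (det.x, det.y)
        pending.discard(det_id)
        # detection error can push a wall-hugging centroid marginally outside
        aim = tuple(cfg.arena.clip(np.array([aim]))[0])
        # diagnostic: is the true target actually inside the capture disc?
        ti = state.index_of(true_id) if true_id is not None else None
        if ti is not None:
            d = float(np.hypot(state.pos[ti, 0] - aim[0], state.pos[ti, 1] - aim[1]))
            if d <= cfg.capture.capture_radius:
                hits += 1
        n_pick_attempts += 1
        event, state = pick_at(
            state, aim, cfg.capture, rng, target_id=true_id, in_place=True
        )
        n_transferred += event.n_picked
        if not event.success or event.n_picked == 0:
            lost += 1
        elif true_id is not None and event.picked_ids == (true_id,):
            successes += 1
        else:
            contaminations += 1

    attempted = len(order)
    return IsolationReport(
        attempted=attempted,
        successes=successes,
        lost_targets=lost,
        contaminations=contaminations,
        recovery=successes / attempted if attempted else 0.0,
        hit_fraction=hits / attempted if attempted else 0.0,
        n_initial=len(cells),
        n_remaining=state.n,
        n_transferred=n_transferred,
        n_pick_attempts=n_pick_attempts,
        initial_volume_nl=initial_volume,
        final_volume_nl=state.medium_volume_nl,
        pick_volume_nl=cfg.capture.pick_volume_nl,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# successive enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentConfig:
    """Dense-inoculum conditions: 50 labeled among 50,000 unlabeled cells
    (1,000:1) in the first of four 5 x 5 mm^2 squares; each pass transfers
    every labeled cell (plus bystanders) to a 500 um deposition grid in the
    next square."""

    arena_side: float = 5000.0
    n_arenas: int = 4
    n_labeled: int = 50
    n_unlabeled: int = 50000
    min_separation: float = 0.0
    cell_size: float = 16.0
    capture_dense: CaptureModel = field(default_factory=CaptureModel.dense)
    capture_sparse: CaptureModel = field(default_factory=CaptureModel.sparse)
    grid_pitch: float = 500.0
    grid_margin: float = 750.0
    motion: MotionModel | None = None  # settled dense culture by default
    cycle_time: float = 60.0  # s; only relevant with motion enabled

    def arenas(self) -> list[ArenaGeometry]:
        return [
            ArenaGeometry.square(self.arena_side, origin=(i * (self.arena_side + 1000.0), 0.0))
            for i in range(self.n_arenas)
        ]


@dataclass
class PassStats:
    n_targets: int
    n_picks: int  # pick events actually fired this pass
    n_labeled_picked: int
    bystanders_mean: float  # unlabeled co-picks per labeled cell
    bystanders_sd: float
    purity: float  # labeled / total transferred this pass
    n_transferred: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EnrichmentReport:
    passes: list  # [PassStats]
    unlabeled_to_labeled_ratio: float  # of the initial inoculum
    n_initial: int
    counts_per_arena: list
    volumes_per_arena: list
    initial_volumes: list

    @property
    def n_passes(self) -> int:
        return len(self.passes)

    def to_dict(self) -> dict:
        return {
            "passes": [p.to_dict() for p in self.passes],
            "unlabeled_to_labeled_ratio": self.unlabeled_to_labeled_ratio,
            "n_initial": self.n_initial,
            "counts_per_arena": self.counts_per_arena,
            "volumes_per_arena": self.volumes_per_arena,
        }


def run_successive_enrichment(
    config: EnrichmentConfig, n_passes: int = 3, rng: np.random.Generator | None = None
) -> EnrichmentReport:
    """Repeated pick-and-redeposit passes between arenas.

    Pass 1 works at the dense effective capture radius; later passes (on
    redeposited, now sparse clusters) use the measured sparse radius.  Every
    labeled cell still present is targeted each pass; its bystanders travel
    with it and are thinned geometrically by the ratio of capture to deposit
    spread area.
    """
    cfg = config
    rng = rng if rng is not None else np.random.default_rng()
    if n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    if cfg.n_arenas < 2 or cfg.n_arenas < n_passes + 1:
        raise ValueError("need at least n_passes + 1 arenas")
    arenas = cfg.arenas()
    pop = make_population(
        arenas[0],
        n_labeled=cfg.n_labeled,
        n_unlabeled=cfg.n_unlabeled,
        min_separation=cfg.min_separation,
        seed=_subseed(rng),
        cell_size=cfg.cell_size,
    )
    states = [SuspensionState.from_cells(arenas[0], pop)]
    for a in arenas[1:]:
        states.append(SuspensionState(a, [], np.empty((0, 2)), np.empty(0, bool)))
    initial_volumes = [s.medium_volume_nl for s in states]

    passes: list[PassStats] = []
    for k in range(1, n_passes + 1):
        source, dest = states[k - 1], states[k]
        capture = cfg.capture_dense if k == 1 else cfg.capture_sparse
        labeled_idx = np.flatnonzero(source.labeled)
        targets = [
            CellRecord(
                id=source.ids[i],
                x=float(source.pos[i, 0]),
                y=float(source.pos[i, 1]),
                labeled=True,
            )
            for i in labeled_idx
        ]
        order, _ = plan_route(targets, start=(source.arena.x0, source.arena.y0))
        grid = assign_destinations(
            max(len(order), 1),
            DestinationLayout(
                mode="grid",
                grid_pitch=cfg.grid_pitch,
                grid_origin=(dest.arena.x0 + cfg.grid_margin, dest.arena.y0 + cfg.grid_margin),
            ),
        )
        bystander_counts: list[int] = []
        n_labeled_transferred = 0
        n_transferred = 0
        n_picks = 0
        node = 0
        for tid in order:
            i = source.index_of(tid)
            if i is None:  # already removed as a bystander of an earlier pick
                continue
            if cfg.motion is not None and cfg.motion.mean_speed > 0:
                source = step_motion(source, cfg.cycle_time, cfg.motion, rng, in_place=True)
                i = source.index_of(tid)
                if i is None:
                    continue
            aim = (float(source.pos[i, 0]), float(source.pos[i, 1]))
            event, source = pick_at(source, aim, capture, rng, target_id=tid, in_place=True)
            n_picks += 1
            if tid in event.picked_ids:
                n_unlabeled_co = sum(1 for lab in event.picked_labeled if not lab)
                bystander_counts.append(n_unlabeled_co)
                n_labeled_transferred += sum(1 for lab in event.picked_labeled if lab)
            n_transferred += event.n_picked
            d = grid[min(node, len(grid) - 1)]
            node += 1
            dest = deposit_at(dest, event.picked_cells, (d.x, d.y), capture, rng, in_place=True)
        states[k - 1], states[k] = source, dest
        counts = np.asarray(bystander_counts, dtype=float)
        passes.append(
            PassStats(
                n_targets=len(order),
                n_picks=n_picks,
                n_labeled_picked=len(bystander_counts),
                bystanders_mean=float(counts.mean()) if len(counts) else 0.0,
                bystanders_sd=float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
                purity=(n_labeled_transferred / n_transferred) if n_transferred else 1.0,
                n_transferred=n_transferred,
            )
        )
    return EnrichmentReport(
        passes=passes,
        unlabeled_to_labeled_ratio=cfg.n_unlabeled / cfg.n_labeled if cfg.n_labeled else np.inf,
        n_initial=len(pop),
        counts_per_arena=[s.n for s in states],
        volumes_per_arena=[s.medium_volume_nl for s in states],
        initial_volumes=initial_volumes,
    )


# ---------------------------------------------------------------------------
# microwell comparison
# ---------------------------------------------------------------------------


@dataclass
class MicrowellConfig:
    """Microwell-entrapment arm: 200,000-400,000 cells applied to a
    10 x 10 mm^2 plate of 10,000 wells at 100 um pitch."""

    array: MicrowellArray = field(default_factory=MicrowellArray.fibroblast)
    n_applied: int = 300000


@dataclass
class ComparisonReport:
    n_applied: int
    n_wells: int
    trapped: int
    untrapped: int
    untrapped_fraction: float
    fill_fraction: float
    n_selected: int
    n_isolated: int
    n_stuck: int
    recovery: float  # isolated / selected

    def to_dict(self) -> dict:
        return asdict(self)


def expected_untrapped_fraction(array: MicrowellArray, n_applied: int) -> float:
    """Closed-form mean untrapped fraction: 1 - wells * efficiency / applied."""
    if n_applied <= 0:
        return 0.0
    trapped = min(array.n_wells * array.fill_efficiency, n_applied)
    return 1.0 - trapped / n_applied


def run_microwell_comparison(
    config: MicrowellConfig, rng: np.random.Generator
) -> ComparisonReport:
    """Load the array, select every filled well, and try to aspirate each."""
    load = load_microwell_array(config.array, config.n_applied, rng)
    occupied = np.argwhere(load.occupancy)
    n_selected = len(occupied)
    n_isolated = n_stuck = 0
    for r, c in occupied:
        outcome = pick_from_well(load, (int(r), int(c)), rng=rng)
        if outcome == "isolated":
            n_isolated += 1
        elif outcome == "stuck":
            n_stuck += 1
    return ComparisonReport(
        n_applied=config.n_applied,
        n_wells=config.array.n_wells,
        trapped=n_selected,
        untrapped=config.n_applied - n_selected,
        untrapped_fraction=(config.n_applied - n_selected) / config.n_applied
        if config.n_applied
        else 0.0,
        fill_fraction=n_selected / config.array.n_wells,
        n_selected=n_selected,
        n_isolated=n_isolated,
        n_stuck=n_stuck,
        recovery=n_isolated / n_selected if n_selected else 0.0,
    )


# ---------------------------------------------------------------------------
# floating-speed estimation
# ---------------------------------------------------------------------------


@dataclass
class SpeedEstimate:
    mean_speed: float  # um/min
    sd: float  # um/min, across cells
    n_cells: int
    interval_s: float

    def to_dict(self) -> dict:
        return asdict(self)


def estimate_floating_speed(tracks: TrackSet, interval: float = 120.0) -> SpeedEstimate:
    """Average floating speed from non-overlapping displacement intervals.

    Per cell, each non-overlapping window of ``interval`` seconds yields
    |net displacement| / interval; window speeds are averaged per cell, then
    across cells (reported in um/min).  Measuring over 120 s rather than the
    30 s sampling interval suppresses tracking noise at the cost of a small
    downward bias once headings decorrelate within the window.
    """
    dt = tracks.sampling_interval
    if dt <= 0:
        raise ValueError("tracks need at least two frames")
    k = interval / dt
    if abs(k - round(k)) > 1e-9:
        raise ValueError(
            f"interval ({interval} s) must be a multiple of the sampling interval ({dt} s)"
        )
    k = int(round(k))
    n_windows = (tracks.n_frames - 1) // k
    if n_windows < 1:
        raise ValueError("tracks must span at least one full interval")
    idx = np.arange(0, n_windows * k + 1, k)
    pts = tracks.tracks[:, idx, :]  # (N, W+1, 2)
    disp = np.linalg.norm(np.diff(pts, axis=1), axis=2)  # (N, W) um
    per_cell = disp.mean(axis=1) / interval * 60.0  # um/min
    return SpeedEstimate(
        mean_speed=float(per_cell.mean()),
        sd=float(per_cell.std(ddof=1)) if len(per_cell) > 1 else 0.0,
        n_cells=len(per_cell),
        interval_s=float(interval),
    )


# ---------------------------------------------------------------------------
# validation harness
# ---------------------------------------------------------------------------


def detection_metrics(
    detections: Sequence[CellRecord],
    ground_truth: Sequence[CellRecord],
    match_radius: float,
) -> tuple[float, float]:
    """Precision and recall under greedy one-to-one matching by distance.

    Conventions for empty inputs: no detections and no truth -> (1, 1);
    no detections against non-empty truth -> precision 0 (undefined-as-0)
    and recall 0; detections against empty truth -> precision 0, recall 1.
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be > 0")
    nd, nt = len(detections), len(ground_truth)
    if nd == 0 and nt == 0:
        return 1.0, 1.0
    if nd == 0:
        return 0.0, 0.0
    if nt == 0:
        return 0.0, 1.0
    from scipy.spatial.distance import cdist

    d = cdist(positions(detections), positions(ground_truth))
    pairs = [
        (d[i, j], i, j) for i in range(nd) for j in range(nt) if d[i, j] <= match_radius
    ]
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    matched = 0
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        matched += 1
    return matched / nd, matched / nt
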