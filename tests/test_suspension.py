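import math

import numpy as np
import pytest

from cellpick import (
    ArenaGeometry,
    CaptureModel,
    CellRecord,
    MicrowellArray,
    MotionModel,
    SuspensionState,
    deposit_at,
    load_microwell_array,
    pick_at,
    pick_from_well,
    simulate_timelapse,
    step_motion,
)

from conftest import cell


def uniform_state(arena, n, rng, labeled=True):
    pts = arena.sample_uniform(n, rng)
    return SuspensionState(arena, list(range(n)), pts, np.full(n, labeled, bool))


class TestStepMotion:
    def test_zero_speed_is_static(self, rng):
        arena = ArenaGeometry.square(1000.0)
        st = uniform_state(arena, 20, rng)
        before = st.pos.copy()
        st = step_motion(st, 60.0, MotionModel(0.0, 0.0), rng)
        np.testing.assert_array_equal(st.pos, before)
        assert st.clock == pytest.approx(60.0)

    def test_pure_drift_displacement_is_speed_times_dt(self, rng):
        arena = ArenaGeometry.square(100000.0)
        st = SuspensionState(
            arena, [0, 1, 2], np.full((3, 2), 50000.0), np.ones(3, bool)
        )
        model = MotionModel(6.0, 0.0, persistence_time=1e12)
        before = st.pos.copy()
        st = step_motion(st, 30.0, model, rng)
        d = np.linalg.norm(st.pos - before, axis=1)
        np.testing.assert_allclose(d, 6.0 / 60.0 * 30.0, rtol=1e-9)

    def test_cells_confined_over_many_steps(self, rng):
        arena = ArenaGeometry.square(500.0)
        st = uniform_state(arena, 10, rng)
        model = MotionModel(39.0, 12.0)  # fastest regime
        for _ in range(10000):
            st = step_motion(st, 30.0, model, rng, in_place=True)
        assert arena.contains(st.pos).all()

    def test_msd_ballistic_versus_diffusive_regimes(self, rng):
        arena = ArenaGeometry.square(10**7)
        n = 400
        start = np.full((n, 2), 5e6)
        # ballistic: persistence far beyond the observation window
        st = SuspensionState(arena, list(range(n)), start.copy(), np.ones(n, bool))
        model = MotionModel(6.0, 0.0, persistence_time=1e9)
        msd = []
        for _ in range(8):
            st = step_motion(st, 30.0, model, rng, in_place=True)
            msd.append(((st.pos - start) ** 2).sum(1).mean())
        t = 30.0 * np.arange(1, 9)
        slope = np.polyfit(np.log(t), np.log(msd), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.05)
        # diffusive: persistence far below the observation window
        st = SuspensionState(arena, list(range(n)), start.copy(), np.ones(n, bool))
        model = MotionModel(6.0, 0.0, persistence_time=5.0)
        msd, taxis = [], []
        for k in range(1, 201):
            st = step_motion(st, 5.0, model, rng, in_place=True)
            if k % 25 == 0:
                msd.append(((st.pos - start) ** 2).sum(1).mean())
                taxis.append(5.0 * k)
        slope = np.polyfit(np.log(taxis), np.log(msd), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.25)

    def test_invalid_dt_rejected(self, rng):
        arena = ArenaGeometry.square(100.0)
        st = uniform_state(arena, 1, rng)
        with pytest.raises(ValueError):
            step_motion(st, 0.0, MotionModel(1.0, 0.0), rng)


class TestPickAt:
    def test_isolated_cell_picked_alone(self, rng):
        arena = ArenaGeometry.square(1000.0)
        st = SuspensionState(arena, ["a", "b"], [[500, 500], [900, 900]], [True, True])
        event, st2 = pick_at(st, (500, 500), CaptureModel(), rng)
        assert event.picked_ids == ("a",)
        assert st2.n == 1 and st2.ids == ["b"]

    def test_neighbor_at_20_copicked_at_50_retained(self, rng):
        arena = ArenaGeometry.square(1000.0)
        st = SuspensionState(
            arena,
            ["target", "near", "far"],
            [[500, 500], [520, 500], [550, 500]],
            [True, True, True],
        )
        event, st2 = pick_at(st, (500, 500), CaptureModel(capture_radius=34.0), rng)
        assert set(event.picked_ids) == {"target", "near"}
        assert st2.ids == ["far"]

    def test_all_picked_within_radius_of_aim(self, rng):
        arena = ArenaGeometry.square(2000.0)
        st = uniform_state(arena, 300, rng)
        before = {i: p for i, p in zip(st.ids, st.pos.copy())}
        event, _ = pick_at(st, (1000.0, 1000.0), CaptureModel(capture_radius=150.0), rng)
        for pid in event.picked_ids:
            assert np.hypot(*(before[pid] - (1000.0, 1000.0))) <= 150.0

    def test_aim_outside_arena_rejected(self, rng):
        arena = ArenaGeometry.square(100.0)
        st = uniform_state(arena, 1, rng)
        with pytest.raises(ValueError, match="outside"):
            pick_at(st, (500.0, 50.0), CaptureModel(), rng)

    def test_failed_pick_removes_volume_but_no_cells(self, rng):
        arena = ArenaGeometry.square(1000.0)
        st = uniform_state(arena, 10, rng)
        v0 = st.medium_volume_nl
        event, st2 = pick_at(st, (500, 500), CaptureModel(pick_success_prob=0.0), rng)
        assert not event.success
        assert st2.n == 10
        assert st2.medium_volume_nl == pytest.approx(v0 - 1.4)

    def test_bystander_count_matches_poisson_and_brute_force(self, rng):
        """Mean cells-per-disc over a uniform field approaches d*pi*R^2 and
        equals brute-force circle counting on identical point sets."""
        arena = ArenaGeometry.square(5000.0)
        radius = 34.0
        n = 5000  # d = 2e-4 um^-2 -> lambda = 0.7264
        lam = n / arena.area_um2 * math.pi * radius**2
        st = uniform_state(arena, n, rng)
        aims = rng.uniform(radius, 5000.0 - radius, size=(1000, 2))
        capture = CaptureModel(capture_radius=radius)
        counts = []
        for aim in aims:
            event, _ = pick_at(st, tuple(aim), capture, rng)
            # brute-force oracle on the same point set
            brute = int(
                (np.hypot(st.pos[:, 0] - aim[0], st.pos[:, 1] - aim[1]) <= radius).sum()
            )
            assert event.n_picked == brute
            counts.append(event.n_picked)
        mean = np.mean(counts)
        tol = 3.0 * math.sqrt(lam / len(aims))
        assert abs(mean - lam) <= tol


class TestDepositAt:
    def test_empty_deposit_still_adds_volume(self, rng):
        arena = ArenaGeometry.square(1000.0)
        st = uniform_state(arena, 5, rng)
        v0 = st.medium_volume_nl
        st2 = deposit_at(st, [], (500, 500), CaptureModel(), rng)
        assert st2.n == 5
        assert st2.medium_volume_nl == pytest.approx(v0 + 147.0)

    def test_cells_land_within_spread_radius(self, rng):
        arena = ArenaGeometry.square(5000.0)
        st = SuspensionState(arena, [], np.empty((0, 2)), np.empty(0, bool))
        cells = [cell(0, 0, cid=f"c{i}") for i in range(26)]
        st2 = deposit_at(st, cells, (2500.0, 2500.0), CaptureModel(), rng)
        assert st2.n == 26
        assert sorted(st2.ids) == sorted(c.id for c in cells)  # ids preserved
        d = np.hypot(st2.pos[:, 0] - 2500.0, st2.pos[:, 1] - 2500.0)
        assert (d <= 127.0 + 1e-9).all()

    def test_pick_then_deposit_conserves_cells_and_volume(self, rng):
        src = uniform_state(ArenaGeometry.square(2000.0), 200, rng)
        dst = SuspensionState(
            ArenaGeometry.square(2000.0), [], np.empty((0, 2)), np.empty(0, bool)
        )
        v_src, v_dst = src.medium_volume_nl, dst.medium_volume_nl
        capture = CaptureModel(capture_radius=60.0)
        n_picks = 20
        for k in range(n_picks):
            aim = tuple(rng.uniform(100, 1900, size=2))
            event, src = pick_at(src, aim, capture, rng)
            dst = deposit_at(dst, event.picked_cells, (1000.0, 1000.0), capture, rng)
        assert src.n + dst.n == 200  # exact integer conservation
        assert src.medium_volume_nl == pytest.approx(v_src - n_picks * 1.4)
        assert dst.medium_volume_nl == pytest.approx(v_dst + n_picks * 147.0)


class TestMicrowells:
    def test_zero_efficiency_traps_nothing(self, rng):
        load = load_microwell_array(MicrowellArray(fill_efficiency=0.0), 1000, rng)
        assert load.trapped == 0
        assert load.untrapped == 1000

    def test_binomial_mean_and_sd(self, rng):
        # 10^3 replicates of 10^4 wells at 0.54: mean 5,400, sd ~ 49.8
        array = MicrowellArray.monocyte()
        counts = [
            load_microwell_array(array, 10**6, rng).trapped for _ in range(1000)
        ]
        sd = math.sqrt(10**4 * 0.54 * 0.46)
        assert np.mean(counts) == pytest.approx(5400, abs=3 * sd / math.sqrt(1000) * 3)
        assert np.std(counts) == pytest.approx(sd, rel=0.15)

    def test_untrapped_fraction_fibroblast_preset(self, rng):
        load = load_microwell_array(MicrowellArray.fibroblast(), 300000, rng)
        assert load.untrapped_fraction == pytest.approx(0.992, abs=0.002)

    def test_occupancy_capped_by_applied_count(self, rng):
        array = MicrowellArray(fill_efficiency=1.0, n_rows=10, n_cols=10)
        load = load_microwell_array(array, 7, rng)
        assert load.trapped == 7
        assert load.untrapped == 0

    def test_pick_from_well_outcomes(self, rng):
        array = MicrowellArray(fill_efficiency=1.0, n_rows=1, n_cols=3)
        load = load_microwell_array(array, 10, rng)
        assert pick_from_well(load, (0, 0), well_pick_success=1.0, rng=rng) == "isolated"
        assert not load.occupancy[0, 0]
        assert pick_from_well(load, (0, 0), rng=rng) == "empty"
        assert pick_from_well(load, (0, 1), well_pick_success=0.0, rng=rng) == "stuck"
        assert load.occupancy[0, 1]

    def test_pick_success_rate_binomial(self, rng):
        array = MicrowellArray(fill_efficiency=1.0, n_rows=100, n_cols=100)
        load = load_microwell_array(array, 10**5, rng)
        outcomes = [
            pick_from_well(load, (r, c), well_pick_success=0.5, rng=rng) == "isolated"
            for r in range(100)
            for c in range(100)
        ]
        assert np.mean(outcomes) == pytest.approx(0.50, abs=0.02)


class TestSimulateTimelapse:
    def test_one_hour_at_30_s_gives_121_frames(self, rng):
        st = uniform_state(ArenaGeometry.square(1000.0), 5, rng)
        tracks = simulate_timelapse(st, MotionModel.thin_layer(), 30.0, 3600.0, rng)
        assert tracks.n_frames == 121
        assert tracks.tracks.shape == (5, 121, 2)

    def test_zero_speed_constant_tracks(self, rng):
        st = uniform_state(ArenaGeometry.square(1000.0), 4, rng)
        tracks = simulate_timelapse(st, MotionModel(0.0, 0.0), 30.0, 300.0, rng)
        for f in range(tracks.n_frames):
            np.testing.assert_array_equal(tracks.tracks[:, f, :], tracks.tracks[:, 0, :])

    def test_drifting_cell_interval_displacement(self, rng):
        arena = ArenaGeometry.square(100000.0)
        st = SuspensionState(arena, [0], [[50000.0, 50000.0]], [True])
        model = MotionModel(6.0, 0.0, persistence_time=1e12)
        tracks = simulate_timelapse(st, model, 30.0, 300.0, rng)
        d = np.linalg.norm(np.diff(tracks.tracks[0], axis=0), axis=1)
        np.testing.assert_allclose(d, 3.0, rtol=1e-9)  # 6 um/min * 0.5 min

    def test_interval_longer_than_duration_rejected(self, rng):
        st = uniform_state(ArenaGeometry.square(100.0), 1, rng)
        with pytest.raises(ValueError):
            simulate_timelapse(st, MotionModel(1.0, 0.0), 60.0, 30.0, rng)

    def test_csv_round_trip(self, tmp_path, rng):
        from cellpick import TrackSet

        st = uniform_state(ArenaGeometry.square(500.0), 3, rng)
        tracks = simulate_timelapse(st, MotionModel.thin_layer(), 30.0, 120.0, rng)
        path = tmp_path / "tracks.csv"
        tracks.to_csv(path)
        back = TrackSet.from_csv(path)
        np.testing.assert_allclose(back.tracks, tracks.tracks)
        np.testing.assert_allclose(back.times, tracks.times)
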