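import datetime as dt

import numpy as np
import pytest

from magnav.geofield import FieldGrid, FieldStack, GridGeometry
from magnav.movekernel import estimate_kernel
from magnav.simulate import (
    SimulatedTrack,
    SimulationConfig,
    combine_surfaces,
    crb_pull_surface,
    initial_heading,
    movement_surface,
    run_batch,
    simulate_crb,
    simulate_crw,
)
from magnav.strategies import (
    NO_BIAS,
    TAXIS,
    ProbabilitySurface,
    StrategySpec,
    TargetInfo,
    no_bias_surface,
    taxis_surface,
)
from magnav.tracks import KM, StepSeries

from conftest import make_stack


def straight_kernel(L=5000.0):
    s = StepSeries(np.full(12, L), np.zeros(12), np.zeros(11))
    return estimate_kernel([s], n_len_bins=5, n_ang_bins=24)


def uniform_stack(n=40, cell=1000.0):
    geo = GridGeometry(0.0, 0.0, cell, n, n, "t")
    F = np.full((n, n), 50000.0)
    I = np.full((n, n), 45.0)
    return FieldStack({
        "F": FieldGrid("F", dt.date(2016, 9, 19), geo, F),
        "I": FieldGrid("I", dt.date(2016, 9, 19), geo, I),
        "H": FieldGrid("H", dt.date(2016, 9, 19), geo,
                       F * np.cos(np.deg2rad(45.0))),
    })


class TestMovementSurface:
    def test_degenerate_kernel_concentrates_ahead(self):
        k = straight_kernel()
        stack = uniform_stack()
        surf = movement_surface(k, (20000.0, -20000.0), 0.0, 5000.0, 0.0,
                                stack.geometry)
        r, c = np.unravel_index(np.argmax(surf.values), surf.values.shape)
        x, y = stack.geometry.cell_center(r, c)
        # the only supported cell sits ~5000 m ahead along +x
        assert y == pytest.approx(-20000.0)
        assert 4000.0 <= x - 20000.0 <= 5000.0

    def test_zero_beyond_largest_observed_step(self):
        k = straight_kernel()
        stack = uniform_stack()
        surf = movement_surface(k, (20000.0, -20000.0), 0.0, 5000.0, 0.0,
                                stack.geometry)
        X, Y = np.meshgrid(stack.geometry.x_coords(), stack.geometry.y_coords())
        d = np.hypot(X - 20000.0, Y + 20000.0)
        assert np.all(surf.values[d > k.L_max] == 0.0)

    def test_window_matches_direct_density_evaluation(self, smoke):
        """Cell weights equal step_density / distance, rescaled."""
        k = smoke.kernel
        geo = smoke.fields[0].geometry
        xy = (300 * KM, -300 * KM)
        surf = movement_surface(k, xy, -np.pi / 4, k.mean_L, 0.0, geo)
        X, Y = np.meshgrid(geo.x_coords(), geo.y_coords())
        d = np.hypot(X - xy[0], Y - xy[1])
        from magnav.tracks import wrap_angle

        phi = wrap_angle(np.arctan2(Y - xy[1], X - xy[0]) + np.pi / 4)
        dens = k.step_density(d.ravel(), phi.ravel(), k.mean_L, 0.0)
        dens = dens.reshape(d.shape) / np.maximum(d, geo.cell_size / 2)
        dens[d > k.L_max] = 0.0
        np.testing.assert_allclose(surf.values, dens / dens.max(), atol=1e-12)


class TestCombineSurfaces:
    def test_square_root_weighting_arithmetic(self, small_geometry):
        m = ProbabilitySurface(small_geometry,
                               np.full((5, 5), 0.25))
        b = ProbabilitySurface(small_geometry, np.full((5, 5), 0.5))
        c = combine_surfaces(m, b, alpha=0.5, beta=1.0)
        # pre-normalisation value sqrt(0.25)*0.5 = 0.25 everywhere ->
        # uniform sampling distribution
        np.testing.assert_allclose(c.values, 1.0 / 25.0)

    def test_beta_zero_reduces_to_movement(self, small_geometry):
        rng = np.random.default_rng(0)
        mv = rng.uniform(0.1, 1.0, (5, 5))
        bv = rng.uniform(0.0, 1.0, (5, 5))
        m = ProbabilitySurface(small_geometry, mv)
        b = ProbabilitySurface(small_geometry, bv)
        c = combine_surfaces(m, b, alpha=1.0, beta=0.0)
        np.testing.assert_allclose(c.values, mv / mv.sum())

    def test_all_zero_bias_falls_back_to_movement(self, small_geometry):
        mv = np.full((5, 5), 0.5)
        bv = np.zeros((5, 5))
        bv[0, 0] = 1e-300  # surface needs one positive cell
        m = ProbabilitySurface(small_geometry, mv)
        b = ProbabilitySurface(small_geometry, bv)
        c = combine_surfaces(m, b, alpha=1.0, beta=1.0)
        np.testing.assert_allclose(c.values.sum(), 1.0)
        # fallback: proportional to movement alone (uniform here)
        assert np.allclose(c.values, 1 / 25.0) or c.values[0, 0] == 1.0


class TestInitialHeading:
    def test_zero_error_gives_exact_optimum(self):
        stack = uniform_stack()
        surf = taxis_values_surface(stack)
        rng = np.random.default_rng(0)
        h = initial_heading(surf, (20000.0, -20000.0), 6000.0, 0.0, rng,
                            target_xy=(30000.0, -20000.0))
        # gradient surface built below points towards +x
        assert h == pytest.approx(0.0, abs=1e-9)

    def test_draws_bounded_by_pi_over_twelve(self):
        stack = uniform_stack()
        surf = taxis_values_surface(stack)
        for seed in range(40):
            rng = np.random.default_rng(seed)
            h = initial_heading(surf, (20000.0, -20000.0), 6000.0,
                                np.pi / 12, rng,
                                target_xy=(30000.0, -20000.0))
            assert abs(h) <= np.pi / 12 + 1e-12

    def test_uniform_bias_falls_back_to_target_bearing(self):
        geo = uniform_stack().geometry
        surf = no_bias_surface(geo)
        rng = np.random.default_rng(1)
        h = initial_heading(surf, (20000.0, -20000.0), 6000.0, 0.0, rng,
                            target_xy=(20000.0, -30000.0))
        assert h == pytest.approx(-np.pi / 2)


def taxis_values_surface(stack):
    """Left-to-right decreasing cue -> taxis optimum towards +x."""
    geo = stack.geometry
    vals = np.tile(np.linspace(60000.0, 30000.0, geo.n_cols), (geo.n_rows, 1))
    grid = FieldGrid("F", dt.date(2016, 9, 19), geo, vals)
    return taxis_surface(grid)


class TestSimulateCrw:
    def test_degenerate_straight_walk(self):
        """No bias, deterministic kernel, zero heading error, cell-centre
        mode: the walk marches in equal 5 km steps along one heading."""
        k = straight_kernel()
        stack = uniform_stack()
        cfg = SimulationConfig(
            mode="CRW", n_steps=4, start_xy=(5000.0, -20000.0),
            target_xy=(35000.0, -20000.0), heading_error=0.0,
            cell_mode="center", alpha=1.0, beta=0.0,
        )
        spec = StrategySpec(NO_BIAS)
        rng = np.random.default_rng(0)
        t = simulate_crw(k, spec, [stack], cfg,
                         TargetInfo(target_xy=cfg.target_xy), rng)
        np.testing.assert_allclose(t.step_lengths, 5000.0)
        np.testing.assert_allclose(t.turning_angles, 0.0, atol=1e-9)
        np.testing.assert_allclose(t.positions[-1], [25000.0, -20000.0])

    def test_fixed_seed_bit_identical(self, smoke):
        b = smoke
        traj = b.trajectories[0]
        cfg = SimulationConfig(n_steps=len(traj) - 1, start_xy=traj.start_xy,
                               target_xy=b.targets[traj.animal_id].target_xy)
        spec = StrategySpec(TAXIS, ("F",))
        runs = [
            simulate_crw(b.kernel, spec, b.fields, cfg,
                         b.targets[traj.animal_id],
                         np.random.default_rng(99))
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].positions, runs[1].positions)

    def test_taxis_descends_towards_field_minimum(self, recovery):
        """With the bias up-weighted, intensity-taxis walkers reduce the
        intensity at their position in nearly every replicate."""
        from magnav.geofield import value_at

        b = recovery
        day0 = [b.fields[0]]
        spec = StrategySpec(TAXIS, ("F",))
        start = (140 * KM, -140 * KM)
        cfg = SimulationConfig(n_steps=24, start_xy=start,
                               target_xy=(600 * KM, -600 * KM), beta=5.0)
        tinfo = TargetInfo(target_xy=cfg.target_xy)
        grid = day0[0]["F"]
        down = 0
        n = 100
        for rep in range(n):
            rng = np.random.default_rng(1000 + rep)
            t = simulate_crw(b.kernel, spec, day0, cfg, tinfo, rng)
            f0 = value_at(grid, *t.positions[0])
            f1 = value_at(grid, *t.positions[-1])
            down += f1 < f0
        assert down >= 95

    def test_step_cap_and_grid_bounds(self, smoke):
        b = smoke
        cap = b.kernel.L_max + b.kernel.len_bin_width
        geo = b.fields[0].geometry
        traj = b.trajectories[1]
        cfg = SimulationConfig(n_steps=len(traj) - 1, start_xy=traj.start_xy,
                               target_xy=b.targets[traj.animal_id].target_xy)
        for spec in (StrategySpec(NO_BIAS), StrategySpec(TAXIS, ("H",))):
            t = simulate_crw(b.kernel, spec, b.fields, cfg,
                             b.targets[traj.animal_id],
                             np.random.default_rng(3))
            assert t.step_lengths.max() <= cap + 1e-9
            half = geo.cell_size / 2
            assert t.positions[:, 0].min() >= geo.x_min - half
            assert t.positions[:, 0].max() <= geo.x_max + half
            assert t.positions[:, 1].min() >= geo.y_min - half
            assert t.positions[:, 1].max() <= geo.y_max + half


class TestCrbPull:
    def test_final_step_is_point_mass_at_target_cell(self, smoke):
        geo = smoke.fields[0].geometry
        target = (300 * KM, -300 * KM)
        surf = crb_pull_surface(smoke.kernel, (310 * KM, -300 * KM), target,
                                1, geo)
        assert surf.values.sum() == 1.0
        r, c = np.unravel_index(np.argmax(surf.values), surf.values.shape)
        assert geo.cell_center(r, c) == target

    def test_infeasible_cells_get_zero(self, smoke):
        k = smoke.kernel
        geo = smoke.fields[0].geometry
        # target one step away; with 2 steps remaining only cells within
        # L_max of the target stay feasible, the far window edge does not
        target = (320 * KM, -310 * KM)
        steps_remaining = 2
        surf = crb_pull_surface(k, (300 * KM, -300 * KM), target,
                                steps_remaining, geo)
        X, Y = np.meshgrid(geo.x_coords(), geo.y_coords())
        d = np.hypot(X - target[0], Y - target[1])
        assert np.all(surf.values[d > (steps_remaining - 1) * k.L_max] == 0.0)

    def test_equidistant_cells_weighted_equally(self, smoke):
        k = smoke.kernel
        geo = smoke.fields[0].geometry
        target = (300 * KM, -300 * KM)
        surf = crb_pull_surface(k, (300 * KM, -310 * KM), target, 4, geo)
        # two cells symmetric about the target have equal distance
        a = surf.values[geo.cell_of(290 * KM, -310 * KM)]
        b = surf.values[geo.cell_of(310 * KM, -310 * KM)]
        assert a == pytest.approx(b)


class TestSimulateCrb:
    def test_endpoint_equals_target_exactly(self, smoke):
        b = smoke
        for traj in b.trajectories:
            tinfo = b.targets[traj.animal_id]
            cfg = SimulationConfig(mode="CRB", n_steps=len(traj) - 1,
                                   start_xy=traj.start_xy,
                                   target_xy=tinfo.target_xy)
            for rep in range(5):
                t = simulate_crb(b.kernel, StrategySpec(NO_BIAS), b.fields,
                                 cfg, tinfo, np.random.default_rng(rep))
                assert tuple(t.positions[-1]) == tinfo.target_xy

    def test_paths_stay_inside_feasibility_lens(self):
        """Toy 3-step bridge: every intermediate point must be within
        k*L_max of both endpoints (k = steps available on that side)."""
        k = straight_kernel()
        stack = uniform_stack(n=40, cell=1000.0)
        start, target = (10000.0, -20000.0), (22000.0, -20000.0)
        cfg = SimulationConfig(mode="CRB", n_steps=3, start_xy=start,
                               target_xy=target)
        for rep in range(10):
            t = simulate_crb(k, StrategySpec(NO_BIAS), [stack], cfg,
                             TargetInfo(target_xy=target),
                             np.random.default_rng(rep))
            for i, p in enumerate(t.positions):
                assert np.hypot(*(p - np.array(start))) <= i * (k.L_max + k.len_bin_width) + 1e-9
                assert np.hypot(*(p - np.array(target))) <= (3 - i) * k.L_max + 1e-9

    def test_bias_weight_changes_spread_not_endpoint(self, recovery):
        b = recovery
        traj = b.trajectories[0]
        tinfo = b.targets[traj.animal_id]
        mids = {}
        for beta in (0.0, 5.0):
            cfg = SimulationConfig(mode="CRB", n_steps=len(traj) - 1,
                                   start_xy=traj.start_xy,
                                   target_xy=tinfo.target_xy, beta=beta)
            pts = []
            for rep in range(12):
                t = simulate_crb(b.kernel, StrategySpec(TAXIS, ("F",)),
                                 b.fields, cfg, tinfo,
                                 np.random.default_rng(rep))
                assert tuple(t.positions[-1]) == tinfo.target_xy
                pts.append(t.positions[len(t.positions) // 2])
            mids[beta] = np.array(pts)
        spread = {b_: np.mean(np.std(m, axis=0)) for b_, m in mids.items()}
        assert spread[0.0] != pytest.approx(spread[5.0], rel=1e-3)


class TestRunBatch:
    def test_replicate_bookkeeping(self, smoke):
        b = smoke
        specs = [StrategySpec(NO_BIAS), StrategySpec(TAXIS, ("F",))]
        cfg = SimulationConfig(n_replicates=4, seed=5)
        tracks = run_batch(b.kernel, specs, b.animals, b.fields, cfg)
        assert len(tracks) == 2 * len(b.animals) * 4
        # per-animal step counts match the empirical trajectories
        steps = {t.animal_id: t.n_steps for t in tracks}
        for traj in b.trajectories:
            assert steps[traj.animal_id] == len(traj) - 1

    def test_same_seed_identical_batch(self, smoke):
        b = smoke
        specs = [StrategySpec(TAXIS, ("I",))]
        cfg = SimulationConfig(n_replicates=3, seed=17)
        t1 = run_batch(b.kernel, specs, b.animals, b.fields, cfg)
        t2 = run_batch(b.kernel, specs, b.animals, b.fields, cfg)
        for a, b_ in zip(t1, t2):
            np.testing.assert_array_equal(a.positions, b_.positions)
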