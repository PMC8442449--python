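import numpy as np
import pytest

from magnav.geofield import extremum_location
from magnav.strategies import (
    BIGRADIENT,
    COMBINATION,
    CONSTANT_HEADING,
    NO_BIAS,
    TAXIS,
    BiasModel,
    DegenerateGeometryError,
    StrategySpec,
    TargetInfo,
    bigradient_surface,
    combination_surface,
    constant_heading_surface,
    constant_heading_theta,
    enumerate_model_configs,
    no_bias_surface,
    taxis_surface,
    vertex_angle_deg,
)
from magnav.synthdata import SynthFieldParams, synth_field_stack
from magnav.geofield import GridGeometry
from magnav.tracks import KM

from conftest import make_grid, make_stack

import datetime as dt


class TestStrategySpec:
    def test_cue_arity_enforced(self):
        with pytest.raises(ValueError):
            StrategySpec(TAXIS, ())
        with pytest.raises(ValueError):
            StrategySpec(BIGRADIENT, ("F",))
        with pytest.raises(ValueError):
            StrategySpec(NO_BIAS, ("F",))

    def test_constant_heading_requires_extreme(self):
        with pytest.raises(ValueError):
            StrategySpec(CONSTANT_HEADING, ("F",))
        spec = StrategySpec(CONSTANT_HEADING, ("F",), extreme="max")
        assert spec.label == "constant_heading-maxF"

    def test_duplicate_cues_rejected(self):
        with pytest.raises(ValueError):
            StrategySpec(BIGRADIENT, ("F", "F"))


class TestEnumerateModelConfigs:
    def test_nineteen_unique_configurations(self):
        specs = enumerate_model_configs()
        assert len(specs) == 19
        assert len({s.label for s in specs}) == 19

    def test_partition_matches_design(self):
        specs = enumerate_model_configs()
        by = {}
        for s in specs:
            by.setdefault(s.strategy, []).append(s)
        assert len(by[NO_BIAS]) == 1
        assert len(by[TAXIS]) == 3
        assert len(by[CONSTANT_HEADING]) == 6
        assert len(by[BIGRADIENT]) == 3
        assert len(by[COMBINATION]) == 6


class TestTaxisSurface:
    def test_extremes_and_midpoint(self):
        vals = np.array([[40000.0, 50000.0], [60000.0, 45000.0]])
        p = taxis_surface(make_grid(vals)).values
        assert p[0, 0] == 1.0       # grid minimum -> highest probability
        assert p[1, 0] == 0.0       # grid maximum -> lowest probability
        assert p[0, 1] == pytest.approx(0.5)

    def test_antitone_in_cue_value(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(3e4, 6e4, (6, 6))
        p = taxis_surface(make_grid(vals)).values
        order = np.argsort(vals.ravel())
        assert np.all(np.diff(p.ravel()[order]) <= 1e-12)

    def test_spring_inversion(self):
        vals = np.array([[40000.0, 50000.0], [60000.0, 45000.0]])
        p = taxis_surface(make_grid(vals), invert=True).values
        assert p[0, 0] == 0.0 and p[1, 0] == 1.0

    def test_constant_grid_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            taxis_surface(make_grid(np.full((3, 3), 5e4)))


class TestConstantHeading:
    def grid(self):
        # minimum in the far south-east corner, maximum at the origin
        vals = np.fromfunction(
            lambda r, c: 60000.0 - 1000.0 * (r + c), (8, 8)
        )
        return make_grid(vals)

    def test_theta_star_zero_when_target_towards_extreme(self):
        grid = self.grid()
        ex, ey, _ = extremum_location(grid, "min")
        theta = constant_heading_theta(grid, (10 * KM, -10 * KM), (ex, ey), "min")
        assert theta == pytest.approx(0.0, abs=1e-9)

    def test_probability_extremes_and_linear_scaling(self):
        grid = self.grid()
        current = (10 * KM, -30 * KM)
        target = (60 * KM, -30 * KM)
        surf = constant_heading_surface(grid, current, target, "min")
        theta = constant_heading_theta(grid, current, target, "min")
        X, Y = np.meshgrid(grid.geometry.x_coords(), grid.geometry.y_coords())
        ex, ey, _ = extremum_location(grid, "min")
        ang = vertex_angle_deg(current, (ex, ey), X, Y)
        np.testing.assert_allclose(surf.values, 1.0 - np.abs(ang - theta) / 180.0)
        # cells at the calibrated angle reach probability ~1
        assert surf.values.max() >= 1.0 - 1e-6 or np.abs(ang - theta).min() > 0

    def test_opposite_angle_scales_to_zero(self):
        # 180 degrees away from theta* maps to probability 0
        assert 1.0 - abs(180.0 - 0.0) / 180.0 == 0.0
        grid = self.grid()
        current = (35 * KM, -35 * KM)
        surf = constant_heading_surface(grid, current, (70 * KM, -70 * KM), "min")
        # the cell most opposite the extreme direction approaches 0
        assert surf.values.min() < 0.06

    def test_forty_five_degrees_is_three_quarters(self):
        grid = self.grid()
        current = (0.0, 0.0)
        theta = 0.0
        ang = 45.0
        assert 1.0 - abs(ang - theta) / 180.0 == pytest.approx(0.75)
        surf = constant_heading_surface(grid, current, (70 * KM, -70 * KM), "min",
                                        theta_star=0.0)
        X, Y = np.meshgrid(grid.geometry.x_coords(), grid.geometry.y_coords())
        ex, ey, _ = extremum_location(grid, "min")
        angs = vertex_angle_deg(current, (ex, ey), X, Y)
        i = np.unravel_index(np.argmin(np.abs(angs - 45.0)), angs.shape)
        assert surf.values[i] == pytest.approx(1.0 - angs[i] / 180.0)

    def test_maximum_lies_along_calibrated_ray(self):
        """Brute-force check: the best cell's vertex angle is the
        closest achievable to theta*."""
        grid = self.grid()
        current = (20 * KM, -20 * KM)
        target = (65 * KM, -50 * KM)
        surf = constant_heading_surface(grid, current, target, "min")
        theta = constant_heading_theta(grid, current, target, "min")
        X, Y = np.meshgrid(grid.geometry.x_coords(), grid.geometry.y_coords())
        ex, ey, _ = extremum_location(grid, "min")
        ang = vertex_angle_deg(current, (ex, ey), X, Y)
        best = np.unravel_index(np.argmax(surf.values), surf.values.shape)
        assert np.abs(ang[best] - theta) == pytest.approx(
            np.abs(ang - theta).min()
        )

    def test_degenerate_geometry_rejected(self):
        grid = self.grid()
        with pytest.raises(DegenerateGeometryError):
            constant_heading_theta(grid, (10.0, -10.0), (10.0, -10.0), "min")
        ex, ey, _ = extremum_location(grid, "min")
        with pytest.raises(DegenerateGeometryError):
            constant_heading_surface(grid, (ex, ey), (0.0, 0.0), "min")


class TestBigradient:
    def test_target_cells_reach_one(self):
        F = np.array([[40000.0, 45000.0], [50000.0, 60000.0]])
        I = np.array([[30.0, 40.0], [50.0, 70.0]])
        stack = make_stack(F, I)
        surf = bigradient_surface(stack["F"], stack["I"],
                                  {"F": 45000.0, "I": 40.0})
        assert surf.values[0, 1] == pytest.approx(1.0)

    def test_single_cue_linear_scaling(self):
        # range [40000, 60000], target 45000, cell at 60000 -> 0.25
        from magnav.strategies import gradient_to_target_values

        p = gradient_to_target_values(60000.0, 45000.0, 40000.0, 60000.0)
        assert p == pytest.approx(0.25)

    def test_product_of_half_probabilities(self):
        from magnav.strategies import gradient_to_target_values

        assert 0.5 * 0.5 == pytest.approx(0.25)

    def test_maximal_at_minimum_deviation_cells(self):
        rng = np.random.default_rng(1)
        F = rng.uniform(3e4, 6e4, (6, 6))
        I = rng.uniform(10, 80, (6, 6))
        stack = make_stack(F, I)
        tv = {"F": 47000.0, "I": 42.0}
        surf = bigradient_surface(stack["F"], stack["I"], tv)
        # exhaustive oracle
        pF = np.clip(1 - np.abs(F - tv["F"]) / (F.max() - F.min()), 0, 1)
        pI = np.clip(1 - np.abs(I - tv["I"]) / (I.max() - I.min()), 0, 1)
        np.testing.assert_allclose(surf.values, pF * pI)
        assert np.argmax(surf.values) == np.argmax(pF * pI)

    def test_missing_target_value_rejected(self):
        stack = make_stack(np.array([[4e4, 6e4], [5e4, 4.5e4]]),
                           np.array([[10.0, 30.0], [50.0, 70.0]]))
        with pytest.raises(ValueError, match="missing"):
            bigradient_surface(stack["F"], stack["I"], {"F": 5e4})


class TestCombination:
    def test_identity_and_annihilation(self):
        F = np.fromfunction(lambda r, c: 60000.0 - 2000.0 * (r + c), (6, 6))
        I = np.fromfunction(lambda r, c: 80.0 - 5.0 * (r + c), (6, 6))
        stack = make_stack(F, I)
        current = (5 * KM, -5 * KM)
        target = (50 * KM, -50 * KM)
        tv = {"F": 44000.0, "I": 40.0}
        surf = combination_surface(stack["F"], stack["I"], current, target, tv)
        from magnav.strategies import gradient_to_target_values

        p_map = gradient_to_target_values(F, tv["F"], F.min(), F.max())
        p_head = constant_heading_surface(stack["I"], current, target, "min").values
        np.testing.assert_allclose(surf.values, p_map * p_head)
        # annihilation: where either factor is ~0 the product is ~0
        assert surf.values[p_map < 1e-12].max(initial=0.0) == 0.0

    def test_component_product_arithmetic(self):
        assert 0.8 * 0.5 == pytest.approx(0.4)


class TestNoBias:
    def test_uniform_ones(self, small_geometry):
        surf = no_bias_surface(small_geometry)
        assert surf.values.min() == surf.values.max() == 1.0


class TestSurfaceInvariants:
    def test_all_surfaces_within_unit_interval_on_random_stacks(self):
        """Probability bounds on randomly generated field stacks."""
        rng = np.random.default_rng(9)
        date = dt.date(2016, 9, 19)
        for trial in range(20):
            geo = GridGeometry(0.0, 0.0, 10 * KM, 12, 12, "t")
            p = SynthFieldParams(
                geometry=geo,
                pole_xy=(rng.uniform(0, 9 * KM), rng.uniform(-9 * KM, 0)),
                daily_drift=rng.uniform(0, 50),
                storm_amplitude=rng.uniform(0, 100),
                profile_k=float(rng.choice([0.0, 5.0])),
                seed=int(rng.integers(1 << 30)),
            )
            (stack,) = synth_field_stack(p, [date])
            target = TargetInfo(
                target_xy=geo.cell_center(9, 9),
                target_values={c: float(stack[c].values[9, 9]) for c in "FIH"},
            )
            # current position chosen off every cell centre so it can
            # never coincide with a grid extreme
            current = (35 * KM + 1.0, -21 * KM + 1.0)
            for spec in enumerate_model_configs():
                model = BiasModel(spec, stack, target)
                surf = model.surface(current)
                assert np.all(surf.values >= 0.0)
                assert np.all(surf.values <= 1.0)
                assert np.any(surf.values > 0)
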