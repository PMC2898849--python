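"""Flow-solver unit and property tests: conductances, analytic solutions,
mass balance, linearity and symmetry."""

import numpy as np
import pytest

from plumeepi import gwflow
from plumeepi.gwflow import (
    AquiferProperties,
    BoundaryConditions,
    GridSpec,
    SingularSystemError,
    StressPeriod,
    WellSpec,
    assemble_system,
    build_stress_periods,
    cell_velocities,
    global_mass_balance,
    solve_steady_state,
)


def make_grid(nr=1, nc=10, nl=1, d=10.0, thick=10.0):
    return GridSpec(
        n_rows=nr, n_cols=nc, n_layers=nl,
        dx=np.full(nc, d), dy=np.full(nr, d),
        layer_top=np.array([-i * thick for i in range(nl)], dtype=float),
        layer_bottom=np.array([-(i + 1) * thick for i in range(nl)], dtype=float),
    )


def uniform_props(grid, k=10.0, n=0.25):
    return AquiferProperties(np.full(grid.shape, k), np.full(grid.shape, n))


class TestStressPeriods:
    def test_breakpoints_at_well_start_years(self):
        wells = [
            WellSpec(f"w{y}", (0, 0, c), 100.0, y, 1993)
            for c, y in enumerate([1953, 1961, 1970, 1984])
        ]
        periods = build_stress_periods(wells, (1937, 1993))
        spans = [(p.start_year, p.end_year) for p in periods]
        assert spans == [(1937, 1953), (1953, 1961), (1961, 1970), (1970, 1984), (1984, 1993)]
        # wells are active only in periods they span entirely
        assert [len(p.active_wells) for p in periods] == [0, 1, 2, 3, 4]

    def test_no_wells_single_period(self):
        assert [(p.start_year, p.end_year) for p in build_stress_periods([], (1937, 1993))] == [
            (1937, 1993)
        ]

    def test_breakpoint_at_horizon_start_degenerate(self):
        wells = [WellSpec("w", (0, 0, 0), 100.0, 1937, 1993)]
        periods = build_stress_periods(wells, (1937, 1993))
        assert len(periods) == 1 and periods[0].active_wells[0][0] == "w"

    def test_well_outside_horizon_excluded_with_warning(self, caplog):
        wells = [WellSpec("old", (0, 0, 0), 100.0, 1900, 1920)]
        with caplog.at_level("WARNING"):
            periods = build_stress_periods(wells, (1937, 1993))
        assert periods[0].active_wells == ()
        assert any("outside horizon" in m for m in caplog.messages)

    def test_empty_horizon_rejected(self):
        with pytest.raises(ValueError):
            build_stress_periods([], (1993, 1993))

    def test_replacement_year_becomes_breakpoint(self):
        wells = [
            WellSpec("a", (0, 0, 1), 100.0, 1961, 1983),
            WellSpec("a2", (0, 0, 1), 100.0, 1984, 1993),
        ]
        spans = [(p.start_year, p.end_year) for p in build_stress_periods(wells, (1937, 1993))]
        assert spans == [(1937, 1961), (1961, 1984), (1984, 1993)]


class TestConductance:
    @pytest.mark.parametrize(
        "k1,k2,expected_interblock",
        [(10.0, 10.0, 10.0), (10.0, 0.0, 0.0), (10.0, 40.0, 16.0)],
    )
    def test_harmonic_mean_interblock(self, k1, k2, expected_interblock):
        # two cells, face area 100 ft^2, spacing 10 ft: C = K_interblock * A / L
        grid = make_grid(nr=1, nc=2, d=10.0, thick=10.0)
        props = uniform_props(grid)
        props.hydraulic_conductivity[0, 0, 0] = k1
        props.hydraulic_conductivity[0, 0, 1] = k2
        bc = BoundaryConditions({(0, 0, 0): 1.0})
        system = assemble_system(grid, props, bc, StressPeriod(1937, 1993))
        cx = system.conductances[0]
        assert cx[0, 0, 0] == pytest.approx(expected_interblock * 100.0 / 10.0)

    def test_no_constant_head_is_singular(self):
        grid = make_grid()
        bc = BoundaryConditions({})
        with pytest.raises(SingularSystemError, match="constant-head"):
            bc.validate(grid)

    def test_well_in_constant_head_cell_rejected(self):
        grid = make_grid()
        bc = BoundaryConditions({(0, 0, 0): 1.0})
        well = WellSpec("w", (0, 0, 0), 500.0, 1937, 1993)
        period = StressPeriod(1937, 1993, (("w", 500.0),))
        with pytest.raises(ValueError, match="constant-head"):
            assemble_system(grid, uniform_props(grid), bc, period, [well])


class TestSteadyState:
    def test_linear_head_profile_1d(self):
        grid = make_grid(nc=10)
        bc = BoundaryConditions({(0, 0, 0): 10.0, (0, 0, 9): 0.0})
        system = assemble_system(grid, uniform_props(grid), bc, StressPeriod(1937, 1993))
        heads = solve_steady_state(system)
        expected = np.linspace(10.0, 0.0, 10)
        np.testing.assert_allclose(heads.head[0, 0], expected, atol=1e-8)

    def test_uniform_boundary_head_gives_constant_field(self):
        grid = make_grid(nr=5, nc=5)
        ch = {(0, r, c): 7.5 for r in range(5) for c in range(5) if r in (0, 4) or c in (0, 4)}
        system = assemble_system(grid, uniform_props(grid), BoundaryConditions(ch),
                                 StressPeriod(1937, 1993))
        heads = solve_steady_state(system)
        np.testing.assert_allclose(heads.head, 7.5, atol=1e-10)

    @staticmethod
    def _thiem_error(n):
        """Max relative error of FD drawdown differences vs the Thiem line.

        Fixed 650x650 ft domain refined by the cell count n; head
        differences between two radii on the +x axis cancel the effective
        well-radius offset, so the comparison isolates discretisation
        error.
        """
        d = 650.0 / n
        grid = make_grid(nr=n, nc=n, d=d, thick=10.0)
        k, b, q = 50.0, 10.0, 5000.0
        props = uniform_props(grid, k=k)
        ch = {
            (0, r, c): 0.0
            for r in range(n) for c in range(n)
            if r in (0, n - 1) or c in (0, n - 1)
        }
        mid = n // 2
        well = WellSpec("w", (0, mid, mid), q, 1937, 1993)
        period = StressPeriod(1937, 1993, (("w", q),))
        system = assemble_system(grid, props, BoundaryConditions(ch), period, [well])
        heads = solve_steady_state(system)
        errs = []
        for r1, r2 in [(50.0, 150.0), (50.0, 200.0), (100.0, 200.0)]:
            c1, c2 = round(r1 / d), round(r2 / d)
            dh = heads.head[0, mid, mid + c2] - heads.head[0, mid, mid + c1]
            thiem = q / (2 * np.pi * k * b) * np.log((c2 * d) / (c1 * d))
            errs.append(abs(dh - thiem) / thiem)
        return max(errs)

    def test_thiem_drawdown_on_fine_grid(self):
        assert self._thiem_error(65) < 0.02

    def test_thiem_error_decreases_under_refinement(self):
        errors = [self._thiem_error(n) for n in (17, 33, 65)]
        assert errors[0] > errors[1] > errors[2]

    def test_global_mass_balance_closes(self, aquifer_model, scenario_runs):
        from plumeepi import synthcape

        cfg = synthcape.AquiferScenarioConfig()
        per = scenario_runs["high"]["periods"][3]
        system = assemble_system(
            aquifer_model.grid, aquifer_model.props, aquifer_model.bc, per, aquifer_model.wells
        )
        heads = solve_steady_state(system)
        inflow, outflow = global_mass_balance(system, heads)
        assert abs(inflow - outflow) <= 1e-6 * inflow

    def test_drawdown_linear_in_stress(self):
        grid = make_grid(nr=11, nc=11)
        props = uniform_props(grid)
        ch = {(0, r, c): 0.0 for r in range(11) for c in range(11)
              if r in (0, 10) or c in (0, 10)}
        bc = BoundaryConditions(ch)

        def drawdown(q):
            well = WellSpec("w", (0, 5, 5), q, 1937, 1993)
            per = StressPeriod(1937, 1993, (("w", q),))
            system = assemble_system(grid, props, bc, per, [well])
            return solve_steady_state(system).head

        h1, h2 = drawdown(1000.0), drawdown(2000.0)
        np.testing.assert_allclose(h2, 2.0 * h1, atol=1e-6)

    def test_symmetric_stress_gives_symmetric_heads(self):
        grid = make_grid(nr=11, nc=11)
        props = uniform_props(grid)
        ch = {(0, r, c): 0.0 for r in range(11) for c in range(11)
              if r in (0, 10) or c in (0, 10)}
        well = WellSpec("w", (0, 5, 5), 1000.0, 1937, 1993)
        per = StressPeriod(1937, 1993, (("w", 1000.0),))
        system = assemble_system(grid, props, BoundaryConditions(ch), per, [well])
        h = solve_steady_state(system).head[0]
        np.testing.assert_allclose(h, h[::-1, :], atol=1e-8)  # north-south mirror
        np.testing.assert_allclose(h, h[:, ::-1], atol=1e-8)  # east-west mirror
        np.testing.assert_allclose(h, h.T, atol=1e-8)  # diagonal


class TestVelocities:
    def test_uniform_gradient_seepage_velocity(self):
        # gradient 0.01, K=100, porosity 0.25 -> v = K i / n = 4 ft/day
        grid = make_grid(nc=11, d=10.0)
        props = uniform_props(grid, k=100.0, n=0.25)
        bc = BoundaryConditions({(0, 0, 0): 1.0, (0, 0, 10): 0.0})
        system = assemble_system(grid, props, bc, StressPeriod(1937, 1993))
        heads = solve_steady_state(system)
        vel = cell_velocities(heads, grid, props, system)
        np.testing.assert_allclose(vel.vx[0, 0, 1:-1], 4.0, rtol=1e-8)

    def test_uniform_head_zero_velocity(self):
        grid = make_grid(nr=3, nc=3)
        ch = {(0, r, c): 5.0 for r in range(3) for c in range(3) if r in (0, 2) or c in (0, 2)}
        props = uniform_props(grid)
        system = assemble_system(grid, props, BoundaryConditions(ch), StressPeriod(1937, 1993))
        heads = solve_steady_state(system)
        vel = cell_velocities(heads, grid, props, system)
        assert np.abs(vel.vx).max() < 1e-10 and np.abs(vel.vy).max() < 1e-10

    def test_interior_face_single_valued(self):
        grid = make_grid(nc=11)
        props = uniform_props(grid)
        bc = BoundaryConditions({(0, 0, 0): 1.0, (0, 0, 10): 0.0})
        system = assemble_system(grid, props, bc, StressPeriod(1937, 1993))
        vel = cell_velocities(solve_steady_state(system), grid, props, system)
        # the +x face of cell (0,0,3) and the -x face of (0,0,4) are vx[0,0,4]
        (_, hi), _, _ = vel.face_velocities(0, 0, 3)
        (lo, _), _, _ = vel.face_velocities(0, 0, 4)
        assert hi == lo

    def test_zero_porosity_rejected(self):
        grid = make_grid(nc=3)
        props = uniform_props(grid)
        bc = BoundaryConditions({(0, 0, 0): 1.0, (0, 0, 2): 0.0})
        system = assemble_system(grid, props, bc, StressPeriod(1937, 1993))
        heads = solve_steady_state(system)
        props.porosity = np.zeros(grid.shape)
        with pytest.raises(ValueError, match="porosity"):
            cell_velocities(heads, grid, props, system)
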