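"""Particle-tracking tests: cell-transit closed form against a numerical
ODE oracle, seeding reproducibility, multi-period tracking, arrival and
private-well impact rules."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from plumeepi import tracker
from plumeepi.gwflow import GridSpec, StressPeriod, VelocityField, WellSpec
from plumeepi.tracker import (
    CAPTURED,
    DAYS_PER_YEAR,
    EXITED,
    STAGNANT,
    TIME_EXHAUSTED,
    Particle,
    ParticleTrack,
    detect_arrivals,
    pollock_step,
    private_well_impact,
    seed_particles,
    track_particle,
)


def grid1(nx=1, ny=1, nl=1, d=10.0, thick=10.0):
    return GridSpec(
        n_rows=ny, n_cols=nx, n_layers=nl,
        dx=np.full(nx, d), dy=np.full(ny, d),
        layer_top=np.array([-i * thick for i in range(nl)], dtype=float),
        layer_bottom=np.array([-(i + 1) * thick for i in range(nl)], dtype=float),
    )


def field_for(grid, vx=0.0, vy=0.0, vz=0.0, vx_faces=None):
    """Uniform velocity field on a grid (optionally explicit x-face values)."""
    nl, nr, nc = grid.shape
    f = VelocityField(
        vx=np.full((nl, nr, nc + 1), vx, dtype=float),
        vy=np.full((nl, nr + 1, nc), vy, dtype=float),
        vz=np.full((nl + 1, nr, nc), vz, dtype=float),
        net_flux=np.zeros(grid.shape),
    )
    if vx_faces is not None:
        f.vx[0, 0, :] = vx_faces
    return f


class TestSeeding:
    def test_reproducible_and_inside_cell(self, aquifer_model):
        grid = aquifer_model.grid
        cell = (0, 12, 6)
        p1 = seed_particles([cell], 4, 1937, 42, grid)
        p2 = seed_particles([cell], 4, 1937, 42, grid)
        assert len(p1) == 4
        (x1, x2), (y1, y2), (z1, z2) = grid.cell_bounds(*cell)
        for a, b in zip(p1, p2):
            assert a.position == b.position
            assert x1 <= a.position[0] <= x2 and y1 <= a.position[1] <= y2

    def test_one_particle_per_cell_counts(self, aquifer_model):
        parts = seed_particles([(0, 1, 1), (0, 2, 2)], 1, 1937, 0, aquifer_model.grid)
        assert len(parts) == 2
        assert {p.current_cell for p in parts} == {(0, 1, 1), (0, 2, 2)}

    def test_different_seed_same_strata_different_jitter(self, aquifer_model):
        a = seed_particles([(0, 3, 3)], 9, 1937, 1, aquifer_model.grid)
        b = seed_particles([(0, 3, 3)], 9, 1937, 2, aquifer_model.grid)
        # same stratification: positions close (within a stratum) but not equal
        da = np.array([p.position for p in a]) - np.array([p.position for p in b])
        assert np.abs(da).max() < 250.0 / 3  # within one stratum width
        assert np.abs(da).max() > 0

    def test_empty_source_rejected(self, aquifer_model):
        with pytest.raises(ValueError):
            seed_particles([], 4, 1937, 0, aquifer_model.grid)


class TestPollockStep:
    def test_uniform_flow_transit_time(self):
        g = grid1()
        f = field_for(g, vx=2.0)
        p = Particle((0.0, 5.0, -5.0), (0, 0, 0))
        exit_pt, te, nxt = pollock_step(p, f, g)
        assert te == pytest.approx(5.0)
        assert exit_pt[0] == pytest.approx(10.0)
        assert nxt == (0, 0, 1)

    def test_linear_field_matches_ode_oracle(self):
        # vx grows 1 -> 3 ft/day across 10 ft: closed form (1/A) ln(v2/v1)
        g = grid1()
        f = field_for(g, vx_faces=[1.0, 3.0])
        p = Particle((0.0, 5.0, -5.0), (0, 0, 0))
        _, te, _ = pollock_step(p, f, g)
        assert te == pytest.approx(np.log(3.0) / 0.2)

        def rhs(t, x):
            return 1.0 + 0.2 * x[0]

        def hit_face(t, x):
            return x[0] - 10.0

        hit_face.terminal = True
        sol = solve_ivp(rhs, (0, 100), [0.0], events=hit_face, rtol=1e-10, atol=1e-12)
        assert te == pytest.approx(sol.t_events[0][0], rel=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_linear_fields_match_ode_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = grid1()
        v1, v2 = rng.uniform(0.5, 5.0, 2)
        f = field_for(g, vx_faces=[v1, v2])
        x0 = rng.uniform(0.5, 9.5)
        p = Particle((x0, 5.0, -5.0), (0, 0, 0))
        _, te, _ = pollock_step(p, f, g)
        a = (v2 - v1) / 10.0

        def rhs(t, x):
            return v1 + a * x[0]

        def hit(t, x):
            return x[0] - 10.0

        hit.terminal = True
        sol = solve_ivp(rhs, (0, 1000), [x0], events=hit, rtol=1e-10, atol=1e-12)
        assert te == pytest.approx(sol.t_events[0][0], rel=1e-3)

    def test_internal_stagnation_point_is_stagnant(self):
        g = grid1()
        f = field_for(g, vx_faces=[-1.0, 1.0])
        p = Particle((5.0, 5.0, -5.0), (0, 0, 0))
        _, te, nxt = pollock_step(p, f, g)
        assert nxt is None and not np.isfinite(te)


class TestTrackParticle:
    def test_uniform_flow_straight_polyline(self):
        g = grid1(nx=10, d=100.0)
        per = StressPeriod(1937, 1993)
        f = field_for(g, vx=100.0)
        p = Particle((0.0, 50.0, -5.0), (0, 0, 0), release_year=1937)
        t = track_particle(p, [(per, f)], 56, g, [])
        assert t.terminal_status == EXITED
        assert t.final_time == pytest.approx(10.0)  # 1000 ft at 100 ft/day
        ys = {v[1] for v in t.vertices}
        assert ys == {50.0}

    def test_reversed_second_period_returns_particle(self):
        g = grid1(nx=10, d=100.0)
        f_fwd = field_for(g, vx=1.0)
        f_rev = field_for(g, vx=-1.0)
        p1 = StressPeriod(1937, 1938, ())
        p2 = StressPeriod(1938, 1939, ())
        p = Particle((50.0, 50.0, -5.0), (0, 0, 0), release_year=1937)
        t = track_particle(p, [(p1, f_fwd), (p2, f_rev)], 2.0, g, [])
        # one year forward (365.25 ft) then one reversed: back at the start
        x_end = t.vertices[-1][0]
        assert abs(x_end - 50.0) <= 1e-6

    def test_horizon_cut_gives_time_exhausted(self):
        g = grid1(nx=10, d=100.0)
        per = StressPeriod(1937, 1993)
        f = field_for(g, vx=1.0)
        p = Particle((0.0, 50.0, -5.0), (0, 0, 0), release_year=1937)
        t = track_particle(p, [(per, f)], 1.0, g, [])
        assert t.terminal_status == TIME_EXHAUSTED

    def test_calendar_gap_between_periods_rejected(self):
        g = grid1()
        f = field_for(g, vx=1.0)
        with pytest.raises(ValueError, match="gap"):
            track_particle(
                Particle((5.0, 5.0, -5.0), (0, 0, 0), release_year=1937),
                [(StressPeriod(1937, 1940), f), (StressPeriod(1950, 1960), f)],
                20, g, [],
            )

    def test_vertices_time_strictly_increasing_in_fixture(self, scenario_runs):
        for t in scenario_runs["high"]["tracks"]:
            times = [v[3] for v in t.vertices]
            assert all(b > a for a, b in zip(times[:-1], times[1:]))

    def test_vertices_inside_domain(self, aquifer_model, scenario_runs):
        g = aquifer_model.grid
        for t in scenario_runs["high"]["tracks"]:
            for (x, y, z, _t) in t.vertices:
                assert g.x_edges[0] <= x <= g.x_edges[-1]
                assert g.y_edges[0] <= y <= g.y_edges[-1]
                assert g.layer_bottom[-1] <= z <= g.layer_top[0]


class TestArrivals:
    def _track_ending_at(self, cell_xyz, clock_days, release=1937):
        return ParticleTrack(
            vertices=[(0, 0, -5.0, 0.0), (*cell_xyz, clock_days)],
            terminal_status=CAPTURED, well_id="w", release_year=release,
        )

    def test_arrival_year_floor_rule(self):
        g = grid1(nx=10, d=100.0)
        w = WellSpec("w", (0, 0, 5), 100.0, 1937, 1993)
        t = self._track_ending_at((550.0, 50.0, -5.0), 3652.5)
        sched = detect_arrivals([t], [w], g)
        assert sched.first_impact_year["w"] == 1947

    def test_pass_through_without_termination_is_no_arrival(self):
        g = grid1(nx=10, d=100.0)
        w = WellSpec("w", (0, 0, 5), 100.0, 1937, 1993)
        # vertex inside the well cell but the track terminates elsewhere
        t = ParticleTrack(
            vertices=[(550.0, 50.0, -5.0, 100.0), (950.0, 50.0, -5.0, 200.0)],
            terminal_status=EXITED, well_id=None, release_year=1937,
        )
        sched = detect_arrivals([t], [w], g)
        assert sched.first_impact_year["w"] is None

    def test_capture_outside_operating_years_not_credited(self):
        g = grid1(nx=10, d=100.0)
        w = WellSpec("w", (0, 0, 5), 100.0, 1960, 1993)
        t = self._track_ending_at((550.0, 50.0, -5.0), 3652.5)  # 1947 < start 1960
        sched = detect_arrivals([t], [w], g)
        assert sched.first_impact_year["w"] is None

    def test_higher_rate_never_later_on_fixture(self, scenario_runs):
        lo = scenario_runs["low"]["schedule"].first_impact_year["straightway"]
        hi = scenario_runs["high"]["schedule"].first_impact_year["straightway"]
        assert lo is not None and hi is not None
        assert hi <= lo


class TestPrivateWellImpact:
    def _vertical_track(self, x, y, z, t_days=3652.5):
        return ParticleTrack(
            vertices=[(x, y, z, t_days)],
            terminal_status=TIME_EXHAUSTED, well_id=None, release_year=1937,
        )

    def test_track_within_depth_criterion_impacts(self, aquifer_model):
        g = aquifer_model.grid
        t = self._vertical_track(1625.0, 3125.0, -50.0)  # 50 ft below surface
        impacted, year = private_well_impact((1625.0, 3125.0), [t], g, 100.0)
        assert impacted and year == 1947

    def test_track_below_criterion_no_impact(self, aquifer_model):
        g = aquifer_model.grid
        wt = self._vertical_track(1625.0, 3125.0, -110.0)
        impacted, year = private_well_impact((1625.0, 3125.0), [wt], g, 100.0)
        assert not impacted and year is None

    def test_zero_criterion_requires_surface_contact(self, aquifer_model):
        g = aquifer_model.grid
        below = self._vertical_track(1625.0, 3125.0, -1.0)
        at_surface = self._vertical_track(1625.0, 3125.0, 0.0)
        assert not private_well_impact((1625.0, 3125.0), [below], g, 0.0)[0]
        assert private_well_impact((1625.0, 3125.0), [at_surface], g, 0.0)[0]

    def test_residence_outside_grid_rejected(self, aquifer_model):
        with pytest.raises(ValueError, match="outside"):
            private_well_impact((-100.0, -100.0), [], aquifer_model.grid, 100.0)

    def test_planar_map_agrees_with_pointwise_rule(self, aquifer_model, scenario_runs):
        g = aquifer_model.grid
        tracks = scenario_runs["high"]["tracks"]
        pmap = tracker.planar_impact_map(tracks, g, 100.0)
        assert pmap  # the plume touches shallow cells
        for (r, c), year in list(pmap.items())[:20]:
            x, y, _ = g.cell_center(0, r, c)
            impacted, first = private_well_impact((x, y), tracks, g, 100.0)
            assert impacted and first == year
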