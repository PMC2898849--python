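"""Semi-analytical advective particle tracking with first-arrival detection.

Within each grid cell the seepage velocity varies linearly per axis
between the two opposite face values, v(x) = v1 + A (x - x1) with
A = (v2 - v1) / dx.  The transit time to the exit face then has the
closed form te = ln(v_exit / v_p) / A (limit (x_exit - x_p) / v_p as
A -> 0); the exit face is the axis with the minimal positive te.  This is
the per-cell solution used by standard semi-analytical tracking codes.

Tracks are advanced through a calendar sequence of piecewise-steady
velocity fields (one per stress period); at a period boundary the
particle keeps its position and continues under the next field.  A
particle terminates when it enters a cell containing an active supply
well whose net flux is a sink (weak sinks are passed through), when it
enters a constant-head or inactive cell (domain exit), when all candidate
exit times vanish (stagnation), or when the tracking horizon is reached.

Indexing is (layer, row, col), layer 0 at top; x grows with column, y
with row, z is elevation.  Time is tracked in days; 365.25 days/year,
arrival years reported as the floor of the fractional calendar year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gwflow import SUPPLY, GridSpec, StressPeriod, VelocityField, WellSpec

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

CAPTURED = "captured_by_well"
EXITED = "exited_domain"
STAGNANT = "stagnant"
TIME_EXHAUSTED = "time_exhausted"

_EPS = 1e-12


@dataclass
class Particle:
    position: tuple[float, float, float]
    current_cell: tuple[int, int, int]
    clock: float = 0.0  # elapsed days since release
    release_year: float = 1937.0


@dataclass
class ParticleTrack:
    """Polyline of (x, y, z, t_days) vertices plus a terminal status."""

    vertices: list[tuple[float, float, float, float]]
    terminal_status: str
    well_id: str | None = None
    release_year: float = 1937.0

    @property
    def final_time(self) -> float:
        return self.vertices[-1][3]


@dataclass
class WellImpactSchedule:
    """First calendar year of effluent arrival per well, for one scenario."""

    scenario_id: str
    first_impact_year: dict[str, int | None] = field(default_factory=dict)


def seed_particles(
    source_cells: list[tuple[int, int, int]],
    n_per_cell: int,
    release_year: float,
    rng_seed: int,
    grid: GridSpec,
    jitter: float = 0.25,
) -> list[Particle]:
    """Place particles on a stratified lattice within each source cell.

    A near-square lattice of n_per_cell strata covers the cell's planar
    extent at mid-layer depth; the seeded RNG only jitters positions
    within each stratum, so runs are reproducible and strata stable
    across seeds.
    """
    if not source_cells:
        raise ValueError("empty source-cell set")
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    rng = np.random.default_rng(rng_seed)
    particles = []
    nx = int(np.ceil(np.sqrt(n_per_cell)))
    ny = int(np.ceil(n_per_cell / nx))
    for cell in source_cells:
        (x1, x2), (y1, y2), (z1, z2) = grid.cell_bounds(*cell)
        zmid = 0.5 * (z1 + z2)
        placed = 0
        for iy in range(ny):
            for ix in range(nx):
                if placed >= n_per_cell:
                    break
                fx = (ix + 0.5 + jitter * rng.uniform(-1, 1)) / nx
                fy = (iy + 0.5 + jitter * rng.uniform(-1, 1)) / ny
                particles.append(
                    Particle(
                        position=(x1 + fx * (x2 - x1), y1 + fy * (y2 - y1), zmid),
                        current_cell=cell,
                        clock=0.0,
                        release_year=release_year,
                    )
                )
                placed += 1
    return particles


def _axis_transit(v1: float, v2: float, vp: float, x1: float, x2: float, xp: float):
    """(te, exit_direction) along one axis; te=inf when no exit is reachable.

    exit_direction is +1 (high face) or -1 (low face).
    """
    a = (v2 - v1) / (x2 - x1)
    if vp > _EPS:
        if v2 > _EPS:  # reaches the high face
            if abs(a) < _EPS * max(abs(v1), abs(v2), 1.0) / (x2 - x1):
                return (x2 - xp) / vp, +1
            return np.log(v2 / vp) / a, +1
        return np.inf, 0  # decelerates into an internal stagnation point
    if vp < -_EPS:
        if v1 < -_EPS:
            if abs(a) < _EPS * max(abs(v1), abs(v2), 1.0) / (x2 - x1):
                return (x1 - xp) / vp, -1
            return np.log(v1 / vp) / a, -1
        return np.inf, 0
    return np.inf, 0  # locally stationary on this axis


def _axis_position(v1: float, v2: float, vp: float, x1: float, x2: float, xp: float, t: float) -> float:
    a = (v2 - v1) / (x2 - x1)
    if abs(a) < _EPS * max(abs(v1), abs(v2), 1.0) / (x2 - x1):
        x = xp + vp * t
    else:
        x = x1 + (vp * np.exp(a * t) - v1) / a
    return min(max(x, x1), x2)


def pollock_step(p: Particle, v: VelocityField, grid: GridSpec):
    """Advance one cell transit: returns (exit_point, exit_time_days, next_cell).

    ``next_cell`` is None when the particle is stagnant.  ``exit_time`` is
    the transit duration within the current cell (days).
    """
    l, r, c = p.current_cell
    (x1, x2), (y1, y2), (z1, z2) = grid.cell_bounds(l, r, c)
    (vx1, vx2), (vy1, vy2), (vz1, vz2) = v.face_velocities(l, r, c)
    xp, yp, zp = p.position

    tx, sx = _axis_transit(vx1, vx2, vx1 + (vx2 - vx1) * (xp - x1) / (x2 - x1), x1, x2, xp)
    ty, sy = _axis_transit(vy1, vy2, vy1 + (vy2 - vy1) * (yp - y1) / (y2 - y1), y1, y2, yp)
    tz, sz = _axis_transit(vz1, vz2, vz1 + (vz2 - vz1) * (zp - z1) / (z2 - z1), z1, z2, zp)

    te = min(tx, ty, tz)
    if not np.isfinite(te) or te <= 0:
        return p.position, np.inf, None

    vxp = vx1 + (vx2 - vx1) * (xp - x1) / (x2 - x1)
    vyp = vy1 + (vy2 - vy1) * (yp - y1) / (y2 - y1)
    vzp = vz1 + (vz2 - vz1) * (zp - z1) / (z2 - z1)
    xe = _axis_position(vx1, vx2, vxp, x1, x2, xp, te)
    ye = _axis_position(vy1, vy2, vyp, y1, y2, yp, te)
    ze = _axis_position(vz1, vz2, vzp, z1, z2, zp, te)

    dl = dr = dc = 0
    tol = te * (1 + 1e-9)
    if tx <= tol:
        dc = sx
        xe = x2 if sx > 0 else x1
    if ty <= tol:
        dr = sy
        ye = y2 if sy > 0 else y1
    if tz <= tol:
        # +z exit (upward) moves to the layer above (smaller index)
        dl = -sz
        ze = z2 if sz > 0 else z1
    next_cell = (l + dl, r + dr, c + dc)
    return (xe, ye, ze), te, next_cell


def _capture_cells(period: StressPeriod, wells: list[WellSpec], vfield: VelocityField):
    """Cells that terminate particles this period: active supply-well cells with net sink flux."""
    by_id = {w.well_id: w for w in wells}
    out = {}
    for well_id, _rate in period.active_wells:
        w = by_id[well_id]
        if w.role != SUPPLY:
            continue
        if vfield.net_flux is not None and vfield.net_flux[w.cell] >= 0:
            continue  # weak/non-sink: pass through
        out[w.cell] = well_id
    return out


def track_particle(
    p: Particle,
    period_fields: list[tuple[StressPeriod, VelocityField]],
    max_years: float,
    grid: GridSpec,
    wells: list[WellSpec],
    boundary_cells: set[tuple[int, int, int]] | None = None,
    max_steps: int = 200_000,
) -> ParticleTrack:
    """Track one particle through the calendar sequence of period fields."""
    if not period_fields:
        raise ValueError("no period fields supplied")
    periods = sorted(period_fields, key=lambda pf: pf[0].start_year)
    for (a, _), (b, _) in zip(periods[:-1], periods[1:]):
        if a.end_year != b.start_year:
            raise ValueError(
                f"calendar gap between stress periods {a.end_year} and {b.start_year}"
            )
    if p.release_year < periods[0][0].start_year:
        raise ValueError("release predates the first stress period")
    boundary_cells = boundary_cells or set()
    horizon_days = max_years * DAYS_PER_YEAR
    capture = {id(vf): _capture_cells(per, wells, vf) for per, vf in periods}

    part = Particle(p.position, p.current_cell, p.clock, p.release_year)
    verts = [(*part.position, part.clock)]
    status, well_hit = TIME_EXHAUSTED, None

    def field_at(t_days: float):
        year = part.release_year + t_days / DAYS_PER_YEAR
        for per, vf in periods:
            if per.start_year <= year < per.end_year:
                return per, vf
        return None, None

    steps = 0
    while part.clock < horizon_days and steps < max_steps:
        steps += 1
        per, vf = field_at(part.clock)
        if vf is None:
            status = TIME_EXHAUSTED
            break
        cap = capture[id(vf)]
        if part.current_cell in cap:
            status, well_hit = CAPTURED, cap[part.current_cell]
            break
        exit_pt, te, next_cell = pollock_step(part, vf, grid)
        if next_cell is None:
            status = STAGNANT
            break
        # clip the step at the earlier of period end and horizon
        period_end_days = (per.end_year - part.release_year) * DAYS_PER_YEAR
        t_stop = min(period_end_days, horizon_days)
        if part.clock + te > t_stop:
            dt = t_stop - part.clock
            l, r, c = part.current_cell
            (x1, x2), (y1, y2), (z1, z2) = grid.cell_bounds(l, r, c)
            (vx1, vx2), (vy1, vy2), (vz1, vz2) = vf.face_velocities(l, r, c)
            xp, yp, zp = part.position
            vxp = vx1 + (vx2 - vx1) * (xp - x1) / (x2 - x1)
            vyp = vy1 + (vy2 - vy1) * (yp - y1) / (y2 - y1)
            vzp = vz1 + (vz2 - vz1) * (zp - z1) / (z2 - z1)
            part.position = (
                _axis_position(vx1, vx2, vxp, x1, x2, xp, dt),
                _axis_position(vy1, vy2, vyp, y1, y2, yp, dt),
                _axis_position(vz1, vz2, vzp, z1, z2, zp, dt),
            )
            part.clock = t_stop
            verts.append((*part.position, part.clock))
            if part.clock >= horizon_days:
                status = TIME_EXHAUSTED
                break
            continue  # period rollover: same position, next field
        part.position = exit_pt
        part.clock += te
        verts.append((*part.position, part.clock))
        nl_, nr_, nc_ = grid.shape
        ll, rr, cc = next_cell
        if not (0 <= ll < nl_ and 0 <= rr < nr_ and 0 <= cc < nc_) or next_cell in boundary_cells:
            status = EXITED
            break
        part.current_cell = next_cell
    else:
        if steps >= max_steps:
            status = STAGNANT
            logger.warning("particle exceeded %d steps; marked stagnant", max_steps)

    return ParticleTrack(
        vertices=verts, terminal_status=status, well_id=well_hit, release_year=part.release_year
    )


def detect_arrivals(
    tracks: list[ParticleTrack],
    wells: list[WellSpec],
    grid: GridSpec,
    scenario_id: str = "default",
) -> WellImpactSchedule:
    """First-arrival calendar year per well from captured tracks.

    first_impact_year = floor(release_year + earliest capture clock /
    365.25) over all particles captured in that well's cell; a well is
    creditable only during its operating years; wells never reached map
    to None.
    """
    sched = WellImpactSchedule(scenario_id=scenario_id)
    for w in wells:
        if w.role != SUPPLY:
            continue
        years = []
        for t in tracks:
            if t.terminal_status == CAPTURED and t.well_id == w.well_id:
                year = int(np.floor(t.release_year + t.final_time / DAYS_PER_YEAR))
                if w.start_year <= year <= w.end_year:
                    years.append(year)
        sched.first_impact_year[w.well_id] = min(years) if years else None
    return sched


def private_well_impact(
    residence_location: tuple[float, float],
    tracks: list[ParticleTrack],
    grid: GridSpec,
    depth_criterion: float = 100.0,
) -> tuple[bool, int | None]:
    """Impact test for a private well at a residence.

    The residence is impacted when any track vertex lies in the planar
    grid cell containing it at a depth (below the land surface, the top
    of layer 0) no greater than the criterion; the first year is the
    floor of the earliest such vertex's calendar time.
    """
    row, col = grid.locate(*residence_location)  # raises outside the footprint
    xe, ye = grid.x_edges, grid.y_edges
    x1, x2 = xe[col], xe[col + 1]
    y1, y2 = ye[row], ye[row + 1]
    surface = grid.layer_top[0]
    best = None
    for t in tracks:
        for (x, y, z, td) in t.vertices:
            if x1 <= x <= x2 and y1 <= y <= y2 and (surface - z) <= depth_criterion:
                year = t.release_year + td / DAYS_PER_YEAR
                if best is None or year < best:
                    best = year
    if best is None:
        return False, None
    return True, int(np.floor(best))


def planar_impact_map(
    tracks: list[ParticleTrack],
    grid: GridSpec,
    depth_criterion: float = 100.0,
) -> dict[tuple[int, int], int]:
    """First impact year per planar cell touched by any track within depth.

    Vectorised companion to :func:`private_well_impact` used when many
    residences must be classified against the same track set.
    """
    surface = grid.layer_top[0]
    first: dict[tuple[int, int], float] = {}
    xe, ye = grid.x_edges, grid.y_edges
    for t in tracks:
        v = np.asarray(t.vertices)
        if v.size == 0:
            continue
        ok = (surface - v[:, 2]) <= depth_criterion
        if not ok.any():
            continue
        cols = np.clip(np.searchsorted(xe, v[ok, 0], side="right") - 1, 0, grid.n_cols - 1)
        rows = np.clip(np.searchsorted(ye, v[ok, 1], side="right") - 1, 0, grid.n_rows - 1)
        years = t.release_year + v[ok, 3] / DAYS_PER_YEAR
        xs, ys_ = v[ok, 0], v[ok, 1]
        for x, yy, r, c, y in zip(xs, ys_, rows, cols, years):
            r, c = int(r), int(c)
            # a vertex on a shared cell edge belongs to both neighbours
            cs = [c] + ([c - 1] if c > 0 and x == xe[c] else [])
            rs = [r] + ([r - 1] if r > 0 and yy == ye[r] else [])
            for ri in rs:
                for ci in cs:
                    key = (ri, ci)
                    if key not in first or y < first[key]:
                        first[key] = y
    return {k: int(np.floor(y)) for k, y in first.items()}


def tracks_to_frame(tracks: list[ParticleTrack]):
    """Flatten tracks to a DataFrame (track_id, vertex_index, x, y, z, t_days, calendar_year)."""
    import pandas as pd

    rows = []
    for i, t in enumerate(tracks):
        for j, (x, y, z, td) in enumerate(t.vertices):
            rows.append(
                (i, j, x, y, z, td, t.release_year + td / DAYS_PER_YEAR, t.terminal_status, t.well_id)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "track_id", "vertex_index", "x", "y", "z", "t_days",
            "calendar_year", "terminal_status", "well_id",
        ],
    )
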