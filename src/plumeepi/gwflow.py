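"""Block-centered finite-difference steady-state groundwater flow.

Solves the confined-equivalent steady-state flow equation on a structured
three-dimensional grid: inter-cell conductances are harmonic means of the
adjacent cells' hydraulic conductivities (half-cell series resistances),
constant-head cells are eliminated from the linear system, and areal
recharge plus well withdrawals/injections enter the right-hand side as
fixed volumetric rates.  Each historical stress period is solved as an
independent steady state; transients at period boundaries are ignored.

Indexing is (layer, row, col), 0-based, layer 0 at top, row 0 at the
origin edge.  Coordinates: x increases with column index, y with row
index, z is elevation (feet, positive up).  Units are feet and days
throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

logger = logging.getLogger(__name__)

SUPPLY = "supply"
EFFLUENT_SOURCE = "effluent_source"


class SingularSystemError(ValueError):
    """Raised when the flow system has no constant-head cell to anchor it."""


class ConvergenceError(RuntimeError):
    """Raised when the iterative solver fails to reach tolerance."""


@dataclass(frozen=True)
class GridSpec:
    """Structured block-centered grid geometry.

    dx is the cell width per column, dy per row (feet); layer_top and
    layer_bottom are elevations per layer (feet, positive up, layer 0
    shallowest); origin is the (x, y) corner of the row-0/col-0 cell.
    """

    n_rows: int
    n_cols: int
    n_layers: int
    dx: np.ndarray
    dy: np.ndarray
    layer_top: np.ndarray
    layer_bottom: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        dx = np.asarray(self.dx, dtype=float)
        dy = np.asarray(self.dy, dtype=float)
        top = np.asarray(self.layer_top, dtype=float)
        bot = np.asarray(self.layer_bottom, dtype=float)
        object.__setattr__(self, "dx", dx)
        object.__setattr__(self, "dy", dy)
        object.__setattr__(self, "layer_top", top)
        object.__setattr__(self, "layer_bottom", bot)
        if dx.shape != (self.n_cols,) or dy.shape != (self.n_rows,):
            raise ValueError("dx/dy lengths must match n_cols/n_rows")
        if top.shape != (self.n_layers,) or bot.shape != (self.n_layers,):
            raise ValueError("layer_top/layer_bottom lengths must match n_layers")
        if (dx <= 0).any() or (dy <= 0).any():
            raise ValueError("cell widths must be positive")
        if (top <= bot).any():
            raise ValueError("layer_top must exceed layer_bottom")
        if self.n_layers > 1 and (bot[:-1] < top[1:] - 1e-9).any():
            raise ValueError("layers must be ordered top-down and non-overlapping")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_layers, self.n_rows, self.n_cols)

    @property
    def thickness(self) -> np.ndarray:
        return self.layer_top - self.layer_bottom

    @property
    def x_edges(self) -> np.ndarray:
        return self.origin[0] + np.concatenate(([0.0], np.cumsum(self.dx)))

    @property
    def y_edges(self) -> np.ndarray:
        return self.origin[1] + np.concatenate(([0.0], np.cumsum(self.dy)))

    def cell_bounds(self, layer: int, row: int, col: int):
        """((x1, x2), (y1, y2), (z1, z2)) of a cell; z1 is the bottom."""
        xe, ye = self.x_edges, self.y_edges
        return (
            (xe[col], xe[col + 1]),
            (ye[row], ye[row + 1]),
            (self.layer_bottom[layer], self.layer_top[layer]),
        )

    def locate(self, x: float, y: float) -> tuple[int, int]:
        """Planar (row, col) of the cell containing (x, y)."""
        xe, ye = self.x_edges, self.y_edges
        if not (xe[0] <= x <= xe[-1] and ye[0] <= y <= ye[-1]):
            raise ValueError(f"point ({x}, {y}) lies outside the model footprint")
        col = min(int(np.searchsorted(xe, x, side="right")) - 1, self.n_cols - 1)
        row = min(int(np.searchsorted(ye, y, side="right")) - 1, self.n_rows - 1)
        return row, col

    def cell_center(self, layer: int, row: int, col: int) -> tuple[float, float, float]:
        (x1, x2), (y1, y2), (z1, z2) = self.cell_bounds(layer, row, col)
        return (0.5 * (x1 + x2), 0.5 * (y1 + y2), 0.5 * (z1 + z2))


@dataclass
class AquiferProperties:
    """Per-cell hydraulic conductivity (ft/day) and porosity (fraction)."""

    hydraulic_conductivity: np.ndarray
    porosity: np.ndarray

    def validate(self, grid: GridSpec) -> None:
        k = np.asarray(self.hydraulic_conductivity, dtype=float)
        n = np.asarray(self.porosity, dtype=float)
        if k.shape != grid.shape or n.shape != grid.shape:
            raise ValueError("property arrays must match the grid shape")
        if (k < 0).any():
            raise ValueError("hydraulic conductivity must be non-negative")
        if (n <= 0).any() or (n > 1).any():
            raise ValueError("porosity must lie in (0, 1]")
        self.hydraulic_conductivity = k
        self.porosity = n


@dataclass
class BoundaryConditions:
    """Fixed heads, areal recharge and inactive-cell mask.

    constant_head maps (layer, row, col) -> head (ft).  Recharge is a
    planar array (ft/day) applied to the top active layer.
    """

    constant_head: dict[tuple[int, int, int], float]
    recharge: np.ndarray | None = None
    inactive: np.ndarray | None = None

    def validate(self, grid: GridSpec) -> None:
        if not self.constant_head:
            raise SingularSystemError(
                "steady-state system is singular: no constant-head cell fixes the datum"
            )
        if self.recharge is None:
            self.recharge = np.zeros((grid.n_rows, grid.n_cols))
        self.recharge = np.asarray(self.recharge, dtype=float)
        if self.recharge.shape != (grid.n_rows, grid.n_cols):
            raise ValueError("recharge must be a planar (n_rows, n_cols) array")
        if not np.isfinite(self.recharge).all():
            raise ValueError("recharge must be finite")
        if self.inactive is None:
            self.inactive = np.zeros(grid.shape, dtype=bool)


@dataclass(frozen=True)
class WellSpec:
    """One well record: location, rated capacity, operating years and role.

    Supply wells withdraw; effluent sources inject.  ``pumping_rate``
    (ft^3/day, positive magnitude) is the rate actually applied; when None
    the rated capacity is used.  Pumping-scenario logic (fractions of
    rated capacity) is expressed by constructing WellSpecs with explicit
    pumping rates.
    """

    well_id: str
    cell: tuple[int, int, int]
    rated_capacity: float
    start_year: int
    end_year: int
    role: str = SUPPLY
    pumping_rate: float | None = None

    def __post_init__(self):
        if self.rated_capacity < 0:
            raise ValueError("rated_capacity must be >= 0")
        if self.start_year > self.end_year:
            raise ValueError(f"well {self.well_id}: start_year > end_year")
        if self.role not in (SUPPLY, EFFLUENT_SOURCE):
            raise ValueError(f"unknown well role {self.role!r}")

    @property
    def rate(self) -> float:
        return self.rated_capacity if self.pumping_rate is None else self.pumping_rate

    @property
    def signed_rate(self) -> float:
        """Volumetric source term: negative for supply (sink), positive for injection."""
        return -self.rate if self.role == SUPPLY else self.rate


@dataclass(frozen=True)
class StressPeriod:
    """Calendar interval with fixed pumping: covers years start_year..end_year-1."""

    start_year: int
    end_year: int
    active_wells: tuple[tuple[str, float], ...] = ()

    def __post_init__(self):
        if self.end_year <= self.start_year:
            raise ValueError("stress period must span at least one year")

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year


@dataclass
class HeadField:
    head: np.ndarray
    mass_balance_residual: float
    period: StressPeriod | None = None


@dataclass
class VelocityField:
    """Seepage velocities (ft/day) on cell faces, outward-positive per axis.

    vx has shape (nl, nr, nc+1): vx[l, r, c] is the velocity on the face
    between columns c-1 and c, positive toward increasing x (column).
    vy is (nl, nr+1, nc), positive toward increasing y (row).  vz is
    (nl+1, nr, nc), positive upward; vz[l] is the face above layer l.
    Each interior face stores a single shared value.
    """

    vx: np.ndarray
    vy: np.ndarray
    vz: np.ndarray
    net_flux: np.ndarray = field(default=None)  # per-cell net source (ft^3/day)

    def face_velocities(self, layer: int, row: int, col: int):
        """Per-axis (v_low_face, v_high_face) for one cell, +axis positive.

        For z the low face is the cell bottom (vz positive up), so the
        returned pair is (v_bottom, v_top).
        """
        return (
            (self.vx[layer, row, col], self.vx[layer, row, col + 1]),
            (self.vy[layer, row, col], self.vy[layer, row + 1, col]),
            (self.vz[layer + 1, row, col], self.vz[layer, row, col]),
        )


# ---------------------------------------------------------------------------
# stress-period construction


def build_stress_periods(
    wells: list[WellSpec],
    horizon: tuple[int, int],
    rates: dict[str, float] | None = None,
) -> list[StressPeriod]:
    """Split a calendar horizon into steady-state stress periods.

    Breakpoints fall at every supply-well start year and at the year after
    a well's retirement (its replacement year) within the horizon; each
    period lists the wells active throughout it with their applied rates.
    Wells whose operating interval lies wholly outside the horizon are
    excluded with a warning.
    """
    start, end = horizon
    if end <= start:
        raise ValueError("empty horizon")
    rates = rates or {}

    usable = []
    for w in wells:
        if w.end_year < start or w.start_year >= end:
            logger.warning("well %s operates outside horizon %s; excluded", w.well_id, horizon)
            continue
        usable.append(w)

    breaks = {start, end}
    for w in usable:
        if w.role != SUPPLY:
            continue
        if start < w.start_year < end:
            breaks.add(w.start_year)
        retire = w.end_year + 1
        if start < retire < end:
            breaks.add(retire)
    cuts = sorted(breaks)

    periods = []
    for s, e in zip(cuts[:-1], cuts[1:]):
        active = tuple(
            (w.well_id, rates.get(w.well_id, w.rate))
            for w in usable
            if w.start_year <= s and w.end_year >= e - 1
        )
        periods.append(StressPeriod(s, e, active))
    return periods


# ---------------------------------------------------------------------------
# system assembly


def _conductances(grid: GridSpec, props: AquiferProperties):
    """Face conductances (ft^2/day) from half-cell series resistances.

    For equal half-spacings this reduces to the harmonic mean of the two
    cell conductivities times face area over center distance.
    """
    k = props.hydraulic_conductivity
    nl, nr, nc = grid.shape
    dz = grid.thickness

    def series(k1, k2, d1, d2, area):
        with np.errstate(divide="ignore", invalid="ignore"):
            res = np.where(k1 > 0, d1 / np.where(k1 > 0, k1, 1.0), np.inf) + np.where(
                k2 > 0, d2 / np.where(k2 > 0, k2, 1.0), np.inf
            )
            c = np.where(np.isfinite(res), area / np.where(res > 0, res, np.inf), 0.0)
        return c

    # x faces between (.., c) and (.., c+1)
    area_x = grid.dy[None, :, None] * dz[:, None, None]  # (nl, nr, 1) broadcast
    cx = series(
        k[:, :, :-1],
        k[:, :, 1:],
        0.5 * grid.dx[None, None, :-1],
        0.5 * grid.dx[None, None, 1:],
        area_x * np.ones((nl, nr, nc - 1)) if nc > 1 else np.zeros((nl, nr, 0)),
    )
    area_y = grid.dx[None, None, :] * dz[:, None, None]
    cy = series(
        k[:, :-1, :],
        k[:, 1:, :],
        0.5 * grid.dy[None, :-1, None],
        0.5 * grid.dy[None, 1:, None],
        area_y * np.ones((nl, nr - 1, nc)) if nr > 1 else np.zeros((nl, 0, nc)),
    )
    area_z = grid.dy[None, :, None] * grid.dx[None, None, :] * np.ones((max(nl - 1, 0), nr, nc))
    cz = series(
        k[:-1, :, :],
        k[1:, :, :],
        0.5 * dz[:-1, None, None],
        0.5 * dz[1:, None, None],
        area_z,
    )
    return cx, cy, cz


@dataclass
class FlowSystem:
    """Assembled sparse steady-state system for one stress period."""

    grid: GridSpec
    props: AquiferProperties
    bc: BoundaryConditions
    period: StressPeriod
    matrix: sp.csr_matrix
    rhs: np.ndarray
    free_index: np.ndarray  # flat cell index per equation
    fixed_head: np.ndarray  # per-cell head with NaN on free cells
    conductances: tuple[np.ndarray, np.ndarray, np.ndarray]
    source: np.ndarray  # per-cell volumetric source term (ft^3/day)


def assemble_system(
    grid: GridSpec,
    props: AquiferProperties,
    bc: BoundaryConditions,
    period: StressPeriod,
    wells: list[WellSpec] | None = None,
) -> FlowSystem:
    """Assemble the symmetric sparse system for one stress period.

    One equation per active, non-constant-head cell.  Wells occupying a
    constant-head cell are a configuration error.
    """
    props.validate(grid)
    bc.validate(grid)
    nl, nr, nc = grid.shape
    n = nl * nr * nc

    fixed = np.full(grid.shape, np.nan)
    for cell, h in bc.constant_head.items():
        fixed[cell] = h
    active = ~bc.inactive
    is_fixed = ~np.isnan(fixed)
    free = active & ~is_fixed

    # volumetric sources: recharge on the top active layer + wells
    source = np.zeros(grid.shape)
    cell_area = grid.dy[:, None] * grid.dx[None, :]
    top_layer = np.argmax(active, axis=0)  # first active layer per column
    any_active = active.any(axis=0)
    rech_q = bc.recharge * cell_area
    for r in range(nr):
        for c in range(nc):
            if not any_active[r, c]:
                continue
            cell = (int(top_layer[r, c]), r, c)
            if cell in bc.constant_head:
                continue  # recharge on a fixed-head cell leaves the budget
            source[cell] += rech_q[r, c]

    wells_by_id = {w.well_id: w for w in (wells or [])}
    for well_id, rate in period.active_wells:
        w = wells_by_id.get(well_id)
        if w is None:
            raise KeyError(f"stress period references unknown well {well_id!r}")
        if w.cell in bc.constant_head:
            raise ValueError(f"well {well_id} occupies a constant-head cell")
        sign = -1.0 if w.role == SUPPLY else 1.0
        source[w.cell] += sign * rate

    cx, cy, cz = _conductances(grid, props)

    flat = np.arange(n).reshape(grid.shape)
    free_flat = flat[free]
    eq_of = np.full(n, -1, dtype=int)
    eq_of[free_flat] = np.arange(free_flat.size)

    if free_flat.size == 0:
        raise SingularSystemError("no free cells to solve for")

    rows, cols, vals = [], [], []
    diag = np.zeros(free_flat.size)
    rhs = source[free].astype(float).copy()

    def couple(cell_a, cell_b, cond):
        if cond == 0.0:
            return
        a_free = free[cell_a]
        b_free = free[cell_b]
        if not (active[cell_a] and active[cell_b]):
            return
        ia = flat[cell_a]
        ib = flat[cell_b]
        if a_free:
            diag[eq_of[ia]] += cond
            if b_free:
                rows.append(eq_of[ia])
                cols.append(eq_of[ib])
                vals.append(-cond)
            else:
                rhs[eq_of[ia]] += cond * fixed[cell_b]
        if b_free:
            diag[eq_of[ib]] += cond
            if a_free:
                rows.append(eq_of[ib])
                cols.append(eq_of[ia])
                vals.append(-cond)
            else:
                rhs[eq_of[ib]] += cond * fixed[cell_a]

    for l in range(nl):
        for r in range(nr):
            for c in range(nc - 1):
                couple((l, r, c), (l, r, c + 1), cx[l, r, c])
    for l in range(nl):
        for r in range(nr - 1):
            for c in range(nc):
                couple((l, r, c), (l, r + 1, c), cy[l, r, c])
    for l in range(nl - 1):
        for r in range(nr):
            for c in range(nc):
                couple((l, r, c), (l + 1, r, c), cz[l, r, c])

    m = free_flat.size
    mat = sp.coo_matrix(
        (np.concatenate([vals, diag]), (np.concatenate([rows, np.arange(m)]), np.concatenate([cols, np.arange(m)]))),
        shape=(m, m),
    ).tocsr()
    return FlowSystem(grid, props, bc, period, mat, rhs, free_flat, fixed, (cx, cy, cz), source)


# ---------------------------------------------------------------------------
# solve


def solve_steady_state(
    system: FlowSystem,
    rtol_factor: float = 1e-8,
    maxiter: int | None = None,
) -> HeadField:
    """Solve the assembled system by preconditioned conjugate gradients.

    The residual tolerance is ``rtol_factor`` times the maximum absolute
    stress (well + recharge + boundary-exchange magnitude); a direct
    sparse factorisation is used as fallback when CG stalls.
    """
    mat, rhs = system.matrix, system.rhs
    scale = max(np.abs(rhs).max(), np.abs(system.source).max(), 1.0)
    tol = rtol_factor * scale

    diag = mat.diagonal()
    precond = sp.diags(np.where(diag > 0, 1.0 / np.where(diag > 0, diag, 1.0), 1.0))
    x, info = spla.cg(mat, rhs, rtol=0.0, atol=tol, maxiter=maxiter or 10 * mat.shape[0], M=precond)
    if info != 0:
        x = spla.spsolve(mat.tocsc(), rhs)
    resid = float(np.abs(mat @ x - rhs).max())
    if resid > max(tol, 1e-6 * scale):
        raise ConvergenceError(f"flow solver residual {resid:.3e} exceeds tolerance {tol:.3e}")

    head = system.fixed_head.copy()
    head.flat[system.free_index] = x
    head[system.bc.inactive] = np.nan
    return HeadField(head=head, mass_balance_residual=resid, period=system.period)


def global_mass_balance(system: FlowSystem, heads: HeadField) -> tuple[float, float]:
    """(total inflow, total outflow) in ft^3/day over boundaries, wells, recharge."""
    inflow = outflow = 0.0
    # wells + recharge
    src = system.source
    inflow += src[src > 0].sum()
    outflow += -src[src < 0].sum()
    # constant-head exchange: net flux out of each fixed cell into free cells
    cx, cy, cz = system.conductances
    h = heads.head
    nl, nr, nc = system.grid.shape

    def face_flow(cell_a, cell_b, cond):
        # flow from a to b (ft^3/day)
        return cond * (h[cell_a] - h[cell_b])

    # water leaving a constant-head cell into the domain is an inflow to
    # the flow system; water arriving at the cell is an outflow.
    inflow_b = outflow_b = 0.0
    for cell in system.bc.constant_head:
        l, r, c = cell
        q = 0.0
        if c + 1 < nc:
            q += face_flow(cell, (l, r, c + 1), cx[l, r, c])
        if c - 1 >= 0:
            q += face_flow(cell, (l, r, c - 1), cx[l, r, c - 1])
        if r + 1 < nr:
            q += face_flow(cell, (l, r + 1, c), cy[l, r, c])
        if r - 1 >= 0:
            q += face_flow(cell, (l, r - 1, c), cy[l, r - 1, c])
        if l + 1 < nl:
            q += face_flow(cell, (l + 1, r, c), cz[l, r, c])
        if l - 1 >= 0:
            q += face_flow(cell, (l - 1, r, c), cz[l - 1, r, c])
        if q > 0:
            inflow_b += q
        else:
            outflow_b += -q
    return inflow + inflow_b, outflow + outflow_b


# ---------------------------------------------------------------------------
# velocities


def cell_velocities(
    heads: HeadField,
    grid: GridSpec,
    props: AquiferProperties,
    system: FlowSystem,
) -> VelocityField:
    """Face seepage velocities from the converged head field.

    Darcy flux across a face is conductance x head difference / face
    area; seepage velocity divides by the porosity of the cell the water
    enters (downstream cell).  Domain-boundary outer faces are no-flow.
    """
    if (props.porosity <= 0).any():
        raise ValueError("porosity must be positive for velocity computation")
    nl, nr, nc = grid.shape
    cx, cy, cz = system.conductances
    h = np.nan_to_num(heads.head, nan=0.0)
    dz = grid.thickness

    vx = np.zeros((nl, nr, nc + 1))
    area = grid.dy[None, :, None] * dz[:, None, None] * np.ones((nl, nr, nc - 1))
    if nc > 1:
        qx = cx * (h[:, :, :-1] - h[:, :, 1:])  # ft^3/day, positive toward +x
        n_down = np.where(qx >= 0, props.porosity[:, :, 1:], props.porosity[:, :, :-1])
        vx[:, :, 1:-1] = qx / (area * n_down)

    vy = np.zeros((nl, nr + 1, nc))
    if nr > 1:
        area = grid.dx[None, None, :] * dz[:, None, None] * np.ones((nl, nr - 1, nc))
        qy = cy * (h[:, :-1, :] - h[:, 1:, :])
        n_down = np.where(qy >= 0, props.porosity[:, 1:, :], props.porosity[:, :-1, :])
        vy[:, 1:-1, :] = qy / (area * n_down)

    vz = np.zeros((nl + 1, nr, nc))
    if nl > 1:
        area = grid.dy[None, :, None] * grid.dx[None, None, :] * np.ones((nl - 1, nr, nc))
        # positive upward: flow from layer l+1 (below) to l (above)
        qz = cz * (h[1:, :, :] - h[:-1, :, :])
        n_down = np.where(qz >= 0, props.porosity[:-1, :, :], props.porosity[1:, :, :])
        vz[1:-1, :, :] = qz / (area * n_down)

    # per-cell net source (ft^3/day): positive = net inflow from stresses, i.e.
    # the cell acts as a source; a pumped cell has negative net flux (sink).
    net = system.source.copy()
    return VelocityField(vx=vx, vy=vy, vz=vz, net_flux=net)


def solve_period(
    grid: GridSpec,
    props: AquiferProperties,
    bc: BoundaryConditions,
    period: StressPeriod,
    wells: list[WellSpec],
) -> tuple[HeadField, VelocityField]:
    """Assemble, solve and differentiate one stress period."""
    system = assemble_system(grid, props, bc, period, wells)
    heads = solve_steady_state(system)
    vel = cell_velocities(heads, grid, props, system)
    return heads, vel
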