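"""Synthetic study system: aquifer, well schedule, cohort, reference tables.

The confidential residential histories and the regional groundwater model
behind the original Cape Cod wastewater study cannot be redistributed, so
every pipeline stage is exercised against synthetic stand-ins with known
ground truth:

* a small unconfined-like sand aquifer (3 layers, uniform or lognormal
  conductivity) with a persistent wastewater discharge upgradient of
  three public supply wells whose start years (1953, 1961/1984, 1970)
  create the five historical stress periods 1937-1953-1961-1970-1984-1993;
* pumping scenarios expressed as fractions of the sensitivity well's
  rated capacity (96,250 ft^3/day): 30% = 28,875, 50% = 48,125 and
  75% = 72,188 ft^3/day;
* a case-control cohort (defaults: 638 cases, 842 controls, index years
  1983-1993, 1-6 addresses per subject) whose outcome is drawn from a
  logistic model with a configurable true exposure log-odds effect and a
  binary confounder correlated with both water source and outcome;
* the published contingency tables of the original study's analysis,
  frozen as machine-readable fixtures for verification.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gwflow, tracker
from .exposure import PRIVATE, PUBLIC, DistributionSystem, compute_exposure_table
from .epi import ContingencyTable
from .gwflow import (
    AquiferProperties,
    BoundaryConditions,
    GridSpec,
    StressPeriod,
    WellSpec,
    build_stress_periods,
    solve_period,
)

RATED_CAPACITY = 96_250.0  # ft^3/day; 30/50/75% give the scenario rates
SCENARIO_FRACTIONS = {"low": 0.30, "mid": 0.50, "high": 0.75}
HORIZON = (1937, 1993)
SUPPLIER_ID = "supplier_A"


@dataclass
class AquiferScenarioConfig:
    """Synthetic aquifer geometry and stress configuration."""

    n_rows: int = 24
    n_cols: int = 40
    n_layers: int = 3
    cell_size: float = 250.0  # ft
    layer_thickness: float = 40.0  # ft per layer
    conductivity: float = 250.0  # ft/day
    conductivity_sigma: float = 0.0  # lognormal sigma; 0 = uniform
    porosity: float = 0.35
    head_west: float = 4.0  # ft, constant-head inflow boundary
    head_east: float = 0.0  # ft, constant-head outflow boundary
    recharge: float = 0.002  # ft/day areal recharge
    source_cell: tuple[int, int, int] = (0, 12, 6)
    source_rate: float = 60_000.0  # ft^3/day effluent discharge
    scenario_fractions: dict = field(default_factory=lambda: dict(SCENARIO_FRACTIONS))
    seed: int = 0


@dataclass
class AquiferModel:
    grid: GridSpec
    props: AquiferProperties
    bc: BoundaryConditions
    wells: list[WellSpec]
    source_cells: list[tuple[int, int, int]]

    @property
    def boundary_cells(self) -> set[tuple[int, int, int]]:
        return set(self.bc.constant_head)


def _well_specs(cfg: AquiferScenarioConfig) -> list[WellSpec]:
    """Three supply wells + the effluent source.

    The sensitivity well ("straightway", replaced in 1984) carries no
    fixed rate here; scenarios set it as a fraction of rated capacity.
    The other two wells pump at 30% and 50% of the same rated capacity
    throughout their operation.
    """
    r0 = cfg.source_cell[1]
    return [
        WellSpec("hyannisport", (1, r0 - 2, 28), RATED_CAPACITY, 1953, 1993,
                 gwflow.SUPPLY, pumping_rate=0.30 * RATED_CAPACITY),
        WellSpec("straightway", (1, r0, 26), RATED_CAPACITY, 1961, 1983, gwflow.SUPPLY),
        WellSpec("straightway_repl", (1, r0, 26), RATED_CAPACITY, 1984, 1993, gwflow.SUPPLY),
        WellSpec("simmons_pond", (1, r0 + 2, 28), RATED_CAPACITY, 1970, 1993,
                 gwflow.SUPPLY, pumping_rate=0.50 * RATED_CAPACITY),
        WellSpec("effluent", cfg.source_cell, cfg.source_rate, 1937, 1993,
                 gwflow.EFFLUENT_SOURCE, pumping_rate=cfg.source_rate),
    ]


def generate_aquifer(cfg: AquiferScenarioConfig) -> AquiferModel:
    """Build the solvable synthetic aquifer for one configuration."""
    nl, nr, nc = cfg.n_layers, cfg.n_rows, cfg.n_cols
    tops = np.array([-i * cfg.layer_thickness for i in range(nl)], dtype=float)
    bots = tops - cfg.layer_thickness
    grid = GridSpec(
        n_rows=nr, n_cols=nc, n_layers=nl,
        dx=np.full(nc, cfg.cell_size), dy=np.full(nr, cfg.cell_size),
        layer_top=tops, layer_bottom=bots,
    )
    rng = np.random.default_rng(cfg.seed)
    if cfg.conductivity_sigma > 0:
        k = cfg.conductivity * rng.lognormal(
            -0.5 * cfg.conductivity_sigma**2, cfg.conductivity_sigma, grid.shape
        )
    else:
        k = np.full(grid.shape, cfg.conductivity)
    props = AquiferProperties(k, np.full(grid.shape, cfg.porosity))

    constant_head = {}
    for l in range(nl):
        for r in range(nr):
            constant_head[(l, r, 0)] = cfg.head_west
            constant_head[(l, r, nc - 1)] = cfg.head_east
    bc = BoundaryConditions(constant_head=constant_head,
                            recharge=np.full((nr, nc), cfg.recharge))
    bc.validate(grid)
    wells = _well_specs(cfg)
    return AquiferModel(grid, props, bc, wells, [cfg.source_cell])


def scenario_rates(cfg: AquiferScenarioConfig, scenario: str) -> dict[str, float]:
    """Applied pumping rate per well under one scenario."""
    frac = cfg.scenario_fractions[scenario]
    rates = {w.well_id: w.rate for w in _well_specs(cfg)}
    rates["straightway"] = frac * RATED_CAPACITY
    rates["straightway_repl"] = frac * RATED_CAPACITY
    return rates


def run_scenario(
    model: AquiferModel,
    cfg: AquiferScenarioConfig,
    scenario: str,
    n_particles_per_cell: int = 25,
    seed: int = 0,
    release_year: int = 1937,
):
    """Flow + tracking for one pumping scenario.

    Returns (stress periods, per-period (heads, velocities), tracks,
    impact schedule).
    """
    rates = scenario_rates(cfg, scenario)
    periods = build_stress_periods(model.wells, HORIZON, rates=rates)
    fields = []
    for per in periods:
        heads, vel = solve_period(model.grid, model.props, model.bc, per, model.wells)
        fields.append((per, vel, heads))
    period_fields = [(per, vel) for per, vel, _ in fields]
    particles = tracker.seed_particles(
        model.source_cells, n_particles_per_cell, release_year, seed, model.grid
    )
    max_years = HORIZON[1] - release_year
    tracks = [
        tracker.track_particle(p, period_fields, max_years, model.grid, model.wells,
                               boundary_cells=model.boundary_cells)
        for p in particles
    ]
    schedule = tracker.detect_arrivals(tracks, model.wells, model.grid, scenario_id=scenario)
    return periods, fields, tracks, schedule


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class CohortConfig:
    """Synthetic case-control cohort configuration.

    Defaults reproduce the shape of the original study population: 638
    cases and 842 controls with index years 1983-1993, most subjects at a
    single address (mobility 0.79 / 0.18 / 0.03 over 1, 2-3 and 4-6
    addresses), a public/private/bottled water mixture, and a true
    exposure log-odds effect plus one binary confounder correlated with
    both water source and outcome.
    """

    n_cases: int = 638
    n_controls: int = 842
    index_years: tuple[int, int] = (1983, 1993)
    true_or: float = 1.5
    confounder_or: float = 1.5
    confounder_prev: float = 0.30
    confounder_source_boost: float = 1.8  # multiplies supplier membership odds
    baseline_logit: float = -1.6
    p_supplier: float = 0.12  # per-residence probability of the impacted supplier
    p_private: float = 0.15
    p_bottled: float = 0.23  # subject-level ever-regular bottled water use
    mobility: tuple[float, float, float] = (0.79, 0.18, 0.03)
    history_start_years: tuple[int, int] = (1943, 1975)
    pool_factor: float = 4.0
    seed: int = 0


def _draw_index_years(rng, n, lo, hi):
    # mildly increasing weight toward later ascertainment years
    years = np.arange(lo, hi + 1)
    w = np.linspace(1.0, 1.6, len(years))
    return rng.choice(years, size=n, p=w / w.sum())


def generate_cohort(
    cfg: CohortConfig,
    schedule: tracker.WellImpactSchedule,
    grid: GridSpec | None = None,
    private_cell_first: dict[tuple[int, int], int] | None = None,
    supplier_wells: set[str] | None = None,
):
    """Draw a cohort whose outcome depends on true exposure through the pipeline.

    A subject pool is generated with residences, water sources and a
    binary confounder; *true* exposure (ever exposed at latency 0 under
    ``schedule``) is computed through the exposure module; case status is
    drawn from logit(p) = baseline + ln(true_or) * exposed +
    ln(confounder_or) * confounder; exactly n_cases cases and n_controls
    controls are then sampled (outcome-dependent sampling preserves the
    odds ratio).  Control index years are drawn from the same
    distribution as case diagnosis years.

    Returns (subjects, residences, systems, truth) where truth records
    the generating parameters and pool exposure rate.
    """
    rng = np.random.default_rng(cfg.seed)
    supplier_wells = supplier_wells or {
        w for w in schedule.first_impact_year if schedule.first_impact_year[w] is not None
    }
    system = DistributionSystem(SUPPLIER_ID, wells=set(supplier_wells))
    sup_first = {
        SUPPLIER_ID: min(
            (y for w, y in schedule.first_impact_year.items()
             if w in supplier_wells and y is not None),
            default=None,
        )
    }
    private_cell_first = private_cell_first or {}

    n_target = cfg.n_cases + cfg.n_controls
    n_pool = int(np.ceil(cfg.pool_factor * n_target))

    sid = np.array([f"S{i:06d}" for i in range(n_pool)])
    index_year = _draw_index_years(rng, n_pool, *cfg.index_years)
    confounder = rng.random(n_pool) < cfg.confounder_prev
    bottled = rng.random(n_pool) < cfg.p_bottled
    hist_start = rng.integers(cfg.history_start_years[0], cfg.history_start_years[1] + 1, n_pool)

    m_draw = rng.choice([0, 1, 2], size=n_pool, p=list(cfg.mobility))
    n_addr = np.where(m_draw == 0, 1, np.where(m_draw == 1, rng.integers(2, 4, n_pool),
                                               rng.integers(4, 7, n_pool)))

    # supplier membership odds boosted for confounder carriers
    p_sup = np.where(confounder, np.clip(cfg.p_supplier * cfg.confounder_source_boost, 0, 0.95),
                     cfg.p_supplier)

    res_rows = []
    for i in range(n_pool):
        k = int(n_addr[i])
        span_lo, span_hi = int(hist_start[i]), int(index_year[i])
        if k == 1:
            bounds = [span_lo, span_hi]
        else:
            cuts = np.sort(rng.choice(np.arange(span_lo + 1, span_hi), size=min(k - 1, span_hi - span_lo - 1), replace=False))
            bounds = [span_lo, *cuts.tolist(), span_hi]
        for j in range(len(bounds) - 1):
            s = bounds[j] if j == 0 else bounds[j] + 1
            e = bounds[j + 1]
            if s > e:
                continue
            u = rng.random()
            if u < p_sup[i]:
                src, supplier = PUBLIC, SUPPLIER_ID
                loc_rc = None
            elif u < p_sup[i] + cfg.p_private:
                src, supplier = PRIVATE, None
                if grid is not None:
                    loc_rc = (int(rng.integers(0, grid.n_rows)), int(rng.integers(1, grid.n_cols - 1)))
                else:
                    loc_rc = None
            else:
                src, supplier = PUBLIC, "supplier_other"
                loc_rc = None
            res_rows.append((sid[i], f"{sid[i]}_A{j}", s, e, src, supplier, loc_rc))

    residences = pd.DataFrame(
        res_rows,
        columns=["subject_id", "address_id", "start_year", "end_year",
                 "water_source", "supplier_id", "cell"],
    )
    if grid is not None:
        xy = residences["cell"].map(
            lambda rc: grid.cell_center(0, rc[0], rc[1])[:2] if rc is not None else (np.nan, np.nan)
        )
        residences["x"] = [p[0] for p in xy]
        residences["y"] = [p[1] for p in xy]
    else:
        residences["x"] = np.nan
        residences["y"] = np.nan

    priv_first = {
        row.address_id: private_cell_first[row.cell]
        for row in residences.itertuples()
        if row.water_source == PRIVATE and row.cell is not None and row.cell in private_cell_first
    }
    residences = residences.drop(columns=["cell"])

    pool_subjects = pd.DataFrame({"subject_id": sid, "index_year": index_year})
    exp0 = compute_exposure_table(
        pool_subjects, residences, sup_first, priv_first, latencies=(0,),
        scenario_id="generation",
    ).set_index("subject_id")["ever_exposed"]
    exposed = exp0.reindex(sid).fillna(False).to_numpy(dtype=bool)

    logit = (cfg.baseline_logit + np.log(cfg.true_or) * exposed
             + np.log(cfg.confounder_or) * confounder)
    p_case = 1.0 / (1.0 + np.exp(-logit))
    is_case = rng.random(n_pool) < p_case

    case_idx = np.flatnonzero(is_case)
    ctrl_idx = np.flatnonzero(~is_case)
    if len(case_idx) < cfg.n_cases or len(ctrl_idx) < cfg.n_controls:
        raise ValueError(
            "subject pool too small for the requested case/control counts; "
            "increase pool_factor"
        )
    pick_cases = rng.choice(case_idx, cfg.n_cases, replace=False)
    pick_ctrls = rng.choice(ctrl_idx, cfg.n_controls, replace=False)
    chosen = np.concatenate([pick_cases, pick_ctrls])

    subjects = pd.DataFrame({
        "subject_id": sid[chosen],
        "status": ["case"] * cfg.n_cases + ["control"] * cfg.n_controls,
        "index_year": index_year[chosen],
        "confounder": confounder[chosen].astype(int),
        "bottled_water_ever": bottled[chosen],
    })
    residences = residences[residences["subject_id"].isin(subjects["subject_id"])].reset_index(drop=True)
    truth = {
        "true_or": cfg.true_or,
        "confounder_or": cfg.confounder_or,
        "pool_exposure_rate": float(exposed.mean()),
        "pool_case_rate": float(is_case.mean()),
        "supplier_first_impact": sup_first[SUPPLIER_ID],
        "private_first_count": len(priv_first),
    }
    return subjects, residences, [system], truth


def private_first_years(
    residences: pd.DataFrame,
    grid: GridSpec,
    planar_map: dict[tuple[int, int], int],
) -> dict[str, int]:
    """address_id -> first impact year for private residences with locations.

    Locates each private residence's (x, y) in the grid and looks up the
    planar first-impact map derived from the particle tracks.
    """
    out = {}
    for r in residences.itertuples():
        if r.water_source == PRIVATE and np.isfinite(r.x):
            rc = grid.locate(r.x, r.y)
            if rc in planar_map:
                out[r.address_id] = planar_map[rc]
    return out


# ---------------------------------------------------------------------------
# published reference tables


@dataclass(frozen=True)
class ReferenceCell:
    """One published cell of the original study's crude-OR table.

    ``published`` is the printed "COR (low-high)" string, None where the
    original renders "-" (a zero cell).  ``discordant`` marks the three
    cells whose printed value differs by one unit in the last digit from
    the value implied by the printed counts themselves (no estimator can
    reproduce them from the counts; verified by hand arithmetic).
    """

    scenario: str
    latency: int
    contrast: str
    table: ContingencyTable
    published: str | None
    discordant: bool = False


def table2_fixture() -> list[ReferenceCell]:
    """Published counts and crude ORs of the original analysis.

    Referent (never exposed over the whole study period): 535 cases / 704
    controls in the low pumping scenario, 533 / 700 in the high scenario.
    """
    low = (535, 704)
    high = (533, 700)

    def cell(scn, lat, ct, a, b, published, discordant=False):
        c, d = low if scn == "low" else high
        return ReferenceCell(scn, lat, ct, ContingencyTable(a, b, c, d), published, discordant)

    return [
        cell("low", 0, "ever", 103, 138, "1.0 (0.7-1.3)"),
        cell("low", 0, ">0-5", 29, 44, "0.9 (0.5-1.4)"),
        cell("low", 0, ">5", 74, 94, "1.0 (0.7-1.4)"),
        cell("low", 0, ">10", 56, 65, "1.1 (0.8-1.6)"),
        cell("low", 10, "ever", 72, 83, "1.1 (0.8-1.6)"),
        cell("low", 10, ">0-5", 41, 56, "1.0 (0.6-1.5)"),
        cell("low", 10, ">5", 31, 27, "1.5 (0.9-2.6)"),
        cell("low", 10, ">10", 7, 2, "4.6 (1.0-22.3)"),
        cell("low", 15, "ever", 39, 32, "1.6 (1.0-2.6)"),
        cell("low", 15, ">0-5", 32, 30, "1.4 (0.8-2.3)"),
        cell("low", 15, ">5", 7, 2, "4.6 (1.0-22.3)"),
        cell("low", 15, ">10", 1, 0, None),
        cell("low", 20, "ever", 9, 2, "5.9 (1.3-27.5)"),
        cell("low", 20, ">0-5", 8, 2, "5.3 (1.1-24.9)"),
        cell("low", 20, ">5", 1, 0, None),
        cell("low", 20, ">10", 1, 0, None),
        cell("high", 0, "ever", 105, 142, "1.0 (0.7-1.3)"),
        cell("high", 0, ">0-5", 26, 47, "0.7 (0.4-1.2)"),
        cell("high", 0, ">5", 79, 95, "1.0 (0.8-1.5)", discordant=True),  # counts imply 1.1
        cell("high", 0, ">10", 58, 71, "1.1 (0.7-1.5)"),
        cell("high", 10, "ever", 74, 88, "1.1 (0.8-1.5)"),
        cell("high", 10, ">0-5", 25, 32, "1.0 (0.6-1.8)"),
        cell("high", 10, ">5", 49, 56, "1.1 (0.7-1.7)", discordant=True),  # counts imply CI-low 0.8
        cell("high", 10, ">10", 23, 19, "1.5 (0.9-2.9)", discordant=True),  # counts imply 1.6
        cell("high", 15, "ever", 57, 65, "1.2 (0.8-1.7)"),
        cell("high", 15, ">0-5", 31, 46, "0.9 (0.6-1.4)"),
        cell("high", 15, ">5", 26, 19, "1.8 (1.0-3.3)"),
        cell("high", 15, ">10", 5, 0, None),
        cell("high", 20, "ever", 31, 21, "1.9 (1.1-3.4)"),
        cell("high", 20, ">0-5", 25, 21, "1.6 (0.9-2.8)"),
        cell("high", 20, ">5", 6, 0, None),
        cell("high", 20, ">10", 1, 0, None),
    ]
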