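"""Residential-history exposure reconstruction.

Turns residential histories, well impact schedules and water-source
information into per-subject, per-latency exposure metrics.

Conventions (year resolution, both endpoints inclusive):

* A public residence is impacted in every calendar year >= the earliest
  first-impact year among its supplier's impacted wells (all customers of
  a supplier mixing water in a common standpipe are equally exposed).
* A private-well residence is impacted from the first year a tracked
  effluent particle passed within the depth criterion of its planar cell.
* A residence is *ever-exposed* when its impact years intersect its
  occupancy years; a subject is ever exposed with one or more years at an
  ever-exposed residence.
* Latency L is an induction criterion on the first exposed year: the
  subject counts as exposed at latency L only when
  first_exposed_year <= index_year - L; otherwise they are analysed as
  unexposed.  Duration is not truncated by latency.
* Cumulative duration (default convention) sums occupancy years at
  ever-exposed residences, truncated at the index year.  The alternative
  ``impacted-only`` convention counts only calendar years in which the
  residence's well was actually impacted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracker import WellImpactSchedule

logger = logging.getLogger(__name__)

PUBLIC = "public"
PRIVATE = "private_well"
UNKNOWN = "unknown"

DEFAULT_LATENCIES = (0, 10, 15, 20)
DURATION_DEFAULT = "default"
DURATION_IMPACTED_ONLY = "impacted-only"

CATEGORY_NEVER = "never"
CATEGORY_0_5 = ">0-5"
CATEGORY_GT5 = ">5"
CATEGORY_GT10 = ">10"


@dataclass(frozen=True)
class Residence:
    subject_id: str
    address_id: str
    location: tuple[float, float] | None
    start_year: int
    end_year: int
    water_source: str  # public | private_well | unknown
    supplier_id: str | None = None

    def __post_init__(self):
        if self.start_year > self.end_year:
            raise ValueError(
                f"residence {self.address_id}: start_year {self.start_year} > end_year {self.end_year}"
            )
        if self.water_source not in (PUBLIC, PRIVATE, UNKNOWN):
            raise ValueError(f"unknown water source {self.water_source!r}")


@dataclass(frozen=True)
class Subject:
    subject_id: str
    status: str  # "case" | "control"
    index_year: int
    covariates: dict = field(default_factory=dict)
    bottled_water_ever: bool = False

    def __post_init__(self):
        if self.status not in ("case", "control"):
            raise ValueError(f"status must be case/control, got {self.status!r}")


@dataclass
class DistributionSystem:
    """A public supplier: member addresses, supply wells, standpipe mixing."""

    supplier_id: str
    member_addresses: set[str] = field(default_factory=set)
    wells: set[str] = field(default_factory=set)
    mixing: bool = True


@dataclass
class ExposureRecord:
    subject_id: str
    scenario_id: str
    latency: int
    ever_exposed: bool
    duration: int
    first_exposed_year: int | None
    n_exposed_addresses: int


def assign_water_source(residence: Residence, systems: list[DistributionSystem]) -> Residence:
    """Resolve a residence's reported source against the supplier registry.

    Public residences must match a supplier by address membership (or
    carry an explicit supplier_id known to the registry); mismatches
    degrade to unknown with a warning.  Private and unknown pass through.
    """
    if residence.water_source != PUBLIC:
        return residence
    by_id = {s.supplier_id: s for s in systems}
    if residence.supplier_id and residence.supplier_id in by_id:
        return residence
    for s in systems:
        if residence.address_id in s.member_addresses:
            return Residence(
                residence.subject_id, residence.address_id, residence.location,
                residence.start_year, residence.end_year, PUBLIC, s.supplier_id,
            )
    logger.warning(
        "public residence %s matches no supplier; treated as unknown source", residence.address_id
    )
    return Residence(
        residence.subject_id, residence.address_id, residence.location,
        residence.start_year, residence.end_year, UNKNOWN, None,
    )


def supplier_first_impact(system: DistributionSystem, schedule: WellImpactSchedule) -> int | None:
    """Earliest first-impact year among a supplier's wells (mixed standpipe)."""
    years = [
        y for wid, y in schedule.first_impact_year.items()
        if wid in system.wells and y is not None
    ]
    return min(years) if years else None


def residence_impact_years(
    residence: Residence,
    schedule: WellImpactSchedule,
    systems: list[DistributionSystem],
    private_first_year: int | None = None,
) -> set[int]:
    """Calendar years in which the residence's drinking water was impacted.

    Public: occupancy years >= the supplier's earliest well impact year.
    Private: occupancy years >= the track-derived first impact year at
    the residence (``private_first_year``).  Unknown sources and
    never-impacted residences yield the empty set.
    """
    if residence.water_source == UNKNOWN:
        return set()
    if residence.water_source == PUBLIC:
        by_id = {s.supplier_id: s for s in systems}
        sys_ = by_id.get(residence.supplier_id)
        if sys_ is None:
            return set()
        first = supplier_first_impact(sys_, schedule)
    else:
        first = private_first_year
    if first is None:
        return set()
    lo = max(residence.start_year, first)
    if lo > residence.end_year:
        return set()
    return set(range(lo, residence.end_year + 1))


def subject_exposure(
    subject: Subject,
    residences: list[Residence],
    impact_years: dict[str, set[int]],
    latency: int,
    scenario_id: str = "default",
    duration_mode: str = DURATION_DEFAULT,
) -> ExposureRecord:
    """Latency-specific exposure status and cumulative duration for one subject.

    ``impact_years`` maps address_id -> set of impacted calendar years.
    Years after the index year never count; a residence wholly after the
    index year is dropped (with a warning when truncation occurs).
    """
    index = subject.index_year
    first_exposed = None
    duration = 0
    n_addr = 0
    for res in residences:
        years = impact_years.get(res.address_id, set())
        eff_years = {y for y in years if y <= index}
        if not eff_years:
            continue
        n_addr += 1
        res_first = min(eff_years)
        if first_exposed is None or res_first < first_exposed:
            first_exposed = res_first
        if res.end_year > index:
            logger.debug(
                "residence %s years after index %d truncated", res.address_id, index
            )
        if duration_mode == DURATION_DEFAULT:
            duration += min(res.end_year, index) - res.start_year + 1
        elif duration_mode == DURATION_IMPACTED_ONLY:
            duration += len(eff_years)
        else:
            raise ValueError(f"unknown duration mode {duration_mode!r}")

    exposed = first_exposed is not None and first_exposed <= index - latency
    return ExposureRecord(
        subject_id=subject.subject_id,
        scenario_id=scenario_id,
        latency=latency,
        ever_exposed=exposed,
        duration=duration if exposed else 0,
        first_exposed_year=first_exposed,
        n_exposed_addresses=n_addr if exposed else 0,
    )


def categorize_duration(record: ExposureRecord) -> list[str]:
    """Duration contrast categories a record belongs to.

    ``>5`` and ``>10`` deliberately overlap: each is contrasted against
    the never-exposed referent separately.
    """
    d = record.duration
    if d < 0:
        raise ValueError("negative exposure duration")
    if d == 0:
        return [CATEGORY_NEVER]
    cats = []
    if 0 < d <= 5:
        cats.append(CATEGORY_0_5)
    if d > 5:
        cats.append(CATEGORY_GT5)
    if d > 10:
        cats.append(CATEGORY_GT10)
    return cats


def nitrate_weighted_exposure(
    subject: Subject,
    residences: list[Residence],
    impact_years: dict[str, set[int]],
    nitrate_series: dict[str, dict[int, float]],
) -> float:
    """Concentration-weighted relative exposure score.

    Sums, over the subject's impacted residence-years up to the index
    year, the available nitrate-N concentrations (mg/L) across wells that
    year; missing years contribute zero (count logged).  The score is a
    scaled relative measure, not a dose.
    """
    score = 0.0
    missing = 0
    for res in residences:
        for y in sorted(impact_years.get(res.address_id, set())):
            if y > subject.index_year:
                continue
            total = None
            for series in nitrate_series.values():
                if y in series:
                    total = (total or 0.0) + series[y]
            if total is None:
                missing += 1
            else:
                score += total
    if missing:
        logger.debug("subject %s: %d impacted years missing nitrate data", subject.subject_id, missing)
    return score


def quartile_assignments(scores: pd.Series) -> pd.Series:
    """Quartile (1-4) among exposed subjects (positive scores); 0 otherwise."""
    out = pd.Series(0, index=scores.index, dtype=int)
    exposed = scores[scores > 0]
    if exposed.empty:
        return out
    q = exposed.rank(method="first").transform(
        lambda r: np.ceil(4 * r / len(exposed)).astype(int)
    )
    out.loc[exposed.index] = np.minimum(q, 4)
    return out


# ---------------------------------------------------------------------------
# vectorised table path (used by the pipeline and the simulation studies)


def compute_exposure_table(
    subjects: pd.DataFrame,
    residences: pd.DataFrame,
    supplier_first: dict[str, int | None],
    private_first: dict[str, int] | None = None,
    latencies: tuple[int, ...] = DEFAULT_LATENCIES,
    scenario_id: str = "default",
    duration_mode: str = DURATION_DEFAULT,
) -> pd.DataFrame:
    """Per-subject exposure records for every latency, vectorised.

    ``subjects`` needs columns subject_id, index_year; ``residences``
    needs subject_id, address_id, start_year, end_year, water_source,
    supplier_id.  ``supplier_first`` maps supplier_id to its first impact
    year; ``private_first`` maps address_id to the first year tracks
    impacted a private residence.  Unknown-source residences contribute
    nothing (their subjects remain in the denominator unless *all* their
    addresses are unknown, in which case callers may exclude them).
    """
    private_first = private_first or {}
    res = residences.merge(
        subjects[["subject_id", "index_year"]], on="subject_id", how="inner"
    ).copy()

    first = np.full(len(res), np.nan)
    is_public = res["water_source"].to_numpy() == PUBLIC
    sup = res["supplier_id"].map(lambda s: supplier_first.get(s) if pd.notna(s) else None)
    first[is_public] = sup[is_public].astype(float)
    is_private = res["water_source"].to_numpy() == PRIVATE
    priv = res["address_id"].map(lambda a: private_first.get(a))
    first[is_private] = priv[is_private].astype(float)
    res["first_impact"] = first

    idx = res["index_year"].to_numpy()
    start = res["start_year"].to_numpy()
    end = np.minimum(res["end_year"].to_numpy(), idx)  # index-year truncation
    impacted = (~np.isnan(first)) & (first <= end) & (start <= idx)
    res["res_first_exposed"] = np.where(impacted, np.maximum(start, np.nan_to_num(first, nan=-1)), np.nan)
    if duration_mode == DURATION_DEFAULT:
        res["dur_contrib"] = np.where(impacted, end - start + 1, 0)
    elif duration_mode == DURATION_IMPACTED_ONLY:
        res["dur_contrib"] = np.where(
            impacted, end - np.maximum(start, np.nan_to_num(first, nan=-1)) + 1, 0
        )
    else:
        raise ValueError(f"unknown duration mode {duration_mode!r}")

    agg = res.groupby("subject_id").agg(
        first_exposed_year=("res_first_exposed", "min"),
        duration=("dur_contrib", "sum"),
        n_exposed_addresses=("res_first_exposed", "count"),
    )
    table = subjects.merge(agg, on="subject_id", how="left")
    table["duration"] = table["duration"].fillna(0).astype(int)
    table["n_exposed_addresses"] = table["n_exposed_addresses"].fillna(0).astype(int)

    frames = []
    for lat in latencies:
        t = table.copy()
        ever = t["first_exposed_year"].notna() & (
            t["first_exposed_year"] <= t["index_year"] - lat
        )
        t["latency"] = lat
        t["ever_exposed"] = ever
        t["duration"] = np.where(ever, t["duration"], 0)
        t["n_exposed_addresses"] = np.where(ever, t["n_exposed_addresses"], 0)
        t["scenario_id"] = scenario_id
        frames.append(t)
    out = pd.concat(frames, ignore_index=True)
    cols = [
        "subject_id", "scenario_id", "latency", "ever_exposed", "duration",
        "first_exposed_year", "n_exposed_addresses",
    ]
    extra = [c for c in out.columns if c not in cols]
    return out[cols + extra]
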