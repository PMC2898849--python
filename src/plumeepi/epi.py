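"""Case-control effect estimation.

2x2 contingency tables, crude odds ratios with Woolf (log-OR) 95%
confidence intervals, covariate-adjusted odds ratios from multivariable
logistic regression, duration-category contrasts against a common
never-exposed referent, and bottled-water-stratified analyses.

The Woolf interval is exp(ln(ad/bc) +/- 1.96 sqrt(1/a + 1/b + 1/c + 1/d));
it is undefined (rendered "-") whenever any cell is zero — no continuity
correction is applied.  Display rounding is one decimal, half-up.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .exposure import (
    CATEGORY_0_5,
    CATEGORY_GT5,
    CATEGORY_GT10,
    CATEGORY_NEVER,
)

logger = logging.getLogger(__name__)

Z95 = 1.96  # conventional normal quantile used in the published intervals

CONTRAST_EVER = "ever"
CONTRASTS = (CONTRAST_EVER, CATEGORY_0_5, CATEGORY_GT5, CATEGORY_GT10)


@dataclass(frozen=True)
class ContingencyTable:
    """a: exposed cases, b: exposed controls, c: unexposed cases, d: unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.c

    @property
    def n_controls(self) -> int:
        return self.b + self.d


@dataclass
class ORResult:
    point: float | None
    ci_low: float | None
    ci_high: float | None
    method: str
    defined: bool

    def formatted(self) -> str:
        """'OR (low-high)' at one decimal, half-up; '-' when undefined."""
        if not self.defined:
            return "-"
        return f"{round_half_up(self.point)} ({round_half_up(self.ci_low)}-{round_half_up(self.ci_high)})"


@dataclass
class LogisticModel:
    coefficients: pd.Series
    cov: pd.DataFrame | None
    converged: bool
    exposure_term: str
    flagged: str | None = None  # separation / non-convergence note

    def odds_ratio(self, z: float = Z95) -> ORResult:
        if not self.converged or self.flagged:
            return ORResult(None, None, None, "adjusted_logistic", False)
        beta = self.coefficients[self.exposure_term]
        se = math.sqrt(self.cov.loc[self.exposure_term, self.exposure_term])
        return ORResult(
            math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se),
            "adjusted_logistic", True,
        )


def round_half_up(x: float, decimals: int = 1) -> str:
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def crude_or(t: ContingencyTable) -> ORResult:
    """Crude odds ratio (ad/bc) with the Woolf 95% interval."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return ORResult(None, None, None, "crude_woolf", False)
    point = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    lo = math.exp(math.log(point) - Z95 * se)
    hi = math.exp(math.log(point) + Z95 * se)
    return ORResult(point, lo, hi, "crude_woolf", True)


def build_table(
    subjects: pd.DataFrame,
    records: pd.DataFrame,
    contrast: str,
    latency: int,
    scenario_id: str,
) -> ContingencyTable:
    """2x2 table for one contrast against the never-exposed referent.

    The referent is subjects never exposed over the entire study period
    (ever_exposed false at latency 0 for the scenario) and is shared by
    every contrast at every latency.  Duration contrasts exclude subjects
    outside both the contrast category and the referent.
    """
    rec = records[records["scenario_id"] == scenario_id]
    at_l = rec[rec["latency"] == latency].set_index("subject_id")
    at_0 = rec[rec["latency"] == 0].set_index("subject_id")
    merged = subjects.set_index("subject_id")
    status = merged["status"]

    never = ~at_0["ever_exposed"].reindex(merged.index).fillna(False).astype(bool)
    if contrast == CONTRAST_EVER:
        in_contrast = at_l["ever_exposed"].reindex(merged.index).fillna(False).astype(bool)
    else:
        dur = at_l["duration"].reindex(merged.index).fillna(0)
        exp_ = at_l["ever_exposed"].reindex(merged.index).fillna(False).astype(bool)
        if contrast == CATEGORY_0_5:
            in_contrast = exp_ & (dur > 0) & (dur <= 5)
        elif contrast == CATEGORY_GT5:
            in_contrast = exp_ & (dur > 5)
        elif contrast == CATEGORY_GT10:
            in_contrast = exp_ & (dur > 10)
        else:
            raise ValueError(f"unknown contrast {contrast!r}")

    if not never.any():
        raise ValueError("empty never-exposed referent")
    a = int((in_contrast & (status == "case")).sum())
    b = int((in_contrast & (status == "control")).sum())
    c = int((never & (status == "case")).sum())
    d = int((never & (status == "control")).sum())
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# adjusted analysis

#: covariate -> reference level used when dummy-encoding; the exposure OR is
#: invariant to this choice, only covariate terms move.
DEFAULT_REFERENCES = {
    "age_category": "<49",
    "vital_status": "alive",
    "family_history": "no",
    "personal_history": "no",
    "age_first_birth": "<30",
    "education": ">12y",
    "race": "white",
    "study": "study1",
    "pce_ever": "never",
}


def encode_design(
    data: pd.DataFrame,
    exposure_col: str,
    covariates: list[str] | None = None,
    references: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Dummy-encode categorical covariates against stated reference levels."""
    covariates = covariates or []
    references = {**DEFAULT_REFERENCES, **(references or {})}
    design = pd.DataFrame(index=data.index)
    design["const"] = 1.0
    design[exposure_col] = data[exposure_col].astype(float)
    for cov in covariates:
        col = data[cov]
        if col.dtype.kind in "biufc":
            design[cov] = col.astype(float)
            continue
        ref = references.get(cov)
        levels = sorted(col.astype(str).unique())
        if ref is None or ref not in levels:
            ref = levels[0]
        for level in levels:
            if level != ref:
                design[f"{cov}[{level}]"] = (col.astype(str) == level).astype(float)
    return design


def fit_logistic(
    data: pd.DataFrame,
    exposure_col: str,
    outcome_col: str = "status",
    covariates: list[str] | None = None,
    references: dict[str, str] | None = None,
) -> LogisticModel:
    """Maximum-likelihood logistic fit (IRLS via statsmodels).

    Returns a flagged, estimate-free model on perfect separation or
    non-convergence, mirroring published tables that leave adjusted
    estimates blank when numbers are too small.
    """
    import statsmodels.api as sm

    y = data[outcome_col]
    if y.dtype == object:
        y = (y == "case").astype(float)
    X = encode_design(data, exposure_col, covariates, references)

    # quick separation screen on the exposure term
    ct = pd.crosstab(X[exposure_col] > 0, y > 0)
    if ct.shape != (2, 2) or (ct == 0).any().any():
        return LogisticModel(pd.Series(dtype=float), None, False, exposure_col,
                             flagged="separation: a 2x2 margin cell is empty")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(np.asarray(y, dtype=float), X).fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation raises inside statsmodels
        return LogisticModel(pd.Series(dtype=float), None, False, exposure_col, flagged=str(exc))
    if not res.mle_retvals.get("converged", False):
        return LogisticModel(pd.Series(dtype=float), None, False, exposure_col,
                             flagged="IRLS did not converge")
    return LogisticModel(
        coefficients=pd.Series(res.params, index=X.columns),
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        converged=True,
        exposure_term=exposure_col,
    )


def adjusted_or_for_table(
    subjects: pd.DataFrame,
    records: pd.DataFrame,
    contrast: str,
    latency: int,
    scenario_id: str,
    covariates: list[str] | None = None,
) -> ORResult:
    """Adjusted OR for one contrast, restricted to contrast + referent subjects."""
    rec = records[(records["scenario_id"] == scenario_id)]
    at_l = rec[rec["latency"] == latency].set_index("subject_id")
    at_0 = rec[rec["latency"] == 0].set_index("subject_id")
    df = subjects.set_index("subject_id").copy()
    never = ~at_0["ever_exposed"].reindex(df.index).fillna(False).astype(bool)
    exp_ = at_l["ever_exposed"].reindex(df.index).fillna(False).astype(bool)
    dur = at_l["duration"].reindex(df.index).fillna(0)
    if contrast == CONTRAST_EVER:
        in_contrast = exp_
    elif contrast == CATEGORY_0_5:
        in_contrast = exp_ & (dur > 0) & (dur <= 5)
    elif contrast == CATEGORY_GT5:
        in_contrast = exp_ & (dur > 5)
    elif contrast == CATEGORY_GT10:
        in_contrast = exp_ & (dur > 10)
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    sub = df[in_contrast | never].copy()
    sub["exposed"] = in_contrast[in_contrast | never].astype(float)
    model = fit_logistic(sub.reset_index(), "exposed", "status", covariates)
    return model.odds_ratio()


def stratified_analysis(
    subjects: pd.DataFrame,
    records: pd.DataFrame,
    latency: int,
    scenario_id: str,
    stratifier: str = "bottled_water_ever",
    contrast: str = CONTRAST_EVER,
) -> dict:
    """Crude ORs computed independently within each stratum of the stratifier."""
    out = {}
    for value, group in subjects.groupby(stratifier):
        try:
            table = build_table(group, records, contrast, latency, scenario_id)
            result = crude_or(table)
        except ValueError:
            table, result = None, ORResult(None, None, None, "crude_woolf", False)
        out[value] = {"n": len(group), "table": table, "or": result}
    return out


def run_analysis_grid(
    subjects: pd.DataFrame,
    records: pd.DataFrame,
    scenarios: list[str],
    latencies: tuple[int, ...] = (0, 10, 15, 20),
    contrasts: tuple[str, ...] = CONTRASTS,
    adjusted: bool = False,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """One row per (scenario, latency, contrast): counts, COR, optional AOR."""
    rows = []
    for sc in scenarios:
        for lat in latencies:
            for ct in contrasts:
                table = build_table(subjects, records, ct, lat, sc)
                cor = crude_or(table)
                row = {
                    "scenario_id": sc,
                    "latency": lat,
                    "contrast": ct,
                    "cases_exposed": table.a,
                    "controls_exposed": table.b,
                    "cases_unexposed": table.c,
                    "controls_unexposed": table.d,
                    "cor": cor.point,
                    "cor_low": cor.ci_low,
                    "cor_high": cor.ci_high,
                    "cor_defined": cor.defined,
                    "cor_formatted": cor.formatted(),
                }
                if adjusted:
                    aor = adjusted_or_for_table(subjects, records, ct, lat, sc, covariates)
                    row.update(
                        aor=aor.point, aor_low=aor.ci_low, aor_high=aor.ci_high,
                        aor_defined=aor.defined, aor_formatted=aor.formatted(),
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def render_grid(grid: pd.DataFrame) -> str:
    """Plain-text rendering of the analysis grid in the published layout."""
    lines = []
    for sc in grid["scenario_id"].unique():
        lines.append(f"Scenario: {sc}")
        sub = grid[grid["scenario_id"] == sc]
        for lat in sorted(sub["latency"].unique()):
            block = sub[sub["latency"] == lat]
            lines.append(f"  Latency {lat} y")
            counts = "   ".join(
                f"{r.contrast}: {r.cases_exposed}/{r.controls_exposed}"
                for r in block.itertuples()
            )
            cors = "   ".join(f"{r.contrast}: {r.cor_formatted}" for r in block.itertuples())
            lines.append(f"    case/control  {counts}")
            lines.append(f"    COR (95% CI)  {cors}")
    return "\n".join(lines)
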