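# Methods

This note documents the models, conventions and design choices behind
`plumeepi`, in the order the pipeline runs.

## Groundwater flow model

**Governing model.**  Steady-state saturated flow on a structured
block-centered grid: for each active cell, the sum of inter-cell flows
plus source terms is zero.  Inter-cell flow between neighbours i and j
is C_ij (h_i − h_j), where the conductance C_ij is the face area divided
by the series resistance of the two half-cells, L₁/(2K₁) + L₂/(2K₂) —
the harmonic-mean interblock conductivity for equal spacings.  Constant-
head cells are eliminated from the linear system (their contributions
move to the right-hand side), recharge enters the top active
non-fixed-head layer as rate × planar area, and wells enter as fixed
volumetric rates (supply wells negative, the effluent discharge
positive).  Units are feet and days throughout.

**Piecewise-steady stress periods.**  The pumping history is split at
every supply-well start year and at the year after a retirement
(replacement year); each period is solved as an independent steady
state and transients at period boundaries are ignored.  With wells
starting 1953, 1961, 1970 and a 1984 replacement inside a 1937–1993
horizon this yields the five periods 1937–1953–1961–1970–1984–1993.

**Numerics.**  The reduced system is symmetric positive definite and is
solved with Jacobi-preconditioned conjugate gradients to an absolute
residual of 10⁻⁸ × the maximum absolute stress, with a direct sparse
factorisation as fallback; convergence failure raises rather than
returning an unconverged field.  Saturated-thickness nonlinearity is
ignored (confined-equivalent transmissivity per layer): the verification
surfaces (Thiem drawdown, mass balance, scenario ordering) do not
require water-table iteration, and omitting it keeps each period's
system linear.  Verified properties: global mass balance closes to
10⁻⁶ × total inflow; drawdowns are linear in stresses; symmetric
configurations produce symmetric heads; the Thiem comparison error
decreases under grid refinement and is below 2% on a 65×65 grid.

**Velocities.**  Face Darcy flux is conductance × head difference /
face area; seepage velocity divides by porosity.  With heterogeneous
porosity the single stored face value uses the porosity of the cell the
water enters (downstream); for the uniform-porosity fixtures this is
exact.  Outer domain faces are no-flow; flow leaves through
constant-head cells.

## Particle tracking

Within a cell, each velocity component varies linearly between its two
face values, v(x) = v₁ + A(x − x₁) with A = (v₂ − v₁)/Δx.  The transit
time to a face is tₑ = ln(v_exit/v_p)/A, with the uniform-flow limit
(x_exit − x_p)/v as A → 0; the exit face is the axis with minimal
positive tₑ and the other coordinates follow the same closed form.  A
particle with no positive finite exit time (internal stagnation point)
terminates as stagnant.  Transit times agree with adaptive Runge–Kutta
integration of the same field to ≤ 10⁻³ relative error (observed
~10⁻¹¹).

Tracking runs across the calendar sequence of per-period fields: a step
that would cross a period boundary is cut at the boundary, the particle
keeps its position, and stepping resumes under the next field (no
interpolation between fields).  Termination: capture, domain exit
(constant-head or out-of-grid cell), stagnation, or horizon end.

**Capture and arrival.**  A particle terminates in a well cell only if
that cell's net stress flux is a sink in the current period (weak or
non-sink cells are passed through), and only wells active in the period
can capture.  A well's first-impact year is floor(release year +
earliest capture clock / 365.25) over its captured particles, credited
only within the well's operating years.  Particle density is 25 per
source cell by default on a stratified lattice whose seeded RNG only
jitters positions within strata; arrival is defined by the earliest
particle.  Doubling the density moves fixture arrival years by ≤ 1 year.

**Private wells.**  A residence on a private well is impacted from the
first calendar year a track vertex lies in its planar grid cell at a
depth ≤ 100 ft below the land surface (top of layer 0), the common
maximum depth for domestic wells in this kind of sand aquifer.  Vertices
suffice because every cell transit contributes entry and exit points in
that cell.

## Exposure reconstruction

Year-resolution, both endpoints inclusive.  Public residences matched to
a supplier inherit impact from the supplier's earliest impacted well
(mixed common standpipe ⇒ all customers equally exposed from that
year).  Unknown-source residences contribute nothing and are logged.

**Latency** is an induction criterion on the first exposed year: a
subject counts as exposed at latency L only if
first_exposed_year ≤ index_year − L; otherwise they are analysed as
unexposed.  Duration is *not* truncated at index − L: the alternative
(truncation) is inconsistent with long observed maxima at high
latencies, since pre-impact occupancy years at an ever-exposed residence
count toward duration.

**Duration** (default) sums occupancy years at ever-exposed residences
across all addresses, truncated at the index year; years after the
index year never count.  The stricter `impacted-only` mode counts only
calendar years in which the residence's source was actually impacted.
Both are implemented because the governing phrase "ever-exposed
residence years" admits either reading; the default is the one
consistent with observed duration maxima.  Duration contrast categories
are >0–5, >5 and >10 years; >5 and >10 deliberately overlap, each being
contrasted separately against the never-exposed referent.

**Bottled water** is a subject-level flag (not reported per residence);
it is used only to stratify, never to zero out exposure.  The
nitrate-weighted score sums available well nitrate-N concentrations
(mg/L) over a subject's impacted residence-years; quartiles are assigned
among exposed subjects only.

## Effect estimation

Crude OR = ad/bc with the Woolf interval
exp(ln OR ± 1.96 √(1/a+1/b+1/c+1/d)); any zero cell renders the
estimate undefined ("−") — no continuity correction, matching the
original table's blank cells.  Display rounding is one decimal,
half-up.  The referent for every contrast at every latency is the set
of subjects never exposed over the entire study period.

Adjusted ORs come from maximum-likelihood logistic regression
(statsmodels IRLS) with categorical covariates dummy-encoded against
declared reference levels; the exposure OR is invariant to the
reference choice.  Perfect separation or non-convergence yields a
flagged model with no estimate.  For a single binary predictor the
fitted exp(β) equals ad/bc to ≤ 10⁻⁶ relative error, which ties the two
estimators together in the tests.  Woolf intervals achieve 93–97%
empirical coverage over 2,000 simulated tables with expected cells ≥ 5.

## Synthetic study system

**Aquifer.**  3 layers × 24 rows × 40 columns of 250-ft cells (10,000 ×
6,000 ft footprint, 120 ft saturated thickness), uniform K = 250 ft/day
(lognormal heterogeneity available), porosity 0.35, constant heads 4 ft
(west) and 0 ft (east), recharge 0.002 ft/day.  These defaults were
chosen once to give a Cape-like ambient seepage velocity (≈ 0.4–0.5
ft/day), placing source-to-well travel times of the 5,000-ft well field
in the multi-decade range so that arrivals fall inside the 1937–1993
horizon after the wells come online.  The effluent discharge (60,000
ft³/day, one top-layer cell) operates from 1937; three supply wells
screen the middle layer: one fixed at 30% and one at 50% of the common
96,250 ft³/day rated capacity (starting 1953 and 1970), and the
sensitivity well (1961, replaced 1984) pumped at the scenario fraction —
30%, 50% or 75% of rated capacity, i.e. 28,875, 48,125 or 72,188
ft³/day.  On this fixture the sensitivity well's first impact is 1968 /
1967 / 1966 under the three fractions: higher pumping never delays
arrival.

**Cohort.**  Defaults: 638 cases, 842 controls, index years 1983–1993
drawn from a mildly late-weighted distribution shared by cases and
controls; residence counts 1 / 2–3 / 4–6 with probabilities 0.79 / 0.18 /
0.03; per-residence water source: impacted supplier 0.12, private well
0.15, other supplier otherwise; 23% of subjects ever regularly use
bottled water.  One binary confounder (prevalence 0.30) multiplies the
odds of living on the impacted supplier by 1.8 and carries its own
outcome effect (OR 1.5), creating genuine positive confounding.  True
exposure (ever exposed at latency 0, computed through the real exposure
module) enters the outcome logit with the configured effect
(default OR 1.5, baseline −1.6); exactly the requested numbers of cases
and controls are then sampled from a pool (outcome-dependent sampling
preserves the OR).  What the generator does **not** emulate: geocoded
street-level geography, supplier service-area polygons, interview
nonresponse/proxy error, partial-year occupancy, or exposure
misclassification — so passing tests demonstrate the estimator chain
and its calibration on clean histories, not robustness to the
measurement problems of real interview data.

**Calibration evidence.**  Over 200 replicates per effect size, the
confounder-adjusted 95% CI covers true ORs 1.0 / 1.5 / 2.0 at ≈ 93–97%,
with mean fitted AORs within ±0.05 of truth (see
`analysis/06_parameter_recovery.py` and `scripts/acceptance.py`).

## Published reference table

The original analysis's printed 2×2 counts (with never-exposed
referents 535/704 and 533/700) are frozen as machine-readable fixtures.
Recomputing every cell with the Woolf estimator reproduces 29 of 32
printed entries exactly at one-decimal rounding, including all zero-cell
"−" entries.  Three cells of the high-pumping scenario are internally
inconsistent with their own printed counts — the printed value differs
by one unit in the last digit from the value any estimator computes
from the counts (e.g. 79·700/(95·533) = 1.09 → 1.1 but 1.0 is printed).
These are characterised as such in the tests rather than matched.

## Problem sizes

Default test and acceptance runs use 9–25 particles per source cell, a
65×65 Thiem verification grid, 200-replicate recovery studies at cohort
sizes of 1,480, and full-pipeline runs at 360–460 subjects — sizes
chosen so the whole suite and the acceptance script each complete in
a couple of minutes on one CPU while leaving every qualitative result
(ordering, monotonicity, coverage) stable under doubling.

## Known limitations

Advection only — no dispersion, sorption, decay or concentration
estimates, so "impact" is a travel-time statement, not a dose.
Piecewise-steady flow ignores storage transients at period switches.
Confined-equivalent layers ignore water-table movement.  The latency
criterion treats late-first-exposed subjects as unexposed rather than
excluding them.  Single-particle arrival defines first impact; a
plume-fraction threshold would be later.
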